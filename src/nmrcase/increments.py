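"""Fast additive ¹³C (and rule-based ¹H) chemical-shift prediction.

This is the "fast" predictor of the two-tier evaluation scheme: an
additive increment model (base value per carbon class plus substituent
increments read off the topological environment), deterministic and
O(atoms) per molecule, used to score every generated candidate before
the slower HOSE-code predictor re-scores the head of the ranked list.

The increment values live in ``data/increments.yaml`` (editable
configuration); the code only interprets the environment classes.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import networkx as nx
import yaml

from .graph import MolecularGraph

__all__ = ["load_increment_table", "predict_c13_incremental", "predict_h1"]

_HALOGENS = {"F", "Cl", "Br", "I"}


def load_increment_table(path=None) -> dict:
    if path is None:
        text = resources.files("nmrcase.data").joinpath("increments.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return yaml.safe_load(text)


_TABLE_CACHE: Optional[dict] = None


def _default_table() -> dict:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = load_increment_table()
    return _TABLE_CACHE


def _cycle_atoms(g: MolecularGraph) -> set[int]:
    nxg = nx.Graph()
    nxg.add_nodes_from(range(len(g.atoms)))
    nxg.add_edges_from(g.bonds)
    atoms: set[int] = set()
    for cyc in nx.cycle_basis(nxg):
        atoms.update(cyc)
    return atoms


def _is_carbonyl(g: MolecularGraph, i: int) -> bool:
    return g.atoms[i].element == "C" and any(
        o == 2 and g.atoms[v].element == "O" for v, o in g.adjacency[i]
    )


def predict_c13_incremental(
    g: MolecularGraph, table: Optional[dict] = None
) -> list[Optional[float]]:
    """Predicted ¹³C shift per atom (None for heteroatoms)."""
    t = (table or _default_table())["c13"]
    in_cycle = _cycle_atoms(g)
    adj = g.adjacency
    out: list[Optional[float]] = [None] * len(g.atoms)
    for i, atom in enumerate(g.atoms):
        if atom.element != "C":
            continue
        triple = [v for v, o in adj[i] if o == 3]
        doubles = [v for v, o in adj[i] if o == 2]
        pi = g.pi_count(i)
        if triple:
            p = triple[0]
            if g.atoms[p].element == "N":
                out[i] = float(t["nitrile"]["base"])
            else:
                a = t["alkyne"]
                own = len(adj[i]) - 1
                far = len(adj[p]) - 1
                out[i] = a["base"] + a["alpha_c"] * own + a["far_c"] * far
        elif any(g.atoms[v].element == "O" for v in doubles):
            c = t["carbonyl"]
            single_nbrs = [v for v, o in adj[i] if o == 1]
            elems = [g.atoms[v].element for v in single_nbrs]
            if "O" in elems:
                val = c["ester"]
            elif "N" in elems:
                val = c["amide"]
            elif atom.hydrogens >= 1:
                val = c["aldehyde"]
            else:
                val = c["ketone"]
            if any(g.pi_count(v) > 0 for v in single_nbrs):
                val += c["extra_conjugation"]
            out[i] = float(val)
        elif any(g.atoms[v].element in ("N", "S") for v in doubles):
            out[i] = float(t["imine"]["base"])
        elif pi >= 2:
            out[i] = float(t["alkyne"]["base"])  # cumulated diene carbon
        elif pi == 1 and i in in_cycle:
            out[i] = _aromatic_shift(g, i, t["aromatic"], in_cycle)
        elif pi == 1:
            out[i] = _alkene_shift(g, i, doubles[0], t["alkene"])
        else:
            out[i] = _sp3_shift(g, i, t["sp3"])
    return out


def _sp3_shift(g: MolecularGraph, i: int, t: dict) -> float:
    dist = g.distances_from(i)
    val = float(t["base"])
    shells = ("alpha", "beta", "gamma", "delta")
    for j, atom in enumerate(g.atoms):
        d = dist[j]
        if 1 <= d <= 4:
            val += t[shells[d - 1]].get(atom.element, 0.0)
    return val


def _alkene_shift(g: MolecularGraph, i: int, partner: int, t: dict) -> float:
    val = float(t["base"])
    key = {"C": "c", "O": "o", "N": "n"}
    for v, _ in g.adjacency[i]:
        if v != partner:
            val += t.get("same_side_" + key.get(g.atoms[v].element, "c"), 0.0)
    for v, _ in g.adjacency[partner]:
        if v != i:
            val += t.get("far_side_" + key.get(g.atoms[v].element, "c"), 0.0)
    return val


def _substituent_class(g: MolecularGraph, s: int) -> str:
    e = g.atoms[s].element
    if e == "O":
        return "oxy"
    if e == "N":
        return "amino"
    if e in _HALOGENS:
        return "halogen"
    if _is_carbonyl(g, s):
        return "carbonyl"
    if g.pi_count(s) > 0:
        return "vinyl"
    return "alkyl"


def _aromatic_shift(g: MolecularGraph, i: int, t: dict, in_cycle: set[int]) -> float:
    # ring system: in-cycle atoms reachable from i through in-cycle atoms
    system = {i}
    stack = [i]
    while stack:
        u = stack.pop()
        for v, _ in g.adjacency[u]:
            if v in in_cycle and v not in system:
                system.add(v)
                stack.append(v)
    dist = g.distances_from(i)
    val = float(t["base"])
    for x in system:
        if x != i and g.atoms[x].element == "N" and 1 <= dist[x] <= 3:
            val += t["aza"][dist[x] - 1]
    for r in system:
        for s, _ in g.adjacency[r]:
            if s in system:
                continue
            pos = min(dist[r], 3)  # ipso/ortho/meta/para
            val += t[_substituent_class(g, s)][pos]
    return val


def predict_h1(g: MolecularGraph, table: Optional[dict] = None) -> list[Optional[float]]:
    """Predicted ¹H shift per atom for its attached protons (None when H=0)."""
    t = (table or _default_table())["h1"]
    in_cycle = _cycle_atoms(g)
    out: list[Optional[float]] = [None] * len(g.atoms)
    for i, atom in enumerate(g.atoms):
        if atom.element != "C" or atom.hydrogens == 0:
            continue
        pi = g.pi_count(i)
        if _is_carbonyl(g, i):
            out[i] = float(t["aldehyde_ch"])
        elif pi >= 2:
            out[i] = float(t["alkyne_ch"])
        elif pi == 1 and i in in_cycle:
            val = float(t["aromatic_ch"])
            for v, _ in g.adjacency[i]:
                if v in in_cycle and g.atoms[v].element == "N":
                    val += t["aromatic_aza_alpha"]
            out[i] = val
        elif pi == 1:
            out[i] = float(t["alkene_ch"])
        else:
            key = {1: "CH", 2: "CH2", 3: "CH3"}.get(min(atom.hydrogens, 3), "CH")
            val = float(t["sp3_base"][key])
            for v, _ in g.adjacency[i]:
                e = g.atoms[v].element
                if e == "O":
                    val += t["sp3_alpha"]["O"]
                elif e == "N":
                    val += t["sp3_alpha"]["N"]
                elif e in _HALOGENS:
                    val += t["sp3_alpha"]["halogen"]
                elif _is_carbonyl(g, v):
                    val += t["sp3_alpha"]["carbonyl"]
                elif g.pi_count(v) > 0 and v in in_cycle:
                    val += t["sp3_alpha"]["aryl"]
            out[i] = val
    return out
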