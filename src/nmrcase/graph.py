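"""Heavy-atom molecular graphs: validation, canonical forms, isomorphism.

A :class:`MolecularGraph` is the candidate-structure representation used
throughout: heavy atoms carry an element symbol, an attached-hydrogen
count and optionally an assigned ¹³C shift; bonds carry integer orders
1–3.  Aromatic rings are represented by alternating single/double bonds
(Kekulé form); two different Kekulé assignments of the same ring system
are distinct graphs here, exactly as they are distinct outputs of the
structure generator.

Canonicalization is by iterative colour refinement followed by
backtracking over the first non-singleton colour cell, taking the
lexicographically minimal adjacency encoding.  Equal keys hold iff the
graphs are isomorphic preserving element, hydrogen count and bond order.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .formula import DEFAULT_VALENCE, MolecularFormula

__all__ = [
    "Atom",
    "MolecularGraph",
    "GraphError",
    "canonical_key",
    "are_isomorphic",
    "automorphism_orbits",
]


class GraphError(ValueError):
    """Raised for graphs violating the molecular-graph invariants."""


@dataclass(frozen=True)
class Atom:
    element: str
    hydrogens: int = 0
    shift: Optional[float] = None  # assigned ¹³C shift, ppm

    def __post_init__(self) -> None:
        if self.element not in DEFAULT_VALENCE or self.element == "H":
            raise GraphError(f"unsupported heavy-atom element {self.element!r}")
        if self.hydrogens < 0:
            raise GraphError("negative hydrogen count")


class MolecularGraph:
    """Simple connected graph of heavy atoms with bond orders 1–3."""

    def __init__(
        self,
        atoms: Sequence[Atom],
        bonds: Iterable[tuple[int, int, int]] = (),
    ) -> None:
        self.atoms: list[Atom] = list(atoms)
        self.bonds: dict[tuple[int, int], int] = {}
        n = len(self.atoms)
        for i, j, order in bonds:
            if i == j:
                raise GraphError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise GraphError(f"bond ({i},{j}) references missing atom")
            if order not in (1, 2, 3):
                raise GraphError(f"bond order {order} outside 1..3")
            key = (i, j) if i < j else (j, i)
            if key in self.bonds:
                raise GraphError(f"duplicate bond between atoms {i} and {j}")
            self.bonds[key] = order
        self._adj: Optional[list[list[tuple[int, int]]]] = None

    # -- structural accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def adjacency(self) -> list[list[tuple[int, int]]]:
        """Per-atom list of (neighbor, bond order)."""
        if self._adj is None:
            adj: list[list[tuple[int, int]]] = [[] for _ in self.atoms]
            for (i, j), o in self.bonds.items():
                adj[i].append((j, o))
                adj[j].append((i, o))
            self._adj = adj
        return self._adj

    def bond_order_sum(self, i: int) -> int:
        return sum(o for _, o in self.adjacency[i])

    def pi_count(self, i: int) -> int:
        """Number of π bonds at atom i (order − 1 summed over bonds)."""
        return sum(o - 1 for _, o in self.adjacency[i])

    def formula(self) -> MolecularFormula:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
            counts["H"] = counts.get("H", 0) + a.hydrogens
        return MolecularFormula(counts)

    def is_connected(self) -> bool:
        n = len(self.atoms)
        if n == 0:
            return False
        seen = [False] * n
        seen[0] = True
        queue = deque([0])
        count = 1
        while queue:
            u = queue.popleft()
            for v, _ in self.adjacency[u]:
                if not seen[v]:
                    seen[v] = True
                    count += 1
                    queue.append(v)
        return count == n

    def validate(self, valence: Optional[dict[str, int]] = None) -> None:
        """Check valence conservation and connectedness.

        Per-atom: sum of bond orders + attached hydrogens must equal the
        element's declared valence.
        """
        if not self.atoms:
            raise GraphError("graph has no atoms")
        table = valence or DEFAULT_VALENCE
        for i, a in enumerate(self.atoms):
            want = table[a.element]
            got = self.bond_order_sum(i) + a.hydrogens
            if got != want:
                raise GraphError(
                    f"atom {i} ({a.element}H{a.hydrogens}) has valence {got}, expected {want}"
                )
        if not self.is_connected():
            raise GraphError("graph is disconnected")

    # -- distances ------------------------------------------------------------

    def distances_from(self, source: int) -> list[int]:
        """BFS skeletal bond distances from one atom (-1 when unreachable)."""
        dist = [-1] * len(self.atoms)
        dist[source] = 0
        queue = deque([source])
        while queue:
            u = queue.popleft()
            for v, _ in self.adjacency[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        return dist

    def distance(self, u: int, v: int) -> int:
        return self.distances_from(u)[v]

    # -- transformations ------------------------------------------------------

    def relabel(self, perm: Sequence[int]) -> "MolecularGraph":
        """Return the graph with atom i moved to position perm[i]."""
        n = len(self.atoms)
        atoms = [self.atoms[0]] * n
        for i, p in enumerate(perm):
            atoms[p] = self.atoms[i]
        bonds = [(perm[i], perm[j], o) for (i, j), o in self.bonds.items()]
        return MolecularGraph(atoms, bonds)

    def with_shifts(self, shifts: Sequence[Optional[float]]) -> "MolecularGraph":
        atoms = [replace(a, shift=s) for a, s in zip(self.atoms, shifts)]
        return MolecularGraph(atoms, [(i, j, o) for (i, j), o in self.bonds.items()])

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(self.atoms, [(i, j, o) for (i, j), o in self.bonds.items()])

    def __repr__(self) -> str:
        return f"<MolecularGraph {self.formula()} atoms={len(self.atoms)} bonds={len(self.bonds)}>"


# -- canonicalization ---------------------------------------------------------


def _refine(colors: list[int], adj: list[list[tuple[int, int]]]) -> list[int]:
    """Iterative neighbourhood colour refinement (1-WL with bond orders)."""
    n = len(colors)
    while True:
        sigs = [
            (colors[i], tuple(sorted((o, colors[v]) for v, o in adj[i])))
            for i in range(n)
        ]
        order = sorted(set(sigs))
        mapping = {s: k for k, s in enumerate(order)}
        new = [mapping[s] for s in sigs]
        if new == colors:
            return new
        colors = new


def _initial_colors(g: MolecularGraph) -> list[int]:
    sigs = [(a.element, a.hydrogens) for a in g.atoms]
    order = sorted(set(sigs))
    mapping = {s: k for k, s in enumerate(order)}
    return [mapping[s] for s in sigs]


def _encode(g: MolecularGraph, perm: list[int]) -> tuple:
    """Adjacency encoding of g under atom ordering perm (position → atom)."""
    pos = {a: p for p, a in enumerate(perm)}
    n = len(perm)
    rows: list[tuple] = []
    for p in range(n):
        a = perm[p]
        atom = g.atoms[a]
        row = [0] * n
        for v, o in g.adjacency[a]:
            row[pos[v]] = o
        rows.append((atom.element, atom.hydrogens, tuple(row[:p])))
    return tuple(rows)


def _canonical_search(g: MolecularGraph, colors: list[int]) -> tuple:
    n = len(g.atoms)
    adj = g.adjacency
    colors = _refine(colors, adj)
    # discrete partition: encoding is determined
    cells: dict[int, list[int]] = {}
    for i, c in enumerate(colors):
        cells.setdefault(c, []).append(i)
    target = None
    for c in sorted(cells):
        if len(cells[c]) > 1:
            target = cells[c]
            break
    if target is None:
        perm = sorted(range(n), key=lambda i: colors[i])
        return _encode(g, perm)
    best: Optional[tuple] = None
    nxt = max(colors) + 1
    for v in target:
        branch = list(colors)
        branch[v] = nxt
        enc = _canonical_search(g, branch)
        if best is None or enc < best:
            best = enc
    assert best is not None
    return best


def canonical_form(g: MolecularGraph) -> tuple:
    """Canonical adjacency encoding; equal iff graphs are isomorphic."""
    if not g.atoms:
        raise GraphError("cannot canonicalize an empty graph")
    if not g.is_connected():
        raise GraphError("cannot canonicalize a disconnected graph")
    return _canonical_search(g, _initial_colors(g))


def canonical_key(g: MolecularGraph) -> str:
    """Opaque canonical string; stable across atom relabelings."""
    return repr(canonical_form(g))


def canonical_order(g: MolecularGraph) -> list[int]:
    """A permutation perm (canonical position → atom index) realizing the
    canonical form: relabeling by it maps isomorphic graphs onto identical
    labeled graphs, which lets per-atom data (e.g. shifts) be averaged
    across instances of one fragment."""
    target = canonical_form(g)
    # recover a realizing order by trying refinement-consistent orders:
    # cheap re-derivation — encode candidate orders until one matches
    colors = _refine(_initial_colors(g), g.adjacency)
    n = len(g.atoms)

    def search(cols: list[int]) -> Optional[list[int]]:
        cols = _refine(cols, g.adjacency)
        cells: dict[int, list[int]] = {}
        for i, c in enumerate(cols):
            cells.setdefault(c, []).append(i)
        tgt = None
        for c in sorted(cells):
            if len(cells[c]) > 1:
                tgt = cells[c]
                break
        if tgt is None:
            perm = sorted(range(n), key=lambda i: cols[i])
            return perm if _encode(g, perm) == target else None
        nxt = max(cols) + 1
        for v in tgt:
            branch = list(cols)
            branch[v] = nxt
            got = search(branch)
            if got is not None:
                return got
        return None

    perm = search(colors)
    assert perm is not None
    return perm


def are_isomorphic(g1: MolecularGraph, g2: MolecularGraph) -> bool:
    """True iff the two graphs are isomorphic (element, H count, bond order)."""
    if not g1.atoms or not g2.atoms:
        raise GraphError("isomorphism on empty graph")
    if len(g1) != len(g2) or len(g1.bonds) != len(g2.bonds):
        return False
    return canonical_form(g1) == canonical_form(g2)


def automorphism_orbits(g: MolecularGraph) -> list[int]:
    """Orbit label per atom: atoms in one orbit are symmetry-equivalent.

    Computed by marking each atom in turn (the mark becomes part of the
    atom label, so it survives into the canonical encoding) and comparing
    the canonical forms of the marked graphs: equal forms hold iff an
    automorphism maps one marked atom to the other.  Quadratic in
    canonical-key cost, which is fine at skeleton scale.
    """
    marks: list[tuple] = []
    for i in range(len(g.atoms)):
        marked = [
            replace(a, hydrogens=a.hydrogens + 100) if j == i else a
            for j, a in enumerate(g.atoms)
        ]
        gi = MolecularGraph(marked, [(u, v, o) for (u, v), o in g.bonds.items()])
        marks.append(canonical_form(gi))
    order: dict[tuple, int] = {}
    out = []
    for m in marks:
        if m not in order:
            order[m] = len(order)
        out.append(order[m])
    return out
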