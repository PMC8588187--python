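"""Fragment mode: user fragment databases, spectrum search, MCD embedding.

For hydrogen-deficient molecules the correlation network alone leaves
the generator too much freedom.  Fragment mode shortcuts the search
with prior knowledge: assigned reference structures are cut into a
database of fragments (atom-centred spheres of radius 1–3 and complete
rings with their first shell — the same environments the HOSE predictor
keys on), the database is screened against the experimental ¹³C list
(every carbon of a found fragment must land on a distinct peak within
tolerance E, multiplicities compatible, no 2D correlation contradicted),
and compatible combinations of found fragments are projected onto the
MCD as fixed bonds, shrinking the generation problem to the remaining
skeleton.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .graph import Atom, MolecularGraph, canonical_key, canonical_order
from .mcd import MCD, ConnectivityConstraint, quick_feasible
from .nmr_io import CorrelationSet, Peak1D

__all__ = [
    "FragmentRecord",
    "FragmentSearchConfig",
    "FoundFragment",
    "build_user_fragment_db",
    "search_fragments",
    "embed_fragments",
]


@dataclass
class FragmentRecord:
    """A connected subgraph with assigned ¹³C shifts and open valences."""

    subgraph: MolecularGraph  # not valence-complete: attachment points open
    source: str = ""
    n_obs: int = 1  # instances merged into this record

    def __post_init__(self) -> None:
        if len(self.subgraph) < 2:
            raise ValueError("fragments need at least 2 heavy atoms")
        if not self.subgraph.is_connected():
            raise ValueError("fragments must be connected")
        for i, a in enumerate(self.subgraph.atoms):
            if a.element == "C" and a.shift is None:
                raise ValueError(f"fragment carbon {i} lacks an assigned shift")

    @property
    def key(self) -> str:
        return canonical_key(self.subgraph)


@dataclass(frozen=True)
class FragmentSearchConfig:
    E: float = 1.5  # ppm tolerance between fragment and experimental shifts
    min_fragments_per_mcd: int = 1
    max_found: int = 200  # found-fragment cap
    max_assignments: int = 100_000  # per-fragment assignment cap
    max_mcds: int = 50  # embedded MCD variants kept (ranked by coverage)

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("tolerance E must be > 0")


def _induced(g: MolecularGraph, atoms: Sequence[int]) -> MolecularGraph:
    atoms = sorted(set(atoms))
    index = {a: k for k, a in enumerate(atoms)}
    bonds = [
        (index[i], index[j], o)
        for (i, j), o in g.bonds.items()
        if i in index and j in index
    ]
    return MolecularGraph([g.atoms[a] for a in atoms], bonds)


def _candidate_atom_sets(g: MolecularGraph, size_cap: int) -> list[tuple[int, ...]]:
    """Sphere (radius 1–3) and ring+shell atom sets, capped by size."""
    out: set[tuple[int, ...]] = set()
    n = len(g.atoms)
    for center in range(n):
        dist = g.distances_from(center)
        for radius in (1, 2, 3):
            atoms = tuple(sorted(i for i in range(n) if 0 <= dist[i] <= radius))
            if 2 <= len(atoms) <= size_cap:
                out.add(atoms)
    nxg = nx.Graph()
    nxg.add_nodes_from(range(n))
    nxg.add_edges_from(g.bonds)
    for ring in nx.cycle_basis(nxg):
        shell = set(ring)
        for a in ring:
            shell.update(v for v, _ in g.adjacency[a])
        for atoms in (tuple(sorted(ring)), tuple(sorted(shell))):
            if 2 <= len(atoms) <= size_cap:
                out.add(atoms)
    return sorted(out)


def build_user_fragment_db(
    structures: Sequence[MolecularGraph],
    size_cap: int = 12,
    sources: Optional[Sequence[str]] = None,
) -> list[FragmentRecord]:
    """Cut every assigned structure into its sphere and ring fragments.

    Isomorphic fragments from different cut sites are merged; their
    per-atom shifts are averaged position-wise in canonical order.
    """
    merged: dict[str, FragmentRecord] = {}
    order: list[str] = []
    for s_idx, g in enumerate(structures):
        for i, a in enumerate(g.atoms):
            if a.element == "C" and a.shift is None:
                raise ValueError(f"structure {s_idx} carbon {i} is unassigned")
        label = sources[s_idx] if sources else str(s_idx)
        for atom_set in _candidate_atom_sets(g, size_cap):
            sub = _induced(g, atom_set)
            perm = canonical_order(sub)
            canon = sub.relabel([perm.index(i) for i in range(len(perm))])
            rec = FragmentRecord(canon, source=label)
            if rec.key not in merged:
                merged[rec.key] = rec
                order.append(rec.key)
            else:
                prev = merged[rec.key]
                n = prev.n_obs
                shifts = []
                for old, new in zip(prev.subgraph.atoms, canon.atoms):
                    if old.shift is None or new.shift is None:
                        shifts.append(old.shift)
                    else:
                        shifts.append((old.shift * n + new.shift) / (n + 1))
                merged[rec.key] = FragmentRecord(
                    prev.subgraph.with_shifts(shifts),
                    source=prev.source,
                    n_obs=n + 1,
                )
    return [merged[k] for k in order]


@dataclass
class FoundFragment:
    fragment: FragmentRecord
    assignments: list[dict[int, int]]  # fragment atom → ¹³C peak index
    best_max_delta: float = 0.0
    truncated: bool = False  # assignment cap was hit


def _peak_constraints(cs: CorrelationSet) -> list[tuple[int, int, int, int]]:
    """(peak_u, peak_v, d_lo, d_hi) between ¹³C peaks, from resolved 2D data."""
    carrier: dict[int, int] = {}
    for corr in cs.correlations:
        if corr.kind == "HSQC" and corr.peak_a is not None and not corr.ambiguous:
            carrier[corr.peak_a] = corr.peak_b
    out = []
    for corr in cs.correlations:
        if corr.ambiguous or corr.peak_a is None:
            continue
        n_lo, n_hi = cs.coupling_range(corr)
        if corr.kind == "COSY":
            if corr.peak_a in carrier and corr.peak_b in carrier:
                out.append((carrier[corr.peak_a], carrier[corr.peak_b], n_lo - 2, n_hi - 2))
        elif corr.kind == "HMBC":
            if corr.peak_a in carrier:
                out.append((carrier[corr.peak_a], corr.peak_b, n_lo - 1, n_hi - 1))
    return out


def search_fragments(
    db: Sequence[FragmentRecord],
    observed: Sequence[Peak1D],
    correlations: Optional[CorrelationSet] = None,
    cfg: FragmentSearchConfig = FragmentSearchConfig(),
) -> list[FoundFragment]:
    """Screen the fragment DB against the experimental ¹³C peak list.

    A fragment is found iff an injective carbon→peak map exists with
    |Δδ| ≤ E per carbon, compatible multiplicities, peak capacities
    (degeneracy) respected, and no resolved 2D correlation between
    mapped peaks contradicting the fragment's internal distances (an
    internal distance below a correlation's lower bound can only get
    shorter in the full molecule, hence is a contradiction).
    """
    if not observed:
        raise ValueError("observed peak list is empty")
    pcons = _peak_constraints(correlations) if correlations is not None else []
    found: list[FoundFragment] = []
    for rec in db:
        g = rec.subgraph
        carbons = [i for i, a in enumerate(g.atoms) if a.element == "C"]
        cand: dict[int, list[int]] = {}
        feasible = True
        for i in carbons:
            opts = [
                p for p, peak in enumerate(observed)
                if abs(peak.shift - g.atoms[i].shift) <= cfg.E
                and (peak.attached_h is None or peak.attached_h == g.atoms[i].hydrogens)
            ]
            if not opts:
                feasible = False
                break
            cand[i] = sorted(opts, key=lambda p: abs(observed[p].shift - g.atoms[i].shift))
        if not feasible:
            continue
        dists = {i: g.distances_from(i) for i in carbons}
        order = sorted(carbons, key=lambda i: len(cand[i]))
        assignments: list[dict[int, int]] = []
        used: dict[int, int] = {}
        current: dict[int, int] = {}
        truncated = False
        visited = 0

        def rec_assign(pos: int) -> bool:
            nonlocal visited, truncated
            visited += 1
            if visited > cfg.max_assignments:
                truncated = True
                return True
            if pos == len(order):
                assignments.append(dict(current))
                return False
            i = order[pos]
            for p in cand[i]:
                if used.get(p, 0) >= observed[p].degeneracy:
                    continue
                ok = True
                for (pu, pv, lo, _hi) in pcons:
                    # contradiction: both peaks inside the fragment but
                    # internally too close to ever satisfy the lower bound
                    mapped_u = [j for j, q in current.items() if q == pu]
                    mapped_v = [j for j, q in current.items() if q == pv]
                    if p == pu:
                        mapped_u.append(i)
                    if p == pv:
                        mapped_v.append(i)
                    if mapped_u and mapped_v:
                        dmin = min(
                            dists[a][b] for a in mapped_u for b in mapped_v if a != b
                        ) if any(a != b for a in mapped_u for b in mapped_v) else None
                        if dmin is not None and 0 <= dmin < lo:
                            ok = False
                            break
                if not ok:
                    continue
                current[i] = p
                used[p] = used.get(p, 0) + 1
                if rec_assign(pos + 1):
                    return True
                used[p] -= 1
                del current[i]
            return False

        rec_assign(0)
        if truncated and not assignments:
            continue  # combinatorial blow-up: fragment skipped
        if assignments:
            best = min(
                max(abs(observed[p].shift - g.atoms[i].shift) for i, p in asg.items())
                for asg in assignments
            )
            found.append(FoundFragment(rec, assignments, best, truncated))
        if len(found) >= cfg.max_found:
            break
    return found


def embed_fragments(
    mcd: MCD,
    found: Sequence[FoundFragment],
    cfg: FragmentSearchConfig = FragmentSearchConfig(),
) -> list[MCD]:
    """Project compatible found-fragment combinations onto the MCD.

    Each output MCD carries the internal bonds of one non-overlapping
    fragment combination (size ≥ min_fragments_per_mcd) as fixed bonds.
    Combinations are ranked by skeleton coverage and screened with the
    cheap consistency stages; at most ``max_mcds`` variants are kept.
    """
    if not found:
        return []
    peak_atoms: dict[int, list[int]] = {}
    for idx, a in enumerate(mcd.atoms):
        if a.peak is not None:
            peak_atoms.setdefault(a.peak, []).append(idx)
    hetero_pool = [
        idx for idx, a in enumerate(mcd.atoms) if a.element != "C"
    ]

    # flatten (fragment, assignment) choices
    choices: list[tuple[int, dict[int, int]]] = []
    for f_idx, ff in enumerate(found):
        for asg in ff.assignments:
            choices.append((f_idx, asg))

    def materialize(combo: Sequence[tuple[int, dict[int, int]]]) -> Optional[MCD]:
        used_atoms: set[int] = set()
        used_het: set[int] = set()
        fixed = list(mcd.fixed_bonds)
        for f_idx, asg in combo:
            g = found[f_idx].fragment.subgraph
            atom_map: dict[int, int] = {}
            taken: dict[int, int] = {}
            for i, a in enumerate(g.atoms):
                if a.element == "C":
                    peak = asg[i]
                    slots = [
                        s for s in peak_atoms.get(peak, ())
                        if s not in used_atoms and s not in atom_map.values()
                    ]
                    if not slots:
                        return None
                    atom_map[i] = slots[taken.get(peak, 0) % len(slots)]
                    taken[peak] = taken.get(peak, 0) + 1
                else:
                    slots = [
                        s for s in hetero_pool
                        if mcd.atoms[s].element == a.element
                        and s not in used_het and s not in used_atoms
                    ]
                    if not slots:
                        return None
                    atom_map[i] = slots[0]
                    used_het.add(slots[0])
            if used_atoms & set(atom_map.values()):
                return None
            used_atoms.update(atom_map.values())
            for (i, j), o in g.bonds.items():
                u, v = atom_map[i], atom_map[j]
                fixed.append((u, v, o) if u < v else (v, u, o))
        fixed = sorted(set(fixed))
        variant = MCD(mcd.formula, mcd.atoms, mcd.free_h, mcd.constraints, fixed)
        if not quick_feasible(variant).feasible:
            return None
        return variant

    scored: list[tuple[int, int, MCD]] = []
    seen_bonds: set[tuple] = set()
    max_size = min(len(choices), 4)
    for size in range(max(cfg.min_fragments_per_mcd, 1), max_size + 1):
        for combo in itertools.combinations(choices, size):
            if len({c[0] for c in combo}) != size:
                continue  # one assignment per fragment
            variant = materialize(combo)
            if variant is None:
                continue
            sig = tuple(sorted(variant.fixed_bonds))
            if sig in seen_bonds:
                continue
            seen_bonds.add(sig)
            coverage = len({a for u, v, _ in variant.fixed_bonds for a in (u, v)})
            scored.append((coverage, -len(scored), variant))
            if len(scored) >= cfg.max_mcds * 8:
                break
        if len(scored) >= cfg.max_mcds * 8:
            break
    if not scored and cfg.min_fragments_per_mcd > 1:
        return []
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [v for _, _, v in scored[: cfg.max_mcds]]
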