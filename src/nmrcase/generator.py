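"""Exhaustive constrained generation of constitutional isomers.

Given an MCD the generator enumerates every connected molecular graph
that satisfies, simultaneously:

* exact valences (Σ bond order + attached H = element valence),
* the hybridization π-bond budget per carbon (sp³ 0, sp² 1, sp 2),
* hetero-neighbour flags (*fb* forbidden / *ob* obligatory),
* every connectivity constraint (skeletal path length within its
  interval, disjunctively over degenerate atom groups),
* fixed (user or fragment) bonds,

and returns one representative per isomorphism class.  Free hydrogens
are distributed over the atoms whose H count the data did not fix.

The search walks the adjacency matrix row by row (pair (i,j) in
lexicographic order), deciding each bond order 0–3 once, so every
*labeled* graph is visited exactly once; duplicates can then only arise
from relabelings of interchangeable atoms and are removed by canonical
key.  Pruning is by admissible bounds only — remaining-valence caps,
row-exactness, dead components, and distance bounds in the "potential
graph" (current bonds plus every still-decidable pair) — so the output
is complete as well as sound.

Fuzzy structure generation re-runs this search over subsets of up to
*m* suspect connectivities, each elongated by *a* bonds (or deleted,
with the conventional sentinel a=16), and unions the results: the
remedy for non-standard correlations of unknown number and length.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field, replace
from math import comb
from typing import Iterator, Optional, Sequence

from .formula import DEFAULT_VALENCE, MolecularFormula
from .graph import Atom, MolecularGraph, canonical_key
from .mcd import MCD, ConnectivityConstraint, MCDAtom, quick_feasible

__all__ = [
    "GenerationOptions",
    "GenerationResult",
    "FSGOptions",
    "FSGResult",
    "DELETE_SENTINEL",
    "generate",
    "verify_candidate",
    "fuzzy_generate",
    "count_combinations",
    "brute_force_enumerate",
]

#: FSG convention: elongation parameter value meaning "delete the connectivity".
DELETE_SENTINEL = 16


@dataclass(frozen=True)
class GenerationOptions:
    max_structures: int = 200_000
    node_budget: int = 5_000_000  # search-tree nodes before giving up
    time_budget: Optional[float] = None  # seconds; None = unlimited
    explore_alt_valences: bool = False  # also try N(V) skeletons

    def __post_init__(self) -> None:
        if self.max_structures <= 0 or self.node_budget <= 0:
            raise ValueError("caps must be positive")


@dataclass
class GenerationResult:
    structures: list[MolecularGraph]
    complete: bool  # False when a cap or budget truncated the search
    nodes: int = 0
    elapsed: float = 0.0

    def __iter__(self):
        return iter(self.structures)

    def __len__(self):
        return len(self.structures)


class _Budget(Exception):
    pass


# -- the core labeled-graph search -------------------------------------------


class _Search:
    def __init__(
        self,
        elements: Sequence[str],
        hydrogens: Sequence[int],
        valences: Sequence[int],
        pi_allowed: Sequence[frozenset],
        hetero: Sequence[Optional[str]],
        constraints: Sequence[ConnectivityConstraint],
        fixed: dict[tuple[int, int], int],
        node_budget: int,
        deadline: Optional[float],
        emit=None,
        lex_tail: Sequence[int] = (),
    ) -> None:
        self.n = n = len(elements)
        self.elements = list(elements)
        self.h = list(hydrogens)
        self.rem = [valences[i] - hydrogens[i] for i in range(n)]
        self.max_pi = [max(p) for p in pi_allowed]
        self.pi_allowed = list(pi_allowed)
        self.pi_used = [0] * n
        self.hetero = list(hetero)
        self.is_het = [e != "C" for e in elements]
        self.adj: list[dict[int, int]] = [dict() for _ in range(n)]
        self.fixed = fixed
        self.pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        self.node_budget = node_budget
        self.deadline = deadline
        self.nodes = 0
        self.cons = [(c.pairs(), c.d_lo, c.d_hi) for c in constraints]
        self.cons_atoms = sorted(
            {a for c in constraints for a in c.group_u + c.group_v}
        )
        self.out: list[dict[tuple[int, int], int]] = []
        self.emit = emit if emit is not None else self.out.append
        # atoms v whose predecessor v-1 is interchangeable with v: the
        # adjacency row of v-1 must be lexicographically >= that of v
        # (columns v-1, v excluded) — adjacent-transposition symmetry
        # breaking that skips most duplicate labelings
        self.lex_tail = frozenset(lex_tail)

    # breadth-first distances over an adjacency-dict list
    def _bfs(self, adj: list[dict[int, int]], src: int) -> list[int]:
        dist = [-1] * self.n
        dist[src] = 0
        queue = [src]
        for u in queue:
            du = dist[u]
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue.append(v)
        return dist

    def _row_checks(self, i: int, next_pair: int) -> bool:
        """Checks fired when atom i's adjacency row is final."""
        if self.pi_used[i] not in self.pi_allowed[i]:
            return False
        if self.hetero[i] == "ob" and not any(self.is_het[v] for v in self.adj[i]):
            return False
        if i in self.lex_tail:
            u, v = i - 1, i
            for k in range(self.n):
                if k == u or k == v:
                    continue
                a, b = self.adj[u].get(k, 0), self.adj[v].get(k, 0)
                if a != b:
                    if a < b:
                        return False
                    break
        # dead-component prune: a finished component that is not everything
        seen = [False] * self.n
        for start in range(self.n):
            if seen[start]:
                continue
            comp = [start]
            seen[start] = True
            alive = self.rem[start] > 0
            for u in comp:
                for v in self.adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        alive = alive or self.rem[v] > 0
                        comp.append(v)
            if len(comp) < self.n and not alive:
                return False
        return self._constraint_checks(next_pair)

    def _constraint_checks(self, next_pair: int) -> bool:
        if not self.cons:
            return True
        n = self.n
        # current distances from every constraint atom
        cur = {u: self._bfs(self.adj, u) for u in self.cons_atoms}
        # potential graph: add every undecided pair with spare valence
        pot = [dict(d) for d in self.adj]
        rem = self.rem
        for k in range(next_pair, len(self.pairs)):
            a, b = self.pairs[k]
            if rem[a] > 0 and rem[b] > 0 and b not in pot[a]:
                fb_blocked = (self.hetero[a] == "fb" and self.is_het[b]) or (
                    self.hetero[b] == "fb" and self.is_het[a]
                )
                if fb_blocked and (a, b) not in self.fixed:
                    continue
                pot[a][b] = 1
                pot[b][a] = 1
        potd = {u: self._bfs(pot, u) for u in self.cons_atoms}
        for pairs, lo, hi in self.cons:
            ok = False
            for a, b in pairs:
                d_now = cur[a][b]
                if 0 <= d_now < lo:
                    continue  # distances only shrink: permanently too close
                d_min = potd[a][b]
                if d_min < 0 or d_min > hi:
                    continue  # can never get close enough
                ok = True
                break
            if not ok:
                return False
        return True

    def run(self) -> bool:
        """Exhaust the search; returns False when a budget truncated it."""
        if (sum(self.rem) % 2) != 0 or any(r < 0 for r in self.rem):
            return True
        if self.n > 1 and any(r == 0 for r in self.rem):
            return True  # an atom with no free valence cannot connect
        for (a, b), o in self.fixed.items():
            if o > min(self.rem[a], self.rem[b]):
                return True
            if o - 1 > min(self.max_pi[a] - self.pi_used[a], self.max_pi[b] - self.pi_used[b]):
                return True
        try:
            self._rec(0)
            return True
        except _Budget:
            return False

    def _rec(self, k: int) -> None:
        self.nodes += 1
        if self.nodes > self.node_budget:
            raise _Budget
        if self.deadline is not None and (self.nodes & 0x3FF) == 0:
            if time.monotonic() > self.deadline:
                raise _Budget
        if k == len(self.pairs):
            i = self.n - 1
            if self.n > 1 and self.rem[i] != 0:
                return
            if not self._row_checks(i, k):
                return
            if not self._final_check():
                return
            bonds = {}
            for a in range(self.n):
                for b, o in self.adj[a].items():
                    if a < b:
                        bonds[(a, b)] = o
            self.emit(bonds)
            return
        i, j = self.pairs[k]
        rem = self.rem
        last_of_row = j == self.n - 1
        fixed_o = self.fixed.get((i, j))
        max_o = min(3, rem[i], rem[j])
        # π headroom
        max_o = min(
            max_o,
            1 + self.max_pi[i] - self.pi_used[i],
            1 + self.max_pi[j] - self.pi_used[j],
        )
        fb_blocked = (self.hetero[i] == "fb" and self.is_het[j]) or (
            self.hetero[j] == "fb" and self.is_het[i]
        )
        for o in range(max_o, -1, -1):
            if fixed_o is not None and o != fixed_o:
                continue
            if fixed_o is None and o > 0 and fb_blocked:
                continue
            if last_of_row and rem[i] - o != 0:
                continue
            if not last_of_row and rem[i] - o > 3 * (self.n - 1 - j):
                continue  # atom i cannot place its remaining valence
            if o:
                self.adj[i][j] = o
                self.adj[j][i] = o
                rem[i] -= o
                rem[j] -= o
                self.pi_used[i] += o - 1
                self.pi_used[j] += o - 1
            ok = True
            if last_of_row:
                ok = self._row_checks(i, k + 1)
            if ok:
                self._rec(k + 1)
            if o:
                del self.adj[i][j]
                del self.adj[j][i]
                rem[i] += o
                rem[j] += o
                self.pi_used[i] -= o - 1
                self.pi_used[j] -= o - 1

    def _final_check(self) -> bool:
        # connectivity
        if self.n > 1:
            dist = self._bfs(self.adj, 0)
            if any(d < 0 for d in dist):
                return False
        # exact constraint intervals
        cache: dict[int, list[int]] = {}
        for pairs, lo, hi in self.cons:
            ok = False
            for a, b in pairs:
                if a not in cache:
                    cache[a] = self._bfs(self.adj, a)
                d = cache[a][b]
                if 0 <= d and lo <= d <= hi:
                    ok = True
                    break
            if not ok:
                return False
        return True


# -- hydrogen distribution ----------------------------------------------------


def _h_distributions(
    free_slots: Sequence[int], caps: Sequence[int], total: int
) -> Iterator[tuple[int, ...]]:
    """All ways to put `total` hydrogens on the open slots within caps."""
    if not free_slots:
        if total == 0:
            yield ()
        return

    def rec(idx: int, left: int, acc: list[int]) -> Iterator[tuple[int, ...]]:
        if idx == len(free_slots):
            if left == 0:
                yield tuple(acc)
            return
        tail_cap = sum(caps[idx:])
        if left > tail_cap:
            return
        for h in range(min(caps[idx], left) + 1):
            acc.append(h)
            yield from rec(idx + 1, left - h, acc)
            acc.pop()

    yield from rec(0, total, [])


def _skeleton_variants(mcd: MCD, options: GenerationOptions):
    """Yield (hydrogens, valences) per atom for every H/valence assignment."""
    n = len(mcd.atoms)
    base_val = [DEFAULT_VALENCE[a.element] for a in mcd.atoms]
    n_indices = [i for i, a in enumerate(mcd.atoms) if a.element == "N"]
    valence_choices = [base_val]
    if options.explore_alt_valences and n_indices:
        for picks in itertools.product([3, 5], repeat=len(n_indices)):
            if all(p == 3 for p in picks):
                continue
            val = list(base_val)
            for idx, p in zip(n_indices, picks):
                val[idx] = p
            valence_choices.append(val)
    for valences in valence_choices:
        open_slots = [i for i, a in enumerate(mcd.atoms) if a.hydrogens is None]
        caps = [valences[i] - (1 if n > 1 else 0) for i in open_slots]
        for dist in _h_distributions(open_slots, caps, mcd.free_h):
            hydrogens = [a.hydrogens or 0 for a in mcd.atoms]
            for slot, h in zip(open_slots, dist):
                hydrogens[slot] = h
            yield hydrogens, valences


# -- public API ---------------------------------------------------------------


def generate(mcd: MCD, options: Optional[GenerationOptions] = None) -> GenerationResult:
    """All non-isomorphic molecular graphs consistent with the MCD."""
    options = options or GenerationOptions()
    mcd.validate()
    t0 = time.monotonic()
    deadline = None if options.time_budget is None else t0 + options.time_budget
    fixed = {}
    for u, v, o in mcd.fixed_bonds:
        fixed[(u, v) if u < v else (v, u)] = o
    pi_allowed = []
    for a in mcd.atoms:
        if a.element == "C":
            cap = frozenset(p for p in a.prop.allowed_pi)
        else:
            cap = frozenset(range(0, 3))
        pi_allowed.append(cap)
    hetero = [a.prop.hetero if a.element == "C" else None for a in mcd.atoms]
    elements = [a.element for a in mcd.atoms]
    shifts = [a.shift for a in mcd.atoms]

    seen: set[str] = set()
    structures: list[MolecularGraph] = []
    nodes = 0
    complete = True
    for hydrogens, valences in _skeleton_variants(mcd, options):
        lex_tail = _interchangeable_tail(mcd, hydrogens)

        def on_emit(bonds, _h=tuple(hydrogens)):
            atoms = [Atom(e, h, s) for e, h, s in zip(elements, _h, shifts)]
            g = MolecularGraph(atoms, [(i, j, o) for (i, j), o in bonds.items()])
            key = canonical_key(g)
            if key not in seen:
                seen.add(key)
                structures.append(g)
                if len(structures) >= options.max_structures:
                    raise _Budget

        search = _Search(
            elements, hydrogens, valences, pi_allowed, hetero,
            mcd.constraints, fixed,
            node_budget=options.node_budget - nodes,
            deadline=deadline,
            emit=on_emit,
            lex_tail=lex_tail,
        )
        finished = search.run()
        nodes += search.nodes
        if not finished:
            complete = False
            break
    return GenerationResult(structures, complete, nodes, time.monotonic() - t0)


def _interchangeable_tail(mcd: MCD, hydrogens: Sequence[int]) -> list[int]:
    """Atoms whose predecessor is fully interchangeable with them.

    Two consecutive atoms are interchangeable when they share element,
    hydrogen count and property constraints, play identical roles in
    every connectivity constraint (same group memberships — true for
    atoms expanded from one degenerate peak) and appear in no fixed
    bond.  Swapping such a pair maps solutions to solutions, so the
    search may impose a lex order between their adjacency rows.
    """
    fixed_atoms = {a for u, v, _ in mcd.fixed_bonds for a in (u, v)}

    def signature(i: int):
        a = mcd.atoms[i]
        roles = tuple(
            (i in c.group_u, i in c.group_v) for c in mcd.constraints
        )
        return (a.element, hydrogens[i], a.prop, roles)

    tail = []
    for v in range(1, len(mcd.atoms)):
        if v in fixed_atoms or (v - 1) in fixed_atoms:
            continue
        if signature(v - 1) == signature(v):
            tail.append(v)
    return tail


def verify_candidate(
    g: MolecularGraph, mcd: MCD, mapping: Optional[Sequence[int]] = None
) -> tuple[bool, list[str]]:
    """Recompute every MCD requirement against a finished structure.

    With ``mapping=None`` and a structure whose atom order matches the
    MCD (the generator's own outputs), requirements are checked in place
    and each violation is itemized.  For an externally ordered structure
    (e.g. the known answer of a simulated problem) an embedding of the
    MCD onto the graph is searched — atoms paired by element, H count
    and assigned shift — and the structure passes iff one exists.
    """
    if mapping is None and not _order_compatible(g, mcd):
        found = _find_embedding(g, mcd)
        if found is None:
            return False, ["no consistent embedding of the MCD onto the structure"]
        mapping = found
    if mapping is None:
        mapping = list(range(len(g.atoms)))
    violations: list[str] = []
    n = len(mcd.atoms)
    if len(g.atoms) != n:
        return False, [f"atom count {len(g.atoms)} != MCD {n}"]
    inv = list(mapping)  # mcd index -> graph index
    for i, ma in enumerate(mcd.atoms):
        gi = inv[i]
        atom = g.atoms[gi]
        if atom.element != ma.element:
            violations.append(f"atom {i}: element {atom.element} != {ma.element}")
        if ma.hydrogens is not None and atom.hydrogens != ma.hydrogens:
            violations.append(f"atom {i}: H{atom.hydrogens} != H{ma.hydrogens}")
        want = DEFAULT_VALENCE[ma.element]
        got = g.bond_order_sum(gi) + atom.hydrogens
        if got != want:
            violations.append(f"atom {i}: valence {got} != {want}")
        if ma.element == "C":
            if g.pi_count(gi) not in ma.prop.allowed_pi:
                violations.append(
                    f"atom {i}: {g.pi_count(gi)} pi bonds outside {sorted(ma.prop.allowed_pi)}"
                )
            nbr_het = any(g.atoms[v].element != "C" for v, _ in g.adjacency[gi])
            if ma.prop.hetero == "fb" and nbr_het:
                violations.append(f"atom {i}: hetero neighbour forbidden")
            if ma.prop.hetero == "ob" and not nbr_het:
                violations.append(f"atom {i}: hetero neighbour obligatory")
    if not g.is_connected():
        violations.append("graph is disconnected")
    for u, v, o in mcd.fixed_bonds:
        a, b = inv[u], inv[v]
        key = (a, b) if a < b else (b, a)
        if g.bonds.get(key) != o:
            violations.append(f"fixed bond ({u},{v},{o}) absent")
    dist_cache: dict[int, list[int]] = {}
    for idx, c in enumerate(mcd.constraints):
        ok = False
        for a, b in c.pairs():
            ga, gb = inv[a], inv[b]
            if ga not in dist_cache:
                dist_cache[ga] = g.distances_from(ga)
            d = dist_cache[ga][gb]
            if 0 <= d and c.d_lo <= d <= c.d_hi:
                ok = True
                break
        if not ok:
            violations.append(
                f"constraint {idx} ({c.source or c.origin}) outside [{c.d_lo},{c.d_hi}]"
            )
    return not violations, violations


def _order_compatible(g: MolecularGraph, mcd: MCD) -> bool:
    if len(g.atoms) != len(mcd.atoms):
        return False
    for atom, ma in zip(g.atoms, mcd.atoms):
        if atom.element != ma.element:
            return False
        if ma.hydrogens is not None and atom.hydrogens != ma.hydrogens:
            return False
        if (
            ma.shift is not None
            and atom.shift is not None
            and abs(ma.shift - atom.shift) > 0.5
        ):
            return False
    return True


def _find_embedding(
    g: MolecularGraph, mcd: MCD, shift_tol: Optional[float] = 0.2
):
    """Injective MCD-atom → graph-atom map satisfying all constraints.

    ``shift_tol=None`` ignores assigned shifts when pairing atoms: the
    map then only respects element and H count, answering whether the
    *constitution* could carry the constraint set under any assignment.
    """
    n = len(mcd.atoms)
    if len(g.atoms) != n:
        return None
    cands: list[list[int]] = []
    for ma in mcd.atoms:
        opts = []
        for gi, atom in enumerate(g.atoms):
            if atom.element != ma.element:
                continue
            if ma.hydrogens is not None and atom.hydrogens != ma.hydrogens:
                continue
            if (
                shift_tol is not None
                and ma.shift is not None
                and atom.shift is not None
                and abs(ma.shift - atom.shift) > shift_tol
            ):
                continue
            opts.append(gi)
        if not opts:
            return None
        cands.append(opts)
    order = sorted(range(n), key=lambda i: len(cands[i]))
    assignment: list[Optional[int]] = [None] * n
    used = [False] * len(g.atoms)

    def rec(pos: int) -> bool:
        if pos == n:
            ok, _ = verify_candidate(g, mcd, mapping=[assignment[i] for i in range(n)])
            return ok
        i = order[pos]
        for gi in cands[i]:
            if used[gi]:
                continue
            assignment[i] = gi
            used[gi] = True
            if rec(pos + 1):
                return True
            used[gi] = False
            assignment[i] = None
        return False

    return [assignment[i] for i in range(n)] if rec(0) else None


# -- fuzzy structure generation ----------------------------------------------


@dataclass(frozen=True)
class FSGOptions:
    m: int = 1  # max connectivities treated as non-standard
    a: int = DELETE_SENTINEL  # elongation in bonds; 16 = delete
    restrict_to_suspicious: bool = True
    auto: bool = False  # escalate m upward until structures appear

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.a < 1:
            raise ValueError("a must be >= 1 (16 = delete)")


@dataclass
class FSGResult:
    n_math: int = 0  # theoretical combination count over the eligible set
    n_real: int = 0  # combinations actually run through generation
    n_skipped: int = 0  # combinations rejected by the quick pre-test
    k_generated: int = 0  # structures produced across all runs
    k_filtered: int = 0  # after re-verification per combination
    k_unique: int = 0  # after duplicate removal over the union
    t_g: float = 0.0
    complete: bool = True
    eligible: tuple[int, ...] = ()
    m_used: int = 0


def count_combinations(n: int, m: int, cumulative: bool = False) -> int:
    """Number of suspect-connectivity combinations, n_math = C(N, m).

    ``cumulative`` sums over subset sizes 1..m (the sets actually tried
    when generation is re-run for every size up to m); with m=0 the
    single common-mode run counts as 1.
    """
    if not 0 <= m <= n:
        raise ValueError(f"need 0 <= m <= N, got m={m}, N={n}")
    if not cumulative:
        return comb(n, m)
    if m == 0:
        return 1
    return sum(comb(n, i) for i in range(1, m + 1))


def _relax(mcd: MCD, subset: Sequence[int], a: int) -> MCD:
    constraints = []
    for idx, c in enumerate(mcd.constraints):
        if idx in subset:
            if a == DELETE_SENTINEL:
                continue
            constraints.append(replace(c, d_hi=c.d_hi + a, suspicious=True))
        else:
            constraints.append(c)
    return MCD(mcd.formula, mcd.atoms, mcd.free_h, constraints, mcd.fixed_bonds)


def fuzzy_generate(
    mcd: MCD,
    fsg: Optional[FSGOptions] = None,
    gen: Optional[GenerationOptions] = None,
) -> tuple[list[MolecularGraph], FSGResult]:
    """Union of generation runs over relaxed connectivity subsets.

    The eligible set is the suspicious subset from the consistency check
    when ``restrict_to_suspicious`` is on and detection succeeded,
    otherwise every connectivity.  Subsets of size 0..m are tried —
    elongating (or deleting) the chosen connectivities — with a cheap
    feasibility pre-test that skips combinations from which generation
    is impossible.
    """
    from .mcd import check_consistency

    fsg = fsg or FSGOptions()
    gen = gen or GenerationOptions()
    t0 = time.monotonic()
    eligible = list(range(len(mcd.constraints)))
    if fsg.restrict_to_suspicious:
        report = check_consistency(mcd, node_budget=min(gen.node_budget, 300_000))
        flagged = [i for i, c in enumerate(mcd.constraints) if c.suspicious]
        flagged = sorted(set(flagged) | set(report.suspicious_constraints))
        if not report.feasible and flagged:
            eligible = flagged
    res = FSGResult(eligible=tuple(eligible))
    m = min(fsg.m, len(eligible))
    res.m_used = m
    res.n_math = count_combinations(len(eligible), m, cumulative=True) if eligible else 1

    seen: set[str] = set()
    structures: list[MolecularGraph] = []
    for size in range(0, m + 1):
        for subset in itertools.combinations(eligible, size):
            relaxed = _relax(mcd, subset, fsg.a)
            if size and not quick_feasible(relaxed).feasible:
                res.n_skipped += 1
                continue
            run = generate(relaxed, gen)
            if not run.complete:
                res.complete = False
            if size:
                res.n_real += 1
            res.k_generated += len(run.structures)
            for g in run.structures:
                ok, _ = verify_candidate(g, relaxed)
                if not ok:
                    continue
                res.k_filtered += 1
                key = canonical_key(g)
                if key not in seen:
                    seen.add(key)
                    structures.append(g)
    res.k_unique = len(structures)
    res.t_g = time.monotonic() - t0
    return structures, res


# -- brute-force oracle -------------------------------------------------------


def brute_force_enumerate(
    formula: MolecularFormula,
    constraints: Sequence[ConnectivityConstraint] = (),
    hydrogens: Optional[Sequence[Optional[int]]] = None,
    pi_allowed: Optional[Sequence[frozenset]] = None,
    hetero: Optional[Sequence[Optional[str]]] = None,
    max_heavy: int = 7,
) -> list[MolecularGraph]:
    """Dumb exact enumeration for small problems (test oracle).

    Atoms are laid out carbons first, then the other elements in
    alphabetical order, so constraint atom ids are well defined.  Every
    bond-order assignment over atom pairs is tried with nothing beyond
    remaining-valence bookkeeping, leaves are filtered by the
    from-scratch candidate checker, and isomorphs are collapsed.
    """
    elements = ["C"] * formula["C"]
    for e in sorted(x for x in formula.element_counts if x not in ("C", "H")):
        elements.extend([e] * formula[e])
    n = len(elements)
    if n > max_heavy:
        raise ValueError(f"brute force limited to {max_heavy} heavy atoms, got {n}")
    if n == 0:
        return []
    valence = [DEFAULT_VALENCE[e] for e in elements]
    if hydrogens is None:
        hydrogens = [None] * n
    open_slots = [i for i in range(n) if hydrogens[i] is None]
    caps = [valence[i] - (1 if n > 1 else 0) for i in open_slots]
    free_h = formula["H"] - sum(h for h in hydrogens if h is not None)
    if free_h < 0:
        return []
    mcd_atoms = [
        MCDAtom(e, None if i in open_slots else hydrogens[i]) for i, e in enumerate(elements)
    ]
    if pi_allowed is not None or hetero is not None:
        from .apct import AtomProperty, FULL_HYBRIDIZATION

        rev = {0: "sp3", 1: "sp2", 2: "sp"}
        mcd_atoms = [
            MCDAtom(
                a.element,
                a.hydrogens,
                prop=AtomProperty(
                    frozenset(rev[p] for p in pi_allowed[i]) if pi_allowed else FULL_HYBRIDIZATION,
                    hetero[i] if hetero else None,
                ),
            )
            for i, a in enumerate(mcd_atoms)
        ]
    check_mcd = MCD(formula, mcd_atoms, free_h, list(constraints))

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    seen: set[str] = set()
    out: list[MolecularGraph] = []

    for dist in _h_distributions(open_slots, caps, free_h):
        hs = [h if h is not None else 0 for h in hydrogens]
        for slot, h in zip(open_slots, dist):
            hs[slot] = h
        rem = [valence[i] - hs[i] for i in range(n)]
        if sum(rem) % 2:
            continue
        bonds: dict[tuple[int, int], int] = {}

        def rec(k: int) -> None:
            if k == len(pairs):
                if any(rem):
                    return
                g = MolecularGraph(
                    [Atom(e, h) for e, h in zip(elements, hs)],
                    [(i, j, o) for (i, j), o in bonds.items()],
                )
                if not g.is_connected():
                    return
                ok, _ = verify_candidate(g, check_mcd, mapping=list(range(n)))
                if not ok:
                    return
                key = canonical_key(g)
                if key not in seen:
                    seen.add(key)
                    out.append(g)
                return
            i, j = pairs[k]
            for o in range(0, min(3, rem[i], rem[j]) + 1):
                if j == n - 1 and rem[i] - o != 0:
                    continue
                if o:
                    bonds[(i, j)] = o
                    rem[i] -= o
                    rem[j] -= o
                rec(k + 1)
                if o:
                    del bonds[(i, j)]
                    rem[i] += o
                    rem[j] += o

        rec(0)
    return out
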