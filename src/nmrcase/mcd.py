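"""Molecular Connectivity Diagram: the structure generator's input.

The MCD lays out one skeleton atom per heavy atom of the formula —
quaternary C, CH, CH₂ and CH₃ groups carrying their ¹³C shifts and
APCT-derived property constraints, plus the unplaced heteroatoms and any
free (hetero-bound) hydrogens — together with heavy-atom connectivity
constraints translated from the 2D correlations:

* a COSY cross peak between protons spanning n bonds puts their carrier
  carbons at skeletal distance n−2;
* an HMBC cross peak from a proton to a carbon over n bonds puts the
  carrier carbon and the target at distance n−1 (¹H-¹⁵N HMBC identically,
  with nitrogen as the target).

Symmetry-degenerate peaks spawn several interchangeable skeleton atoms;
constraints that reference such a peak hold disjunctively over the
group.  Ambiguously matched coordinates (two 1D peaks within tolerance)
are likewise kept as disjunctive groups rather than broken silently.

``check_consistency`` looks for contradictions — the signature of
non-standard (>3-bond) correlations taken at face value — with a
three-stage heuristic: per-atom valence pigeonhole, interval propagation
over the constraint graph, and a bounded trial generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .apct import AtomProperty, apply_apct
from .formula import DEFAULT_VALENCE, MolecularFormula
from .nmr_io import CorrelationSet

__all__ = [
    "MCDAtom",
    "ConnectivityConstraint",
    "MCD",
    "MCDError",
    "ContradictionError",
    "ConsistencyReport",
    "translate_correlations",
    "build_mcd",
    "check_consistency",
]


class MCDError(ValueError):
    pass


class ContradictionError(MCDError):
    """Two correlation records imply an empty distance interval."""


@dataclass(frozen=True)
class MCDAtom:
    element: str
    hydrogens: Optional[int]  # None = not fixed by the data (heteroatoms)
    shift: Optional[float] = None
    prop: AtomProperty = AtomProperty()
    peak: Optional[int] = None  # index into peaks_c13

    def free_valence(self) -> int:
        return DEFAULT_VALENCE[self.element] - (self.hydrogens or 0)


@dataclass(frozen=True)
class ConnectivityConstraint:
    """One 2D-NMR-derived heavy-atom pair with an allowed path-length interval.

    ``group_u``/``group_v`` list the interchangeable skeleton atoms behind
    each coordinate (symmetry degeneracy or unresolved overlap); the
    constraint is satisfied if *some* pair of distinct atoms drawn from
    the two groups lies within ``[d_lo, d_hi]`` skeletal bonds.
    """

    group_u: tuple[int, ...]
    group_v: tuple[int, ...]
    d_lo: int
    d_hi: int
    origin: str = "USER"  # COSY | HMBC | HN_HMBC | USER
    suspicious: bool = False
    ambiguous: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.d_lo <= self.d_hi):
            raise MCDError(f"bad distance interval [{self.d_lo}, {self.d_hi}]")
        if not self.group_u or not self.group_v:
            raise MCDError("empty constraint group")

    @property
    def atom_u(self) -> int:
        return self.group_u[0]

    @property
    def atom_v(self) -> int:
        return self.group_v[0]

    def pairs(self) -> list[tuple[int, int]]:
        return [
            (a, b) if a < b else (b, a)
            for a in self.group_u
            for b in self.group_v
            if a != b
        ]


@dataclass
class MCD:
    formula: MolecularFormula
    atoms: list[MCDAtom]
    free_h: int = 0
    constraints: list[ConnectivityConstraint] = field(default_factory=list)
    fixed_bonds: list[tuple[int, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        for e, c in counts.items():
            if self.formula[e] != c:
                raise MCDError(
                    f"MCD has {c} {e} atoms but formula {self.formula} has {self.formula[e]}"
                )
        if self.formula.heavy_atom_count != len(self.atoms):
            raise MCDError("MCD heavy-atom count does not match formula")
        known_h = sum(a.hydrogens for a in self.atoms if a.hydrogens is not None)
        if known_h + self.free_h != self.formula["H"] and not any(
            a.hydrogens is None for a in self.atoms
        ):
            raise MCDError(
                f"hydrogen bookkeeping violation: {known_h} attached + {self.free_h} free"
                f" != formula H{self.formula['H']}"
            )
        if known_h > self.formula["H"]:
            raise MCDError("more CHn protons than the formula allows")
        n = len(self.atoms)
        for u, v, o in self.fixed_bonds:
            if not (0 <= u < n and 0 <= v < n and u != v and 1 <= o <= 3):
                raise MCDError(f"bad fixed bond ({u},{v},{o})")
        for c in self.constraints:
            for g in (c.group_u, c.group_v):
                if any(not 0 <= a < n for a in g):
                    raise MCDError(f"constraint references missing atom: {c}")

    # -- serialization (file-based MCD inspection/editing) -------------------

    def to_json(self) -> str:
        doc = {
            "formula": str(self.formula),
            "free_h": self.free_h,
            "atoms": [
                {
                    "element": a.element,
                    "hydrogens": a.hydrogens,
                    "shift": a.shift,
                    "hybridization": sorted(a.prop.hybridizations),
                    "hetero": a.prop.hetero,
                    "peak": a.peak,
                }
                for a in self.atoms
            ],
            "constraints": [
                {
                    "group_u": list(c.group_u),
                    "group_v": list(c.group_v),
                    "d_lo": c.d_lo,
                    "d_hi": c.d_hi,
                    "origin": c.origin,
                    "suspicious": c.suspicious,
                    "ambiguous": c.ambiguous,
                    "source": c.source,
                }
                for c in self.constraints
            ],
            "fixed_bonds": [list(b) for b in self.fixed_bonds],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MCD":
        from .formula import parse_formula

        doc = json.loads(text)
        atoms = [
            MCDAtom(
                a["element"],
                a["hydrogens"],
                a["shift"],
                AtomProperty(frozenset(a["hybridization"]), a["hetero"]),
                a.get("peak"),
            )
            for a in doc["atoms"]
        ]
        constraints = [
            ConnectivityConstraint(
                tuple(c["group_u"]),
                tuple(c["group_v"]),
                c["d_lo"],
                c["d_hi"],
                c.get("origin", "USER"),
                c.get("suspicious", False),
                c.get("ambiguous", False),
                c.get("source", ""),
            )
            for c in doc["constraints"]
        ]
        return cls(
            parse_formula(doc["formula"]),
            atoms,
            doc["free_h"],
            constraints,
            [tuple(b) for b in doc["fixed_bonds"]],
        )


# -- correlation translation --------------------------------------------------


def _merge(constraints: list[ConnectivityConstraint]) -> list[ConnectivityConstraint]:
    """Merge duplicate atom-pair constraints by interval intersection."""
    merged: dict[frozenset, ConnectivityConstraint] = {}
    for c in constraints:
        key = frozenset((c.group_u, c.group_v))
        prev = merged.get(key)
        if prev is None:
            merged[key] = c
            continue
        lo, hi = max(prev.d_lo, c.d_lo), min(prev.d_hi, c.d_hi)
        if lo > hi:
            raise ContradictionError(
                f"constraints contradict: {prev.source or prev} vs {c.source or c} "
                f"give empty interval [{lo}, {hi}]"
            )
        merged[key] = replace(
            prev,
            d_lo=lo,
            d_hi=hi,
            ambiguous=prev.ambiguous or c.ambiguous,
            source=(prev.source + " & " + c.source).strip(" &"),
        )
    return list(merged.values())


def translate_correlations(
    cs: CorrelationSet,
    carbon_atoms: dict[int, tuple[int, ...]],
    nitrogen_atoms: tuple[int, ...] = (),
) -> list[ConnectivityConstraint]:
    """Translate resolved 2D records into heavy-atom distance constraints.

    ``carbon_atoms`` maps a ¹³C peak index to the skeleton atoms carrying
    it.  The proton→carrier map is taken from the HSQC records in ``cs``;
    protons without an HSQC partner (OH/NH) yield no constraints.
    """
    if not cs.resolved:
        raise MCDError("correlations must be resolved by match_shifts first")
    h_carrier: dict[int, tuple[int, ...]] = {}
    for corr in cs.correlations:
        if corr.kind == "HSQC" and corr.peak_a is not None:
            c_peaks = corr.ambiguous_b or (corr.peak_b,)
            atoms: tuple[int, ...] = ()
            for p in c_peaks:
                atoms += carbon_atoms[p]
            h_peaks = corr.ambiguous_a or (corr.peak_a,)
            for hp in h_peaks:
                h_carrier[hp] = tuple(sorted(set(h_carrier.get(hp, ()) + atoms)))

    out: list[ConnectivityConstraint] = []
    for idx, corr in enumerate(cs.correlations):
        if corr.kind in ("HSQC", "NOESY"):
            continue
        n_lo, n_hi = cs.coupling_range(corr)
        src = f"{corr.kind}[{idx}] {corr.shift_a:.2f}/{corr.shift_b:.2f}"
        h_peaks = corr.ambiguous_a or (corr.peak_a,)
        gu: tuple[int, ...] = ()
        for hp in h_peaks:
            gu += h_carrier.get(hp, ())
        gu = tuple(sorted(set(gu)))
        if not gu:
            continue  # hetero-bound proton: no carrier carbon
        if corr.kind == "COSY":
            gv: tuple[int, ...] = ()
            for hp in corr.ambiguous_b or (corr.peak_b,):
                gv += h_carrier.get(hp, ())
            gv = tuple(sorted(set(gv)))
            if not gv:
                continue
            lo, hi = n_lo - 2, n_hi - 2
        elif corr.kind == "HMBC":
            gv = ()
            for cp in corr.ambiguous_b or (corr.peak_b,):
                gv += carbon_atoms[cp]
            gv = tuple(sorted(set(gv)))
            lo, hi = n_lo - 1, n_hi - 1
        else:  # HN_HMBC
            if not nitrogen_atoms:
                continue
            gv = tuple(nitrogen_atoms)
            lo, hi = n_lo - 1, n_hi - 1
        if gu == gv and len(gu) == 1:
            continue  # geminal COSY / one-bond artifact: no heavy-atom info
        # distinct heavy atoms are at distance >= 1; an interval that only
        # allowed the geminal case carries no skeletal information
        lo = max(lo, 1)
        if hi < lo:
            continue
        out.append(
            ConnectivityConstraint(
                gu, gv, lo, hi, corr.kind,
                ambiguous=corr.ambiguous, source=src,
            )
        )
    return _merge(out)


def build_mcd(
    formula: MolecularFormula,
    cs: Optional[CorrelationSet] = None,
    apct_rules=None,
    fixed_bonds: Sequence[tuple[int, int, int]] = (),
) -> MCD:
    """Assemble the MCD from formula + resolved correlation set.

    With ``cs=None`` (formula-only input) every atom is unconstrained and
    hydrogens are left for the generator to distribute.
    """
    atoms: list[MCDAtom] = []
    carbon_atoms: dict[int, tuple[int, ...]] = {}
    known_h = 0
    if cs is not None and cs.peaks_c13:
        total_c = sum(p.degeneracy for p in cs.peaks_c13)
        if total_c != formula["C"]:
            raise MCDError(
                f"13C peak degeneracies sum to {total_c}, formula has C{formula['C']}"
            )
        for p_idx, peak in enumerate(cs.peaks_c13):
            prop = apply_apct(peak.shift, peak.multiplicity, apct_rules)
            ids = []
            for _ in range(peak.degeneracy):
                ids.append(len(atoms))
                atoms.append(
                    MCDAtom("C", peak.attached_h, peak.shift, prop, p_idx)
                )
                if peak.attached_h is not None:
                    known_h += peak.attached_h
            carbon_atoms[p_idx] = tuple(ids)
    else:
        for _ in range(formula["C"]):
            atoms.append(MCDAtom("C", None))
    nitrogen_atoms: list[int] = []
    for element in sorted(e for e in formula.element_counts if e not in ("C", "H")):
        for _ in range(formula[element]):
            if element == "N":
                nitrogen_atoms.append(len(atoms))
            atoms.append(MCDAtom(element, None))
    free_h = formula["H"] - known_h
    if free_h < 0:
        raise MCDError("more CHn protons than the formula allows")
    constraints: list[ConnectivityConstraint] = []
    if cs is not None and cs.correlations:
        constraints = translate_correlations(cs, carbon_atoms, tuple(nitrogen_atoms))
    mcd = MCD(formula, atoms, free_h, constraints, list(fixed_bonds))
    mcd.validate()
    return mcd


# -- consistency check --------------------------------------------------------


@dataclass
class ConsistencyReport:
    feasible: bool
    suspicious_atoms: list[int] = field(default_factory=list)
    suspicious_constraints: list[int] = field(default_factory=list)
    stage: Optional[str] = None  # stage that fired, if any
    exhausted: bool = True  # stage-3 search ran to completion
    notes: list[str] = field(default_factory=list)
    trial = None  # stage-3 GenerationResult, reusable by the caller


def _incident(mcd: MCD, atoms: set[int]) -> list[int]:
    out = []
    for idx, c in enumerate(mcd.constraints):
        if atoms & (set(c.group_u) | set(c.group_v)):
            out.append(idx)
    return out


def quick_feasible(mcd: MCD) -> ConsistencyReport:
    """Stages 1–2 only: cheap deterministic contradiction screen."""
    # stage 1: pigeonhole — forced distance-1 partners cannot exceed the
    # free valence of an atom
    forced: dict[int, set[int]] = {}
    for c in mcd.constraints:
        if len(c.group_u) == 1 and len(c.group_v) == 1 and c.d_lo == c.d_hi == 1:
            u, v = c.atom_u, c.atom_v
            forced.setdefault(u, set()).add(v)
            forced.setdefault(v, set()).add(u)
    for u, v, _ in mcd.fixed_bonds:
        forced.setdefault(u, set()).add(v)
        forced.setdefault(v, set()).add(u)
    bad_atoms = set()
    for a, partners in forced.items():
        cap = mcd.atoms[a].free_valence()
        if mcd.atoms[a].element == "C" and mcd.atoms[a].prop.hetero == "fb":
            partners = set(partners)  # fb narrows nothing here: partners may be C
        if len(partners) > cap:
            bad_atoms.add(a)
    if bad_atoms:
        return ConsistencyReport(
            False,
            sorted(bad_atoms),
            _incident(mcd, bad_atoms),
            stage="pigeonhole",
            notes=[f"atom {a}: forced neighbours exceed free valence" for a in sorted(bad_atoms)],
        )
    # stage 2: min-plus closure of pairwise upper bounds (triangle
    # inequality over the constraint graph) against the lower bounds
    n = len(mcd.atoms)
    INF = 10**6
    D = [[INF] * n for _ in range(n)]
    for i in range(n):
        D[i][i] = 0
    for c in mcd.constraints:
        if len(c.group_u) == 1 and len(c.group_v) == 1:
            u, v = c.atom_u, c.atom_v
            if c.d_hi < D[u][v]:
                D[u][v] = D[v][u] = c.d_hi
    for u, v, _ in mcd.fixed_bonds:
        if D[u][v] > 1:
            D[u][v] = D[v][u] = 1
    for k in range(n):
        Dk = D[k]
        for i in range(n):
            dik = D[i][k]
            if dik >= INF:
                continue
            row = D[i]
            for j in range(n):
                alt = dik + Dk[j]
                if alt < row[j]:
                    row[j] = alt
    for idx, c in enumerate(mcd.constraints):
        if all(D[a][b] < c.d_lo for a, b in c.pairs()):
            atoms = set(c.group_u) | set(c.group_v)
            return ConsistencyReport(
                False,
                sorted(atoms),
                _incident(mcd, atoms),
                stage="interval-propagation",
                notes=[f"constraint {idx} ({c.source}) cannot reach its lower bound"],
            )
    return ConsistencyReport(True)


def check_consistency(
    mcd: MCD,
    trial_generation: bool = True,
    node_budget: int = 4_000_000,
    max_trial_structures: int = 4000,
    deviation_threshold: float = 5.5,
) -> ConsistencyReport:
    """Three-stage contradiction check.

    Stages 1–2 are deterministic and cheap.  Stage 3 runs a bounded
    trial generation and fires on either signature of non-standard
    correlations taken at face value: the search space exhausts without
    a single structure, or every surviving structure deviates grossly
    from the observed ¹³C shifts (best fast-prediction deviation above
    ``deviation_threshold`` ppm).  Detection is heuristic by design —
    a relaxed-enough wrong set can evade both signatures — and the
    suspicious set is the whole constraint list when the contradiction
    cannot be localized to an atom.
    """
    report = quick_feasible(mcd)
    if not report.feasible or not trial_generation or not mcd.constraints:
        return report
    from .generator import GenerationOptions, generate  # deferred: cycle

    res = generate(
        mcd,
        GenerationOptions(max_structures=max_trial_structures, node_budget=node_budget),
    )
    if res.complete and not res.structures:
        out = ConsistencyReport(
            False,
            [],
            list(range(len(mcd.constraints))),
            stage="trial-generation",
            notes=["no structure satisfies the constraint set; localization unavailable"],
        )
        out.trial = res
        return out
    shifts_known = any(a.shift is not None for a in mcd.atoms)
    if res.complete and res.structures and shifts_known:
        from .nmr_io import Peak1D
        from .ranking import score_incremental

        observed = [
            Peak1D("13C", a.shift,
                   {0: "C", 1: "CH", 2: "CH2", 3: "CH3"}.get(a.hydrogens or 0, "undefined"))
            for a in mcd.atoms
            if a.element == "C" and a.shift is not None
        ]
        best = min(score_incremental(g, observed) for g in res.structures)
        if best > deviation_threshold:
            out = ConsistencyReport(
                False,
                [],
                list(range(len(mcd.constraints))),
                stage="trial-ranking",
                notes=[
                    f"best fast-prediction deviation {best:.1f} ppm exceeds "
                    f"{deviation_threshold} ppm: indirect evidence of non-standard correlations"
                ],
            )
            out.trial = res
            return out
    out = ConsistencyReport(
        True,
        exhausted=res.complete,
        notes=[] if res.complete else ["trial generation inconclusive (budget)"],
    )
    out.trial = res
    return out
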