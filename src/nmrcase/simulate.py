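"""Forward simulation of correlation tables from a known structure.

The simulator closes the loop that makes the whole engine testable
without spectrometer data: from an assigned structure it emits exactly
the tables a spectroscopist would curate — HSQC records anchoring the
CHn groups, COSY records for proton pairs coupled over three bonds,
HMBC records for proton–carbon pairs coupled over 2–3 bonds — collapsed
over symmetry-equivalent atoms with degeneracy counts, optionally with
peak drops, coordinate noise, and injected non-standard correlations
(true coupling length ≥ 4 bonds, recorded like any other peak: the
elucidator is not told).

Reference shifts are produced by the packaged incremental predictor
plus fixed per-molecule curated offsets, spaced so that distinct
symmetry orbits stay resolvable at the matching tolerances.  They are
internally consistent ground truth and make no claim of matching
literature spectra.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .graph import MolecularGraph, automorphism_orbits, canonical_key
from .increments import predict_c13_incremental, predict_h1
from .nmr_io import Correlation2D, CorrelationSet, Peak1D

__all__ = [
    "SimulationOptions",
    "FixtureCase",
    "FIXTURE_SMILES",
    "assign_reference_shifts",
    "simulate_correlations",
    "eligible_nsc_pairs",
    "make_fixture_suite",
]

#: The packaged fixture corpus: 8–14 heavy atoms spanning alkaloid-like
#: fused (aza)aromatics, symmetric polysubstituted benzenes, terpenoid-like
#: aliphatics, and a proton-deficient ester with an H-free ("silent")
#: alkyne/dicarbonyl core.
FIXTURE_SMILES: list[tuple[str, str]] = [
    ("4-methylanisole", "COc1ccc(C)cc1"),
    ("p-cresol", "Cc1ccc(O)cc1"),
    ("anisole", "COc1ccccc1"),
    ("quinoline", "c1ccc2ncccc2c1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("n-methylindole", "Cn1ccc2ccccc21"),
    ("acetanilide", "CC(=O)Nc1ccccc1"),
    ("methyl-benzoate", "COC(=O)c1ccccc1"),
    ("dimethyl-acetylenedicarboxylate", "COC(=O)C#CC(=O)OC"),
    ("2-methylcyclohexanone", "CC1CCCCC1=O"),
    ("5-methylhexan-2-one", "CC(=O)CCC(C)C"),
    ("2,6-dimethylheptan-1-ol", "OCC(C)CCCC(C)C"),
]


@dataclass(frozen=True)
class SimulationOptions:
    include_cosy: bool = True
    include_hmbc: bool = True
    include_hn_hmbc: bool = False
    hmbc_range: tuple[int, int] = (2, 3)  # coupling lengths emitted
    cosy_range: tuple[int, int] = (3, 3)  # ³J only; ²J geminal off
    nsc_injections: tuple = ()  # (kind, (atom_u, atom_v), true n)
    drop_probability: float = 0.0  # per COSY/HMBC record; HSQC never drops
    shift_noise_sd: float = 0.0  # ppm, on ¹³C 2D coordinates (¹H: /10)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_probability <= 1.0:
            raise ValueError("drop_probability must be in [0, 1]")
        for rng_ in (self.hmbc_range, self.cosy_range):
            if not (2 <= rng_[0] <= rng_[1] <= 6):
                raise ValueError(f"coupling range {rng_} outside [2, 6]")


@dataclass
class FixtureCase:
    name: str
    variant: str  # clean | nsc | noisy
    structure: MolecularGraph  # carries reference ¹³C shifts
    h_shifts: list[Optional[float]]
    options: SimulationOptions
    simulated: CorrelationSet
    truth: str  # canonical key of the structure
    nsc_pairs: tuple = ()


def _spread(values: dict[int, float], min_sep: float) -> dict[int, float]:
    """Push orbit shifts apart so distinct orbits stay resolvable."""
    order = sorted(values, key=lambda k: (values[k], k))
    out = dict(values)
    for prev, cur in zip(order, order[1:]):
        if out[cur] - out[prev] < min_sep:
            out[cur] = out[prev] + min_sep
    return out


def assign_reference_shifts(
    g: MolecularGraph, name: str
) -> tuple[MolecularGraph, list[Optional[float]]]:
    """Reference ¹³C/¹H shifts: predictor output + curated orbit offsets.

    Offsets are drawn from a generator seeded by the molecule name, so a
    fixture's ground truth never changes; equal-shift orbits are then
    separated (0.25 ppm ¹³C, 0.04 ppm ¹H) to keep peak matching
    unambiguous, mirroring the resolved tables a spectroscopist would
    deliver.
    """
    rng = np.random.default_rng(zlib.crc32(name.encode()) & 0x7FFFFFFF)
    orbits = automorphism_orbits(g)
    c13 = predict_c13_incremental(g)
    h1 = predict_h1(g)
    c_orbit = {}
    h_orbit = {}
    for i, a in enumerate(g.atoms):
        if c13[i] is not None and orbits[i] not in c_orbit:
            c_orbit[orbits[i]] = c13[i] + rng.uniform(-0.4, 0.4)
        if h1[i] is not None and orbits[i] not in h_orbit:
            h_orbit[orbits[i]] = h1[i] + rng.uniform(-0.15, 0.15)
    c_orbit = _spread(c_orbit, 0.25)
    h_orbit = _spread(h_orbit, 0.04)
    shifts = [c_orbit.get(orbits[i]) if c13[i] is not None else None for i in range(len(g.atoms))]
    h_out = [h_orbit.get(orbits[i]) if h1[i] is not None else None for i in range(len(g.atoms))]
    return g.with_shifts(shifts), h_out


#: default ¹H shift for hetero-bound (free) protons, per element
_FREE_H_SHIFT = {"N": 8.2, "O": 2.6, "S": 1.4}


def simulate_correlations(
    g: MolecularGraph,
    h_shifts: Sequence[Optional[float]],
    opts: SimulationOptions = SimulationOptions(),
) -> CorrelationSet:
    """Emit the correlation tables a clean experiment on ``g`` would give."""
    n = len(g.atoms)
    if any(a.element == "C" and a.shift is None for a in g.atoms):
        raise ValueError("simulate_correlations needs assigned 13C shifts")
    rng = np.random.default_rng(opts.seed)
    orbits = automorphism_orbits(g)
    orbit_atoms: dict[int, list[int]] = {}
    for i, o in enumerate(orbits):
        orbit_atoms.setdefault(o, []).append(i)

    peaks_c13: list[Peak1D] = []
    c_peak_of_orbit: dict[int, int] = {}
    mult = {0: "C", 1: "CH", 2: "CH2", 3: "CH3"}
    for o, atoms in sorted(orbit_atoms.items()):
        rep = g.atoms[atoms[0]]
        if rep.element != "C":
            continue
        c_peak_of_orbit[o] = len(peaks_c13)
        peaks_c13.append(
            Peak1D("13C", rep.shift, mult[min(rep.hydrogens, 3)],
                   float(len(atoms)), len(atoms))
        )
    peaks_h1: list[Peak1D] = []
    h_shift_of_orbit: dict[int, float] = {}
    for o, atoms in sorted(orbit_atoms.items()):
        rep_i = atoms[0]
        rep = g.atoms[rep_i]
        if rep.hydrogens == 0:
            continue
        shift = h_shifts[rep_i]
        if shift is None:
            shift = _FREE_H_SHIFT.get(rep.element, 5.0)
        h_shift_of_orbit[o] = shift
        peaks_h1.append(
            Peak1D("1H", shift, "undefined", 1.0, rep.hydrogens * len(atoms))
        )

    dists = [g.distances_from(i) for i in range(n)]
    correlations: list[Correlation2D] = []

    def noisy(value: float, scale: float) -> float:
        if opts.shift_noise_sd:
            return value + rng.normal(0.0, opts.shift_noise_sd * scale)
        return value

    def dropped() -> bool:
        return opts.drop_probability > 0 and rng.random() < opts.drop_probability

    # HSQC: one record per protonated-carbon orbit (never dropped: it
    # anchors the CHn partition)
    for o, p_idx in sorted(c_peak_of_orbit.items()):
        rep = g.atoms[orbit_atoms[o][0]]
        if rep.hydrogens > 0:
            correlations.append(
                Correlation2D("HSQC", h_shift_of_orbit[o], peaks_c13[p_idx].shift,
                              "strong", len(orbit_atoms[o]))
            )

    carbon_orbits = sorted(c_peak_of_orbit)
    protonated = [
        o for o in carbon_orbits if g.atoms[orbit_atoms[o][0]].hydrogens > 0
    ]
    if opts.include_cosy:
        lo, hi = opts.cosy_range
        for a_pos, oa in enumerate(protonated):
            for ob_ in protonated[a_pos + 1:]:
                npairs = sum(
                    1
                    for u in orbit_atoms[oa]
                    for v in orbit_atoms[ob_]
                    if lo <= dists[u][v] + 2 <= hi
                )
                if npairs and not dropped():
                    correlations.append(
                        Correlation2D("COSY", h_shift_of_orbit[oa],
                                      noisy(h_shift_of_orbit[ob_], 0.1),
                                      "strong", npairs)
                    )
    if opts.include_hmbc:
        lo, hi = opts.hmbc_range
        for oa in protonated:
            for ob_ in carbon_orbits:
                npairs = sum(
                    1
                    for u in orbit_atoms[oa]
                    for v in orbit_atoms[ob_]
                    if u != v and lo <= dists[u][v] + 1 <= hi
                )
                if npairs and not dropped():
                    correlations.append(
                        Correlation2D("HMBC", noisy(h_shift_of_orbit[oa], 0.1),
                                      noisy(peaks_c13[c_peak_of_orbit[ob_]].shift, 1.0),
                                      "strong", npairs)
                    )
    for kind, (u, v), true_n in opts.nsc_injections:
        ou, ov = orbits[u], orbits[v]
        if kind == "HMBC":
            if dists[u][v] + 1 != true_n:
                raise ValueError(f"injected HMBC {u}->{v} is {dists[u][v] + 1} bonds, not {true_n}")
            correlations.append(
                Correlation2D("HMBC", h_shift_of_orbit[ou],
                              peaks_c13[c_peak_of_orbit[ov]].shift, "weak")
            )
        elif kind == "COSY":
            if dists[u][v] + 2 != true_n:
                raise ValueError(f"injected COSY {u}-{v} is {dists[u][v] + 2} bonds, not {true_n}")
            correlations.append(
                Correlation2D("COSY", h_shift_of_orbit[ou], h_shift_of_orbit[ov], "strong")
            )
        else:
            raise ValueError(f"cannot inject NSC of kind {kind!r}")
    return CorrelationSet(g.formula(), peaks_c13, peaks_h1, correlations)


def eligible_nsc_pairs(g: MolecularGraph, kind: str = "HMBC", n: int = 4) -> list[tuple[int, int]]:
    """Atom pairs whose injection would be an n-bond non-standard correlation.

    Because records are collapsed over symmetry orbits, the injected
    record only contradicts the default bond range if *no* pair of atoms
    from the two orbits lies within it: the minimum distance over the
    orbit pair must equal the requested length.  Highly symmetric
    molecules can therefore have no eligible pair at all.
    """
    skel = n - 1 if kind == "HMBC" else n - 2
    orbits = automorphism_orbits(g)
    orbit_atoms: dict[int, list[int]] = {}
    for i, o in enumerate(orbits):
        orbit_atoms.setdefault(o, []).append(i)
    dists = [g.distances_from(i) for i in range(len(g.atoms))]
    out = []
    seen = set()
    for u, au in enumerate(g.atoms):
        if au.element != "C" or au.hydrogens == 0:
            continue
        for v, av in enumerate(g.atoms):
            if v == u or av.element != "C" or dists[u][v] != skel:
                continue
            if kind == "COSY" and av.hydrogens == 0:
                continue
            key = (orbits[u], orbits[v])
            if key in seen:
                continue
            seen.add(key)
            min_d = min(
                dists[a][b]
                for a in orbit_atoms[orbits[u]]
                for b in orbit_atoms[orbits[v]]
                if a != b
            )
            if min_d == skel:
                out.append((u, v))
    return out


def _nsc_excludes_truth(g: MolecularGraph, simulated: CorrelationSet) -> bool:
    """True when no peak assignment reconciles the structure with the data.

    The injected record must rule the true constitution out under *every*
    element/H-compatible assignment of peaks to atoms, not merely the
    correct one — otherwise the generator legitimately recovers the true
    skeleton with a shuffled assignment and no contradiction exists.
    """
    from .generator import _find_embedding  # deferred: import cycle
    from .mcd import build_mcd
    from .nmr_io import match_shifts

    mcd = build_mcd(g.formula(), match_shifts(simulated))
    return _find_embedding(g, mcd, shift_tol=None) is None


def make_fixture_suite(seed: int = 0, names: Optional[Sequence[str]] = None) -> list[FixtureCase]:
    """Deterministic suite: per corpus molecule a clean, a +1-NSC (n=4)
    and a noisy case."""
    from .sdf import from_smiles  # deferred: RDKit import cost

    suite: list[FixtureCase] = []
    for idx, (name, smi) in enumerate(FIXTURE_SMILES):
        if names is not None and name not in names:
            continue
        g, h1 = assign_reference_shifts(from_smiles(smi), name)
        truth = canonical_key(g)
        clean_opts = SimulationOptions(seed=seed * 1009 + idx)
        suite.append(
            FixtureCase(name, "clean", g, h1, clean_opts,
                        simulate_correlations(g, h1, clean_opts), truth)
        )
        pairs = eligible_nsc_pairs(g, "HMBC", 4)
        if pairs:
            rng = np.random.default_rng(seed * 2003 + idx)
            order = list(rng.permutation(len(pairs)))
            for k in order:
                pick = pairs[int(k)]
                nsc_opts = SimulationOptions(
                    nsc_injections=(("HMBC", pick, 4),), seed=seed * 1009 + idx
                )
                simulated = simulate_correlations(g, h1, nsc_opts)
                if not _nsc_excludes_truth(g, simulated):
                    # the false record can be absorbed by reassigning
                    # same-multiplicity peaks: not a usable contradiction
                    continue
                suite.append(
                    FixtureCase(name, "nsc", g, h1, nsc_opts, simulated, truth,
                                nsc_pairs=(pick,))
                )
                break
        noisy_opts = SimulationOptions(
            drop_probability=0.05, shift_noise_sd=0.02, seed=seed * 1009 + idx
        )
        suite.append(
            FixtureCase(name, "noisy", g, h1, noisy_opts,
                        simulate_correlations(g, h1, noisy_opts), truth)
        )
    return suite
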