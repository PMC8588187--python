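"""Forward simulator: determinism, degeneracy collapsing, NSC ground truth."""

import pytest

from nmrcase.graph import automorphism_orbits, canonical_key
from nmrcase.nmr_io import match_shifts, write_correlation_set
from nmrcase.sdf import from_smiles
from nmrcase.simulate import (
    FIXTURE_SMILES,
    SimulationOptions,
    assign_reference_shifts,
    eligible_nsc_pairs,
    make_fixture_suite,
    simulate_correlations,
)


def test_suite_size_and_composition(suite):
    names = {n for n, _ in FIXTURE_SMILES}
    assert len(names) == 12
    by_variant = {}
    for c in suite:
        by_variant.setdefault(c.variant, set()).add(c.name)
    assert by_variant["clean"] == names
    assert by_variant["noisy"] == names
    assert by_variant["nsc"] == names  # every fixture admits a usable NSC


def test_same_seed_reproduces_suite(suite):
    again = make_fixture_suite(1)
    for a, b in zip(suite, again):
        assert (a.name, a.variant, a.truth) == (b.name, b.variant, b.truth)
        assert len(a.simulated.correlations) == len(b.simulated.correlations)
        for ca, cb in zip(a.simulated.correlations, b.simulated.correlations):
            assert (ca.kind, ca.shift_a, ca.shift_b) == (cb.kind, cb.shift_a, cb.shift_b)


def test_corpus_size_range():
    for name, smi in FIXTURE_SMILES:
        g = from_smiles(smi)
        assert 8 <= len(g.atoms) <= 25, name


def test_ethane_collapsed_records():
    """Equivalent CH3 groups share one peak: the mutual COSY response is
    the invisible diagonal, so ethane gives one HSQC and one HMBC record."""
    g, h1 = assign_reference_shifts(from_smiles("CC"), "ethane")
    cs = simulate_correlations(g, h1)
    kinds = [c.kind for c in cs.correlations]
    assert kinds.count("HSQC") == 1
    assert kinds.count("HMBC") == 1  # 2-bond H→C across the single bond
    assert kinds.count("COSY") == 0
    assert cs.peaks_c13[0].degeneracy == 2


def test_benzene_degeneracy_collapse():
    g, h1 = assign_reference_shifts(from_smiles("c1ccccc1"), "benzene")
    cs = simulate_correlations(g, h1)
    assert len(cs.peaks_c13) == 1 and cs.peaks_c13[0].degeneracy == 6
    hmbc = [c for c in cs.correlations if c.kind == "HMBC"]
    assert len(hmbc) == 1  # ortho+meta targets, all one orbit


def test_drop_probability_one_keeps_hsqc():
    g, h1 = assign_reference_shifts(from_smiles("COc1ccccc1"), "anisole")
    cs = simulate_correlations(g, h1, SimulationOptions(drop_probability=1.0))
    kinds = {c.kind for c in cs.correlations}
    assert kinds == {"HSQC"}


def test_injected_records_are_exactly_the_beyond_range_set(nsc_cases):
    """Re-auditing every record against the true structure isolates the
    injected ones as the only correlations beyond the default range."""
    for case in nsc_cases:
        g = case.structure
        orbits = automorphism_orbits(g)
        cs = match_shifts(case.simulated)
        carrier = {}
        for corr in cs.correlations:
            if corr.kind == "HSQC":
                carrier[corr.peak_a] = corr.peak_b
        shift_to_atoms = {}
        for i, a in enumerate(g.atoms):
            if a.element == "C":
                shift_to_atoms.setdefault(round(a.shift, 4), []).append(i)
        beyond = []
        for corr in cs.correlations:
            if corr.kind != "HMBC":
                continue
            us = shift_to_atoms[round(cs.peaks_c13[carrier[corr.peak_a]].shift, 4)]
            vs = shift_to_atoms[round(cs.peaks_c13[corr.peak_b].shift, 4)]
            dmin = min(g.distances_from(u)[v] for u in us for v in vs if u != v)
            if dmin + 1 > 3:
                beyond.append(corr)
        assert len(beyond) == 1, case.name
        (u, v) = case.nsc_pairs[0]
        assert orbits[u] in {orbits[a] for a in shift_to_atoms[
            round(cs.peaks_c13[carrier[beyond[0].peak_a]].shift, 4)]}


def test_eligible_nsc_pairs_have_orbit_min_distance():
    g, _ = assign_reference_shifts(from_smiles("COc1ccc(C)cc1"), "4-methylanisole")
    orbits = automorphism_orbits(g)
    for (u, v) in eligible_nsc_pairs(g, "HMBC", 4):
        dmin = min(
            g.distances_from(a)[b]
            for a in range(len(g.atoms)) if orbits[a] == orbits[u]
            for b in range(len(g.atoms)) if orbits[b] == orbits[v] and a != b
        )
        assert dmin == 3


def test_missing_shifts_raise():
    g = from_smiles("CC")
    with pytest.raises(ValueError, match="assigned"):
        simulate_correlations(g, [None, None])


def test_clean_cases_round_trip_structures(clean_runs):
    for case, cs, mcd, res, keys in clean_runs:
        assert res.complete
        assert case.truth in keys, case.name
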