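"""HOSE codes, shift databases, incremental prediction, deviation, ranking."""

import itertools
import random

import numpy as np
import pytest

from nmrcase.graph import canonical_key
from nmrcase.hose import ShiftDB, build_shift_db, hose_code, predict_c13_hose
from nmrcase.increments import load_increment_table, predict_c13_incremental
from nmrcase.nmr_io import Peak1D
from nmrcase.ranking import (
    RankedCandidate,
    deviation,
    rank_candidates,
    remove_duplicates,
    score_incremental,
)
from nmrcase.sdf import from_smiles


# -- HOSE codes ---------------------------------------------------------------


def test_benzene_carbons_share_one_code_at_every_depth():
    g = from_smiles("c1ccccc1")
    for depth in (1, 2, 3, 4):
        assert len({hose_code(g, i, depth) for i in range(6)}) == 1


def test_neopentane_has_two_symmetry_classes():
    g = from_smiles("CC(C)(C)C")
    codes = {hose_code(g, i, 4) for i in range(5)}
    assert len(codes) == 2


def test_hose_code_is_relabeling_invariant():
    g = from_smiles("CC(=O)OC")
    perm = [3, 0, 4, 1, 2]
    h = g.relabel(perm)
    for i in range(len(g.atoms)):
        if g.atoms[i].element == "C":
            assert hose_code(g, i, 4) == hose_code(h, perm[i], 4)


def test_hose_code_rejects_non_carbon():
    g = from_smiles("CO")
    with pytest.raises(ValueError):
        hose_code(g, 1, 4)


# -- ShiftDB ------------------------------------------------------------------


def test_db_depth_fallback_and_prefix_invariant(shift_db):
    # every depth-k entry has its depth-(k-1) counterpart
    for (depth, code), entry in shift_db.entries.items():
        assert entry.n_obs >= 1 and entry.sd >= 0.0
    by_depth = {d: 0 for d in (1, 2, 3, 4)}
    for (depth, _), _e in shift_db.entries.items():
        by_depth[depth] += 1
    assert all(v > 0 for v in by_depth.values())


def test_leave_in_prediction_reproduces_stored_shifts(clean_cases):
    g = clean_cases[0].structure
    db = build_shift_db([g])
    for i, (atom, pred) in enumerate(zip(g.atoms, predict_c13_hose(g, db))):
        if atom.element == "C":
            shift, depth = pred
            assert depth == 4
            assert shift == pytest.approx(atom.shift, abs=1e-9)


def test_duplicate_molecule_doubles_counts_same_means(clean_cases):
    g = clean_cases[0].structure
    db1 = build_shift_db([g])
    db2 = build_shift_db([g, g])
    for key, e1 in db1.entries.items():
        e2 = db2.entries[key]
        assert e2.n_obs == 2 * e1.n_obs
        assert e2.mean_shift == pytest.approx(e1.mean_shift)


def test_empty_db_returns_flagged_defaults():
    g = from_smiles("CCO")
    preds = predict_c13_hose(g, ShiftDB())
    assert all(p is None or p[1] == 0 for p in preds)


def test_db_text_round_trip(tmp_path, shift_db):
    path = tmp_path / "shifts.db"
    shift_db.dump(path)
    back = ShiftDB.load(path)
    assert len(back) == len(shift_db)
    for key, e in shift_db.entries.items():
        assert back.entries[key].mean_shift == pytest.approx(e.mean_shift, abs=1e-4)


# -- incremental --------------------------------------------------------------


def test_methane_class_carbon_is_base_value():
    table = load_increment_table()
    g = from_smiles("C")
    assert predict_c13_incremental(g)[0] == pytest.approx(table["c13"]["sp3"]["base"])


def test_ethane_propane_differ_by_one_beta_increment():
    table = load_increment_table()
    ethane = predict_c13_incremental(from_smiles("CC"))[0]
    propane_terminal = predict_c13_incremental(from_smiles("CCC"))[0]
    assert propane_terminal - ethane == pytest.approx(table["c13"]["sp3"]["beta"]["C"])


def test_fixture_deviation_is_small(clean_cases):
    """Reference shifts are predictor + bounded curated offsets."""
    for case in clean_cases:
        obs = [
            Peak1D("13C", a.shift, {0: "C", 1: "CH", 2: "CH2", 3: "CH3"}[min(a.hydrogens, 3)])
            for a in case.structure.atoms
            if a.element == "C"
        ]
        d = score_incremental(case.structure, obs)
        assert d < 1.0, case.name


# -- deviation ----------------------------------------------------------------


def test_deviation_zero_for_perfect_assignment():
    obs = [Peak1D("13C", 10.0, "CH3"), Peak1D("13C", 20.0, "CH2")]
    assert deviation([(10.0, 3), (20.0, 2)], obs) == 0.0


def test_deviation_is_assignment_not_positional():
    obs = [Peak1D("13C", 20.0, "undefined"), Peak1D("13C", 10.0, "undefined")]
    assert deviation([(10.0, None), (20.0, None)], obs) == 0.0


def test_deviation_respects_multiplicity_classes():
    obs = [Peak1D("13C", 10.0, "CH3"), Peak1D("13C", 10.5, "CH2")]
    # swapping classes would be cheaper but is forbidden
    d = deviation([(10.4, 3), (10.1, 2)], obs)
    assert d == pytest.approx((0.4 + 0.4) / 2)


def test_deviation_count_mismatch_raises():
    with pytest.raises(ValueError):
        deviation([(10.0, None)], [Peak1D("13C", 10.0), Peak1D("13C", 20.0)])


def test_deviation_invariant_to_input_order():
    rng = random.Random(0)
    pred = [(rng.uniform(0, 200), None) for _ in range(6)]
    obs = [Peak1D("13C", rng.uniform(0, 200)) for _ in range(6)]
    d = deviation(pred, obs)
    for _ in range(5):
        p2 = pred[:]
        rng.shuffle(p2)
        o2 = obs[:]
        rng.shuffle(o2)
        assert deviation(p2, o2) == pytest.approx(d)


@pytest.mark.parametrize("n", [2, 4, 6, 8])
def test_deviation_equals_exhaustive_permutation_minimum(n):
    rng = random.Random(n)
    for _ in range(40):
        pred = [(rng.uniform(0, 200), None) for _ in range(n)]
        obs = [Peak1D("13C", rng.uniform(0, 200)) for _ in range(n)]
        d = deviation(pred, obs)
        brute = min(
            sum(abs(pred[i][0] - obs[p[i]].shift) for i in range(n)) / n
            for p in itertools.permutations(range(n))
        )
        assert d == pytest.approx(brute, abs=1e-9)


# -- dedup + ranking ----------------------------------------------------------


def test_remove_duplicates_keeps_best_representative(clean_cases):
    g = clean_cases[0].structure
    obs = [
        Peak1D("13C", a.shift, {0: "C", 1: "CH", 2: "CH2", 3: "CH3"}[min(a.hydrogens, 3)])
        for a in g.atoms if a.element == "C"
    ]
    relabeled = g.relabel(list(reversed(range(len(g.atoms)))))
    out = remove_duplicates([g, relabeled, g], obs)
    assert len(out) == 1


def test_remove_duplicates_leaves_distinct_list_unchanged():
    gs = [from_smiles(s) for s in ("CCCC", "CC(C)C")]
    obs = [Peak1D("13C", x) for x in (10.0, 20.0, 30.0, 40.0)]
    out = remove_duplicates(gs, obs)
    assert [canonical_key(g) for g in out] == [canonical_key(g) for g in gs]


def test_rank_candidates_single_candidate_rank_one(clean_cases, shift_db):
    g = clean_cases[0].structure
    obs = [
        Peak1D("13C", a.shift, {0: "C", 1: "CH", 2: "CH2", 3: "CH3"}[min(a.hydrogens, 3)])
        for a in g.atoms if a.element == "C"
    ]
    out = rank_candidates([g], obs, shift_db=shift_db)
    assert out[0].rank == 1 and not out[0].suspicious


def test_rank_is_deterministic_under_permutation(clean_runs, shift_db):
    case, cs, mcd, res, _ = clean_runs[3]
    cands = list(res.structures)
    base = rank_candidates(cands, cs.peaks_c13, shift_db=shift_db)
    perm = rank_candidates(list(reversed(cands)), cs.peaks_c13, shift_db=shift_db)
    assert [c.key for c in base] == [c.key for c in perm]


def test_suspicion_flag_above_threshold(clean_cases, shift_db):
    g = clean_cases[0].structure
    obs = [Peak1D("13C", a.shift + 10.0, "undefined") for a in g.atoms if a.element == "C"]
    out = rank_candidates([g], obs, shift_db=shift_db)
    assert out[0].d_A is not None and out[0].d_A > 5.5
    assert out[0].suspicious
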