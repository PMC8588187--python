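"""APCT property assignment, correlation translation, consistency checks."""

import pytest

from nmrcase.apct import AtomProperty, apply_apct
from nmrcase.formula import parse_formula
from nmrcase.mcd import (
    MCD,
    ConnectivityConstraint,
    ContradictionError,
    MCDAtom,
    MCDError,
    build_mcd,
    check_consistency,
    quick_feasible,
)
from nmrcase.nmr_io import Correlation2D, CorrelationSet, Peak1D, match_shifts


# -- APCT ---------------------------------------------------------------------


@pytest.mark.parametrize(
    "shift,mult,hyb,hetero",
    [
        (90.0, "CH", {"sp3", "sp2"}, None),  # ambiguous window: "not sp"
        (12.0, "CH3", {"sp3"}, "fb"),
        (170.0, "C", {"sp2"}, "ob"),
        (128.0, "CH", {"sp2"}, None),
        (65.0, "CH", {"sp3", "sp"}, None),
    ],
)
def test_apct_examples(shift, mult, hyb, hetero):
    prop = apply_apct(shift, mult)
    assert prop.hybridizations == frozenset(hyb)
    assert prop.hetero == hetero


def test_apct_out_of_window_warns_and_leaves_unconstrained():
    with pytest.warns(UserWarning):
        prop = apply_apct(260.0, "C")
    assert prop == AtomProperty()


def test_apct_is_sound_for_every_fixture_carbon(clean_cases):
    """The rule table must never exclude a fixture carbon's real state."""
    hyb_of_pi = {0: "sp3", 1: "sp2", 2: "sp"}
    mult = {0: "C", 1: "CH", 2: "CH2", 3: "CH3"}
    for case in clean_cases:
        g = case.structure
        for i, a in enumerate(g.atoms):
            if a.element != "C":
                continue
            prop = apply_apct(a.shift, mult[min(a.hydrogens, 3)])
            assert hyb_of_pi[min(g.pi_count(i), 2)] in prop.hybridizations
            has_het = any(g.atoms[v].element != "C" for v, _ in g.adjacency[i])
            if prop.hetero == "fb":
                assert not has_het, (case.name, i)
            if prop.hetero == "ob":
                assert has_het, (case.name, i)


# -- translation --------------------------------------------------------------


def _set_for(formula, peaks, correlations):
    return CorrelationSet(parse_formula(formula), peaks, correlations=correlations)


def simple_set():
    # three distinct carbons A(CH3) B(CH) C(C) with full HSQC anchoring
    peaks_c = [Peak1D("13C", 20.0, "CH3"), Peak1D("13C", 130.0, "CH"), Peak1D("13C", 140.0, "C")]
    peaks_h = [Peak1D("1H", 2.0), Peak1D("1H", 7.0)]
    corr = [
        Correlation2D("HSQC", 2.0, 20.0),
        Correlation2D("HSQC", 7.0, 130.0),
    ]
    cs = CorrelationSet(parse_formula("C3H4O"), peaks_c, peaks_h, corr)
    return cs


@pytest.mark.parametrize(
    "kind,icls,expected",
    [
        ("COSY", "strong", (1, 1)),  # 2–3 bond HH: adjacent carriers
        ("COSY", "weak", (1, 2)),  # 3–4 bond HH
        ("HMBC", "strong", (1, 2)),  # 2–3 bond CH
    ],
)
def test_translation_arithmetic(kind, icls, expected):
    cs = simple_set()
    target = 130.0 if kind == "COSY" else 140.0
    cs.correlations.append(Correlation2D(kind, 2.0, 7.0 if kind == "COSY" else target, icls))
    mcd = build_mcd(cs.formula, match_shifts(cs))
    assert len(mcd.constraints) == 1
    c = mcd.constraints[0]
    assert (c.d_lo, c.d_hi) == expected


def test_duplicate_constraints_merge_by_intersection():
    cs = simple_set()
    cs.correlations += [
        Correlation2D("HMBC", 2.0, 130.0, "strong"),  # [1,2]
        Correlation2D("COSY", 2.0, 7.0, "weak"),  # [1,2] same pair
        Correlation2D("COSY", 2.0, 7.0, "strong"),  # [1,1] same pair
    ]
    mcd = build_mcd(cs.formula, match_shifts(cs))
    assert len(mcd.constraints) == 1
    assert (mcd.constraints[0].d_lo, mcd.constraints[0].d_hi) == (1, 1)


def test_monotonicity_adding_correlations_never_widens(clean_cases):
    case = clean_cases[2]
    cs = match_shifts(case.simulated)
    mcd_full = build_mcd(cs.formula, cs)
    import copy

    reduced = copy.copy(case.simulated)
    reduced.correlations = case.simulated.correlations[:-2]
    mcd_red = build_mcd(cs.formula, match_shifts(reduced))
    full = {
        (c.group_u, c.group_v): (c.d_lo, c.d_hi) for c in mcd_full.constraints
    }
    for c in mcd_red.constraints:
        lo, hi = full.get((c.group_u, c.group_v), (None, None))
        if lo is not None:
            assert lo >= c.d_lo and hi <= c.d_hi


def test_geminal_cosy_is_dropped():
    peaks_c = [Peak1D("13C", 40.0, "CH2"), Peak1D("13C", 20.0, "CH3")]
    peaks_h = [Peak1D("1H", 1.9), Peak1D("1H", 1.0)]
    corr = [
        Correlation2D("HSQC", 1.9, 40.0),
        Correlation2D("HSQC", 1.0, 20.0),
        Correlation2D("COSY", 1.9, 1.9, "strong"),  # geminal: same carrier
    ]
    cs = CorrelationSet(parse_formula("C2H5Cl"), peaks_c, peaks_h, corr)
    mcd = build_mcd(cs.formula, match_shifts(cs))
    assert mcd.constraints == []


def test_build_mcd_ethanol_layout():
    peaks_c = [Peak1D("13C", 18.0, "CH3"), Peak1D("13C", 58.0, "CH2")]
    cs = CorrelationSet(parse_formula("C2H6O"), peaks_c)
    mcd = build_mcd(cs.formula, cs)
    assert len(mcd.atoms) == 3 and mcd.free_h == 1
    assert [a.element for a in mcd.atoms] == ["C", "C", "O"]


def test_formula_only_mcd_has_no_constraints():
    mcd = build_mcd(parse_formula("C2H6O"))
    assert mcd.constraints == [] and mcd.free_h == 6


def test_h_bookkeeping_violation_raises():
    peaks_c = [Peak1D("13C", 18.0, "CH3"), Peak1D("13C", 58.0, "CH3")]
    cs = CorrelationSet(parse_formula("C2H4O"), peaks_c)
    with pytest.raises(MCDError, match="protons"):
        build_mcd(cs.formula, cs)


def test_degeneracy_must_cover_formula():
    cs = CorrelationSet(parse_formula("C4H10"), [Peak1D("13C", 18.0, "CH3", degeneracy=2)])
    with pytest.raises(MCDError, match="degenerac"):
        build_mcd(cs.formula, cs)


# -- consistency --------------------------------------------------------------


def test_pigeonhole_flags_overbonded_atom():
    f = parse_formula("C5H8")
    atoms = [MCDAtom("C", 1)] + [MCDAtom("C", 1), MCDAtom("C", 2), MCDAtom("C", 2), MCDAtom("C", 2)]
    cons = [
        ConnectivityConstraint((0,), (v,), 1, 1) for v in (1, 2, 3, 4)
    ]
    mcd = MCD(f, atoms, 0, cons)
    report = quick_feasible(mcd)
    assert not report.feasible and 0 in report.suspicious_atoms
    assert len(report.suspicious_constraints) == 4


def test_interval_propagation_detects_pair_contradiction():
    # A-B and B-C forced adjacent, but A-C demanded >= 4 bonds apart
    f = parse_formula("C4H10")
    atoms = [MCDAtom("C", 2), MCDAtom("C", 2), MCDAtom("C", 3), MCDAtom("C", 3)]
    cons = [
        ConnectivityConstraint((0,), (1,), 1, 1),
        ConnectivityConstraint((1,), (2,), 1, 1),
        ConnectivityConstraint((0,), (2,), 4, 5),
    ]
    report = quick_feasible(MCD(f, atoms, 0, cons))
    assert not report.feasible and report.stage == "interval-propagation"


def test_no_false_positives_on_ideal_data(clean_runs):
    for case, cs, mcd, res, keys in clean_runs:
        report = check_consistency(mcd, node_budget=8_000_000)
        assert report.feasible, case.name
        assert report.suspicious_constraints == []


def test_contradictory_records_raise_on_merge():
    cs = simple_set()
    cs.correlations += [
        Correlation2D("COSY", 2.0, 7.0, "strong"),
    ]
    # same pair demanded at >= 4 bonds via policy override
    cs.bond_range_policy[("HMBC", "strong")] = (5, 6)
    cs.correlations += [Correlation2D("HMBC", 2.0, 130.0, "strong")]
    with pytest.raises(ContradictionError):
        build_mcd(cs.formula, match_shifts(cs))


def test_mcd_json_round_trip(clean_runs):
    _, _, mcd, _, _ = clean_runs[0]
    back = MCD.from_json(mcd.to_json())
    assert len(back.atoms) == len(mcd.atoms)
    assert [
        (c.group_u, c.group_v, c.d_lo, c.d_hi) for c in back.constraints
    ] == [(c.group_u, c.group_v, c.d_lo, c.d_hi) for c in mcd.constraints]
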