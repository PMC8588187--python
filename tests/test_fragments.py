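"""Fragment cutting, spectrum search with tolerance E, MCD embedding."""

import pytest

from nmrcase.fragments import (
    FragmentSearchConfig,
    build_user_fragment_db,
    embed_fragments,
    search_fragments,
)
from nmrcase.generator import GenerationOptions, generate
from nmrcase.graph import canonical_key
from nmrcase.mcd import build_mcd
from nmrcase.nmr_io import Peak1D, match_shifts
from nmrcase.sdf import from_smiles


def assigned(smiles):
    from nmrcase.increments import predict_c13_incremental

    g = from_smiles(smiles)
    return g.with_shifts(predict_c13_incremental(g))


def test_benzene_ring_fragment_is_cut():
    db = build_user_fragment_db([assigned("c1ccccc1")])
    sizes = {len(rec.subgraph) for rec in db}
    assert 6 in sizes  # the complete ring
    ring = [rec for rec in db if len(rec.subgraph) == 6][0]
    assert len(ring.subgraph.bonds) == 6


def test_two_atom_structure_yields_the_whole():
    db = build_user_fragment_db([assigned("CO")], size_cap=8)
    assert len(db) == 1 and len(db[0].subgraph) == 2


def test_db_build_is_deterministic(clean_cases):
    structures = [c.structure for c in clean_cases[:4]]
    a = build_user_fragment_db(structures)
    b = build_user_fragment_db(structures)
    assert [r.key for r in a] == [r.key for r in b]
    assert len({r.key for r in a}) == len(a)


def test_unassigned_carbon_is_an_error():
    with pytest.raises(ValueError, match="unassigned"):
        build_user_fragment_db([from_smiles("CCO")])


def test_search_exact_match_and_threshold():
    g = assigned("CCO")
    db = build_user_fragment_db([g], size_cap=3)
    shifts = [a.shift for a in g.atoms if a.element == "C"]
    obs = [Peak1D("13C", s) for s in shifts]
    found = search_fragments(db, obs, cfg=FragmentSearchConfig(E=0.01))
    assert {f.fragment.key for f in found} == {r.key for r in db}
    # one shift off by 2E: whole-molecule fragment can no longer map
    obs_off = [Peak1D("13C", shifts[0] + 3.0), Peak1D("13C", shifts[1])]
    found_off = search_fragments(db, obs_off, cfg=FragmentSearchConfig(E=1.5))
    whole = [r for r in db if len([a for a in r.subgraph.atoms if a.element == "C"]) == 2]
    assert all(f.fragment.key != whole[0].key for f in found_off)


def test_search_monotone_in_tolerance(clean_cases):
    case = clean_cases[1]
    db = build_user_fragment_db([case.structure])
    obs = case.simulated.peaks_c13
    tight = {f.fragment.key for f in search_fragments(db, obs, cfg=FragmentSearchConfig(E=0.5))}
    loose = {f.fragment.key for f in search_fragments(db, obs, cfg=FragmentSearchConfig(E=5.0))}
    assert tight <= loose


def test_closed_loop_all_true_fragments_found(clean_cases):
    """Fragments cut from the true structure match its own spectrum at E=1.5."""
    case = clean_cases[7]  # methyl benzoate
    cs = match_shifts(case.simulated)
    db = build_user_fragment_db([case.structure])
    found = search_fragments(db, cs.peaks_c13, cs, FragmentSearchConfig(E=1.5))
    assert {f.fragment.key for f in found} == {r.key for r in db}


def test_embedding_accelerates_without_changing_the_answer(clean_cases):
    case = clean_cases[7]
    cs = match_shifts(case.simulated)
    mcd = build_mcd(cs.formula, cs)
    base = generate(mcd, GenerationOptions(node_budget=8_000_000))
    base_keys = {canonical_key(g) for g in base}
    db = build_user_fragment_db([case.structure], size_cap=10)
    found = search_fragments(db, cs.peaks_c13, cs, FragmentSearchConfig(E=1.5))
    variants = embed_fragments(mcd, found, FragmentSearchConfig(E=1.5, max_mcds=5))
    assert variants
    accel_keys = set()
    nodes = 0
    for v in variants:
        assert len(v.fixed_bonds) > 0
        r = generate(v, GenerationOptions(node_budget=8_000_000))
        nodes += r.nodes
        accel_keys |= {canonical_key(g) for g in r}
    assert case.truth in accel_keys
    assert accel_keys <= base_keys
    assert nodes < base.nodes


def test_overlapping_fragments_never_co_embedded(clean_cases):
    case = clean_cases[7]
    cs = match_shifts(case.simulated)
    mcd = build_mcd(cs.formula, cs)
    db = build_user_fragment_db([case.structure], size_cap=10)
    found = search_fragments(db, cs.peaks_c13, cs, FragmentSearchConfig(E=1.5))
    variants = embed_fragments(
        mcd, found, FragmentSearchConfig(E=1.5, min_fragments_per_mcd=2, max_mcds=10)
    )
    for v in variants:
        # fixed bonds from two fragments: atom sets must be disjoint, so no
        # atom may exceed its free valence through fixed bonds alone
        load: dict[int, int] = {}
        for u, w, o in v.fixed_bonds:
            load[u] = load.get(u, 0) + o
            load[w] = load.get(w, 0) + o
        for atom_idx, total in load.items():
            assert total <= v.atoms[atom_idx].free_valence()


def test_min_fragment_count_unreachable_gives_empty(clean_cases):
    case = clean_cases[1]
    cs = match_shifts(case.simulated)
    mcd = build_mcd(cs.formula, cs)
    db = build_user_fragment_db([case.structure], size_cap=10)
    found = search_fragments(db, cs.peaks_c13, cs, FragmentSearchConfig(E=1.5))
    variants = embed_fragments(
        mcd, found, FragmentSearchConfig(E=1.5, min_fragments_per_mcd=30)
    )
    assert variants == []
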