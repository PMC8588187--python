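"""Shared fixtures: the simulated fixture suite and reference databases.

Everything is generated programmatically at collection time; nothing is
read from data files.  Session scope keeps the expensive closed-loop
artifacts (generation runs over the whole corpus) computed once.
"""

from __future__ import annotations

import pytest

from nmrcase.graph import canonical_key
from nmrcase.hose import build_shift_db
from nmrcase.mcd import build_mcd, check_consistency
from nmrcase.nmr_io import match_shifts
from nmrcase.generator import (
    FSGOptions,
    GenerationOptions,
    fuzzy_generate,
    generate,
)
from nmrcase.sdf import from_smiles
from nmrcase.simulate import make_fixture_suite

SUITE_SEED = 1


@pytest.fixture(scope="session")
def suite():
    return make_fixture_suite(SUITE_SEED)


@pytest.fixture(scope="session")
def clean_cases(suite):
    return [c for c in suite if c.variant == "clean"]


@pytest.fixture(scope="session")
def nsc_cases(suite):
    return [c for c in suite if c.variant == "nsc"]


@pytest.fixture(scope="session")
def shift_db(clean_cases):
    """HOSE database over the corpus reference shifts (the 'knowledgebase')."""
    return build_shift_db([c.structure for c in clean_cases])


@pytest.fixture(scope="session")
def clean_runs(clean_cases):
    """Per clean case: (case, mcd, generation result, canonical key set)."""
    out = []
    for case in clean_cases:
        cs = match_shifts(case.simulated)
        mcd = build_mcd(cs.formula, cs)
        res = generate(mcd, GenerationOptions(node_budget=8_000_000))
        out.append((case, cs, mcd, res, {canonical_key(g) for g in res}))
    return out


@pytest.fixture(scope="session")
def nsc_runs(nsc_cases):
    """Per +1-NSC case: consistency report, common-mode keys, fuzzy keys."""
    out = []
    gen = GenerationOptions(node_budget=8_000_000)
    for case in nsc_cases:
        cs = match_shifts(case.simulated)
        mcd = build_mcd(cs.formula, cs)
        report = check_consistency(mcd, node_budget=gen.node_budget)
        if report.trial is not None and report.trial.complete:
            common = report.trial.structures
        else:
            common = generate(mcd, gen).structures
        common_keys = {canonical_key(g) for g in common}
        elong, _ = fuzzy_generate(mcd, FSGOptions(m=1, a=1), gen)
        dele, _ = fuzzy_generate(mcd, FSGOptions(m=1, a=16), gen)
        out.append(
            (
                case,
                report,
                common_keys,
                {canonical_key(g) for g in elong},
                {canonical_key(g) for g in dele},
            )
        )
    return out


@pytest.fixture(scope="session")
def small_molecules():
    """A mixed bag of small graphs for canonicalization/prediction checks."""
    smiles = [
        "CCCC", "CC(C)C", "CCO", "COC", "C1CCCCC1", "c1ccccc1",
        "CC(C)(C)C", "CC=CC", "C#CC", "CC(=O)C", "c1ccncc1", "C1CC1",
        "OCC(O)CO", "CCN", "CC(=O)OC",
    ]
    return [from_smiles(s) for s in smiles]
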