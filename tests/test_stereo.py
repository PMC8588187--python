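"""Stereoisomer enumeration and NOE-based configuration selection."""

import numpy as np
import pytest
from rdkit import Chem

from nmrcase.sdf import from_smiles
from nmrcase.stereo import (
    NOE_ABSENCE_CUTOFF,
    NOE_CLASS_RANGES,
    NOEConstraint,
    effective_distance,
    enumerate_stereoisomers,
    noe_penalty,
    rdkit_embedder,
    select_stereoisomer,
)


def test_class_ranges_are_ordered_and_meet_cutoff():
    assert NOE_CLASS_RANGES["strong"] == (1.8, 2.5)
    assert NOE_CLASS_RANGES["medium"] == (2.5, 4.0)
    assert NOE_CLASS_RANGES["weak"] == (4.0, 5.0)
    assert NOE_CLASS_RANGES["weak"][1] == NOE_ABSENCE_CUTOFF


def test_one_stereocenter_collapses_to_single_relative_configuration():
    g = from_smiles("CC(O)CC")  # butan-2-ol
    assert len(enumerate_stereoisomers(g)) == 1
    assert len(enumerate_stereoisomers(g, mirror_collapse=False)) == 2


def test_independent_centers_count():
    g = from_smiles("CC(O)C(N)CC(O)C")  # 3 distinct stereocenters
    full = enumerate_stereoisomers(g, mirror_collapse=False)
    assert len(full) == 8
    assert len(enumerate_stereoisomers(g)) == 4


def test_meso_symmetric_two_center_case():
    g = from_smiles("CC(O)C(O)C")  # 2,3-butanediol
    full = enumerate_stereoisomers(g, mirror_collapse=False)
    assert len(full) == 3  # RR, SS, meso — symmetry removes one
    collapsed = enumerate_stereoisomers(g)
    assert len(collapsed) == 2  # RR~SS under the global mirror


def test_double_bond_geometries_enumerated():
    g = from_smiles("CC=CC")
    smis = {Chem.MolToSmiles(m) for m in enumerate_stereoisomers(g)}
    assert smis == {"C/C=C/C", "C/C=C\\C"}


def synthetic_molh(distance):
    """An ethene skeleton whose closest H–H approach between the two
    carbons is exactly ``distance`` (other H pairs pushed far away)."""
    mol = Chem.AddHs(Chem.MolFromSmiles("C=C"))
    conf = Chem.Conformer(mol.GetNumAtoms())
    conf.SetAtomPosition(0, (0.0, 0.0, 0.0))
    conf.SetAtomPosition(1, (1.33, 0.0, 0.0))
    conf.SetAtomPosition(2, (0.0, 0.0, 1.0))  # H on C0
    conf.SetAtomPosition(3, (0.0, 100.0, 0.0))  # H on C0, parked far away
    conf.SetAtomPosition(4, (0.0, 0.0, 1.0 + distance))  # H on C1
    conf.SetAtomPosition(5, (0.0, 200.0, 0.0))  # H on C1, parked far away
    mol.RemoveAllConformers()
    cid = mol.AddConformer(conf, assignId=True)
    return mol, [cid]


@pytest.mark.parametrize(
    "r,cls,expected",
    [
        (2.0, "strong", 0.0),  # inside the strong window
        (3.5, "strong", 1.0),  # (3.5 − 2.5)² past the upper bound
        (1.5, "strong", 0.09),  # (1.8 − 1.5)² below it
        (4.5, "medium", 0.25),
        (6.0, "weak", 1.0),  # beyond the absence cutoff
    ],
)
def test_penalty_window_arithmetic(r, cls, expected):
    molh, cids = synthetic_molh(r)
    pen = noe_penalty(molh, cids, [NOEConstraint(0, 1, cls)])
    assert pen == pytest.approx(expected, abs=1e-6)


def test_single_conformer_effective_distance_is_geometric():
    molh, cids = synthetic_molh(2.7)
    assert effective_distance(molh, cids, 0, 1) == pytest.approx(2.7, abs=1e-6)


def test_penalty_invariant_to_constraint_and_conformer_order():
    molh, cids = synthetic_molh(3.1)
    cons = [NOEConstraint(0, 1, "strong"), NOEConstraint(0, 1, "medium")]
    assert noe_penalty(molh, cids, cons) == noe_penalty(molh, cids, cons[::-1])


def test_empty_constraint_list_zero_for_all():
    ranked = select_stereoisomer(from_smiles("CC=CC"), [], seed=7)
    assert all(c.penalty == 0.0 for c in ranked)
    # order then falls back to the energy proxy
    assert ranked[0].energy_proxy <= ranked[-1].energy_proxy


def test_cis_trans_discrimination_by_one_strong_noe():
    """Z-2-butene puts the two vinylic H's ~2.3 Å apart, E ~3.1 Å."""
    g = from_smiles("CC=CC")
    ranked = select_stereoisomer(g, [NOEConstraint(1, 2, "strong")], seed=7)
    assert ranked[0].configuration == "C/C=C\\C"
    assert ranked[0].penalty < ranked[1].penalty


def test_mirror_invariance_of_penalty():
    """Reflecting every conformer leaves distances, hence penalties, fixed."""
    g = from_smiles("CC(O)C(O)C")
    iso = enumerate_stereoisomers(g, mirror_collapse=False)[0]
    molh, cids, _ = rdkit_embedder(iso, n_confs=3, seed=3)
    mirrored = Chem.Mol(molh)
    for cid in cids:
        conf = mirrored.GetConformer(cid)
        for i in range(mirrored.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (-p.x, p.y, p.z))
    cons = [NOEConstraint(1, 3, "medium"), NOEConstraint(0, 4, "weak")]
    assert noe_penalty(molh, cids, cons) == pytest.approx(
        noe_penalty(mirrored, cids, cons)
    )


def test_unsatisfiable_constraints_still_return_minimum():
    g = from_smiles("CC=CC")
    # the same pair demanded in two disjoint windows cannot be satisfied
    cons = [NOEConstraint(1, 2, "strong"), NOEConstraint(1, 2, "weak")]
    ranked = select_stereoisomer(g, cons, seed=7)
    assert ranked and all(c.penalty > 0 for c in ranked)
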