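"""Relative stereochemistry from NOE/ROE distance classes.

NOE intensity falls with the inverse sixth power of the proton–proton
distance, so cross peaks are binned into distance classes: strong
1.8–2.5 Å, medium 2.5–4.0 Å, weak 4.0–5.0 Å, with responses generally
absent beyond 5.0 Å.  Given a constitution, all relative configurations
(tetrahedral parities × double-bond geometries, quotiented by molecular
symmetry and the global mirror) are enumerated, each is embedded as a
small conformer ensemble, and candidates are ranked by a penalty that
sums squared violations of the class windows using r⁻⁶-averaged
effective distances — the lower the penalty the better the fit, with
an energy proxy breaking ties.

Conformers come from RDKit distance-geometry embedding (ETKDG) with
force-field refinement; any provider with the same contract
(configuration → coordinate sets + energy) can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

from .graph import MolecularGraph
from .sdf import to_rdkit

__all__ = [
    "NOE_CLASS_RANGES",
    "NOE_ABSENCE_CUTOFF",
    "NOEConstraint",
    "StereoCandidate",
    "enumerate_stereoisomers",
    "noe_penalty",
    "select_stereoisomer",
    "rdkit_embedder",
]

#: distance class → allowed proton–proton distance window (Å)
NOE_CLASS_RANGES: dict[str, tuple[float, float]] = {
    "strong": (1.8, 2.5),
    "medium": (2.5, 4.0),
    "weak": (4.0, 5.0),
}

#: beyond this distance NOE responses are not commonly observed (Å)
NOE_ABSENCE_CUTOFF = 5.0


@dataclass(frozen=True)
class NOEConstraint:
    """One observed NOE between protons of two heavy atoms."""

    atom_a: int  # heavy-atom index carrying proton(s)
    atom_b: int
    cls: str = "strong"

    def __post_init__(self) -> None:
        if self.atom_a == self.atom_b:
            raise ValueError("NOE constraint needs two distinct atoms")
        if self.cls not in NOE_CLASS_RANGES:
            raise ValueError(f"unknown NOE class {self.cls!r}")


@dataclass
class StereoCandidate:
    configuration: str  # isomeric SMILES of the relative configuration
    penalty: float = 0.0
    energy_proxy: float = 0.0
    rank: int = 0
    n_conformers: int = 0
    failed: bool = False  # embedding failure: flagged, not dropped
    conformers: list = field(default_factory=list, repr=False)  # (mol, conf ids)


def _mirror_key(mol: Chem.Mol) -> str:
    """Canonical key identifying a configuration up to global mirror."""
    smi = Chem.MolToSmiles(mol)
    inv = Chem.MolFromSmiles(smi)
    for atom in inv.GetAtoms():
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
        elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
    mirror = Chem.MolToSmiles(inv)
    return min(smi, mirror)


def enumerate_stereoisomers(
    g: MolecularGraph,
    mirror_collapse: bool = True,
    cap: int = 2**14,
) -> list[Chem.Mol]:
    """All relative configurations of a constitution, atom order preserved.

    Tetrahedral parities and double-bond geometries are enumerated
    exhaustively, duplicates under molecular symmetry are removed, and
    (by default) enantiomeric pairs are collapsed to one representative
    since NOE data determine relative configuration only.
    """
    mol = to_rdkit(g)
    opts = StereoEnumerationOptions(onlyUnassigned=True, unique=True, maxIsomers=cap)
    isomers = list(EnumerateStereoisomers(mol, options=opts))
    if not mirror_collapse:
        return isomers
    seen: dict[str, Chem.Mol] = {}
    for iso in isomers:
        key = _mirror_key(iso)
        if key not in seen:
            seen[key] = iso
    return list(seen.values())


def rdkit_embedder(
    mol: Chem.Mol, n_confs: int = 8, seed: int = 7
) -> tuple[Optional[Chem.Mol], list[int], float]:
    """Default conformer provider: ETKDG + MMFF (UFF fallback).

    Returns (H-explicit mol, conformer ids, energy proxy = lowest
    force-field energy); (None, [], inf) when embedding fails.
    """
    molh = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    ids = list(AllChem.EmbedMultipleConfs(molh, numConfs=n_confs, params=params))
    if not ids:
        return None, [], float("inf")
    energies = []
    try:
        results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
        energies = [e for ok, e in results if ok == 0]
    except Exception:
        pass
    if not energies:
        try:
            results = AllChem.UFFOptimizeMoleculeConfs(molh, maxIters=500)
            energies = [e for ok, e in results if ok == 0]
        except Exception:
            energies = [0.0]
    return molh, ids, float(min(energies)) if energies else 0.0


def _proton_positions(molh: Chem.Mol, conf_id: int, heavy: int) -> np.ndarray:
    conf = molh.GetConformer(conf_id)
    out = []
    atom = molh.GetAtomWithIdx(heavy)
    for nbr in atom.GetNeighbors():
        if nbr.GetAtomicNum() == 1:
            p = conf.GetAtomPosition(nbr.GetIdx())
            out.append([p.x, p.y, p.z])
    return np.array(out)


def effective_distance(
    molh: Chem.Mol, conf_ids: Sequence[int], atom_a: int, atom_b: int
) -> float:
    """r_eff = (⟨r⁻⁶⟩ over conformers)^(−1/6), r = closest H–H approach.

    On a single rigid conformer this reduces to the geometric distance.
    """
    inv6 = []
    for cid in conf_ids:
        pa = _proton_positions(molh, cid, atom_a)
        pb = _proton_positions(molh, cid, atom_b)
        if pa.size == 0 or pb.size == 0:
            raise ValueError(
                f"atoms {atom_a}/{atom_b} carry no protons in the embedded model"
            )
        d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)).min()
        inv6.append(d ** -6.0)
    return float(np.mean(inv6) ** (-1.0 / 6.0))


def noe_penalty(
    molh: Chem.Mol,
    conf_ids: Sequence[int],
    constraints: Sequence[NOEConstraint],
) -> float:
    """Σ over constraints of squared distance-window violations.

    Zero when every effective distance sits inside its class window;
    otherwise each constraint adds (r_eff − nearest window bound)².
    Order of constraints and of conformers is immaterial.
    """
    total = 0.0
    for c in constraints:
        lo, hi = NOE_CLASS_RANGES[c.cls]
        r = effective_distance(molh, conf_ids, c.atom_a, c.atom_b)
        if r < lo:
            total += (lo - r) ** 2
        elif r > hi:
            total += (r - hi) ** 2
    return total


def select_stereoisomer(
    g: MolecularGraph,
    constraints: Sequence[NOEConstraint],
    embedder: Optional[Callable] = None,
    n_confs: int = 8,
    seed: int = 7,
    mirror_collapse: bool = True,
) -> list[StereoCandidate]:
    """Rank all relative configurations by (NOE penalty, energy proxy).

    Configurations the embedder cannot realize are flagged and sorted
    last rather than dropped; with an empty constraint list the order
    is by energy proxy alone.
    """
    candidates: list[StereoCandidate] = []
    embed = embedder or (lambda m: rdkit_embedder(m, n_confs=n_confs, seed=seed))
    for iso in enumerate_stereoisomers(g, mirror_collapse=mirror_collapse):
        smi = Chem.MolToSmiles(iso)
        molh, conf_ids, energy = embed(iso)
        if molh is None or not conf_ids:
            candidates.append(
                StereoCandidate(smi, float("inf"), float("inf"), failed=True)
            )
            continue
        pen = noe_penalty(molh, conf_ids, constraints)
        candidates.append(
            StereoCandidate(smi, pen, energy, n_conformers=len(conf_ids),
                            conformers=[(molh, list(conf_ids))])
        )
    candidates.sort(key=lambda c: (c.failed, c.penalty, c.energy_proxy, c.configuration))
    for pos, c in enumerate(candidates, start=1):
        c.rank = pos
    return candidates
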