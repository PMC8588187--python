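"""Molfile/SDF V2000 read/write and SMILES parsing for molecular graphs.

RDKit does the format work; graphs cross the boundary in Kekulé form
with explicit attached-hydrogen counts.  Assigned ¹³C shifts travel in
one SDF data field, ``PPM_C13``, as space-separated ``index:shift``
pairs (0-based atom indices).
"""

from __future__ import annotations

from typing import Optional, Sequence

from rdkit import Chem

from .graph import Atom, GraphError, MolecularGraph

__all__ = ["from_smiles", "from_rdkit", "to_rdkit", "read_sdf", "write_sdf"]

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def to_rdkit(g: MolecularGraph) -> Chem.Mol:
    """Build an RDKit mol preserving atom order; hydrogens stay implicit."""
    rw = Chem.RWMol()
    for a in g.atoms:
        at = Chem.Atom(a.element)
        at.SetNumExplicitHs(a.hydrogens)
        at.SetNoImplicit(True)
        rw.AddAtom(at)
    for (i, j), o in g.bonds.items():
        rw.AddBond(i, j, _BOND_TYPES[o])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def from_rdkit(mol: Chem.Mol) -> MolecularGraph:
    """Convert an RDKit mol (any aromaticity state) to a Kekulé graph."""
    mol = Chem.RemoveHs(Chem.Mol(mol))
    Chem.Kekulize(mol, clearAromaticFlags=True)
    atoms = [
        Atom(a.GetSymbol(), a.GetTotalNumHs())
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = int(round(b.GetBondTypeAsDouble()))
        if order not in (1, 2, 3):
            raise GraphError(f"unsupported bond type {b.GetBondType()}")
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms, bonds)


def from_smiles(smiles: str) -> MolecularGraph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GraphError(f"unparseable SMILES {smiles!r}")
    return from_rdkit(mol)


def _shift_field(g: MolecularGraph) -> Optional[str]:
    pairs = [f"{i}:{a.shift:.4f}" for i, a in enumerate(g.atoms) if a.shift is not None]
    return " ".join(pairs) if pairs else None


def _parse_shift_field(text: str, n: int) -> list[Optional[float]]:
    shifts: list[Optional[float]] = [None] * n
    for token in text.split():
        idx, val = token.split(":")
        shifts[int(idx)] = float(val)
    return shifts


def write_sdf(
    graphs: Sequence[MolecularGraph],
    path,
    properties: Optional[Sequence[dict]] = None,
    names: Optional[Sequence[str]] = None,
) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for k, g in enumerate(graphs):
            mol = to_rdkit(g)
            if names is not None:
                mol.SetProp("_Name", str(names[k]))
            field = _shift_field(g)
            if field:
                mol.SetProp("PPM_C13", field)
            if properties is not None:
                for key, val in properties[k].items():
                    mol.SetProp(str(key), str(val))
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path) -> list[tuple[MolecularGraph, dict]]:
    """Read an SDF into (graph, data-field dict) records.

    ``PPM_C13`` fields are decoded onto the atoms; all data fields are
    also returned verbatim in the dict.
    """
    out: list[tuple[MolecularGraph, dict]] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for mol in supplier:
        if mol is None:
            raise GraphError(f"unreadable SDF record in {path}")
        g = from_rdkit(mol)
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        if mol.HasProp("_Name") and mol.GetProp("_Name"):
            props["_Name"] = mol.GetProp("_Name")
        if "PPM_C13" in props:
            g = g.with_shifts(_parse_shift_field(props["PPM_C13"], len(g)))
        out.append((g, props))
    return out
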