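"""Tabular prediction output shared by the CLI and reports."""

from __future__ import annotations

from typing import Optional, Sequence

from .hose import ShiftDB, predict_c13_hose
from .increments import predict_c13_incremental


def predict_table(records: Sequence[tuple], db: Optional[ShiftDB] = None) -> list[list]:
    """Rows (structure, atom, element, H, incremental, hose, depth) for an SDF."""
    rows: list[list] = []
    for s_idx, (g, props) in enumerate(records):
        name = props.get("_Name", str(s_idx))
        inc = predict_c13_incremental(g)
        hose = predict_c13_hose(g, db) if db is not None else [None] * len(g.atoms)
        for i, atom in enumerate(g.atoms):
            if atom.element != "C":
                continue
            h = hose[i]
            rows.append([
                name, i, atom.element, atom.hydrogens,
                f"{inc[i]:.2f}",
                "" if h is None else f"{h[0]:.2f}",
                "" if h is None else h[1],
            ])
    return rows
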