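"""Molecular formulas: parsing, nominal mass, degree of unsaturation.

The formula is the primary hard constraint of a structure elucidation run:
it fixes the heavy-atom inventory and the total hydrogen count that the
generator must distribute over the skeleton.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "parse_formula",
    "nominal_mass",
    "degree_of_unsaturation",
    "NOMINAL_MASS",
    "DEFAULT_VALENCE",
]

#: Principal-isotope nominal masses (u) for the supported element set.
NOMINAL_MASS: dict[str, int] = {
    "H": 1, "B": 11, "C": 12, "N": 14, "O": 16, "F": 19,
    "Si": 28, "P": 31, "S": 32, "Cl": 35, "Br": 79, "I": 127,
}

#: Standard valences used for skeleton bookkeeping.  C/N/O are the default
#: generation element set; S and P are accepted via configuration.
DEFAULT_VALENCE: dict[str, int] = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "Si": 4, "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1,
}

#: Halogens counted as X in the degree-of-unsaturation formula.
_HALOGENS = ("F", "Cl", "Br", "I")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically infeasible formulas."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element → count map with Hill-notation rendering.

    Invariants: at least one non-hydrogen atom, all counts positive.
    """

    element_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {e: int(c) for e, c in self.element_counts.items() if c}
        for e, c in counts.items():
            if e not in NOMINAL_MASS:
                raise FormulaError(f"unknown element symbol: {e!r}")
            if c < 0:
                raise FormulaError(f"negative count for {e}: {c}")
        if not counts:
            raise FormulaError("empty formula")
        if not any(e != "H" for e in counts):
            warnings.warn(
                "formula contains no heavy atom; structure generation is undefined",
                stacklevel=3,
            )
        object.__setattr__(self, "element_counts", counts)

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __str__(self) -> str:
        return hill_string(self.element_counts)

    @property
    def heavy_atom_count(self) -> int:
        return sum(c for e, c in self.element_counts.items() if e != "H")


def hill_string(counts: dict[str, int]) -> str:
    """Render counts in Hill order: C, H, then other elements alphabetically."""
    parts: list[str] = []
    order: list[str]
    if counts.get("C"):
        order = ["C", "H"] + sorted(e for e in counts if e not in ("C", "H"))
    else:
        order = sorted(counts)
    for e in order:
        c = counts.get(e, 0)
        if c == 0:
            continue
        parts.append(e if c == 1 else f"{e}{c}")
    return "".join(parts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string, e.g. ``"C32H22N4O"``.

    Raises :class:`FormulaError` naming the offending token on malformed
    input or unknown element symbols.
    """
    text = text.strip()
    if not text:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in NOMINAL_MASS:
            raise FormulaError(f"malformed formula {text!r}: unknown element {symbol!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def nominal_mass(f: MolecularFormula) -> int:
    """Integer nominal (principal isotope) mass in u."""
    return sum(NOMINAL_MASS[e] * c for e, c in f.element_counts.items())


def degree_of_unsaturation(f: MolecularFormula) -> float:
    """DBE = (2·C + 2 + N − H − X) / 2, X summed over halogens.

    A half-integer result is returned as-is with a warning (radical or
    inconsistent formula); a negative result raises :class:`FormulaError`.
    """
    c = f["C"] + f["Si"]
    n = f["N"] + f["P"] + f["B"]
    h = f["H"]
    x = sum(f[e] for e in _HALOGENS)
    dbe = (2 * c + 2 + n - h - x) / 2
    if dbe < 0:
        raise FormulaError(f"infeasible formula {f}: negative degree of unsaturation")
    if dbe != int(dbe):
        warnings.warn(
            f"formula {f} has half-integer DBE {dbe}; radical or inconsistent formula",
            stacklevel=2,
        )
        return dbe
    return float(dbe)
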