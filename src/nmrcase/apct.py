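"""Atom Property Correlation Table: shift-range rules → carbon properties.

The APCT assigns every carbon, from its ¹³C shift and CHn multiplicity,
a hybridization possibility set (sp³/sp²/sp; the full set reads "not
defined", {sp³, sp²} reads "not sp") and a hetero-neighbour verdict
(forbidden *fb*, obligatory *ob*, or undefined).  These properties prune
the structure generator hard: an sp³ carbon takes no π bond, an sp²
carbon exactly one, an sp carbon two, and *fb*/*ob* constrain bonds to
heteroatoms.

The packaged rule table lives in ``data/apct.yaml`` and is configuration,
not code: it can be replaced per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import yaml

__all__ = ["AtomProperty", "APCTRule", "load_apct", "apply_apct", "FULL_HYBRIDIZATION"]

FULL_HYBRIDIZATION = frozenset({"sp3", "sp2", "sp"})

#: π-bond count implied by each hybridization state.
PI_OF_HYBRIDIZATION = {"sp3": 0, "sp2": 1, "sp": 2}


@dataclass(frozen=True)
class AtomProperty:
    """Hybridization possibility set + hetero-neighbour flag for one atom."""

    hybridizations: frozenset = FULL_HYBRIDIZATION
    hetero: Optional[str] = None  # 'fb' | 'ob' | None

    def __post_init__(self) -> None:
        if not self.hybridizations:
            raise ValueError("empty hybridization set")
        if self.hetero not in (None, "fb", "ob"):
            raise ValueError(f"bad hetero flag {self.hetero!r}")

    @property
    def allowed_pi(self) -> frozenset:
        return frozenset(PI_OF_HYBRIDIZATION[h] for h in self.hybridizations)

    def render(self) -> str:
        if self.hybridizations == FULL_HYBRIDIZATION:
            hyb = "not defined"
        elif self.hybridizations == frozenset({"sp3", "sp2"}):
            hyb = "not sp"
        else:
            hyb = "/".join(sorted(self.hybridizations))
        return f"{hyb}, hetero={self.hetero or 'not defined'}"


@dataclass(frozen=True)
class APCTRule:
    lo: float
    hi: float
    hybridizations: frozenset
    hetero: Optional[str] = None
    multiplicities: Optional[frozenset] = None  # None = any

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"APCT rule with lo {self.lo} >= hi {self.hi}")

    def matches(self, shift: float, multiplicity: str) -> bool:
        if not (self.lo <= shift < self.hi):
            return False
        if self.multiplicities is not None and multiplicity not in self.multiplicities:
            return False
        return True


def load_apct(path=None) -> list[APCTRule]:
    if path is None:
        text = resources.files("nmrcase.data").joinpath("apct.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    rules = []
    for rec in doc["rules"]:
        rules.append(
            APCTRule(
                float(rec["lo"]),
                float(rec["hi"]),
                frozenset(rec["hybridization"]),
                rec.get("hetero"),
                frozenset(rec["multiplicity"]) if "multiplicity" in rec else None,
            )
        )
    return rules


def apply_apct(
    shift: float, multiplicity: str = "undefined", rules: Optional[Sequence[APCTRule]] = None
) -> AtomProperty:
    """Intersect every matching rule into one :class:`AtomProperty`.

    Shifts outside the tabulated 0–240 ppm window return the undefined
    property with a warning rather than failing.
    """
    if rules is None:
        rules = _default_rules()
    hyb = FULL_HYBRIDIZATION
    hetero: Optional[str] = None
    matched = False
    for rule in rules:
        if rule.matches(shift, multiplicity):
            matched = True
            hyb = hyb & rule.hybridizations
            if hetero is None:
                hetero = rule.hetero
    if not matched:
        warnings.warn(
            f"13C shift {shift} ppm outside the APCT window; atom left unconstrained",
            stacklevel=2,
        )
        return AtomProperty()
    if not hyb:
        raise ValueError(
            f"APCT rules intersect to an empty hybridization set at {shift} ppm"
        )
    return AtomProperty(hyb, hetero)


_RULES_CACHE: Optional[list[APCTRule]] = None


def _default_rules() -> list[APCTRule]:
    global _RULES_CACHE
    if _RULES_CACHE is None:
        _RULES_CACHE = load_apct()
    return _RULES_CACHE
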