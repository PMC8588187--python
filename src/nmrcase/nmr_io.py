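"""Peak tables and 2D correlation tables in a documented CSV dialect.

The input to an elucidation run is never a raw spectrum here but the
spectroscopist-curated tables: a 1D ¹³C peak list (shift, multiplicity
from DEPT/edited HSQC, intensity, degeneracy), a ¹H peak list, and 2D
correlation records (HSQC, COSY, HMBC, ¹H-¹⁵N HMBC, NOESY) given as
chemical-shift pairs with an intensity class.

The experiment-level defaults for how many bonds a correlation may span
live in the :data:`DEFAULT_BOND_RANGE_POLICY`: COSY cross peaks are read
as 2–3 bond couplings when strong and 3–4 bonds when weak; HMBC cross
peaks as 2–3 bonds.  A ``[policy]`` section in the file overrides these
per (kind, intensity class).

File dialect (CSV, ``#`` comments allowed)::

    formula,C9H12
    [peaks_c13]
    shift,multiplicity,intensity,degeneracy
    21.2,CH3,100,3
    [peaks_h1]
    shift,intensity,degeneracy
    2.25,300,9
    [correlations]
    kind,shift_a,shift_b,intensity_class
    HMBC,2.25,137.6,strong
    [policy]
    kind,intensity_class,n_lo,n_hi
    COSY,strong,2,3
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from math import isfinite
from typing import Optional, Sequence

from .formula import MolecularFormula, parse_formula

__all__ = [
    "Peak1D",
    "Correlation2D",
    "CorrelationSet",
    "CorrelationFileError",
    "ShiftMatchError",
    "DEFAULT_BOND_RANGE_POLICY",
    "read_correlation_set",
    "parse_correlation_set",
    "write_correlation_set",
    "match_shifts",
    "write_report",
]

_KINDS = ("HSQC", "COSY", "HMBC", "HN_HMBC", "NOESY")
_INTENSITY = ("strong", "weak", "undefined")
_MULTIPLICITIES = ("C", "CH", "CH2", "CH3", "undefined")

#: (kind, intensity_class) → allowed coupling length interval in bonds.
DEFAULT_BOND_RANGE_POLICY: dict[tuple[str, str], tuple[int, int]] = {
    ("COSY", "strong"): (2, 3),
    ("COSY", "weak"): (3, 4),
    ("COSY", "undefined"): (2, 3),
    ("HMBC", "strong"): (2, 3),
    ("HMBC", "weak"): (2, 3),
    ("HMBC", "undefined"): (2, 3),
    ("HN_HMBC", "strong"): (2, 3),
    ("HN_HMBC", "weak"): (2, 3),
    ("HN_HMBC", "undefined"): (2, 3),
}


class CorrelationFileError(ValueError):
    """Raised with a line number for malformed correlation files."""


class ShiftMatchError(ValueError):
    """Raised when a 2D coordinate has no 1D peak within tolerance."""


@dataclass(frozen=True)
class Peak1D:
    nucleus: str  # 13C | 1H | 15N
    shift: float
    multiplicity: str = "undefined"  # carbon CHn class, from edited data
    intensity: float = 1.0
    degeneracy: int = 1  # symmetry-equivalent atoms sharing this peak

    def __post_init__(self) -> None:
        if not isfinite(self.shift):
            raise ValueError("peak shift must be finite")
        if self.multiplicity not in _MULTIPLICITIES:
            raise ValueError(f"unknown multiplicity {self.multiplicity!r}")
        if self.degeneracy < 1:
            raise ValueError("degeneracy must be >= 1")

    @property
    def attached_h(self) -> Optional[int]:
        if self.multiplicity == "undefined":
            return None
        return {"C": 0, "CH": 1, "CH2": 2, "CH3": 3}[self.multiplicity]


@dataclass(frozen=True)
class Correlation2D:
    kind: str
    shift_a: float  # ¹H coordinate
    shift_b: float  # partner coordinate: ¹H, ¹³C or ¹⁵N depending on kind
    intensity_class: str = "undefined"
    degeneracy: int = 1
    # resolved peak references (filled in by match_shifts); an ambiguous
    # coordinate lists every candidate peak index instead of being broken
    # silently.
    peak_a: Optional[int] = None
    peak_b: Optional[int] = None
    ambiguous_a: tuple[int, ...] = ()
    ambiguous_b: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown correlation kind {self.kind!r}")
        if self.intensity_class not in _INTENSITY:
            raise ValueError(f"unknown intensity class {self.intensity_class!r}")
        if not (isfinite(self.shift_a) and isfinite(self.shift_b)):
            raise ValueError("correlation shifts must be finite")

    @property
    def ambiguous(self) -> bool:
        return bool(self.ambiguous_a or self.ambiguous_b)


@dataclass
class CorrelationSet:
    formula: MolecularFormula
    peaks_c13: list[Peak1D] = field(default_factory=list)
    peaks_h1: list[Peak1D] = field(default_factory=list)
    correlations: list[Correlation2D] = field(default_factory=list)
    bond_range_policy: dict[tuple[str, str], tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BOND_RANGE_POLICY)
    )
    resolved: bool = False

    def coupling_range(self, corr: Correlation2D) -> tuple[int, int]:
        key = (corr.kind, corr.intensity_class)
        if key in self.bond_range_policy:
            return self.bond_range_policy[key]
        return self.bond_range_policy.get((corr.kind, "undefined"), (2, 3))


# -- reading ------------------------------------------------------------------


def parse_correlation_set(text: str, source: str = "<string>") -> CorrelationSet:
    formula: Optional[MolecularFormula] = None
    peaks_c13: list[Peak1D] = []
    peaks_h1: list[Peak1D] = []
    correlations: list[Correlation2D] = []
    policy = dict(DEFAULT_BOND_RANGE_POLICY)
    section = None
    header: list[str] = []

    def err(lineno: int, msg: str) -> CorrelationFileError:
        return CorrelationFileError(f"{source}:{lineno}: {msg}")

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("peaks_c13", "peaks_h1", "correlations", "policy"):
                raise err(lineno, f"unknown section [{section}]")
            header = []
            continue
        row = next(csv.reader(io.StringIO(line)))
        row = [c.strip() for c in row]
        if section is None:
            if row and row[0].lower() == "formula" and len(row) >= 2:
                formula = parse_formula(row[1])
                continue
            raise err(lineno, f"unexpected content before first section: {line!r}")
        if not header:
            header = [c.lower() for c in row]
            continue
        rec = dict(zip(header, row))
        try:
            if section == "peaks_c13":
                peaks_c13.append(
                    Peak1D(
                        "13C",
                        float(rec["shift"]),
                        rec.get("multiplicity", "undefined") or "undefined",
                        float(rec.get("intensity", 1.0) or 1.0),
                        int(rec.get("degeneracy", 1) or 1),
                    )
                )
            elif section == "peaks_h1":
                peaks_h1.append(
                    Peak1D(
                        "1H",
                        float(rec["shift"]),
                        "undefined",
                        float(rec.get("intensity", 1.0) or 1.0),
                        int(rec.get("degeneracy", 1) or 1),
                    )
                )
            elif section == "correlations":
                correlations.append(
                    Correlation2D(
                        rec["kind"],
                        float(rec["shift_a"]),
                        float(rec["shift_b"]),
                        rec.get("intensity_class", "undefined") or "undefined",
                        int(rec.get("degeneracy", 1) or 1),
                    )
                )
            elif section == "policy":
                policy[(rec["kind"], rec["intensity_class"])] = (
                    int(rec["n_lo"]),
                    int(rec["n_hi"]),
                )
        except (KeyError, ValueError) as exc:
            raise err(lineno, f"bad record {line!r}: {exc}") from exc
    if formula is None:
        raise CorrelationFileError(f"{source}: missing 'formula' line")
    return CorrelationSet(formula, peaks_c13, peaks_h1, correlations, policy)


def read_correlation_set(path) -> CorrelationSet:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_correlation_set(fh.read(), source=str(path))


def write_correlation_set(cs: CorrelationSet, path) -> None:
    lines = [f"formula,{cs.formula}"]
    lines.append("[peaks_c13]")
    lines.append("shift,multiplicity,intensity,degeneracy")
    for p in cs.peaks_c13:
        lines.append(f"{p.shift:.6f},{p.multiplicity},{p.intensity:.6f},{p.degeneracy}")
    lines.append("[peaks_h1]")
    lines.append("shift,intensity,degeneracy")
    for p in cs.peaks_h1:
        lines.append(f"{p.shift:.6f},{p.intensity:.6f},{p.degeneracy}")
    lines.append("[correlations]")
    lines.append("kind,shift_a,shift_b,intensity_class,degeneracy")
    for c in cs.correlations:
        lines.append(
            f"{c.kind},{c.shift_a:.6f},{c.shift_b:.6f},{c.intensity_class},{c.degeneracy}"
        )
    if cs.bond_range_policy != DEFAULT_BOND_RANGE_POLICY:
        lines.append("[policy]")
        lines.append("kind,intensity_class,n_lo,n_hi")
        for (kind, icls), (lo, hi) in sorted(cs.bond_range_policy.items()):
            lines.append(f"{kind},{icls},{lo},{hi}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# -- shift matching -----------------------------------------------------------


def _snap(shift: float, peaks: Sequence[Peak1D], tol: float, what: str):
    """Nearest peak within tolerance; ties within tolerance are reported."""
    within = [
        (abs(p.shift - shift), idx) for idx, p in enumerate(peaks)
        if abs(p.shift - shift) <= tol
    ]
    if not within:
        raise ShiftMatchError(
            f"{what} coordinate {shift} ppm has no 1D peak within {tol} ppm"
        )
    within.sort()
    if len(within) > 1:
        return within[0][1], tuple(idx for _, idx in within)
    return within[0][1], ()


def match_shifts(cs: CorrelationSet, tol_c: float = 0.1, tol_h: float = 0.01) -> CorrelationSet:
    """Snap every 2D coordinate to the nearest 1D peak within tolerance.

    A coordinate with two or more peaks within tolerance is marked
    ambiguous (candidates recorded) rather than resolved silently; a
    coordinate with no peak in range raises :class:`ShiftMatchError`.
    """
    if not cs.peaks_c13 and not cs.peaks_h1:
        raise ShiftMatchError("cannot match shifts: peak lists are empty")
    resolved: list[Correlation2D] = []
    for corr in cs.correlations:
        a_idx, a_amb = _snap(corr.shift_a, cs.peaks_h1, tol_h, f"{corr.kind} 1H")
        if corr.kind in ("HSQC", "HMBC"):
            b_idx, b_amb = _snap(corr.shift_b, cs.peaks_c13, tol_c, f"{corr.kind} 13C")
        elif corr.kind in ("COSY", "NOESY"):
            b_idx, b_amb = _snap(corr.shift_b, cs.peaks_h1, tol_h, f"{corr.kind} 1H")
        else:  # HN_HMBC: ¹⁵N target; no ¹⁵N peak list is carried, the MCD
            # builder assigns the correlation to the nitrogen atoms directly.
            b_idx, b_amb = -1, ()
        resolved.append(
            replace(corr, peak_a=a_idx, peak_b=b_idx, ambiguous_a=a_amb, ambiguous_b=b_amb)
        )
    out = CorrelationSet(
        cs.formula, list(cs.peaks_c13), list(cs.peaks_h1), resolved,
        dict(cs.bond_range_policy),
    )
    out.resolved = True
    return out


# -- candidate reports --------------------------------------------------------


def write_report(candidates, path) -> None:
    """Write ranked candidates as an SDF with rank/dI/dA/dH data fields.

    A CSV summary table with the same content is written next to the SDF
    (``<path>.csv``).  Empty candidate lists produce an empty file and a
    warning.
    """
    from . import sdf  # deferred: RDKit import cost

    path = str(path)
    if not candidates:
        warnings.warn("write_report: empty candidate list", stacklevel=2)
        open(path, "w").close()
        return
    graphs, props = [], []
    rows = ["rank,formula,dI,dA,dH,suspicious"]
    for c in candidates:
        graphs.append(c.graph)
        rec = {"rank": c.rank, "dI": f"{c.d_I:.4f}", "suspicious": int(c.suspicious)}
        if c.d_A is not None:
            rec["dA"] = f"{c.d_A:.4f}"
        if c.d_H is not None:
            rec["dH"] = f"{c.d_H:.4f}"
        props.append(rec)
        rows.append(
            f"{c.rank},{c.graph.formula()},{c.d_I:.4f},"
            f"{'' if c.d_A is None else f'{c.d_A:.4f}'},"
            f"{'' if c.d_H is None else f'{c.d_H:.4f}'},{int(c.suspicious)}"
        )
    sdf.write_sdf(graphs, path, properties=props)
    with open(path + ".csv", "w", encoding="utf-8") as fh:
        fh.write("\n".join(rows) + "\n")
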