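"""Candidate scoring and the four-step ranking protocol.

Structures are compared with the experimental ¹³C list through the
average deviation d = mean |δ_pred − δ_obs| under the *best possible*
assignment of predicted to observed shifts — a min-cost bipartite
assignment, restricted so that a CH₃ prediction can only pair with a
CH₃ peak (and so on) when multiplicities are known.

The protocol: (1) score every candidate with the fast incremental
predictor (d_I); (2) remove duplicate structures keeping the
best-scoring representative of each family; (3) sort by d_I;
(4) re-score the head of the list with the accurate HOSE predictor
(d_A) and re-rank it, computing the ¹H deviation d_H alongside when
proton data are present.  A best d_A above 5.5 ppm flags the run as
suspicious — the signature of undetected non-standard correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .graph import MolecularGraph, canonical_key
from .hose import ShiftDB, predict_c13_hose
from .increments import predict_c13_incremental, predict_h1
from .nmr_io import Peak1D

__all__ = ["RankedCandidate", "deviation", "remove_duplicates", "rank_candidates"]

_INFEASIBLE = 1.0e3  # per-pair cost of a multiplicity-incompatible match

#: d_A above which the top-ranked answer is considered suspicious
SUSPICION_THRESHOLD_PPM = 5.5


@dataclass
class RankedCandidate:
    graph: MolecularGraph
    d_I: float
    d_A: Optional[float] = None
    d_H: Optional[float] = None
    rank: int = 0
    suspicious: bool = False
    key: str = ""


def _expand_observed(observed: Sequence[Peak1D]) -> tuple[list[float], list[Optional[int]]]:
    shifts: list[float] = []
    hcounts: list[Optional[int]] = []
    for p in observed:
        for _ in range(p.degeneracy):
            shifts.append(p.shift)
            hcounts.append(p.attached_h)
    return shifts, hcounts


def deviation(
    predicted: Sequence[tuple[float, Optional[int]]],
    observed: Sequence[Peak1D],
    respect_multiplicity: bool = True,
) -> float:
    """Mean |Δδ| under the optimal predicted→observed assignment (ppm).

    ``predicted`` carries (shift, attached-H) pairs; observed peaks are
    expanded by their degeneracy.  Counts must agree.  Incompatible
    multiplicity pairings receive a prohibitive cost, so a structurally
    impossible candidate scores far outside the plausible range instead
    of silently reusing peaks.
    """
    obs_shifts, obs_h = _expand_observed(observed)
    if len(predicted) != len(obs_shifts):
        raise ValueError(
            f"predicted {len(predicted)} shifts vs {len(obs_shifts)} observed"
        )
    if not predicted:
        return 0.0
    pred = np.array([p[0] for p in predicted])
    cost = np.abs(pred[:, None] - np.array(obs_shifts)[None, :])
    if respect_multiplicity:
        for r, (_, h) in enumerate(predicted):
            if h is None:
                continue
            for c, oh in enumerate(obs_h):
                if oh is not None and oh != h:
                    cost[r, c] = _INFEASIBLE
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def _predicted_c13(g: MolecularGraph, table: Optional[dict]) -> list[tuple[float, int]]:
    shifts = predict_c13_incremental(g, table)
    return [
        (s, g.atoms[i].hydrogens)
        for i, s in enumerate(shifts)
        if s is not None
    ]


def score_incremental(
    g: MolecularGraph,
    observed: Sequence[Peak1D],
    table: Optional[dict] = None,
    respect_multiplicity: bool = True,
) -> float:
    return deviation(_predicted_c13(g, table), observed, respect_multiplicity)


def score_hose(
    g: MolecularGraph,
    observed: Sequence[Peak1D],
    db: ShiftDB,
    respect_multiplicity: bool = True,
) -> float:
    pred = predict_c13_hose(g, db)
    pairs = [
        (p[0], g.atoms[i].hydrogens) for i, p in enumerate(pred) if p is not None
    ]
    return deviation(pairs, observed, respect_multiplicity)


def score_h1(g: MolecularGraph, observed_h1: Sequence[Peak1D], table=None) -> float:
    """Mean |Δδ| for protons, rectangular assignment when counts differ."""
    pred = predict_h1(g, table)
    pred_shifts: list[float] = []
    for i, s in enumerate(pred):
        if s is not None:
            pred_shifts.extend([s] * g.atoms[i].hydrogens)
    obs: list[float] = []
    for p in observed_h1:
        obs.extend([p.shift] * p.degeneracy)
    if not pred_shifts or not obs:
        return 0.0
    a, b = np.array(pred_shifts), np.array(obs)
    cost = np.abs(a[:, None] - b[None, :])
    if cost.shape[0] > cost.shape[1]:
        cost = cost.T
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def remove_duplicates(
    candidates: Sequence[MolecularGraph],
    observed: Sequence[Peak1D],
    table: Optional[dict] = None,
    respect_multiplicity: bool = True,
) -> list[MolecularGraph]:
    """One structure per isomorphism class: the minimum-d_I member."""
    best: dict[str, tuple[float, int, MolecularGraph]] = {}
    order: list[str] = []
    for pos, g in enumerate(candidates):
        key = canonical_key(g)
        d = score_incremental(g, observed, table, respect_multiplicity)
        if key not in best:
            best[key] = (d, pos, g)
            order.append(key)
        elif d < best[key][0]:
            best[key] = (d, best[key][1], g)
    return [best[k][2] for k in order]


def rank_candidates(
    candidates: Sequence[MolecularGraph],
    observed: Sequence[Peak1D],
    shift_db: Optional[ShiftDB] = None,
    observed_h1: Optional[Sequence[Peak1D]] = None,
    increment_table: Optional[dict] = None,
    k_accurate: int = 50,
    suspicion_threshold: float = SUSPICION_THRESHOLD_PPM,
    respect_multiplicity: bool = True,
) -> list[RankedCandidate]:
    """Full protocol: fast scores → dedup → sort → accurate re-rank of head."""
    if not candidates:
        return []
    scored: dict[str, RankedCandidate] = {}
    for g in candidates:
        key = canonical_key(g)
        d = score_incremental(g, observed, increment_table, respect_multiplicity)
        prev = scored.get(key)
        if prev is None or d < prev.d_I:
            scored[key] = RankedCandidate(g, d_I=d, key=key)
    ranked = sorted(scored.values(), key=lambda c: (c.d_I, c.key))
    if shift_db is not None and len(shift_db):
        head, tail = ranked[:k_accurate], ranked[k_accurate:]
        for c in head:
            c.d_A = score_hose(c.graph, observed, shift_db, respect_multiplicity)
            if observed_h1:
                c.d_H = score_h1(c.graph, observed_h1)
        head.sort(key=lambda c: (c.d_A, c.key))
        ranked = head + tail
        if head and head[0].d_A is not None and head[0].d_A > suspicion_threshold:
            for c in ranked:
                c.suspicious = True
    elif observed_h1:
        for c in ranked[:k_accurate]:
            c.d_H = score_h1(c.graph, observed_h1)
    for pos, c in enumerate(ranked, start=1):
        c.rank = pos
    return ranked
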