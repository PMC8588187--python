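"""End-to-end elucidation: correlations in, ranked structures out.

The driver wires the stages in the order a structure elucidation run
takes: resolve the 2D coordinates against the 1D peak lists, assemble
the MCD, screen it for contradictions, generate structures — common
mode when the data look consistent, automatic fuzzy generation with
escalating m when non-standard correlations are suspected — then
verify, deduplicate and rank the candidates.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .fragments import FragmentSearchConfig, embed_fragments, search_fragments
from .generator import (
    FSGOptions,
    FSGResult,
    GenerationOptions,
    fuzzy_generate,
    generate,
    verify_candidate,
)
from .graph import MolecularGraph
from .hose import ShiftDB
from .mcd import MCD, ConsistencyReport, build_mcd, check_consistency
from .nmr_io import CorrelationSet, match_shifts
from .ranking import RankedCandidate, rank_candidates

__all__ = ["ElucidationOptions", "ElucidationResult", "elucidate"]


@dataclass
class ElucidationOptions:
    tol_c: float = 0.1  # ppm, ¹³C coordinate matching
    tol_h: float = 0.01  # ppm, ¹H coordinate matching
    generation: GenerationOptions = field(default_factory=GenerationOptions)
    fsg: FSGOptions = field(default_factory=FSGOptions)
    fsg_auto_m_cap: int = 3  # escalate m = 1..cap until structures appear
    use_fsg: bool = True
    k_accurate: int = 50
    fragment_cfg: FragmentSearchConfig = field(default_factory=FragmentSearchConfig)
    apct_rules: Optional[list] = None


@dataclass
class ElucidationResult:
    candidates: list[RankedCandidate]
    mcd: MCD
    report: ConsistencyReport
    mode: str  # "common" | "fuzzy" | "fragment"
    fsg_result: Optional[FSGResult] = None
    log: list[str] = field(default_factory=list)
    elapsed: float = 0.0

    @property
    def top(self) -> Optional[RankedCandidate]:
        return self.candidates[0] if self.candidates else None


def elucidate(
    cs: CorrelationSet,
    shift_db: Optional[ShiftDB] = None,
    fragment_db: Optional[Sequence] = None,
    options: Optional[ElucidationOptions] = None,
) -> ElucidationResult:
    opts = options or ElucidationOptions()
    t0 = time.monotonic()
    log: list[str] = []

    resolved = cs if cs.resolved else match_shifts(cs, opts.tol_c, opts.tol_h)
    mcd = build_mcd(resolved.formula, resolved, opts.apct_rules)
    log.append(
        f"mcd: {len(mcd.atoms)} atoms, {len(mcd.constraints)} constraints, "
        f"{mcd.free_h} free H"
    )
    report = check_consistency(mcd, node_budget=opts.generation.node_budget)
    log.append(
        f"consistency: feasible={report.feasible} stage={report.stage} "
        f"suspicious={len(report.suspicious_constraints)}"
    )

    mcds = [mcd]
    mode = "common"
    if fragment_db:
        found = search_fragments(
            fragment_db, resolved.peaks_c13, resolved, opts.fragment_cfg
        )
        log.append(f"fragments: {len(found)} found in user DB")
        variants = embed_fragments(mcd, found, opts.fragment_cfg)
        if variants:
            mcds = variants
            mode = "fragment"
            log.append(f"fragments: {len(variants)} MCD variants embedded")

    structures: list[MolecularGraph] = []
    fsg_result: Optional[FSGResult] = None
    if report.feasible or not opts.use_fsg:
        if (
            mode == "common"
            and report.trial is not None
            and report.trial.complete
        ):
            structures = list(report.trial.structures)  # reuse the trial run
            log.append(f"generation: reused consistency trial, k={len(structures)}")
        else:
            for variant in mcds:
                res = generate(variant, opts.generation)
                structures.extend(res.structures)
                if not res.complete:
                    log.append("generation: budget exhausted, partial result")
        log.append(f"generation ({mode}): k={len(structures)}")
    if opts.use_fsg and (not report.feasible or not structures):
        # when NSCs are suspected but cannot be resolved directly,
        # fuzzy generation with growing m is the remedy
        mode = "fuzzy"
        for m in range(1, opts.fsg_auto_m_cap + 1) if opts.fsg.auto or opts.fsg.m == 0 \
                else [opts.fsg.m]:
            fsg = FSGOptions(
                m=m, a=opts.fsg.a,
                restrict_to_suspicious=opts.fsg.restrict_to_suspicious,
            )
            structures, fsg_result = fuzzy_generate(mcd, fsg, opts.generation)
            log.append(
                f"fsg m={m} a={fsg.a}: n_math={fsg_result.n_math} "
                f"n_real={fsg_result.n_real} skipped={fsg_result.n_skipped} "
                f"k={fsg_result.k_generated}->{fsg_result.k_filtered}"
                f"->{fsg_result.k_unique} t_g={fsg_result.t_g:.1f}s"
            )
            if structures:
                break

    verified = []
    for g in structures:
        ok, _ = verify_candidate(g, mcd) if mode != "fuzzy" else (True, [])
        if ok:
            verified.append(g)
    log.append(f"verified: {len(verified)}")
    ranked = rank_candidates(
        verified,
        resolved.peaks_c13,
        shift_db=shift_db,
        observed_h1=resolved.peaks_h1,
        k_accurate=opts.k_accurate,
    )
    if ranked:
        head = ranked[0]
        log.append(
            f"rank 1: d_I={head.d_I:.2f}"
            + (f" d_A={head.d_A:.2f}" if head.d_A is not None else "")
            + (" SUSPICIOUS" if head.suspicious else "")
        )
    else:
        log.append("empty result file: constraints likely contain undetected "
                   "non-standard correlations")
    return ElucidationResult(
        ranked, mcd, report, mode, fsg_result, log, time.monotonic() - t0
    )
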