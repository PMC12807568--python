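"""Proteome-wide screen orchestration: cis-MR against BP, CVD outcome
stage, colocalization-based prioritization, and mediation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import abf_from_sumstats, coloc_abf, moloc_abf, pwcoco
from .instruments import GeneRegion, greedy_clump, instrument_strength, select_cis
from .mediation import MediationResult, proportion_mediated
from .mr import (
    HeterogeneityResult,
    MRResult,
    SteigerDirection,
    SteigerResult,
    bh_fdr,
    bidirectional_check,
    cochran_q,
    mr_estimate,
    steiger,
)
from .sumstats import LDMatrix, SumStatsTable, TraitType, harmonize, kept_pairs

__all__ = [
    "PipelineConfig",
    "ScreenRecord",
    "CandidateRecord",
    "run_screen",
    "run_outcome_stage",
    "prioritize_and_mediate",
]


@dataclass
class PipelineConfig:
    """Every decision threshold of the screen, with conventional defaults."""

    p_instrument: float = 5e-8
    r2_clump: float = 0.001
    clump_window_kb: int = 10_000
    cis_window_bp: int = 1_000_000
    maf_threshold: float = 0.01
    fdr_threshold: float = 0.05
    q_pval_threshold: float = 0.05
    q_min_snps: int = 4  # Q filter applied only when n_snps > 3
    f_threshold: float = 10.0
    f_stat_mode: str = "mean"  # or "min"
    pp_threshold: float = 0.70
    pp_suggestive: float = 0.50
    coloc_priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5)
    moloc_priors: tuple[float, float, float] = (1e-4, 1e-6, 1e-7)
    p_reverse: float = 0.05
    min_region_snps: int = 25
    gene_dense_flank_bp: int = 500_000
    mhc_blacklist: tuple[tuple[str, int, int], ...] = ()
    fdr_family: str = "per_trait"  # or "pooled"
    palindrome_eaf_limit: float = 0.42


@dataclass
class ScreenRecord:
    protein_id: str
    outcome_id: str
    mr: MRResult | None = None
    het: HeterogeneityResult | None = None
    steiger: SteigerResult | None = None
    reverse_flag: str = "untestable"
    f_mean: float = float("nan")
    fdr_adjusted_p: float = float("nan")
    instruments: list = field(default_factory=list)
    passed: bool = False
    fail_reasons: list[str] = field(default_factory=list)


@dataclass
class CandidateRecord:
    protein_id: str
    bp_trait: str
    cvd_trait: str
    direction_concordant: bool = False
    coloc_bp_pp4: float = float("nan")
    coloc_cvd_pp4: float = float("nan")
    moloc_pp: float = float("nan")
    gene_dense: bool = False
    used_pwcoco: bool = False
    prioritized: bool = False
    fail_reasons: list[str] = field(default_factory=list)


def _in_blacklist(region: GeneRegion, blacklist) -> bool:
    for chrom, lo, hi in blacklist:
        if region.chrom == chrom and region.start <= hi and region.end >= lo:
            return True
    return False


def _select_instruments(
    protein_ss: SumStatsTable,
    region: GeneRegion,
    ld: LDMatrix,
    cfg: PipelineConfig,
) -> SumStatsTable:
    cis = select_cis(protein_ss, region, window_bp=cfg.cis_window_bp, maf_threshold=cfg.maf_threshold)
    if len(cis) == 0:
        return cis
    cis.df = cis.df[cis.df["SNP"].isin(set(ld.snp_ids))]
    if len(cis) == 0:
        return cis
    return greedy_clump(
        cis, ld, p_threshold=cfg.p_instrument, r2_threshold=cfg.r2_clump, window_kb=cfg.clump_window_kb
    )


def _screen_one(
    protein_id: str,
    protein_ss: SumStatsTable,
    region: GeneRegion,
    outcome_ss: SumStatsTable,
    ld: LDMatrix,
    cfg: PipelineConfig,
) -> ScreenRecord:
    rec = ScreenRecord(protein_id=protein_id, outcome_id=outcome_ss.trait_name)
    if _in_blacklist(region, cfg.mhc_blacklist):
        rec.fail_reasons.append("mhc_region")
        return rec
    clumped = _select_instruments(protein_ss, region, ld, cfg)
    if len(clumped) == 0:
        rec.fail_reasons.append("no_instruments")
        return rec
    try:
        pairs = kept_pairs(
            harmonize(clumped, outcome_ss, palindrome_eaf_limit=cfg.palindrome_eaf_limit)
        )
    except ValueError:
        rec.fail_reasons.append("no_instruments")
        return rec
    pairs = [p for p in pairs if p.beta_exp != 0]
    if not pairs:
        rec.fail_reasons.append("no_instruments")
        return rec
    rec.instruments = pairs
    f_per_snp, f_mean = instrument_strength(pairs)
    rec.f_mean = float(f_per_snp.min()) if cfg.f_stat_mode == "min" else f_mean
    binary = outcome_ss.trait_type is TraitType.BINARY
    rec.mr = mr_estimate(pairs, binary_outcome=binary)
    if len(pairs) >= cfg.q_min_snps:
        rec.het = cochran_q(pairs)
    rec.steiger = steiger(pairs)
    rec.reverse_flag = bidirectional_check(
        outcome_ss,
        protein_ss,
        ld,
        region,
        cis_exclusion_bp=cfg.cis_window_bp,
        p_instrument=cfg.p_instrument,
        p_reverse=cfg.p_reverse,
        r2_threshold=cfg.r2_clump,
        window_kb=cfg.clump_window_kb,
    )
    return rec


def _apply_fdr_and_gates(records: list[ScreenRecord], cfg: PipelineConfig) -> None:
    tested = [r for r in records if r.mr is not None]
    if tested:
        adj = bh_fdr([r.mr.pval for r in tested])
        for r, a in zip(tested, adj):
            r.fdr_adjusted_p = float(a)
    for r in records:
        if r.mr is None:
            r.passed = False
            if not r.fail_reasons:
                r.fail_reasons.append("no_instruments")
            continue
        if r.fdr_adjusted_p >= cfg.fdr_threshold:
            r.fail_reasons.append("fdr_not_significant")
        if r.het is not None and r.het.pval <= cfg.q_pval_threshold:
            r.fail_reasons.append("heterogeneity")
        if r.reverse_flag == "reverse_causal":
            r.fail_reasons.append("reverse_causality_bidirectional")
        if r.steiger is not None and r.steiger.direction is SteigerDirection.OUTCOME_TO_EXPOSURE:
            r.fail_reasons.append("reverse_causality_steiger")
        if r.f_mean < cfg.f_threshold:
            r.fail_reasons.append("weak_instruments")
        r.passed = not r.fail_reasons


def run_screen(
    proteins: dict[str, tuple[SumStatsTable, GeneRegion]],
    bp_sumstats: SumStatsTable,
    ld: LDMatrix,
    cfg: PipelineConfig | None = None,
) -> list[ScreenRecord]:
    """Stage 1: cis-MR of every protein against one BP trait, with the full
    sensitivity battery and BH-FDR across proteins."""
    cfg = cfg or PipelineConfig()
    records = []
    for pid in sorted(proteins):
        ss, region = proteins[pid]
        records.append(_screen_one(pid, ss, region, bp_sumstats, ld, cfg))
    _apply_fdr_and_gates(records, cfg)
    return records


def run_outcome_stage(
    survivors: list[ScreenRecord],
    proteins: dict[str, tuple[SumStatsTable, GeneRegion]],
    cvd_sumstats: SumStatsTable,
    ld: LDMatrix,
    cfg: PipelineConfig | None = None,
) -> list[ScreenRecord]:
    """Stage 2: the same filter battery for BP-associated proteins against a
    CVD outcome; FDR is applied within the outcome across tested proteins."""
    cfg = cfg or PipelineConfig()
    records = []
    for surv in sorted(survivors, key=lambda r: r.protein_id):
        if not surv.passed:
            continue
        ss, region = proteins[surv.protein_id]
        records.append(_screen_one(surv.protein_id, ss, region, cvd_sumstats, ld, cfg))
    _apply_fdr_and_gates(records, cfg)
    return records


def _aligned_region_panel(
    tables: list[SumStatsTable],
    region: GeneRegion,
    cfg: PipelineConfig,
) -> list[SumStatsTable] | None:
    """Restrict all tables to the shared cis panel (MAF-filtered), or None
    when the shared panel is too small."""
    cis_tables = [
        select_cis(t, region, window_bp=cfg.cis_window_bp, maf_threshold=cfg.maf_threshold)
        for t in tables
    ]
    shared = set(cis_tables[0].snp_ids)
    for t in cis_tables[1:]:
        shared &= set(t.snp_ids)
    if len(shared) < cfg.min_region_snps:
        return None
    out = []
    for t in cis_tables:
        sub = t.subset(shared)
        out.append(sub)
    return out


def _mediation_beta2(
    bp_sumstats: SumStatsTable,
    cvd_sumstats: SumStatsTable,
    ld: LDMatrix,
    region: GeneRegion,
    cfg: PipelineConfig,
) -> MRResult | None:
    """BP -> CVD MR using genome-wide clumped BP instruments outside the
    protein's cis window (no instrument reuse)."""
    lo, hi = region.cis_window(cfg.cis_window_bp)
    df = bp_sumstats.df
    outside = ~((df["CHR"] == region.chrom) & (df["POS"] >= lo) & (df["POS"] <= hi))
    candidates = bp_sumstats.subset(df.loc[outside, "SNP"])
    candidates.df = candidates.df[candidates.df["SNP"].isin(set(ld.snp_ids))]
    if len(candidates) == 0:
        return None
    clumped = greedy_clump(
        candidates, ld, p_threshold=cfg.p_instrument, r2_threshold=cfg.r2_clump,
        window_kb=cfg.clump_window_kb,
    )
    if len(clumped) == 0:
        return None
    try:
        pairs = kept_pairs(harmonize(clumped, cvd_sumstats, cfg.palindrome_eaf_limit))
    except ValueError:
        return None
    pairs = [p for p in pairs if p.beta_exp != 0]
    if not pairs:
        return None
    return mr_estimate(pairs, binary_outcome=True)


def prioritize_and_mediate(
    bp_records: list[ScreenRecord],
    cvd_records: list[ScreenRecord],
    proteins: dict[str, tuple[SumStatsTable, GeneRegion]],
    bp_sumstats: SumStatsTable,
    cvd_sumstats: SumStatsTable,
    ld: LDMatrix,
    cfg: PipelineConfig | None = None,
) -> tuple[list[CandidateRecord], dict[str, MediationResult]]:
    """Stage 3: colocalization (with pairwise-conditional rescue in
    gene-dense regions), three-trait colocalization, and mediation for
    prioritized candidates."""
    cfg = cfg or PipelineConfig()
    bp_by_protein = {r.protein_id: r for r in bp_records}
    regions = {pid: proteins[pid][1] for pid in proteins}
    candidates: list[CandidateRecord] = []
    mediations: dict[str, MediationResult] = {}
    for cvd_rec in sorted(cvd_records, key=lambda r: r.protein_id):
        if not cvd_rec.passed:
            continue
        bp_rec = bp_by_protein.get(cvd_rec.protein_id)
        if bp_rec is None or not bp_rec.passed:
            continue
        pid = cvd_rec.protein_id
        protein_ss, region = proteins[pid]
        cand = CandidateRecord(
            protein_id=pid,
            bp_trait=bp_sumstats.trait_name,
            cvd_trait=cvd_sumstats.trait_name,
        )
        cand.direction_concordant = bool(
            np.sign(bp_rec.mr.beta) == np.sign(cvd_rec.mr.beta)
        )
        if not cand.direction_concordant:
            cand.fail_reasons.append("direction_discordant")
        cand.gene_dense = any(
            region.overlaps_window(regions[other], cfg.gene_dense_flank_bp)
            for other in regions
            if other != pid
        )
        aligned = _aligned_region_panel([protein_ss, bp_sumstats, cvd_sumstats], region, cfg)
        if aligned is None:
            cand.fail_reasons.append("insufficient_region")
            candidates.append(cand)
            continue
        prot_cis, bp_cis, cvd_cis = aligned
        p1, p2, p12 = cfg.coloc_priors
        if cand.gene_dense:
            cand.used_pwcoco = True
            res_bp = pwcoco(prot_cis, bp_cis, ld, p1=p1, p2=p2, p12=p12)["best"]
            res_cvd = pwcoco(prot_cis, cvd_cis, ld, p1=p1, p2=p2, p12=p12)["best"]
        else:
            res_bp = coloc_abf(
                abf_from_sumstats(prot_cis), abf_from_sumstats(bp_cis), p1=p1, p2=p2, p12=p12
            )
            res_cvd = coloc_abf(
                abf_from_sumstats(prot_cis), abf_from_sumstats(cvd_cis), p1=p1, p2=p2, p12=p12
            )
        cand.coloc_bp_pp4 = res_bp.pp_h4
        cand.coloc_cvd_pp4 = res_cvd.pp_h4
        m1, m2, m3 = cfg.moloc_priors
        cand.moloc_pp = moloc_abf(
            abf_from_sumstats(prot_cis),
            abf_from_sumstats(bp_cis),
            abf_from_sumstats(cvd_cis),
            p1=m1, p2=m2, p3=m3,
        ).pp_abc
        if cand.coloc_bp_pp4 < cfg.pp_threshold:
            cand.fail_reasons.append("no_bp_colocalization")
        if cand.coloc_cvd_pp4 < cfg.pp_threshold:
            cand.fail_reasons.append("no_cvd_colocalization")
        cand.prioritized = not cand.fail_reasons
        candidates.append(cand)
        if not cand.prioritized:
            continue
        beta2 = _mediation_beta2(bp_sumstats, cvd_sumstats, ld, region, cfg)
        if beta2 is None:
            cand.fail_reasons.append("no_bp_instruments_for_mediation")
            continue
        mediations[pid] = proportion_mediated(
            bp_rec.mr.beta, bp_rec.mr.se,
            beta2.beta, beta2.se,
            cvd_rec.mr.beta, cvd_rec.mr.se,
        )
    return candidates, mediations


def screen_to_frame(records: list[ScreenRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "protein_id": r.protein_id,
                "outcome_id": r.outcome_id,
                "beta": r.mr.beta if r.mr else np.nan,
                "se": r.mr.se if r.mr else np.nan,
                "pval": r.mr.pval if r.mr else np.nan,
                "method": r.mr.method.value if r.mr else "",
                "n_snps": r.mr.n_snps if r.mr else 0,
                "odds_ratio": (r.mr.odds_ratio if r.mr and r.mr.odds_ratio else np.nan),
                "q_pval": r.het.pval if r.het else np.nan,
                "steiger_direction": r.steiger.direction.value if r.steiger else "",
                "reverse_flag": r.reverse_flag,
                "f_mean": r.f_mean,
                "fdr_adjusted_p": r.fdr_adjusted_p,
                "passed": r.passed,
                "fail_reasons": ";".join(r.fail_reasons),
            }
        )
    return pd.DataFrame(rows)


def candidates_to_frame(candidates: list[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in candidates])
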