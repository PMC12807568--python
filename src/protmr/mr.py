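"""Two-sample MR estimators (Wald ratio, IVW) and sensitivity filters
(Cochran's Q, Steiger directionality, bidirectional MR, BH-FDR)."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .sumstats import (
    HarmonizedPair,
    LDMatrix,
    SumStatsTable,
    harmonize,
    kept_pairs,
)
from .instruments import GeneRegion, greedy_clump

__all__ = [
    "MRMethod",
    "MRResult",
    "HeterogeneityResult",
    "SteigerResult",
    "SteigerDirection",
    "wald_ratio",
    "ivw",
    "mr_estimate",
    "cochran_q",
    "steiger",
    "bidirectional_check",
    "bh_fdr",
]


class MRMethod(str, Enum):
    WALD = "wald"
    IVW = "ivw"


class SteigerDirection(str, Enum):
    EXPOSURE_TO_OUTCOME = "exposure_to_outcome"
    OUTCOME_TO_EXPOSURE = "outcome_to_exposure"


@dataclass
class MRResult:
    beta: float
    se: float
    pval: float
    method: MRMethod
    n_snps: int
    odds_ratio: float | None = None

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class HeterogeneityResult:
    q_stat: float
    df: int
    pval: float


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction: SteigerDirection
    pval: float


def _two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _ratio_estimates(
    pairs: Sequence[HarmonizedPair], second_order: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    be = np.array([p.beta_exp for p in pairs])
    se_e = np.array([p.se_exp for p in pairs])
    bo = np.array([p.beta_out for p in pairs])
    se_o = np.array([p.se_out for p in pairs])
    if np.any(be == 0):
        raise ZeroDivisionError("wald ratio undefined: beta_exp = 0")
    beta = bo / be
    var = se_o**2 / be**2
    if second_order:
        var = var + bo**2 * se_e**2 / be**4
    return beta, np.sqrt(var)


def wald_ratio(pair: HarmonizedPair, second_order: bool = False, binary_outcome: bool = False) -> MRResult:
    """Single-instrument causal estimate: beta_out / beta_exp.

    Default SE is first-order (ignores se_exp); ``second_order`` adds the
    exposure-uncertainty term.
    """
    beta, se = _ratio_estimates([pair], second_order=second_order)
    b, s = float(beta[0]), float(se[0])
    return MRResult(
        beta=b,
        se=s,
        pval=_two_sided_p(b / s),
        method=MRMethod.WALD,
        n_snps=1,
        odds_ratio=float(np.exp(b)) if binary_outcome else None,
    )


def ivw(
    pairs: Sequence[HarmonizedPair],
    second_order: bool = False,
    binary_outcome: bool = False,
    overdispersion: bool = True,
) -> MRResult:
    """Inverse-variance-weighted combination of per-variant Wald ratios.

    By default uses multiplicative random effects: the variance is inflated
    by phi = max(1, Q/(J-1)), never deflated below the fixed-effect
    variance (which makes the test slightly conservative under the null).
    ``overdispersion=False`` gives the exactly calibrated fixed-effect test.
    """
    if len(pairs) < 2:
        raise ValueError("ivw requires >= 2 instruments; use wald_ratio")
    betas, ses = _ratio_estimates(pairs, second_order=second_order)
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    q = float((w * (betas - beta) ** 2).sum())
    phi = max(1.0, q / (len(pairs) - 1)) if overdispersion else 1.0
    se = float(np.sqrt(phi / w.sum()))
    return MRResult(
        beta=beta,
        se=se,
        pval=_two_sided_p(beta / se),
        method=MRMethod.IVW,
        n_snps=len(pairs),
        odds_ratio=float(np.exp(beta)) if binary_outcome else None,
    )


def mr_estimate(pairs: Sequence[HarmonizedPair], binary_outcome: bool = False, **kw) -> MRResult:
    """Dispatch: Wald ratio for a single instrument, IVW otherwise."""
    if len(pairs) == 0:
        raise ValueError("no instruments")
    if len(pairs) == 1:
        return wald_ratio(pairs[0], binary_outcome=binary_outcome, **kw)
    return ivw(pairs, binary_outcome=binary_outcome, **kw)


def cochran_q(pairs: Sequence[HarmonizedPair]) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test on the per-variant ratio estimates,
    referenced to the fixed-effect (phi = 1) IVW estimate."""
    if len(pairs) < 2:
        raise ValueError("cochran_q requires >= 2 instruments")
    betas, ses = _ratio_estimates(pairs)
    w = 1.0 / ses**2
    beta_fixed = (w * betas).sum() / w.sum()
    q = float((w * (betas - beta_fixed) ** 2).sum())
    df = len(pairs) - 1
    return HeterogeneityResult(q_stat=q, df=df, pval=float(stats.chi2.sf(q, df)))


def steiger(pairs: Sequence[HarmonizedPair], n_exp: float | None = None, n_out: float | None = None) -> SteigerResult:
    """Directionality check comparing instrument variance explained in
    exposure vs outcome.

    Per-trait r^2 sums z_j^2/(z_j^2 + n - 2) over instruments; the p-value
    compares Fisher-transformed correlations with variance
    1/(n_exp-3) + 1/(n_out-3).
    """
    if len(pairs) == 0:
        raise ValueError("steiger: no pairs")
    if n_exp is None:
        n_exp = float(np.mean([p.n_exp for p in pairs]))
    if n_out is None:
        n_out = float(np.mean([p.n_out for p in pairs]))
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("steiger requires sample sizes > 3")
    z_exp = np.array([p.beta_exp / p.se_exp for p in pairs])
    z_out = np.array([p.beta_out / p.se_out for p in pairs])
    r2_exp = float(np.clip((z_exp**2 / (z_exp**2 + n_exp - 2)).sum(), 0, 1))
    r2_out = float(np.clip((z_out**2 / (z_out**2 + n_out - 2)).sum(), 0, 1))
    direction = (
        SteigerDirection.EXPOSURE_TO_OUTCOME
        if r2_exp > r2_out
        else SteigerDirection.OUTCOME_TO_EXPOSURE
    )
    fz = np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))
    var = 1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    pval = _two_sided_p(fz / np.sqrt(var))
    return SteigerResult(r2_exposure=r2_exp, r2_outcome=r2_out, direction=direction, pval=pval)


def bidirectional_check(
    outcome_sumstats: SumStatsTable,
    exposure_sumstats: SumStatsTable,
    ld: LDMatrix,
    region: GeneRegion,
    cis_exclusion_bp: int = 1_000_000,
    p_instrument: float = 5e-8,
    p_reverse: float = 0.05,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> str:
    """Reverse-direction MR (outcome -> exposure) using outcome instruments
    outside the exposure's cis region.

    Returns "reverse_causal", "ok", or "untestable" (no valid reverse
    instruments).
    """
    lo, hi = region.cis_window(cis_exclusion_bp)
    df = outcome_sumstats.df
    outside = ~((df["CHR"] == region.chrom) & (df["POS"] >= lo) & (df["POS"] <= hi))
    candidates = outcome_sumstats.subset(df.loc[outside, "SNP"])
    candidates.df = candidates.df[candidates.df["SNP"].isin(set(ld.snp_ids))]
    if len(candidates) == 0:
        return "untestable"
    clumped = greedy_clump(
        candidates, ld, p_threshold=p_instrument, r2_threshold=r2_threshold, window_kb=window_kb
    )
    if len(clumped) == 0:
        return "untestable"
    try:
        pairs = kept_pairs(harmonize(clumped, exposure_sumstats))
    except ValueError:
        return "untestable"
    pairs = [p for p in pairs if p.beta_exp != 0]
    if len(pairs) == 0:
        return "untestable"
    result = mr_estimate(pairs)
    return "reverse_causal" if result.pval < p_reverse else "ok"


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
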