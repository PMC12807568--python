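"""Bayesian colocalization: two-trait ABF colocalization, three-trait
configuration enumeration, and pairwise-conditional colocalization for
regions with multiple independent signals.

All posterior algebra is carried out in log space with log-sum-exp; raw
exponentials of log Bayes factors are never formed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _st
from scipy.special import logsumexp

from .sumstats import LDMatrix, SumStatsTable, TraitType

__all__ = [
    "ABFVector",
    "ColocResult",
    "MolocResult",
    "ConditionalSumStats",
    "wakefield_labf",
    "abf_from_sumstats",
    "coloc_abf",
    "moloc_abf",
    "conditional_sumstats",
    "stepwise_select",
    "pwcoco",
    "MOLOC_CONFIGS",
]

DEFAULT_PRIOR_SD_QUANT = 0.15  # scaled by sd_y
DEFAULT_PRIOR_SD_BINARY = 0.2  # log-odds scale


class PanelMismatchError(ValueError):
    pass


class ConditioningError(RuntimeError):
    pass


@dataclass
class ABFVector:
    """Per-SNP log approximate Bayes factors for one trait in one region."""

    snp_ids: list[str]
    labf: np.ndarray
    v: np.ndarray
    w: float
    z: np.ndarray

    def __post_init__(self) -> None:
        self.labf = np.asarray(self.labf, dtype=float)
        if not np.all(np.isfinite(self.labf)):
            raise ValueError("non-finite log ABF")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class ColocResult:
    pp: dict  # keys H0..H4
    priors: tuple[float, float, float]
    n_snps: int

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]

    @property
    def pp_h3(self) -> float:
        return self.pp["H3"]


@dataclass
class MolocResult:
    pp: dict  # keys: 15 configuration labels ("zero", "a", "ab.c", "abc", ...)
    priors: tuple[float, float, float]
    n_snps: int

    @property
    def pp_abc(self) -> float:
        """Posterior that all three traits share one causal variant."""
        return self.pp["abc"]


@dataclass
class ConditionalSumStats:
    index_snps: list[str]
    snp_ids: list[str]
    beta_cond: np.ndarray
    se_cond: np.ndarray
    pval_cond: np.ndarray


def wakefield_labf(
    beta: np.ndarray,
    se: np.ndarray,
    trait_type: TraitType | str = TraitType.QUANTITATIVE,
    sd_y: float | None = None,
    prior_sd: float | None = None,
) -> np.ndarray:
    """Log approximate Bayes factor for association at each SNP.

    With V = se^2, W the prior effect variance and z = beta/se:
    labf = 0.5*log(V/(V+W)) + 0.5*z^2*W/(V+W).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    trait_type = TraitType(trait_type)
    if prior_sd is None:
        if trait_type is TraitType.QUANTITATIVE:
            prior_sd = DEFAULT_PRIOR_SD_QUANT * (sd_y if sd_y is not None else 1.0)
        else:
            prior_sd = DEFAULT_PRIOR_SD_BINARY
    v = se**2
    w = float(prior_sd) ** 2
    z = beta / se
    r = w / (v + w)
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def abf_from_sumstats(
    table: SumStatsTable,
    prior_sd: float | None = None,
    beta: np.ndarray | None = None,
    se: np.ndarray | None = None,
) -> ABFVector:
    """Build an ABFVector from a SumStatsTable (optionally overriding the
    effect columns, e.g. with conditional estimates)."""
    b = table.df["BETA"].to_numpy() if beta is None else np.asarray(beta, dtype=float)
    s = table.df["SE"].to_numpy() if se is None else np.asarray(se, dtype=float)
    labf = wakefield_labf(b, s, table.trait_type, sd_y=table.sd_y, prior_sd=prior_sd)
    if prior_sd is None:
        if table.trait_type is TraitType.QUANTITATIVE:
            prior_sd = DEFAULT_PRIOR_SD_QUANT * (table.sd_y if table.sd_y is not None else 1.0)
        else:
            prior_sd = DEFAULT_PRIOR_SD_BINARY
    return ABFVector(
        snp_ids=table.snp_ids, labf=labf, v=s**2, w=float(prior_sd) ** 2, z=b / s
    )


def _log_diff(la: float, lb: float) -> float:
    """log(exp(la) - exp(lb)); -inf when the difference is <= 0."""
    if lb >= la:
        return -np.inf
    return la + np.log1p(-np.exp(lb - la))


def _check_panels(*vectors: ABFVector) -> int:
    ids = vectors[0].snp_ids
    for v in vectors[1:]:
        if v.snp_ids != ids:
            raise PanelMismatchError("SNP panels differ between traits")
    return len(ids)


def coloc_abf(
    trait1: ABFVector,
    trait2: ABFVector,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Five-hypothesis colocalization posterior for two traits.

    H0 no association; H1/H2 only one trait associated; H3 both associated
    with distinct causal variants; H4 both associated sharing one variant.
    """
    n = _check_panels(trait1, trait2)
    l1, l2 = trait1.labf, trait2.labf
    ls1 = float(logsumexp(l1))
    ls2 = float(logsumexp(l2))
    ls12 = float(logsumexp(l1 + l2))
    lh = np.array(
        [
            0.0,
            np.log(p1) + ls1,
            np.log(p2) + ls2,
            np.log(p1) + np.log(p2) + _log_diff(ls1 + ls2, ls12),
            np.log(p12) + ls12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    return ColocResult(
        pp={f"H{i}": float(pp[i]) for i in range(5)},
        priors=(p1, p2, p12),
        n_snps=n,
    )


# the 15 three-trait configurations: blocks of jointly-associated traits,
# distinct causal variants across blocks; "zero" is the global null
MOLOC_CONFIGS: list[tuple[str, tuple[frozenset, ...]]] = [
    ("zero", ()),
    ("a", (frozenset("a"),)),
    ("b", (frozenset("b"),)),
    ("c", (frozenset("c"),)),
    ("ab", (frozenset("ab"),)),
    ("a.b", (frozenset("a"), frozenset("b"))),
    ("ac", (frozenset("ac"),)),
    ("a.c", (frozenset("a"), frozenset("c"))),
    ("bc", (frozenset("bc"),)),
    ("b.c", (frozenset("b"), frozenset("c"))),
    ("abc", (frozenset("abc"),)),
    ("ab.c", (frozenset("ab"), frozenset("c"))),
    ("ac.b", (frozenset("ac"), frozenset("b"))),
    ("bc.a", (frozenset("bc"), frozenset("a"))),
    ("a.b.c", (frozenset("a"), frozenset("b"), frozenset("c"))),
]


def moloc_abf(
    trait_a: ABFVector,
    trait_b: ABFVector,
    trait_c: ABFVector,
    p1: float = 1e-4,
    p2: float = 1e-6,
    p3: float = 1e-7,
) -> MolocResult:
    """Posterior over the 15 three-trait colocalization configurations.

    A block's per-SNP Bayes factor is the product of its member traits'
    ABFs; distinct blocks must occupy distinct SNPs, handled by
    inclusion-exclusion over the block sums.
    """
    n = _check_panels(trait_a, trait_b, trait_c)
    labf = {"a": trait_a.labf, "b": trait_b.labf, "c": trait_c.labf}
    # log sums over SNPs for every non-empty trait subset
    ls: dict[frozenset, float] = {}
    for subset in ("a", "b", "c", "ab", "ac", "bc", "abc"):
        key = frozenset(subset)
        ls[key] = float(logsumexp(sum(labf[t] for t in subset)))
    prior_of_block = {1: np.log(p1), 2: np.log(p2), 3: np.log(p3)}

    log_weights = {}
    for name, blocks in MOLOC_CONFIGS:
        lprior = sum(prior_of_block[len(b)] for b in blocks)
        log_weights[name] = lprior + _log_distinct_assignments(blocks, ls)
    labels = list(log_weights)
    lw = np.array([log_weights[k] for k in labels])
    pp = np.exp(lw - logsumexp(lw))
    return MolocResult(
        pp={k: float(v) for k, v in zip(labels, pp)},
        priors=(p1, p2, p3),
        n_snps=n,
    )


def _log_distinct_assignments(blocks: tuple[frozenset, ...], ls: dict) -> float:
    """log of the summed evidence over assignments of *distinct* SNPs to the
    blocks, via inclusion-exclusion on coincidence patterns."""
    k = len(blocks)
    if k == 0:
        return 0.0
    if k == 1:
        return ls[blocks[0]]
    if k == 2:
        merged = blocks[0] | blocks[1]
        return _log_diff(ls[blocks[0]] + ls[blocks[1]], ls[merged])
    if k == 3:
        b0, b1, b2 = blocks
        pos = logsumexp(
            [ls[b0] + ls[b1] + ls[b2], np.log(2.0) + ls[b0 | b1 | b2]]
        )
        neg = logsumexp(
            [ls[b0 | b1] + ls[b2], ls[b0 | b2] + ls[b1], ls[b1 | b2] + ls[b0]]
        )
        return _log_diff(float(pos), float(neg))
    raise ValueError("at most 3 blocks supported")


def _genotype_variance(eaf: np.ndarray) -> np.ndarray:
    return 2.0 * eaf * (1.0 - eaf)


def _var_y_estimate(v: np.ndarray, beta: np.ndarray, se: np.ndarray, n: float) -> float:
    # per-SNP implied phenotypic variance; robust to a few outliers
    return float(np.median(v * beta**2 + n * v * se**2))


def conditional_sumstats(
    sumstats: SumStatsTable,
    ld: LDMatrix,
    index_set: Sequence[str],
    n: float | None = None,
    r2_collinear: float = 0.9,
) -> ConditionalSumStats:
    """Approximate conditional association statistics given an index set.

    Joint coefficients over the index set are solved from the LD-scaled
    normal equations; each non-index SNP's conditional effect subtracts its
    LD projection onto the index set, with SEs propagated through the same
    linear algebra.  Index SNPs themselves get conditional z = 0.
    """
    df = sumstats.df
    snp_ids = df["SNP"].tolist()
    if n is None:
        n = float(df["N"].median())
    index_set = list(index_set)
    for s in index_set:
        if s not in ld:
            raise KeyError(f"index SNP not in LD panel: {s}")
    beta = df["BETA"].to_numpy(dtype=float)
    se = df["SE"].to_numpy(dtype=float)
    eaf = df["EAF"].to_numpy(dtype=float)
    v = _genotype_variance(eaf)
    pos = {s: i for i, s in enumerate(snp_ids)}

    if not index_set:
        return ConditionalSumStats(
            index_snps=[],
            snp_ids=snp_ids,
            beta_cond=beta.copy(),
            se_cond=se.copy(),
            pval_cond=2 * _st.norm.sf(np.abs(beta / se)),
        )

    r_ii = ld.submatrix(index_set)
    k = len(index_set)
    for i in range(k):
        for j in range(i + 1, k):
            if r_ii[i, j] ** 2 > r2_collinear:
                raise ConditioningError(
                    f"collinear index pair: {index_set[i]}, {index_set[j]} "
                    f"(r^2 = {r_ii[i, j] ** 2:.3f})"
                )
    eigmin = float(np.linalg.eigvalsh(r_ii).min())
    if eigmin <= 1e-6:
        raise ConditioningError(f"ill-conditioned index LD (min eigenvalue {eigmin:.2e})")

    idx = [pos[s] for s in index_set]
    v_i = v[idx]
    b_i = beta[idx]
    sqrt_vi = np.sqrt(v_i)
    s_ii = sqrt_vi[:, None] * r_ii * sqrt_vi[None, :]
    c_i = v_i * b_i  # X_I'y / n
    var_y = _var_y_estimate(v, beta, se, n)

    b_joint = np.linalg.solve(s_ii, c_i)
    s_ii_inv = np.linalg.inv(s_ii)

    # LD between every panel SNP and the index set, allele-oriented
    panel_idx = [ld.index_of(s) for s in snp_ids]
    ld_idx = [ld.index_of(s) for s in index_set]
    r_pi = ld.r[np.ix_(panel_idx, ld_idx)]
    u = np.sqrt(v)[:, None] * r_pi * sqrt_vi[None, :]  # n x k covariances

    a_inv_u = u @ s_ii_inv  # rows: u_i' A^{-1}
    s_cond = v - np.einsum("ij,ij->i", a_inv_u, u)
    s_cond = np.maximum(s_cond, 1e-12)
    b_cond = (v * beta - a_inv_u @ c_i) / s_cond

    # residual variance of the augmented fit, per SNP, floored at >= 0;
    # explained = b_aug' c_aug with b_I_aug = A^{-1}(c_I - u b_cond)
    bi_aug = (s_ii_inv @ (c_i[:, None] - u.T * b_cond[None, :])).T  # panel x k
    explained = b_cond * v * beta + bi_aug @ c_i
    dof = max(n - k - 2, 1.0)
    sigma2 = np.maximum(var_y - explained, 0.0) * n / dof
    sigma2 = np.maximum(sigma2, 1e-12)
    se_cond = np.sqrt(sigma2 / (n * s_cond))

    in_index = np.isin(np.array(snp_ids), index_set)
    b_cond[in_index] = 0.0
    se_cond[in_index] = se[in_index]

    z = b_cond / se_cond
    pval = 2 * _st.norm.sf(np.abs(z))
    pval[in_index] = 1.0
    return ConditionalSumStats(
        index_snps=index_set,
        snp_ids=snp_ids,
        beta_cond=b_cond,
        se_cond=se_cond,
        pval_cond=pval,
    )


def stepwise_select(
    sumstats: SumStatsTable,
    ld: LDMatrix,
    n: float | None = None,
    p_select: float = 5e-8,
    r2_collinear: float = 0.9,
    max_signals: int = 10,
) -> list[str]:
    """Forward stepwise selection of conditionally independent signals."""
    selected: list[str] = []
    snp_ids = sumstats.df["SNP"].tolist()
    while len(selected) < max_signals:
        cond = conditional_sumstats(sumstats, ld, selected, n=n, r2_collinear=r2_collinear)
        best_snp, best_p = None, p_select
        for s, p in zip(cond.snp_ids, cond.pval_cond):
            if s in selected:
                continue
            if any(ld.r_between(s, t) ** 2 > r2_collinear for t in selected):
                continue
            if p < best_p:
                best_snp, best_p = s, p
        if best_snp is None:
            break
        selected.append(best_snp)
    return selected


def pwcoco(
    trait1: SumStatsTable,
    trait2: SumStatsTable,
    ld: LDMatrix,
    n1: float | None = None,
    n2: float | None = None,
    p_select: float = 5e-8,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> dict:
    """Pairwise conditional colocalization.

    Selects independent signals per trait, builds the marginal dataset plus
    one conditional dataset per signal (conditioned on the other signals of
    that trait), and runs coloc on every cross-trait pair of datasets.
    Returns the best (max PP H4) pair plus the full matrix.
    """
    if trait1.snp_ids != trait2.snp_ids:
        raise PanelMismatchError("pwcoco requires a shared SNP panel")
    sel1 = stepwise_select(trait1, ld, n=n1, p_select=p_select)
    sel2 = stepwise_select(trait2, ld, n=n2, p_select=p_select)

    def datasets(table: SumStatsTable, selected: list[str], n, prior_sd):
        out = [("marginal", abf_from_sumstats(table, prior_sd=prior_sd))]
        if len(selected) >= 2:
            for s in selected:
                others = [t for t in selected if t != s]
                cond = conditional_sumstats(table, ld, others, n=n)
                out.append(
                    (
                        f"cond_on_{'+'.join(others)}",
                        abf_from_sumstats(table, prior_sd=prior_sd, beta=cond.beta_cond, se=cond.se_cond),
                    )
                )
        return out

    ds1 = datasets(trait1, sel1, n1, prior_sd1)
    ds2 = datasets(trait2, sel2, n2, prior_sd2)
    results = {}
    best_key, best_res = None, None
    for name1, v1 in ds1:
        for name2, v2 in ds2:
            res = coloc_abf(v1, v2, p1=p1, p2=p2, p12=p12)
            results[(name1, name2)] = res
            if best_res is None or res.pp_h4 > best_res.pp_h4:
                best_key, best_res = (name1, name2), res
    return {
        "best_pair": best_key,
        "best": best_res,
        "all": results,
        "signals_trait1": sel1,
        "signals_trait2": sel2,
    }
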