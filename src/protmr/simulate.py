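"""Synthetic GWAS generator: LD-structured genotypes and a protein -> BP ->
binary CVD causal chain with known ground truth, emitting per-trait summary
statistics from non-overlapping cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .instruments import GeneRegion
from .sumstats import LDMatrix, SumStatsTable, TraitType

__all__ = [
    "SimulationConfig",
    "PanelSimConfig",
    "TruthRecord",
    "SNPPanel",
    "CohortData",
    "simulate_genotypes",
    "simulate_chain",
    "simulate_panel",
    "adjust_for_medication",
    "compute_sumstats",
    "reference_ld",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Structural parameters of the protein -> SBP -> CVD chain.

    ``gamma`` are per-causal-SNP effects on the protein (SD units, applied to
    standardized dosages); ``alpha`` is the protein->SBP effect (mmHg per SD);
    ``theta_bp`` the SBP->CVD liability effect (log-odds per mmHg);
    ``theta_direct`` the direct protein->CVD effect (log-odds per SD).
    ``bp_causal_idx``/``kappa`` optionally give SNPs a direct effect on SBP
    (mmHg per standardized dosage), providing BP instruments outside the
    protein's cis machinery.
    """

    m_snps: int = 60
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    n_protein: int = 5000
    n_bp: int = 5000
    n_cvd: int = 5000
    n_ref: int = 2000
    causal_idx: tuple[int, ...] = (10, 20, 30)
    gamma: tuple[float, ...] = (0.3, 0.25, 0.2)
    bp_causal_idx: tuple[int, ...] = ()
    kappa: tuple[float, ...] = ()
    alpha: float = 2.0
    theta_bp: float = 0.02
    theta_direct: float = 0.0
    prevalence: float = 0.2
    med_fraction: float = 0.0
    med_effect_sbp: float = 15.0
    med_effect_dbp: float = 10.0
    seed: int = 0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_spacing: int = 5_000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0.01, 0.5]: {self.maf_range}")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        for n in (self.n_protein, self.n_bp, self.n_cvd, self.n_ref):
            if n < 100:
                raise ValueError("cohort sizes must be >= 100")
        if len(self.causal_idx) != len(self.gamma):
            raise ValueError("causal_idx and gamma lengths differ")
        if len(self.bp_causal_idx) != len(self.kappa):
            raise ValueError("bp_causal_idx and kappa lengths differ")
        for i in (*self.causal_idx, *self.bp_causal_idx):
            if not 0 <= i < self.m_snps:
                raise ValueError(f"causal index {i} outside [0, {self.m_snps})")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


@dataclass
class TruthRecord:
    """Ground-truth mediation quantities implied by a config."""

    beta1_true: float
    beta2_true: float
    beta_te_true: float
    pm_true: float | None  # None when beta_te_true == 0 (undefined)

    @classmethod
    def from_config(cls, cfg: SimulationConfig) -> "TruthRecord":
        beta_te = cfg.theta_bp * cfg.alpha + cfg.theta_direct
        pm = (cfg.theta_bp * cfg.alpha / beta_te) if beta_te != 0 else None
        return cls(cfg.alpha, cfg.theta_bp, beta_te, pm)


@dataclass
class SNPPanel:
    """Variant metadata shared by all cohorts of one simulation."""

    snp_ids: list[str]
    chrom: str
    pos: np.ndarray
    ea: list[str]
    oa: list[str]
    maf: np.ndarray

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class CohortData:
    genotypes: np.ndarray  # n x m dosages in {0,1,2}
    phenotype: np.ndarray
    panel: SNPPanel
    on_medication: np.ndarray | None = None


def simulate_genotypes(
    m_snps: int,
    maf_range: tuple[float, float],
    ld_rho: float,
    n: int,
    seed_or_rng,
    mafs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw an n x m dosage matrix from a Gaussian-copula haplotype model.

    Each of the two haplotypes per individual is a latent AR(1) Gaussian
    vector with adjacent correlation ``ld_rho``, thresholded at the MAF
    quantile; the dosage is the haplotype sum.  Returns (dosages, target
    MAFs).  Deterministic for a given integer seed.
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    if mafs is None:
        lo, hi = maf_range
        mafs = rng.uniform(lo, hi, size=m_snps)
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("target MAFs must lie in (0, 0.5]")
    thresholds = stats.norm.ppf(mafs)
    dosage = np.zeros((n, m_snps), dtype=np.int8)
    for _ in range(2):
        z = _ar1_latent(n, m_snps, ld_rho, rng)
        dosage += (z < thresholds).astype(np.int8)
    return dosage, mafs


def _ar1_latent(n: int, m: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((n, m))
    if rho > 0:
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
    return z


def _make_panel(cfg: SimulationConfig, mafs: np.ndarray, rng: np.random.Generator) -> SNPPanel:
    m = cfg.m_snps
    alleles = np.array(["A", "C", "G", "T"])
    ea = alleles[rng.integers(0, 4, size=m)]
    # other allele drawn to avoid palindromic pairs so harmonization is exact
    non_palindromic = {"A": ["C", "G"], "T": ["C", "G"], "C": ["A", "T"], "G": ["A", "T"]}
    oa = np.array([non_palindromic[a][rng.integers(0, 2)] for a in ea])
    pos = cfg.pos_start + cfg.pos_spacing * np.arange(m)
    ids = [f"rs{cfg.chrom}_{p}" for p in pos]
    return SNPPanel(ids, cfg.chrom, pos, list(ea), list(oa), mafs)


def _standardize(g: np.ndarray) -> np.ndarray:
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    return (g - mu) / sd


def simulate_chain(cfg: SimulationConfig) -> dict:
    """Simulate the full causal chain over four disjoint cohorts.

    Returns a dict with keys ``protein``, ``bp``, ``cvd``, ``ref`` (CohortData
    or reference dosages), ``panel``, ``ld`` (LDMatrix from the reference
    panel), ``truth`` (TruthRecord), and the three per-trait summary-stat
    tables ``sumstats_protein``, ``sumstats_bp``, ``sumstats_cvd``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    mafs = rng.uniform(lo, hi, size=cfg.m_snps)
    panel = _make_panel(cfg, mafs, rng)

    cohorts = {}
    for name, n in [("protein", cfg.n_protein), ("bp", cfg.n_bp), ("cvd", cfg.n_cvd), ("ref", cfg.n_ref)]:
        g, _ = simulate_genotypes(cfg.m_snps, cfg.maf_range, cfg.ld_rho, n, rng, mafs=mafs)
        cohorts[name] = g

    gamma = np.zeros(cfg.m_snps)
    gamma[list(cfg.causal_idx)] = cfg.gamma
    kappa = np.zeros(cfg.m_snps)
    if cfg.bp_causal_idx:
        kappa[list(cfg.bp_causal_idx)] = cfg.kappa

    def protein_of(g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        gs = _standardize(g)
        genetic = gs @ gamma
        var_g = float(np.var(genetic))
        if var_g >= 1.0:
            raise SimulationError(f"genetic variance of protein {var_g:.3f} >= 1")
        noise = rng.standard_normal(len(g)) * np.sqrt(1.0 - var_g)
        return genetic + noise

    def sbp_of(g: np.ndarray, prot: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        gs = _standardize(g)
        return 120.0 + cfg.alpha * prot + gs @ kappa + rng.standard_normal(len(g)) * 15.0

    # protein cohort
    g_p = cohorts["protein"]
    prot_p = protein_of(g_p, rng)
    protein_cohort = CohortData(g_p, prot_p, panel)

    # BP cohort: latent SBP, medication lowers the measured value
    g_b = cohorts["bp"]
    prot_b = protein_of(g_b, rng)
    sbp_latent = sbp_of(g_b, prot_b, rng)
    on_med = rng.random(cfg.n_bp) < cfg.med_fraction
    sbp_measured = sbp_latent - cfg.med_effect_sbp * on_med
    sbp_adj, _ = adjust_for_medication(
        sbp_measured, np.zeros_like(sbp_measured), on_med,
        sbp_add=cfg.med_effect_sbp, dbp_add=cfg.med_effect_dbp,
    )
    bp_cohort = CohortData(g_b, sbp_adj, panel, on_medication=on_med)

    # CVD cohort: logistic liability thresholded at the prevalence quantile
    g_c = cohorts["cvd"]
    prot_c = protein_of(g_c, rng)
    sbp_c = sbp_of(g_c, prot_c, rng)
    liability = (
        cfg.theta_bp * (sbp_c - 120.0)
        + cfg.theta_direct * prot_c
        + rng.logistic(size=cfg.n_cvd)
    )
    threshold = np.quantile(liability, 1.0 - cfg.prevalence)
    cases = liability > threshold
    if cases.sum() == 0 or cases.sum() == cfg.n_cvd:
        raise SimulationError("infeasible prevalence: degenerate case/control split")
    cvd_cohort = CohortData(g_c, cases.astype(float), panel)

    truth = TruthRecord.from_config(cfg)
    ld = reference_ld(cohorts["ref"], panel)
    return {
        "protein": protein_cohort,
        "bp": bp_cohort,
        "cvd": cvd_cohort,
        "ref": cohorts["ref"],
        "panel": panel,
        "ld": ld,
        "truth": truth,
        "sumstats_protein": compute_sumstats(protein_cohort, TraitType.QUANTITATIVE, "protein"),
        "sumstats_bp": compute_sumstats(bp_cohort, TraitType.QUANTITATIVE, "SBP"),
        "sumstats_cvd": compute_sumstats(cvd_cohort, TraitType.BINARY, "CVD"),
    }


def reference_ld(genotypes: np.ndarray, panel: SNPPanel) -> LDMatrix:
    """Signed allelic correlation matrix from a reference dosage panel."""
    g = np.asarray(genotypes, dtype=float)
    sd = g.std(axis=0)
    keep_sd = np.where(sd == 0, 1.0, sd)
    gs = (g - g.mean(axis=0)) / keep_sd
    r = gs.T @ gs / len(g)
    r[np.diag_indices_from(r)] = 1.0
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    alleles = {s: (panel.ea[i], panel.oa[i]) for i, s in enumerate(panel.snp_ids)}
    return LDMatrix(snp_ids=list(panel.snp_ids), alleles=alleles, r=r)


def adjust_for_medication(
    sbp: np.ndarray,
    dbp: np.ndarray,
    on_med: np.ndarray,
    sbp_add: float = 15.0,
    dbp_add: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Add 15 mmHg to SBP and 10 mmHg to DBP for medicated individuals."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    on_med = np.asarray(on_med, dtype=bool)
    if not (sbp.shape == dbp.shape == on_med.shape):
        raise ValueError(
            f"shape mismatch: sbp {sbp.shape}, dbp {dbp.shape}, on_med {on_med.shape}"
        )
    return sbp + sbp_add * on_med, dbp + dbp_add * on_med


def _linear_assoc(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP simple linear regression: returns (beta, se)."""
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc * gc).sum(axis=0)
    sxy = gc.T @ yc
    beta = sxy / sxx
    syy = float(yc @ yc)
    sse = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(sse / (n - 2) / sxx)
    return beta, se


def _logistic_assoc(g: np.ndarray, y: np.ndarray, max_iter: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP univariate logistic regression via Newton updates.

    Falls back to the score-test approximation (beta = U/V, se = 1/sqrt(V))
    for SNPs where the iteration fails to converge (e.g. separation).
    """
    n, m = g.shape
    ybar = y.mean()
    a = np.full(m, special.logit(ybar))
    b = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        eta = a[None, :] + g * b[None, :]
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu
        g0 = resid.sum(axis=0)
        g1 = (g * resid).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * g).sum(axis=0)
        h11 = (w * g * g).sum(axis=0)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        step_ok = np.isfinite(da) & np.isfinite(db)
        a = np.where(step_ok, a + da, a)
        b = np.where(step_ok, b + db, b)
        converged = step_ok & (np.abs(da) < 1e-8) & (np.abs(db) < 1e-8)
        if converged.all():
            break
    eta = a[None, :] + g * b[None, :]
    mu = special.expit(eta)
    w = mu * (1.0 - mu)
    h00 = w.sum(axis=0)
    h01 = (w * g).sum(axis=0)
    h11 = (w * g * g).sum(axis=0)
    det = h00 * h11 - h01 * h01
    se = np.sqrt(np.where(det > 0, h00 / det, np.nan))
    ok = converged & np.isfinite(b) & np.isfinite(se) & (np.abs(b) < 20)
    if not ok.all():
        # score-test fallback: U = sum g (y - ybar), V = ybar(1-ybar) Sxx
        gc = g - g.mean(axis=0)
        u = gc.T @ (y - ybar)
        v = ybar * (1 - ybar) * (gc * gc).sum(axis=0)
        b = np.where(ok, b, u / v)
        se = np.where(ok, se, 1.0 / np.sqrt(v))
    return b, se


def compute_sumstats(
    cohort: CohortData,
    trait_type: TraitType | str,
    trait_name: str,
) -> SumStatsTable:
    """Per-SNP association scan of a cohort; returns a SumStatsTable.

    Quantitative traits use simple linear regression; binary traits a
    univariate logistic fit with score-test fallback.  Monomorphic SNPs are
    dropped.  EAF is the mean dosage / 2.
    """
    trait_type = TraitType(trait_type)
    g = np.asarray(cohort.genotypes, dtype=float)
    y = np.asarray(cohort.phenotype, dtype=float)
    n = len(y)
    if np.ptp(y) == 0:
        raise SimulationError("phenotype is constant")
    if trait_type is TraitType.BINARY and len(np.unique(y)) < 2:
        raise SimulationError("binary phenotype has a single class")
    poly = g.std(axis=0) > 0
    g = g[:, poly]
    panel = cohort.panel
    if trait_type is TraitType.QUANTITATIVE:
        beta, se = _linear_assoc(g, y)
    else:
        beta, se = _logistic_assoc(g, y)
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    eaf = g.mean(axis=0) / 2.0
    idx = np.flatnonzero(poly)
    df = pd.DataFrame(
        {
            "SNP": [panel.snp_ids[i] for i in idx],
            "CHR": panel.chrom,
            "POS": panel.pos[idx],
            "EA": [panel.ea[i] for i in idx],
            "OA": [panel.oa[i] for i in idx],
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": pval,
            "N": n,
        }
    )
    if trait_type is TraitType.BINARY:
        df["N_CASES"] = int(y.sum())
    sd_y = float(np.std(y, ddof=1)) if trait_type is TraitType.QUANTITATIVE else None
    return SumStatsTable(trait_name=trait_name, trait_type=trait_type, df=df, sd_y=sd_y)


@dataclass
class PanelSimConfig:
    """Multi-protein panel: several genes on one chromosome, a subset with
    true BP-mediated CVD effects, plus a dedicated block of SNPs acting on
    SBP directly (BP instruments outside every protein's cis window)."""

    n_genes: int = 20
    snps_per_gene: int = 30
    causal_per_gene: int = 1
    gamma_scale: float = 0.5
    true_protein_idx: tuple[int, ...] = (0, 4, 8, 12, 16)
    alpha: float = 3.5
    theta_bp: float = 0.14
    theta_direct: float = 0.18
    n_bp_snps: int = 8
    kappa_scale: float = 2.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.4
    n_protein: int = 6000
    n_bp: int = 8000
    n_cvd: int = 12000
    n_ref: int = 2000
    prevalence: float = 0.25
    gene_span_bp: int = 3_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for i in self.true_protein_idx:
            if not 0 <= i < self.n_genes:
                raise ValueError(f"true protein index {i} out of range")


def simulate_panel(cfg: PanelSimConfig) -> dict:
    """Simulate a proteome-like panel with known BP-mediated truth.

    Returns sumstats per protein, BP and CVD sumstats, gene regions, the
    reference LDMatrix, and per-protein TruthRecords.
    """
    rng = np.random.default_rng(cfg.seed)
    m_gene = cfg.n_genes * cfg.snps_per_gene
    m = m_gene + cfg.n_bp_snps
    lo, hi = cfg.maf_range
    mafs = rng.uniform(lo, hi, size=m)

    # genome layout: gene g occupies a window around its SNP block; the BP
    # block sits far downstream of every cis window
    spacing = 5_000
    pos = np.empty(m, dtype=int)
    regions: dict[str, GeneRegion] = {}
    for g in range(cfg.n_genes):
        start = 1_000_000 + g * cfg.gene_span_bp
        sl = slice(g * cfg.snps_per_gene, (g + 1) * cfg.snps_per_gene)
        pos[sl] = start + spacing * np.arange(cfg.snps_per_gene)
        regions[f"P{g:02d}"] = GeneRegion(
            gene_id=f"P{g:02d}", chrom="1",
            start=start, end=int(start + spacing * (cfg.snps_per_gene - 1)),
        )
    bp_start = 1_000_000 + cfg.n_genes * cfg.gene_span_bp + 5_000_000
    pos[m_gene:] = bp_start + spacing * np.arange(cfg.n_bp_snps)

    panel = SNPPanel(
        snp_ids=[f"rs1_{p}" for p in pos],
        chrom="1",
        pos=pos,
        ea=["A"] * m,
        oa=["G"] * m,
        maf=mafs,
    )
    # deterministic non-palindromic allele labels
    alleles = np.array(["A", "C", "G", "T"])
    ea = alleles[rng.integers(0, 4, size=m)]
    non_pal = {"A": ["C", "G"], "T": ["C", "G"], "C": ["A", "T"], "G": ["A", "T"]}
    panel.ea = list(ea)
    panel.oa = [non_pal[a][int(rng.integers(0, 2))] for a in ea]

    cohorts = {}
    for name, n in [("protein", cfg.n_protein), ("bp", cfg.n_bp), ("cvd", cfg.n_cvd), ("ref", cfg.n_ref)]:
        g_mat, _ = simulate_genotypes(m, cfg.maf_range, cfg.ld_rho, n, rng, mafs=mafs)
        cohorts[name] = g_mat

    # per-gene causal architecture
    gammas = np.zeros((cfg.n_genes, m))
    for g in range(cfg.n_genes):
        block = np.arange(g * cfg.snps_per_gene, (g + 1) * cfg.snps_per_gene)
        chosen = rng.choice(block, size=cfg.causal_per_gene, replace=False)
        signs = rng.choice([-1.0, 1.0], size=cfg.causal_per_gene)
        gammas[g, chosen] = cfg.gamma_scale * signs
    kappa = np.zeros(m)
    kappa[m_gene:] = cfg.kappa_scale * rng.choice([-1.0, 1.0], size=cfg.n_bp_snps)
    alphas = np.zeros(cfg.n_genes)
    alphas[list(cfg.true_protein_idx)] = cfg.alpha
    thetas_direct = np.zeros(cfg.n_genes)
    thetas_direct[list(cfg.true_protein_idx)] = cfg.theta_direct

    def proteins_of(g_mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        gs = _standardize(g_mat)
        genetic = gs @ gammas.T  # n x n_genes
        var_g = genetic.var(axis=0)
        if np.any(var_g >= 1.0):
            raise SimulationError("genetic protein variance >= 1")
        noise = rng.standard_normal(genetic.shape) * np.sqrt(1.0 - var_g)
        return genetic + noise

    def sbp_of(g_mat: np.ndarray, prot: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        gs = _standardize(g_mat)
        return 120.0 + prot @ alphas + gs @ kappa + rng.standard_normal(len(g_mat)) * 15.0

    g_p = cohorts["protein"]
    prot_p = proteins_of(g_p, rng)

    g_b = cohorts["bp"]
    prot_b = proteins_of(g_b, rng)
    sbp_b = sbp_of(g_b, prot_b, rng)

    g_c = cohorts["cvd"]
    prot_c = proteins_of(g_c, rng)
    sbp_c = sbp_of(g_c, prot_c, rng)
    liability = (
        cfg.theta_bp * (sbp_c - 120.0)
        + prot_c @ thetas_direct
        + rng.logistic(size=cfg.n_cvd)
    )
    threshold = np.quantile(liability, 1.0 - cfg.prevalence)
    cases = (liability > threshold).astype(float)
    if cases.sum() in (0, cfg.n_cvd):
        raise SimulationError("degenerate case/control split")

    protein_sumstats = {}
    truths = {}
    for g in range(cfg.n_genes):
        pid = f"P{g:02d}"
        cohort = CohortData(g_p, prot_p[:, g], panel)
        protein_sumstats[pid] = compute_sumstats(cohort, TraitType.QUANTITATIVE, pid)
        beta_te = cfg.theta_bp * alphas[g] + thetas_direct[g]
        truths[pid] = TruthRecord(
            beta1_true=float(alphas[g]),
            beta2_true=cfg.theta_bp,
            beta_te_true=float(beta_te),
            pm_true=(float(cfg.theta_bp * alphas[g] / beta_te) if beta_te != 0 else None),
        )

    bp_cohort = CohortData(g_b, sbp_b, panel)
    cvd_cohort = CohortData(g_c, cases, panel)
    return {
        "protein_sumstats": protein_sumstats,
        "regions": regions,
        "sumstats_bp": compute_sumstats(bp_cohort, TraitType.QUANTITATIVE, "SBP"),
        "sumstats_cvd": compute_sumstats(cvd_cohort, TraitType.BINARY, "CVD"),
        "ld": reference_ld(cohorts["ref"], panel),
        "panel": panel,
        "truths": truths,
        "true_proteins": [f"P{g:02d}" for g in cfg.true_protein_idx],
    }


def simulate_region_table(
    ld: LDMatrix,
    eaf: np.ndarray,
    n: int,
    causal: dict[int, float],
    rng: np.random.Generator,
    trait_name: str = "trait",
    chrom: str = "1",
    pos: np.ndarray | None = None,
) -> SumStatsTable:
    """Draw marginal association z-scores for one region directly from the
    multivariate-normal summary-statistic model z ~ N(R @ e, R), where e has
    ``causal[j]`` at each causal index, and package them as a SumStatsTable
    (per-SD betas: beta = z/sqrt(n), se = 1/sqrt(n), sd_y = 1).

    Fast stand-in for individual-level simulation when only regional
    summary statistics are needed.
    """
    r = ld.r
    m = r.shape[0]
    e = np.zeros(m)
    for j, lam in causal.items():
        e[j] = lam
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))
    z = r @ e + chol @ rng.standard_normal(m)
    se = np.full(m, 1.0 / np.sqrt(n))
    beta = z * se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    if pos is None:
        pos = 1_000 + 100 * np.arange(m)
    df = pd.DataFrame(
        {
            "SNP": list(ld.snp_ids),
            "CHR": chrom,
            "POS": pos,
            "EA": [ld.alleles[s][0] if ld.alleles[s][0] != "?" else "A" for s in ld.snp_ids],
            "OA": [ld.alleles[s][1] if ld.alleles[s][1] != "?" else "G" for s in ld.snp_ids],
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": pval,
            "N": n,
        }
    )
    return SumStatsTable(trait_name=trait_name, trait_type=TraitType.QUANTITATIVE, df=df, sd_y=1.0)
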