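"""Self-contained validation experiments: estimator identities, enumeration
oracles, calibration simulations, and the end-to-end funnel.

Each function recomputes its quantity from scratch by running the package on
freshly simulated data, and returns a plain dict of metrics so callers
(pytest, the acceptance report script) can assert or report on them.
"""

from __future__ import annotations

import numpy as np

from .coloc import (
    ABFVector,
    abf_from_sumstats,
    coloc_abf,
    conditional_sumstats,
    moloc_abf,
    pwcoco,
)
from .instruments import GeneRegion, greedy_clump, select_cis
from .mediation import proportion_mediated
from .mr import bh_fdr, cochran_q, ivw, mr_estimate, wald_ratio
from .pipeline import PipelineConfig, prioritize_and_mediate, run_outcome_stage, run_screen, screen_to_frame
from .simulate import (
    PanelSimConfig,
    SimulationConfig,
    SNPPanel,
    adjust_for_medication,
    reference_ld,
    simulate_chain,
    simulate_genotypes,
    simulate_panel,
    simulate_region_table,
)
from .sumstats import HarmonizedPair, harmonize, kept_pairs  # noqa: F401


def _pair(beta_exp, se_exp, beta_out, se_out, snp="s", n_exp=10_000, n_out=10_000):
    return HarmonizedPair(
        snp_id=snp, beta_exp=beta_exp, se_exp=se_exp, eaf_exp=0.3,
        beta_out=beta_out, se_out=se_out, eaf_out=0.3, n_exp=n_exp, n_out=n_out,
    )


# ---------------------------------------------------------------- criterion 1

def estimator_identities(seed: int = 0, n_vectors: int = 1000) -> dict:
    """Exact identities: single-pair IVW dispatch == Wald; IVW == weighted
    origin regression; Q == 0 on identical ratios; BH-FDR vs a textbook
    step-up reimplementation."""
    rng = np.random.default_rng(seed)
    p = _pair(0.5, 0.05, 0.25, 0.05)
    wald = wald_ratio(p)
    dispatch = mr_estimate([p])
    wald_dispatch_err = abs(dispatch.beta - wald.beta) + abs(dispatch.se - wald.se)

    pairs = [
        _pair(float(rng.uniform(0.2, 1.0)), float(rng.uniform(0.02, 0.1)),
              float(rng.normal(0, 0.3)), float(rng.uniform(0.02, 0.1)), snp=f"s{i}")
        for i in range(8)
    ]
    res = ivw(pairs)
    # weighted regression of beta_out on beta_exp through the origin with
    # weights 1/se_ratio^2 scaled to the outcome scale
    be = np.array([q.beta_exp for q in pairs])
    bo = np.array([q.beta_out for q in pairs])
    so = np.array([q.se_out for q in pairs])
    w = be**2 / so**2  # equivalent to 1/se_ratio^2 on the ratio scale
    slope = float((w * (bo / be)).sum() / w.sum())
    ivw_regression_err = abs(res.beta - slope)

    same = [_pair(0.5, 0.05, 0.2, 0.04, snp=f"t{i}") for i in range(4)]
    q0 = cochran_q(same)

    max_fdr_err = 0.0
    for _ in range(n_vectors):
        pv = rng.uniform(0, 1, size=rng.integers(1, 40))
        ours = bh_fdr(pv)
        # independent textbook step-up
        m = len(pv)
        order = np.argsort(pv)
        expected = np.empty(m)
        running_min = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running_min = min(running_min, pv[i] * m / rank)
            expected[i] = running_min
        max_fdr_err = max(max_fdr_err, float(np.abs(ours - expected).max()))

    return {
        "wald_dispatch_err": wald_dispatch_err,
        "ivw_regression_err": ivw_regression_err,
        "q_identical_ratios": q0.q_stat,
        "bh_fdr_max_err": max_fdr_err,
    }


# ---------------------------------------------------------------- criterion 2

def brute_force_coloc(l1, l2, p1=1e-4, p2=1e-4, p12=1e-5) -> np.ndarray:
    """Exhaustive enumeration over causal-variant assignments (oracle)."""
    b1, b2 = np.exp(l1), np.exp(l2)
    n = len(b1)
    e = np.array(
        [
            1.0,
            p1 * b1.sum(),
            p2 * b2.sum(),
            p1 * p2 * sum(b1[i] * b2[j] for i in range(n) for j in range(n) if i != j),
            p12 * (b1 * b2).sum(),
        ]
    )
    return e / e.sum()


def brute_force_moloc(la, lb, lc, p1=1e-4, p2=1e-6, p3=1e-7) -> dict:
    """Exhaustive enumeration over distinct-SNP block assignments (oracle)."""
    ba, bb, bc = np.exp(la), np.exp(lb), np.exp(lc)
    n = len(ba)
    idx = range(n)
    out = {"zero": 1.0}
    out["a"] = p1 * ba.sum()
    out["b"] = p1 * bb.sum()
    out["c"] = p1 * bc.sum()
    out["ab"] = p2 * (ba * bb).sum()
    out["ac"] = p2 * (ba * bc).sum()
    out["bc"] = p2 * (bb * bc).sum()
    out["a.b"] = p1 * p1 * sum(ba[i] * bb[j] for i in idx for j in idx if i != j)
    out["a.c"] = p1 * p1 * sum(ba[i] * bc[j] for i in idx for j in idx if i != j)
    out["b.c"] = p1 * p1 * sum(bb[i] * bc[j] for i in idx for j in idx if i != j)
    out["abc"] = p3 * (ba * bb * bc).sum()
    out["ab.c"] = p2 * p1 * sum(ba[i] * bb[i] * bc[j] for i in idx for j in idx if i != j)
    out["ac.b"] = p2 * p1 * sum(ba[i] * bc[i] * bb[j] for i in idx for j in idx if i != j)
    out["bc.a"] = p2 * p1 * sum(bb[i] * bc[i] * ba[j] for i in idx for j in idx if i != j)
    out["a.b.c"] = p1**3 * sum(
        ba[i] * bb[j] * bc[k]
        for i in idx for j in idx for k in idx
        if i != j and j != k and i != k
    )
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def enumeration_equivalence(seed: int = 0, n_instances: int = 100) -> dict:
    """Max |posterior - enumeration oracle| over random small panels."""
    rng = np.random.default_rng(seed)
    max_coloc, max_moloc = 0.0, 0.0
    for _ in range(n_instances):
        m = int(rng.integers(3, 5))
        ids = [f"s{i}" for i in range(m)]
        labfs = rng.normal(0, 4, size=(3, m))
        mk = lambda l: ABFVector(ids, l, np.ones(m), 0.04, l)
        res = coloc_abf(mk(labfs[0]), mk(labfs[1]))
        expected = brute_force_coloc(labfs[0], labfs[1])
        got = np.array([res.pp[f"H{i}"] for i in range(5)])
        max_coloc = max(max_coloc, float(np.abs(got - expected).max()))
        mres = moloc_abf(mk(labfs[0]), mk(labfs[1]), mk(labfs[2]))
        mexp = brute_force_moloc(labfs[0], labfs[1], labfs[2])
        max_moloc = max(max_moloc, max(abs(mres.pp[k] - mexp[k]) for k in mexp))
    return {"coloc_max_err": max_coloc, "moloc_max_err": max_moloc}


# ---------------------------------------------------------------- criterion 3

def _region_ld(rng, m=40, rho=0.6, n_ref=4000, maf_range=(0.2, 0.5)):
    g, mafs = simulate_genotypes(m, maf_range, rho, n_ref, rng)
    panel = SNPPanel(
        [f"s{i}" for i in range(m)], "1", 1_000 + 100 * np.arange(m),
        ["A"] * m, ["G"] * m, mafs,
    )
    return reference_ld(g, panel), mafs


def coloc_calibration(seed: int = 0, n_reps: int = 200, z_causal: float = 10.0) -> dict:
    """Shared-causal regions should give PP(H4) > 0.9; distinct-causal
    regions PP(H3) > PP(H4)."""
    rng = np.random.default_rng(seed)
    ld, mafs = _region_ld(rng)
    m = len(ld.snp_ids)
    n_gwas = 20_000
    shared_hits = 0
    distinct_hits = 0
    for _ in range(n_reps):
        c = int(rng.integers(0, m))
        t1 = simulate_region_table(ld, mafs, n_gwas, {c: z_causal}, rng, "t1")
        t2 = simulate_region_table(ld, mafs, n_gwas, {c: z_causal}, rng, "t2")
        res = coloc_abf(abf_from_sumstats(t1), abf_from_sumstats(t2))
        shared_hits += res.pp_h4 > 0.9
        # distinct: two causal SNPs with negligible LD (opposite ends)
        c1, c2 = 0, m - 1
        d1 = simulate_region_table(ld, mafs, n_gwas, {c1: z_causal}, rng, "d1")
        d2 = simulate_region_table(ld, mafs, n_gwas, {c2: z_causal}, rng, "d2")
        dres = coloc_abf(abf_from_sumstats(d1), abf_from_sumstats(d2))
        distinct_hits += dres.pp_h3 > dres.pp_h4
    return {
        "shared_pp4_gt_0.9_rate": shared_hits / n_reps,
        "distinct_h3_gt_h4_rate": distinct_hits / n_reps,
    }


# ---------------------------------------------------------------- criterion 4

def conditional_oracle(seed: int = 0, n_reps: int = 50, n: int = 20_000) -> dict:
    """Summary-statistic conditional betas vs a joint regression fitted on
    individual-level data with two causal SNPs."""
    rng = np.random.default_rng(seed)
    m = 20
    within = 0
    worst = 0.0
    for _ in range(n_reps):
        g, mafs = simulate_genotypes(m, (0.1, 0.5), 0.5, n, rng)
        panel = SNPPanel(
            [f"s{i}" for i in range(m)], "1", 1_000 + 100 * np.arange(m),
            ["A"] * m, ["G"] * m, mafs,
        )
        gf = g.astype(float)
        c1, c2 = 5, 12
        y = 0.25 * gf[:, c1] + 0.2 * gf[:, c2] + rng.standard_normal(n)
        from .simulate import CohortData, compute_sumstats
        from .sumstats import TraitType

        ss = compute_sumstats(CohortData(gf, y, panel), TraitType.QUANTITATIVE, "t")
        g_ref, _ = simulate_genotypes(m, (0.1, 0.5), 0.5, 4000, rng, mafs=mafs)
        ld = reference_ld(g_ref, panel)
        cond = conditional_sumstats(ss, ld, [f"s{c1}"], n=n)
        # oracle: joint OLS with both causal SNPs
        x = np.column_stack([np.ones(n), gf[:, c1], gf[:, c2]])
        bhat, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ bhat
        cov = (resid @ resid / (n - 3)) * np.linalg.inv(x.T @ x)
        se_joint = float(np.sqrt(cov[2, 2]))
        i = cond.snp_ids.index(f"s{c2}")
        dev = abs(cond.beta_cond[i] - bhat[2]) / se_joint
        worst = max(worst, dev)
        within += dev < 3.0
    return {"frac_within_3se": within / n_reps, "worst_dev_se": worst}


# ---------------------------------------------------------------- criterion 5

def pwcoco_rescue(seed: int = 0, n_reps: int = 100) -> dict:
    """Two independent signals in trait1, trait2 shares only the secondary:
    marginal coloc should miss (PP4 < 0.7) while the best conditioned pair
    exceeds 0.7."""
    rng = np.random.default_rng(seed)
    ld, mafs = _region_ld(rng)
    m = len(ld.snp_ids)
    n_gwas = 50_000
    c1, c2 = 8, 30
    rescued = 0
    for _ in range(n_reps):
        t1 = simulate_region_table(ld, mafs, n_gwas, {c1: 12.0, c2: 9.0}, rng, "t1")
        t2 = simulate_region_table(ld, mafs, n_gwas, {c2: 10.0}, rng, "t2")
        marg = coloc_abf(abf_from_sumstats(t1), abf_from_sumstats(t2))
        res = pwcoco(t1, t2, ld, n1=n_gwas, n2=n_gwas)
        if marg.pp_h4 < 0.7 and res["best"].pp_h4 > 0.7:
            rescued += 1
    return {"rescue_rate": rescued / n_reps}


# ---------------------------------------------------------------- criterion 6

_MEDIATION_KW = dict(
    m_snps=12, maf_range=(0.1, 0.5), ld_rho=0.2,
    n_protein=4000, n_bp=6000, n_cvd=8000, n_ref=500,
    causal_idx=(2, 5), gamma=(0.45, 0.45),
    bp_causal_idx=(9, 11), kappa=(2.0, 2.0),
    alpha=2.0, theta_bp=0.1, prevalence=0.3,
)


def _estimate_pm_once(seed: int, theta_direct: float):
    cfg = SimulationConfig(seed=seed, theta_direct=theta_direct, **_MEDIATION_KW)
    sim = simulate_chain(cfg)
    panel = sim["panel"]
    prot_snps = [panel.snp_ids[i] for i in cfg.causal_idx]
    bp_snps = [panel.snp_ids[i] for i in cfg.bp_causal_idx]
    prot, bp, cvd = sim["sumstats_protein"], sim["sumstats_bp"], sim["sumstats_cvd"]
    b1 = mr_estimate(kept_pairs(harmonize(prot.subset(prot_snps), bp)))
    b2 = mr_estimate(kept_pairs(harmonize(bp.subset(bp_snps), cvd)))
    bte = mr_estimate(kept_pairs(harmonize(prot.subset(prot_snps), cvd)))
    return proportion_mediated(b1.beta, b1.se, b2.beta, b2.se, bte.beta, bte.se)


def mediation_recovery(seed: int = 0, n_reps: int = 200) -> dict:
    """Median estimated proportion mediated at pm_true = 0.5 and 1.0, using
    the true causal SNPs as instruments (strong, selection-free)."""
    base = seed * 1_000_000
    pm_half = [_estimate_pm_once(base + i, theta_direct=0.2).pm for i in range(n_reps)]
    pm_full = [_estimate_pm_once(base + 500_000 + i, theta_direct=0.0).pm for i in range(n_reps)]
    return {
        "median_pm_at_0.5": float(np.median(pm_half)),
        "median_pm_at_1.0": float(np.median(pm_full)),
    }


def mediation_coverage(seed: int = 0, n_reps: int = 2000) -> dict:
    """Empirical coverage of the delta-method 95% CI at pm_true = 0.5."""
    base = seed * 1_000_000
    covered = 0
    for i in range(n_reps):
        res = _estimate_pm_once(base + i, theta_direct=0.2)
        lo, hi = res.ci95
        covered += lo <= 0.5 <= hi
    return {"ci95_coverage": covered / n_reps}


# ---------------------------------------------------------------- criterion 7

def null_calibration(seed: int = 0, n_reps: int = 5000, n_snps: int = 6) -> dict:
    """Type-I error of the fixed-effect IVW z-test and Cochran's Q under a
    homogeneous two-sample null (true causal effect zero, strong
    instruments); also reports the conservative random-effects rate."""
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.25, 0.5, size=n_snps)
    se_e, se_o = 0.01, 0.05
    rej_fixed = rej_re = rej_q = 0
    for _ in range(n_reps):
        be = gamma + rng.normal(0, se_e, n_snps)
        bo = rng.normal(0, se_o, n_snps)
        pairs = [
            _pair(float(be[j]), se_e, float(bo[j]), se_o, snp=f"s{j}")
            for j in range(n_snps)
        ]
        rej_fixed += ivw(pairs, overdispersion=False).pval < 0.05
        rej_re += ivw(pairs).pval < 0.05
        rej_q += cochran_q(pairs).pval < 0.05
    return {
        "ivw_fixed_rejection_rate": rej_fixed / n_reps,
        "ivw_overdispersed_rejection_rate": rej_re / n_reps,
        "q_rejection_rate": rej_q / n_reps,
    }


# ---------------------------------------------------------------- criterion 8

def end_to_end_funnel(seed: int = 2, check_determinism: bool = True) -> dict:
    """Full screen on a 20-protein panel with 5 true BP-mediated proteins."""
    sim = simulate_panel(PanelSimConfig(seed=seed))
    proteins = {
        pid: (sim["protein_sumstats"][pid], sim["regions"][pid])
        for pid in sim["protein_sumstats"]
    }
    cfg = PipelineConfig()
    bp = run_screen(proteins, sim["sumstats_bp"], sim["ld"], cfg)
    survivors = [r for r in bp if r.passed]
    cvd = run_outcome_stage(survivors, proteins, sim["sumstats_cvd"], sim["ld"], cfg)
    cands, meds = prioritize_and_mediate(
        bp, cvd, proteins, sim["sumstats_bp"], sim["sumstats_cvd"], sim["ld"], cfg
    )
    truths = set(sim["true_proteins"])
    prioritized = {c.protein_id for c in cands if c.prioritized}
    stage1 = {r.protein_id for r in bp if r.passed}
    deterministic = True
    if check_determinism:
        bp2 = run_screen(proteins, sim["sumstats_bp"], sim["ld"], cfg)
        deterministic = screen_to_frame(bp).equals(screen_to_frame(bp2))
    pm_values = {pid: m.pm for pid, m in meds.items()}
    return {
        "n_true": len(truths),
        "true_positives_prioritized": len(prioritized & truths),
        "false_positives_prioritized": len(prioritized - truths),
        "stage1_false_positives": len(stage1 - truths),
        "stage1_true_positives": len(stage1 & truths),
        "n_proteins": len(proteins),
        "deterministic": deterministic,
        "median_pm": float(np.median(list(pm_values.values()))) if pm_values else float("nan"),
        "pm_true": sim["truths"][sim["true_proteins"][0]].pm_true,
    }


# ---------------------------------------------------------------- criterion 9

def exact_rules(seed: int = 0) -> dict:
    """Medication constants, inclusive cis bounds, pairwise clumped r^2."""
    sbp, dbp = adjust_for_medication(np.array([130.0]), np.array([80.0]), np.array([True]))
    med_ok = (sbp[0] == 145.0) and (dbp[0] == 90.0)

    rng = np.random.default_rng(seed)
    sim = simulate_chain(SimulationConfig(seed=seed, m_snps=40, gamma=(0.4,), causal_idx=(20,)))
    prot = sim["sumstats_protein"]
    region = GeneRegion("G", "1", 2_100_000, 2_100_000)
    cis = select_cis(prot, region, window_bp=1_000_000)
    lo, hi = region.cis_window(1_000_000)
    pos = prot.df["POS"]
    maf = np.minimum(prot.df["EAF"], 1 - prot.df["EAF"])
    expected = set(prot.df.loc[(pos >= lo) & (pos <= hi) & (maf > 0.01), "SNP"])
    cis_ok = set(cis.snp_ids) == expected
    boundary_snp = prot.df.loc[pos == lo, "SNP"]
    boundary_ok = boundary_snp.empty or boundary_snp.iloc[0] in set(cis.snp_ids)

    clumped = greedy_clump(prot, sim["ld"], p_threshold=0.99, r2_threshold=0.001)
    ids = clumped.df["SNP"].tolist()
    max_r2 = 0.0
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            max_r2 = max(max_r2, sim["ld"].r_between(a, b) ** 2)
    return {
        "medication_adds_15_10": bool(med_ok),
        "cis_window_inclusive": bool(cis_ok and boundary_ok),
        "clumped_max_pairwise_r2": max_r2,
    }
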