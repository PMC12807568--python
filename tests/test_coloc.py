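import numpy as np
import pytest
from scipy import integrate, stats

from protmr.coloc import (
    ABFVector,
    ConditioningError,
    MOLOC_CONFIGS,
    PanelMismatchError,
    abf_from_sumstats,
    coloc_abf,
    conditional_sumstats,
    moloc_abf,
    pwcoco,
    stepwise_select,
    wakefield_labf,
)
from protmr.simulate import (
    CohortData,
    SNPPanel,
    compute_sumstats,
    reference_ld,
    simulate_genotypes,
    simulate_region_table,
)
from protmr.sumstats import TraitType
from protmr.validation import brute_force_coloc, brute_force_moloc


def abf(labf, ids=None):
    labf = np.asarray(labf, dtype=float)
    if ids is None:
        ids = [f"s{i}" for i in range(len(labf))]
    return ABFVector(ids, labf, np.ones(len(labf)), 0.04, labf)


class TestWakefieldLABF:
    def test_zero_prior_variance(self):
        assert wakefield_labf(np.array([3.0]), np.array([1.0]), prior_sd=0.0)[0] == 0.0

    def test_direct_substitution(self):
        # z = 0, V = W = 1
        got = wakefield_labf(np.array([0.0]), np.array([1.0]), prior_sd=1.0)[0]
        assert got == pytest.approx(0.5 * np.log(0.5))

    def test_quadrature_oracle(self, rng):
        # exp(labf) equals the marginal likelihood ratio integrated over the
        # effect prior
        for _ in range(50):
            v = float(rng.uniform(0.01, 1.0))
            w = float(rng.uniform(0.01, 1.0))
            z = float(rng.uniform(-4, 4))
            bhat = z * np.sqrt(v)
            labf = wakefield_labf(np.array([bhat]), np.array([np.sqrt(v)]),
                                  prior_sd=np.sqrt(w))[0]
            num, _ = integrate.quad(
                lambda b: stats.norm.pdf(bhat, b, np.sqrt(v)) * stats.norm.pdf(b, 0, np.sqrt(w)),
                -10, 10,
            )
            denom = stats.norm.pdf(bhat, 0, np.sqrt(v))
            assert np.exp(labf) == pytest.approx(num / denom, rel=0.01)

    def test_binary_default_prior(self):
        quant = wakefield_labf(np.array([0.1]), np.array([0.02]),
                               TraitType.QUANTITATIVE, sd_y=2.0)
        binary = wakefield_labf(np.array([0.1]), np.array([0.02]), TraitType.BINARY)
        assert quant[0] != binary[0]


class TestColocABF:
    def test_posteriors_sum_to_one(self, rng):
        res = coloc_abf(abf(rng.normal(0, 3, 10)), abf(rng.normal(0, 3, 10)))
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_snp_h3_zero(self):
        res = coloc_abf(abf([5.0]), abf([4.0]))
        assert res.pp["H3"] == 0.0

    def test_enumeration_oracle_small_panels(self, rng):
        for _ in range(100):
            l1, l2 = rng.normal(0, 4, (2, 3))
            res = coloc_abf(abf(l1), abf(l2))
            expected = brute_force_coloc(l1, l2)
            got = np.array([res.pp[f"H{i}"] for i in range(5)])
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_p12_monotonicity(self, rng):
        l1, l2 = rng.normal(0, 3, (2, 20))
        pp4 = [
            coloc_abf(abf(l1), abf(l2), p12=p12).pp_h4
            for p12 in (1e-7, 1e-6, 1e-5, 1e-4)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(pp4, pp4[1:]))

    def test_panel_mismatch(self):
        with pytest.raises(PanelMismatchError):
            coloc_abf(abf([1.0, 2.0]), abf([1.0, 2.0], ids=["x", "y"]))

    def test_extreme_z_no_overflow(self):
        # z = 60: raw exponentials would overflow; log-space must not
        labf = wakefield_labf(np.array([6.0, 0.0]), np.array([0.1, 0.1]), prior_sd=0.2)
        res = coloc_abf(abf(labf), abf(labf))
        assert np.isfinite(list(res.pp.values())).all()
        assert res.pp_h4 > 0.9


class TestMolocABF:
    def test_fifteen_configurations(self):
        assert len(MOLOC_CONFIGS) == 15
        res = moloc_abf(abf([1.0, 2.0]), abf([1.0, 2.0]), abf([1.0, 2.0]))
        assert len(res.pp) == 15

    def test_posteriors_sum_to_one(self, rng):
        res = moloc_abf(*[abf(rng.normal(0, 3, 8)) for _ in range(3)])
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_snp_structural_zeros(self):
        res = moloc_abf(abf([5.0]), abf([4.0]), abf([3.0]))
        for name, blocks in MOLOC_CONFIGS:
            if len(blocks) >= 2:
                assert res.pp[name] == 0.0, name

    def test_enumeration_oracle_small_panels(self, rng):
        for _ in range(100):
            la, lb, lc = rng.normal(0, 4, (3, 4))
            res = moloc_abf(abf(la), abf(lb), abf(lc))
            expected = brute_force_moloc(la, lb, lc)
            for k, v in expected.items():
                assert res.pp[k] == pytest.approx(v, abs=1e-9), k

    def test_reduces_to_coloc_with_flat_third_trait(self, rng):
        # matched effective priors: moloc (p1, p2) vs coloc (p1, p1, p12=p2)
        l1 = rng.normal(0, 2, 50)
        l2 = rng.normal(0, 2, 50)
        shared = 10.0
        l1[7] += shared
        l2[7] += shared
        flat = np.zeros(50)
        mres = moloc_abf(abf(l1), abf(l2), abf(flat), p1=1e-4, p2=1e-6, p3=1e-7)
        cres = coloc_abf(abf(l1), abf(l2), p1=1e-4, p2=1e-4, p12=1e-6)
        marginal_share = mres.pp["ab"] + mres.pp["abc"] + mres.pp["ab.c"]
        assert marginal_share == pytest.approx(cres.pp_h4, abs=0.05)


def _region(rng, m=20, n_ref=4000, rho=0.5):
    g, mafs = simulate_genotypes(m, (0.1, 0.5), rho, n_ref, rng)
    panel = SNPPanel([f"s{i}" for i in range(m)], "1", 1_000 + 100 * np.arange(m),
                     ["A"] * m, ["G"] * m, mafs)
    return reference_ld(g, panel), mafs, panel


class TestConditionalSumStats:
    def test_orthogonal_index_leaves_beta(self, rng):
        m = 5
        ids = [f"s{i}" for i in range(m)]
        from protmr.sumstats import LDMatrix

        ld = LDMatrix(ids, {s: ("A", "G") for s in ids}, np.eye(m))
        t = simulate_region_table(ld, np.full(m, 0.3), 10_000, {0: 8.0}, rng)
        cond = conditional_sumstats(t, ld, ["s4"], n=10_000)
        i0 = cond.snp_ids.index("s0")
        marg = t.df.set_index("SNP").loc["s0", "BETA"]
        assert cond.beta_cond[i0] == pytest.approx(marg, rel=1e-6)

    def test_self_conditioning_zero(self, rng):
        ld, mafs, _ = _region(rng)
        t = simulate_region_table(ld, mafs, 10_000, {3: 8.0}, rng)
        cond = conditional_sumstats(t, ld, ["s3"], n=10_000)
        i = cond.snp_ids.index("s3")
        assert cond.beta_cond[i] == 0.0
        assert cond.pval_cond[i] == 1.0

    def test_individual_level_oracle(self, rng):
        n, m = 20_000, 20
        g, mafs = simulate_genotypes(m, (0.1, 0.5), 0.5, n, rng)
        panel = SNPPanel([f"s{i}" for i in range(m)], "1", 1_000 + 100 * np.arange(m),
                         ["A"] * m, ["G"] * m, mafs)
        gf = g.astype(float)
        y = 0.25 * gf[:, 5] + 0.2 * gf[:, 12] + rng.standard_normal(n)
        ss = compute_sumstats(CohortData(gf, y, panel), TraitType.QUANTITATIVE, "t")
        g_ref, _ = simulate_genotypes(m, (0.1, 0.5), 0.5, 4000, rng, mafs=mafs)
        ld = reference_ld(g_ref, panel)
        cond = conditional_sumstats(ss, ld, ["s5"], n=n)
        x = np.column_stack([np.ones(n), gf[:, 5], gf[:, 12]])
        bhat, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ bhat
        cov = (resid @ resid / (n - 3)) * np.linalg.inv(x.T @ x)
        i = cond.snp_ids.index("s12")
        assert abs(cond.beta_cond[i] - bhat[2]) < 3 * np.sqrt(cov[2, 2])

    def test_collinear_index_raises(self, rng):
        m = 3
        ids = ["s0", "s1", "s2"]
        from protmr.sumstats import LDMatrix

        r = np.array([[1.0, 0.99, 0.1], [0.99, 1.0, 0.1], [0.1, 0.1, 1.0]])
        ld = LDMatrix(ids, {s: ("A", "G") for s in ids}, r)
        t = simulate_region_table(ld, np.full(m, 0.3), 10_000, {0: 8.0}, rng)
        with pytest.raises(ConditioningError, match="collinear"):
            conditional_sumstats(t, ld, ["s0", "s1"], n=10_000)

    def test_stepwise_finds_both_signals(self, rng):
        ld, mafs, _ = _region(rng, m=30)
        t = simulate_region_table(ld, mafs, 50_000, {3: 10.0, 25: 8.0}, rng)
        sel = stepwise_select(t, ld, n=50_000)
        assert "s3" in sel and "s25" in sel


class TestPWCoCo:
    def test_single_shared_signal_equals_marginal(self, rng):
        ld, mafs, _ = _region(rng, m=25)
        t1 = simulate_region_table(ld, mafs, 50_000, {10: 10.0}, rng, "t1")
        t2 = simulate_region_table(ld, mafs, 50_000, {10: 10.0}, rng, "t2")
        marginal = coloc_abf(abf_from_sumstats(t1), abf_from_sumstats(t2))
        res = pwcoco(t1, t2, ld, n1=50_000, n2=50_000)
        assert res["best_pair"] == ("marginal", "marginal")
        assert res["best"].pp_h4 == pytest.approx(marginal.pp_h4, abs=1e-12)

    def test_rescues_secondary_signal(self, rng):
        ld, mafs, _ = _region(rng, m=40, rho=0.6)
        c1, c2 = 5, 34
        t1 = simulate_region_table(ld, mafs, 50_000, {c1: 12.0, c2: 9.0}, rng, "t1")
        t2 = simulate_region_table(ld, mafs, 50_000, {c2: 10.0}, rng, "t2")
        marginal = coloc_abf(abf_from_sumstats(t1), abf_from_sumstats(t2))
        res = pwcoco(t1, t2, ld, n1=50_000, n2=50_000)
        assert res["best"].pp_h4 >= marginal.pp_h4 - 1e-12

    def test_snp_order_invariance(self, rng):
        ld, mafs, _ = _region(rng, m=15)
        t1 = simulate_region_table(ld, mafs, 50_000, {3: 9.0}, rng, "t1")
        t2 = simulate_region_table(ld, mafs, 50_000, {3: 9.0}, rng, "t2")
        res1 = pwcoco(t1, t2, ld, n1=50_000, n2=50_000)
        perm = np.random.default_rng(0).permutation(len(t1))
        t1p = t1.subset(list(np.array(t1.snp_ids)[perm]))
        t2p = t2.subset(list(np.array(t2.snp_ids)[perm]))
        res2 = pwcoco(t1p, t2p, ld, n1=50_000, n2=50_000)
        assert res1["best"].pp_h4 == pytest.approx(res2["best"].pp_h4, abs=1e-12)
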