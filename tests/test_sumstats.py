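import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protmr.sumstats import (
    EmptyInputError,
    SumStatsFormatError,
    TraitType,
    harmonize,
    kept_pairs,
    read_ld,
    read_sumstats,
    write_ld,
    write_sumstats,
)

from conftest import make_table, random_table

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def write_lines(path, rows):
    path.write_text(HEADER + "".join(rows))


GOOD_ROWS = [
    "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.05\t0.04\t5000\n",
    "rs2\t1\t200\tC\tT\t0.4\t-0.2\t0.04\t0.001\t5000\n",
    "rs3\t2\t150\tG\tC\t0.3\t0.05\t0.06\t0.5\t5000\n",
]


class TestReadSumstats:
    def test_well_formed_roundtrip(self, tmp_path):
        f = tmp_path / "ss.tsv"
        write_lines(f, GOOD_ROWS)
        table, report = read_sumstats(f, "t", TraitType.QUANTITATIVE)
        assert len(table) == 3
        assert report.n_dropped == 0

    def test_zero_se_row_dropped(self, tmp_path):
        f = tmp_path / "ss.tsv"
        write_lines(f, GOOD_ROWS + ["rs4\t2\t500\tA\tC\t0.3\t0.1\t0.0\t0.5\t5000\n"])
        table, report = read_sumstats(f, "t", TraitType.QUANTITATIVE)
        assert len(table) == 3
        assert report.n_dropped == 1
        assert report.drop_reasons == {"nonpositive_se": 1}

    @pytest.mark.parametrize(
        "row,reason",
        [
            ("rs4\t2\t500\tAT\tA\t0.3\t0.1\t0.05\t0.5\t5000\n", "non_snp_allele"),
            ("rs4\t2\t500\tA\tA\t0.3\t0.1\t0.05\t0.5\t5000\n", "identical_alleles"),
            ("rs4\t2\t500\tA\tC\t1.0\t0.1\t0.05\t0.5\t5000\n", "eaf_out_of_range"),
            ("rs4\t2\t500\tA\tC\t0.3\t0.1\t0.05\t0.0\t5000\n", "pval_out_of_range"),
            ("rs4\t2\t0\tA\tC\t0.3\t0.1\t0.05\t0.5\t5000\n", "bad_position"),
        ],
    )
    def test_invariant_enforcement(self, tmp_path, row, reason):
        f = tmp_path / "ss.tsv"
        write_lines(f, GOOD_ROWS + [row])
        _, report = read_sumstats(f, "t", TraitType.QUANTITATIVE)
        assert report.drop_reasons == {reason: 1}

    def test_missing_column_raises(self, tmp_path):
        f = tmp_path / "ss.tsv"
        f.write_text("SNP\tCHR\tPOS\n" + "rs1\t1\t100\n")
        with pytest.raises(SumStatsFormatError):
            read_sumstats(f, "t", TraitType.QUANTITATIVE)

    def test_all_rows_invalid_raises(self, tmp_path):
        f = tmp_path / "ss.tsv"
        write_lines(f, ["rs1\t1\t100\tA\tG\t0.2\t0.1\t0.0\t0.04\t5000\n"])
        with pytest.raises(EmptyInputError):
            read_sumstats(f, "t", TraitType.QUANTITATIVE)

    def test_write_read_roundtrip_random_tables(self, tmp_path, rng):
        # numeric content preserved to 6 significant digits
        for i in range(5):
            table = random_table(rng, m=15)
            f = tmp_path / f"rt{i}.tsv"
            write_sumstats(table, f)
            back, report = read_sumstats(f, "t", TraitType.QUANTITATIVE)
            assert report.n_dropped == 0
            for col in ("BETA", "SE", "P", "EAF"):
                np.testing.assert_allclose(
                    back.df[col].to_numpy(), table.df[col].to_numpy(), rtol=1e-6
                )
            assert back.df["SNP"].tolist() == table.df["SNP"].tolist()

    def test_n_cases_validation(self, tmp_path):
        f = tmp_path / "ss.tsv"
        f.write_text(
            HEADER.replace("\n", "\tN_CASES\n")
            + "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.05\t0.04\t5000\t1000\n"
            + "rs2\t1\t200\tC\tT\t0.4\t0.2\t0.04\t0.01\t5000\t6000\n"
        )
        table, report = read_sumstats(f, "t", TraitType.BINARY)
        assert len(table) == 1
        assert report.drop_reasons == {"bad_n_cases": 1}


class TestSumStatsTable:
    def test_duplicate_snp_rejected(self):
        with pytest.raises(SumStatsFormatError):
            make_table(
                [
                    {"SNP": "rs1", "POS": 100, "EA": "A", "OA": "G", "BETA": 0.1},
                    {"SNP": "rs1", "POS": 200, "EA": "A", "OA": "G", "BETA": 0.2},
                ]
            )

    def test_sorted_by_chrom_pos(self):
        t = make_table(
            [
                {"SNP": "b", "CHR": "2", "POS": 100, "EA": "A", "OA": "G", "BETA": 0.1},
                {"SNP": "a", "CHR": "1", "POS": 500, "EA": "A", "OA": "G", "BETA": 0.1},
                {"SNP": "c", "CHR": "1", "POS": 100, "EA": "A", "OA": "G", "BETA": 0.1},
            ]
        )
        assert t.df["SNP"].tolist() == ["c", "a", "b"]


class TestLDMatrixIO:
    def test_roundtrip(self, tmp_path, rng):
        from protmr.simulate import SNPPanel, reference_ld, simulate_genotypes

        g, mafs = simulate_genotypes(8, (0.1, 0.5), 0.4, 500, rng)
        panel = SNPPanel([f"s{i}" for i in range(8)], "1", np.arange(8) * 100 + 1,
                         ["A"] * 8, ["G"] * 8, mafs)
        ld = reference_ld(g, panel)
        f = tmp_path / "ld.tsv"
        write_ld(ld, f)
        back = read_ld(f)
        np.testing.assert_allclose(back.r, ld.r, atol=1e-9)
        assert back.snp_ids == ld.snp_ids

    def test_asymmetric_rejected(self):
        from protmr.sumstats import LDMatrix

        r = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], {"a": ("A", "G"), "b": ("A", "G")}, r)


def _exposure_outcome(out_ea="G", out_oa="A", out_beta=-0.2, out_eaf=0.7):
    exp = make_table([{"SNP": "rs1", "POS": 100, "EA": "A", "OA": "G", "BETA": 0.3}])
    out = make_table(
        [{"SNP": "rs1", "POS": 100, "EA": out_ea, "OA": out_oa, "BETA": out_beta, "EAF": out_eaf}]
    )
    return exp, out


class TestHarmonize:
    def test_swapped_alleles_flip(self):
        exp, out = _exposure_outcome()
        (pair,) = harmonize(exp, out)
        assert pair.action_taken == "flipped"
        assert pair.beta_out == pytest.approx(0.2)
        assert pair.eaf_out == pytest.approx(0.3)

    def test_matching_alleles_kept(self):
        exp, out = _exposure_outcome(out_ea="A", out_oa="G", out_beta=0.2, out_eaf=0.3)
        (pair,) = harmonize(exp, out)
        assert pair.action_taken == "kept"
        assert pair.beta_out == pytest.approx(0.2)

    def test_ambiguous_palindrome_dropped(self):
        exp = make_table(
            [{"SNP": "rs1", "POS": 100, "EA": "A", "OA": "T", "BETA": 0.3, "EAF": 0.5}]
        )
        out = make_table(
            [{"SNP": "rs1", "POS": 100, "EA": "A", "OA": "T", "BETA": 0.2, "EAF": 0.5}]
        )
        with pytest.raises(EmptyInputError):
            harmonize(exp, out)

    def test_informative_palindrome_oriented_by_eaf(self):
        exp = make_table(
            [{"SNP": "rs1", "POS": 100, "EA": "A", "OA": "T", "BETA": 0.3, "EAF": 0.1}]
        )
        out = make_table(
            [{"SNP": "rs1", "POS": 100, "EA": "A", "OA": "T", "BETA": 0.2, "EAF": 0.9}]
        )
        (pair,) = harmonize(exp, out)
        assert pair.action_taken == "flipped"
        assert pair.beta_out == pytest.approx(-0.2)
        assert pair.eaf_out == pytest.approx(0.1)

    def test_irreconcilable_alleles_dropped(self):
        exp, out = _exposure_outcome(out_ea="A", out_oa="C")
        with pytest.raises(EmptyInputError):
            harmonize(exp, out)

    def test_strand_complement_recognized(self):
        # exposure A/G; outcome reported on opposite strand as T/C
        exp, out = _exposure_outcome(out_ea="T", out_oa="C", out_beta=0.2, out_eaf=0.3)
        (pair,) = harmonize(exp, out)
        assert pair.action_taken == "kept"
        assert pair.beta_out == pytest.approx(0.2)

    def test_simulated_consistent_alleles_identity(self, small_chain):
        cfg, sim = small_chain
        pairs = kept_pairs(harmonize(sim["sumstats_protein"], sim["sumstats_bp"]))
        assert len(pairs) == cfg.m_snps
        raw = sim["sumstats_bp"].df.set_index("SNP")["BETA"]
        for p in pairs:
            assert p.action_taken == "kept"
            assert p.beta_out == pytest.approx(raw[p.snp_id])

    def test_idempotent(self, small_chain):
        _, sim = small_chain
        exp, out = sim["sumstats_protein"], sim["sumstats_bp"]
        once = kept_pairs(harmonize(exp, out))
        # apply the harmonized outcome effects back into a table and re-run
        out2 = out.subset([p.snp_id for p in once])
        df = out2.df.set_index("SNP")
        for p in once:
            df.loc[p.snp_id, ["BETA", "EAF"]] = [p.beta_out, p.eaf_out]
        out2.df = df.reset_index()
        twice = kept_pairs(harmonize(exp, out2))
        for p1, p2 in zip(once, twice):
            assert p2.action_taken == "kept"
            assert p1.beta_out == pytest.approx(p2.beta_out)

    def test_sign_invariance_downstream(self, small_chain):
        # flipping outcome alleles and beta signs leaves MR unchanged
        from protmr.mr import mr_estimate

        _, sim = small_chain
        exp, out = sim["sumstats_protein"], sim["sumstats_bp"]
        flipped = out.subset(out.snp_ids)
        df = flipped.df.copy()
        df["BETA"] = -df["BETA"]
        df["EAF"] = 1 - df["EAF"]
        df[["EA", "OA"]] = df[["OA", "EA"]].to_numpy()
        flipped.df = df
        res1 = mr_estimate(kept_pairs(harmonize(exp, out)))
        res2 = mr_estimate(kept_pairs(harmonize(exp, flipped)))
        assert res1.beta == pytest.approx(res2.beta, abs=1e-12)
        assert res1.se == pytest.approx(res2.se, abs=1e-12)

    @given(
        beta=st.floats(-1, 1, allow_nan=False),
        eaf=st.floats(0.05, 0.95),
        swap=st.booleans(),
    )
    @settings(max_examples=50, deadline=None)
    def test_flip_recovers_original(self, beta, eaf, swap):
        ea, oa = ("G", "A") if swap else ("A", "G")
        exp = make_table([{"SNP": "rs1", "POS": 100, "EA": "A", "OA": "G", "BETA": 0.3}])
        out = make_table(
            [{"SNP": "rs1", "POS": 100, "EA": ea, "OA": oa, "BETA": beta, "EAF": eaf}]
        )
        (pair,) = harmonize(exp, out)
        expected_beta = -beta if swap else beta
        assert pair.beta_out == pytest.approx(expected_beta)
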