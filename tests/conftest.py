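import numpy as np
import pandas as pd
import pytest

from protmr.sumstats import SumStatsTable, TraitType


def make_table(rows, trait_name="trait", trait_type=TraitType.QUANTITATIVE, sd_y=1.0):
    """Build a SumStatsTable from a list of dicts with canonical columns."""
    df = pd.DataFrame(rows)
    defaults = {"CHR": "1", "EAF": 0.3, "SE": 0.05, "P": 0.5, "N": 10_000}
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    return SumStatsTable(trait_name=trait_name, trait_type=trait_type, df=df, sd_y=sd_y)


def random_table(rng, m=20, trait_name="trait", chrom="1"):
    """Random but valid summary statistics over m variants."""
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    rows = []
    for i in range(m):
        ea, oa = alleles[int(rng.integers(0, 4))]
        rows.append(
            {
                "SNP": f"rs{i}",
                "CHR": chrom,
                "POS": 1000 + 500 * i,
                "EA": ea,
                "OA": oa,
                "EAF": float(rng.uniform(0.05, 0.95)),
                "BETA": float(rng.normal(0, 0.2)),
                "SE": float(rng.uniform(0.01, 0.1)),
                "P": float(rng.uniform(1e-10, 1)),
                "N": int(rng.integers(1000, 50_000)),
            }
        )
    return make_table(rows, trait_name=trait_name)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_chain():
    """One small simulated causal chain shared across tests (read-only)."""
    from protmr.simulate import SimulationConfig, simulate_chain

    cfg = SimulationConfig(
        seed=42, m_snps=30, n_protein=3000, n_bp=3000, n_cvd=3000, n_ref=1000,
        causal_idx=(5, 15), gamma=(0.4, 0.3), bp_causal_idx=(25, 28), kappa=(2.0, 2.0),
        alpha=2.0, theta_bp=0.1, theta_direct=0.1, prevalence=0.3,
    )
    return cfg, simulate_chain(cfg)
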