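"""cis-window instrument selection, greedy LD clumping, and instrument
strength (F-statistics)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sumstats import HarmonizedPair, LDMatrix, SumStatsTable

__all__ = [
    "GeneRegion",
    "InstrumentSet",
    "select_cis",
    "greedy_clump",
    "instrument_strength",
]


@dataclass
class GeneRegion:
    """1-based inclusive coding-region bounds of a gene."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    def cis_window(self, window_bp: int) -> tuple[int, int]:
        return max(1, self.start - window_bp), self.end + window_bp

    def overlaps_window(self, other: "GeneRegion", flank_bp: int = 500_000) -> bool:
        """True when the two genes' flanked windows overlap (gene-dense test)."""
        if self.chrom != other.chrom:
            return False
        a_lo, a_hi = self.start - flank_bp, self.end + flank_bp
        b_lo, b_hi = other.start - flank_bp, other.end + flank_bp
        return a_lo <= b_hi and b_lo <= a_hi


@dataclass
class InstrumentSet:
    pairs: list[HarmonizedPair]
    f_per_snp: np.ndarray
    f_mean: float
    selection_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def select_cis(
    sumstats: SumStatsTable,
    region: GeneRegion,
    window_bp: int = 1_000_000,
    maf_threshold: float = 0.01,
) -> SumStatsTable:
    """Restrict to SNPs within +/- window_bp of the gene body (inclusive
    bounds) with MAF above ``maf_threshold``."""
    lo, hi = region.cis_window(window_bp)
    df = sumstats.df
    maf = np.minimum(df["EAF"], 1 - df["EAF"])
    mask = (df["CHR"] == region.chrom) & (df["POS"] >= lo) & (df["POS"] <= hi) & (maf > maf_threshold)
    return dataclasses.replace(sumstats, df=df[mask].copy())


def greedy_clump(
    sumstats: SumStatsTable,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> SumStatsTable:
    """Greedy LD clumping of p < ``p_threshold`` candidates.

    Repeatedly takes the smallest-p remaining SNP as index and discards all
    remaining SNPs within ``window_kb`` of it with r^2 >= ``r2_threshold``.
    Ties on p are broken by (chrom, pos, snp_id).  Index SNPs are returned in
    selection order.
    """
    df = sumstats.df[sumstats.df["P"] < p_threshold].copy()
    missing = [s for s in df["SNP"] if s not in ld]
    if missing:
        raise KeyError(f"SNPs absent from LD panel: {missing[:10]}")
    df = df.sort_values(["P", "CHR", "POS", "SNP"], kind="mergesort")
    window_bp = window_kb * 1000
    remaining = list(df.itertuples(index=False))
    selected = []
    while remaining:
        index = remaining.pop(0)
        selected.append(index)
        kept = []
        for row in remaining:
            if row.CHR == index.CHR and abs(row.POS - index.POS) <= window_bp:
                if ld.r_between(index.SNP, row.SNP) ** 2 >= r2_threshold:
                    continue
            kept.append(row)
        remaining = kept
    out = df.set_index("SNP").loc[[r.SNP for r in selected]].reset_index()
    clumped = dataclasses.replace(sumstats, df=out)
    # selection order is meaningful; bypass positional re-sort
    clumped.df = out
    return clumped


def instrument_strength(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, float]:
    """Per-SNP F-statistic (z^2 of the exposure association) and its mean."""
    if len(pairs) == 0:
        raise ValueError("instrument_strength: no pairs")
    f = np.array([(p.beta_exp / p.se_exp) ** 2 for p in pairs])
    return f, float(f.mean())
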