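"""GWAS summary-statistics data model, I/O, and allele harmonization.

The canonical on-disk format is a tab-delimited table with header columns
``SNP CHR POS EA OA EAF BETA SE P N`` and optionally ``N_CASES``.  LD is a
square TSV matrix of signed allelic correlations with SNP ids as the first
row and first column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitType",
    "SumStatsTable",
    "LDMatrix",
    "HarmonizedPair",
    "ReadReport",
    "read_sumstats",
    "write_sumstats",
    "read_ld",
    "write_ld",
    "harmonize",
]

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_REQUIRED_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


class TraitType(str, Enum):
    QUANTITATIVE = "quantitative"
    BINARY = "binary"


class SumStatsFormatError(ValueError):
    """Raised when a summary-statistics file is malformed."""


class EmptyInputError(ValueError):
    """Raised when an operation receives no usable rows."""


@dataclass
class ReadReport:
    """Row-level audit from :func:`read_sumstats`."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)

    def add_drop(self, reason: str, count: int = 1) -> None:
        self.n_dropped += count
        self.drop_reasons[reason] = self.drop_reasons.get(reason, 0) + count


@dataclass
class SumStatsTable:
    """Per-trait GWAS summary statistics for a genomic region.

    ``df`` holds one row per variant with the canonical columns; rows are
    sorted by (CHR, POS) and SNP ids are unique.
    """

    trait_name: str
    trait_type: TraitType
    df: pd.DataFrame
    sd_y: float | None = None

    def __post_init__(self) -> None:
        self.trait_type = TraitType(self.trait_type)
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumStatsFormatError(f"missing columns: {missing}")
        if self.df["SNP"].duplicated().any():
            dups = self.df.loc[self.df["SNP"].duplicated(), "SNP"].tolist()
            raise SumStatsFormatError(f"duplicate SNP ids: {dups[:5]}")
        self.df = self.df.sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["SNP"].tolist()

    def subset(self, snp_ids: Iterable[str]) -> "SumStatsTable":
        keep = set(snp_ids)
        sub = self.df[self.df["SNP"].isin(keep)].copy()
        return dataclasses.replace(self, df=sub)


@dataclass
class LDMatrix:
    """Signed allelic correlation matrix over a SNP panel.

    ``alleles`` records the (effect, other) orientation each row/column of
    ``r`` refers to; sign conventions follow the effect allele.
    """

    snp_ids: list[str]
    alleles: dict[str, tuple[str, str]]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.snp_ids)
        if len(set(self.snp_ids)) != n:
            raise ValueError("duplicate SNP ids in LD panel")
        if self.r.shape != (n, n):
            raise ValueError(f"LD matrix shape {self.r.shape} != panel size {n}")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-9):
            raise ValueError("LD diagonal must be 1")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP not in LD panel: {snp_id}") from None

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self.index_of(a), self.index_of(b)])

    def submatrix(self, snp_ids: Sequence[str]) -> np.ndarray:
        idx = [self.index_of(s) for s in snp_ids]
        return self.r[np.ix_(idx, idx)]


@dataclass
class HarmonizedPair:
    """One variant's harmonized exposure/outcome effects."""

    snp_id: str
    beta_exp: float
    se_exp: float
    eaf_exp: float
    beta_out: float
    se_out: float
    eaf_out: float
    n_exp: float
    n_out: float
    action_taken: str = "kept"


def _is_palindromic(ea: str, oa: str) -> bool:
    return ea in _BASES and oa in _BASES and _COMPLEMENT[ea] == oa


def read_sumstats(
    path,
    trait_name: str,
    trait_type: TraitType | str,
    sd_y: float | None = None,
) -> tuple[SumStatsTable, ReadReport]:
    """Read a canonical TSV into a validated :class:`SumStatsTable`.

    Rows violating the per-variant invariants (non-ACGT alleles, se <= 0,
    eaf outside (0,1), p outside (0,1], pos < 1, invalid case counts) are
    dropped and counted in the returned :class:`ReadReport`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "EA": str, "OA": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsFormatError(f"{path}: missing mandatory columns {missing}")
    report = ReadReport(n_read=len(df))

    def drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        n = int(mask.sum())
        if n:
            report.add_drop(reason, n)
        return df[~mask]

    ea = df["EA"].str.upper()
    oa = df["OA"].str.upper()
    df = df.assign(EA=ea, OA=oa)
    # indels / multi-allelic representations are out of scope at read time
    df = drop(~(df["EA"].isin(_BASES) & df["OA"].isin(_BASES)), "non_snp_allele")
    df = drop(df["EA"] == df["OA"], "identical_alleles")
    df = drop(~(df["SE"] > 0), "nonpositive_se")
    df = drop(~((df["EAF"] > 0) & (df["EAF"] < 1)), "eaf_out_of_range")
    df = drop(~((df["P"] > 0) & (df["P"] <= 1)), "pval_out_of_range")
    df = drop(~(df["POS"] >= 1), "bad_position")
    df = drop(~(df["N"] > 0), "bad_n")
    if "N_CASES" in df.columns:
        has_cases = df["N_CASES"].notna()
        bad = has_cases & ~((df["N_CASES"] > 0) & (df["N_CASES"] < df["N"]))
        df = drop(bad, "bad_n_cases")
    df = drop(df["SNP"].duplicated(keep="first"), "duplicate_snp")
    report.n_kept = len(df)
    if report.n_kept == 0:
        raise EmptyInputError(f"{path}: no valid rows after filtering")
    table = SumStatsTable(trait_name=trait_name, trait_type=trait_type, df=df, sd_y=sd_y)
    return table, report


def write_sumstats(table: SumStatsTable, path) -> None:
    cols = list(_REQUIRED_COLUMNS)
    if "N_CASES" in table.df.columns:
        cols.append("N_CASES")
    out = table.df[cols].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ld(path, alleles: dict[str, tuple[str, str]] | None = None) -> LDMatrix:
    """Read an LD TSV (snp ids as first row and column) into :class:`LDMatrix`.

    If ``alleles`` is not given, orientation metadata defaults to ("?", "?")
    per SNP, meaning sign orientation is taken at face value.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    snp_ids = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != snp_ids:
        raise SumStatsFormatError(f"{path}: LD row/column ids disagree")
    if alleles is None:
        alleles = {s: ("?", "?") for s in snp_ids}
    return LDMatrix(snp_ids=snp_ids, alleles=alleles, r=df.to_numpy(dtype=float))


def write_ld(ld: LDMatrix, path) -> None:
    df = pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def harmonize(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    palindrome_eaf_limit: float = 0.42,
) -> list[HarmonizedPair]:
    """Align outcome effect alleles to the exposure's.

    Swapped alleles flip the outcome beta sign and replace eaf by 1-eaf.
    Palindromic (A/T, C/G) variants are oriented by allele frequency when
    both frequencies sit on the same side of 0.5 and the minor frequency is
    below ``palindrome_eaf_limit``; otherwise they are dropped.  Allele sets
    that cannot be reconciled (including via strand complement) are dropped
    as mismatches.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise EmptyInputError("harmonize: empty input table")
    out_by_snp = {r.SNP: r for r in outcome.df.itertuples(index=False)}
    pairs: list[HarmonizedPair] = []
    for e in exposure.df.itertuples(index=False):
        o = out_by_snp.get(e.SNP)
        if o is None:
            continue
        pair = _harmonize_one(e, o, palindrome_eaf_limit)
        if pair is not None:
            pairs.append(pair)
    if not any(p.action_taken in ("kept", "flipped") for p in pairs):
        raise EmptyInputError("harmonize: no variants could be reconciled")
    return pairs


def _harmonize_one(e, o, palindrome_eaf_limit: float) -> HarmonizedPair | None:
    base = dict(
        snp_id=e.SNP,
        beta_exp=float(e.BETA),
        se_exp=float(e.SE),
        eaf_exp=float(e.EAF),
        beta_out=float(o.BETA),
        se_out=float(o.SE),
        eaf_out=float(o.EAF),
        n_exp=float(e.N),
        n_out=float(o.N),
    )
    if _is_palindromic(e.EA, e.OA):
        if {o.EA, o.OA} != {e.EA, e.OA}:
            return HarmonizedPair(**base, action_taken="dropped_mismatch")
        # allele labels cannot resolve strand for palindromes; frequencies must
        if (
            min(e.EAF, 1 - e.EAF) >= palindrome_eaf_limit
            or min(o.EAF, 1 - o.EAF) >= palindrome_eaf_limit
        ):
            return HarmonizedPair(**base, action_taken="dropped_palindromic")
        # align labels first, then orient so frequencies agree on a side of 0.5
        flipped = o.EA != e.EA
        eaf_out = 1 - float(o.EAF) if flipped else float(o.EAF)
        if (e.EAF - 0.5) * (eaf_out - 0.5) < 0:
            flipped = not flipped
            eaf_out = 1 - eaf_out
        if flipped:
            return HarmonizedPair(
                **{**base, "beta_out": -base["beta_out"], "eaf_out": eaf_out},
                action_taken="flipped",
            )
        return HarmonizedPair(**base, action_taken="kept")
    # non-palindromic: try direct match, swap, strand complement, swapped complement
    if (o.EA, o.OA) == (e.EA, e.OA):
        return HarmonizedPair(**base, action_taken="kept")
    if (o.EA, o.OA) == (e.OA, e.EA):
        return HarmonizedPair(
            **{**base, "beta_out": -base["beta_out"], "eaf_out": 1 - base["eaf_out"]},
            action_taken="flipped",
        )
    cea, coa = _COMPLEMENT.get(o.EA), _COMPLEMENT.get(o.OA)
    if (cea, coa) == (e.EA, e.OA):
        return HarmonizedPair(**base, action_taken="kept")
    if (cea, coa) == (e.OA, e.EA):
        return HarmonizedPair(
            **{**base, "beta_out": -base["beta_out"], "eaf_out": 1 - base["eaf_out"]},
            action_taken="flipped",
        )
    return HarmonizedPair(**base, action_taken="dropped_mismatch")


def kept_pairs(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    """Pairs surviving harmonization (kept or flipped)."""
    return [p for p in pairs if p.action_taken in ("kept", "flipped")]


def pairs_to_frame(pairs: Iterable[HarmonizedPair]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in pairs])
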