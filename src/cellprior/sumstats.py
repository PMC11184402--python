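"""Reading, validation and munging of GWAS summary statistics.

The downstream regression engines consume a canonical per-SNP table
(``snp_id, chrom, pos_bp, a1, a2, z, n``) with chi2 = z**2.  Munging
restricts to a SNP whitelist (the role HapMap3 plays in heritability
analyses), excises the extended MHC region whose extreme LD distorts
LD-score regression, resolves z from beta/se when needed, and drops
strand-ambiguous and duplicated records.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default MHC exclusion interval: chromosome, start, end (1-based, closed).
MHC_REGION: tuple[str, int, int] = ("6", 25_000_000, 34_000_000)

VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

# Case-insensitive aliases for incoming column headers.
_COLUMN_ALIASES: dict[str, str] = {
    "snp": "snp_id", "snpid": "snp_id", "rsid": "snp_id", "markername": "snp_id",
    "snp_id": "snp_id",
    "chr": "chrom", "chrom": "chrom", "chromosome": "chrom",
    "bp": "pos_bp", "pos": "pos_bp", "pos_bp": "pos_bp", "position": "pos_bp",
    "a1": "a1", "effect_allele": "a1", "ea": "a1",
    "a2": "a2", "other_allele": "a2", "oa": "a2", "nea": "a2",
    "z": "z", "zscore": "z",
    "beta": "beta", "b": "beta",
    "se": "se", "stderr": "se",
    "p": "p", "pval": "p", "pvalue": "p", "p_value": "p",
    "n": "n", "nobs": "n", "samplesize": "n",
}

CANONICAL_COLUMNS = ["snp_id", "chrom", "pos_bp", "a1", "a2", "z", "n"]


class SumStatsError(ValueError):
    """Schema or content problem in a summary-statistics table."""


@dataclass
class SnpFilterReport:
    """Accounting of SNPs dropped at each munging stage."""

    n_input: int = 0
    n_after_hapmap: int = 0
    n_after_mhc: int = 0
    n_after_qc: int = 0
    dropped_reasons: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_after_hapmap": self.n_after_hapmap,
                "n_after_mhc": self.n_after_mhc,
                "n_after_qc": self.n_after_qc,
                "dropped_reasons": self.dropped_reasons,
            },
            indent=2,
        )


def _canonicalize_columns(raw: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in raw.columns:
        key = str(col).strip().lower()
        if key in _COLUMN_ALIASES:
            mapping[col] = _COLUMN_ALIASES[key]
    out = raw.rename(columns=mapping)
    dup = out.columns[out.columns.duplicated()]
    if len(dup):
        raise SumStatsError(f"ambiguous column aliases resolve to {sorted(set(dup))}")
    return out


def read_raw_sumstats(path) -> pd.DataFrame:
    """Read a whitespace- or tab-delimited association table with a header."""
    return pd.read_csv(path, sep=r"\s+")


def munge(
    raw_table: pd.DataFrame,
    snp_whitelist: Iterable[str] | None = None,
    mhc_region: tuple[str, int, int] = MHC_REGION,
) -> tuple[pd.DataFrame, SnpFilterReport]:
    """Munge a raw association table into the canonical SumStats form.

    Parameters
    ----------
    raw_table
        Table containing (aliases of) snp_id, chrom, pos_bp, a1, a2 and
        either a signed ``z`` or ``beta`` + ``se``, plus ``n`` (per-SNP
        or a single global value broadcast to all rows).
    snp_whitelist
        Optional set of SNP identifiers to restrict to (e.g. a HapMap3
        SNP list).  ``None`` disables the restriction.
    mhc_region
        ``(chrom, start_bp, end_bp)`` closed 1-based interval to excise.

    Returns
    -------
    (stats, report)
        Canonical DataFrame (snp_id, chrom, pos_bp, a1, a2, z, n, chi2)
        and a :class:`SnpFilterReport` in which every input SNP is
        counted exactly once (retained or one drop reason).
    """
    df = _canonicalize_columns(raw_table).copy()
    report = SnpFilterReport(n_input=len(df))
    reasons = report.dropped_reasons

    required = {"snp_id", "chrom", "pos_bp", "a1", "a2"}
    missing = required - set(df.columns)
    if missing:
        raise SumStatsError(f"missing mandatory columns: {sorted(missing)}")
    if "z" not in df.columns and not {"beta", "se"} <= set(df.columns):
        raise SumStatsError("need either a Z column or BETA and SE columns")
    if "n" not in df.columns:
        raise SumStatsError("missing mandatory column: n (sample size)")

    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    df["pos_bp"] = pd.to_numeric(df["pos_bp"], errors="coerce")
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()
    df["n"] = pd.to_numeric(df["n"], errors="coerce")

    if "z" not in df.columns:
        beta = pd.to_numeric(df["beta"], errors="coerce")
        se = pd.to_numeric(df["se"], errors="coerce")
        df["z"] = beta / se.where(se > 0)
    df["z"] = pd.to_numeric(df["z"], errors="coerce")

    def drop(frame: pd.DataFrame, mask: pd.Series, reason: str) -> pd.DataFrame:
        k = int(mask.sum())
        if k:
            reasons[reason] = reasons.get(reason, 0) + k
        return frame.loc[~mask]

    if snp_whitelist is not None:
        wl = set(snp_whitelist)
        df = drop(df, ~df["snp_id"].isin(wl), "not_in_whitelist")
    report.n_after_hapmap = len(df)

    mhc_chrom, mhc_start, mhc_end = mhc_region
    in_mhc = (
        (df["chrom"] == str(mhc_chrom).removeprefix("chr"))
        & (df["pos_bp"] >= mhc_start)
        & (df["pos_bp"] <= mhc_end)
    )
    df = drop(df, in_mhc, "in_mhc")
    report.n_after_mhc = len(df)

    bad_allele = ~(df["a1"].isin(VALID_ALLELES) & df["a2"].isin(VALID_ALLELES))
    df = drop(df, bad_allele, "invalid_allele")

    ambiguous = pd.Series(
        [(r.a1, r.a2) in _AMBIGUOUS_PAIRS for r in df.itertuples()], index=df.index, dtype=bool
    )
    df = drop(df, ambiguous, "strand_ambiguous")

    bad_stat = df["z"].isna() | df["pos_bp"].isna() | ~(df["n"] > 0)
    df = drop(df, bad_stat, "missing_or_invalid_stat")

    dup = df.duplicated(subset=["chrom", "pos_bp"], keep="first")
    if dup.any():
        logger.warning("dropping %d duplicated (chrom,pos) records, keeping first", int(dup.sum()))
    df = drop(df, dup, "duplicate_position")

    out = df
    report.n_after_qc = len(out)
    if out.empty:
        raise SumStatsError("munging removed every SNP; check inputs and whitelist")

    out = out[CANONICAL_COLUMNS].copy()
    out["pos_bp"] = out["pos_bp"].astype(np.int64)
    out["z"] = out["z"].astype(float)
    out["n"] = out["n"].astype(float)
    out["chi2"] = out["z"] ** 2
    return out.reset_index(drop=True), report


def qc_filter(
    stats: pd.DataFrame,
    min_n_frac: float = 0.67,
    max_chi2: float | None = None,
) -> pd.DataFrame:
    """Drop SNPs with atypically low N or implausibly large chi2.

    ``max_chi2`` defaults to ``max(80, 0.001 * median(n))``, the
    conventional munging safeguard against unremoved genotyping
    artefacts.
    """
    if stats.empty:
        raise SumStatsError("qc_filter requires a nonempty table")
    med_n = float(stats["n"].median())
    if max_chi2 is None:
        max_chi2 = max(80.0, 0.001 * med_n)
    keep = (stats["n"] >= min_n_frac * med_n) & (stats["chi2"] <= max_chi2)
    out = stats.loc[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("qc_filter removed every SNP", stacklevel=2)
    return out


def write_sumstats(stats: pd.DataFrame, path) -> None:
    stats[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    """Read a canonical ``*.sumstats.tsv`` written by :func:`write_sumstats`."""
    out = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CANONICAL_COLUMNS) - set(out.columns)
    if missing:
        raise SumStatsError(f"not a canonical sumstats table; missing {sorted(missing)}")
    out["chi2"] = out["z"] ** 2
    return out
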