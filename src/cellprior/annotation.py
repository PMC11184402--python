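"""Per-SNP annotation values from gene windows and an ES_mu column.

Each gene's transcribed region is extended by a symmetric flank
(default 100 kb); a SNP inside one or more windows receives the
maximum ES_mu of the covering genes, SNPs outside every window get 0,
and a constant all-ones baseline column is always included so every
SNP enters the regression with a defined annotation value.

Coordinates are 1-based closed intervals throughout; BED input
(0-based half-open) is converted on read.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 100_000
BASELINE_COL = "baseline"


@dataclass(frozen=True)
class GeneModel:
    """A gene's transcribed span (1-based, closed)."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start_bp > end_bp")


def gene_window(g: GeneModel, flank_bp: int = DEFAULT_FLANK_BP) -> tuple[int, int]:
    """Window [start - flank, end + flank], clipped at position 1.

    The flank is symmetric; strand is ignored.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    return (max(1, g.start_bp - flank_bp), g.end_bp + flank_bp)


def read_gene_models_bed(path) -> list[GeneModel]:
    """BED with >=4 columns (chrom, start, end, name[, score, strand]).

    BED starts are 0-based half-open and converted to 1-based closed.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("gene model BED needs chrom,start,end,name")
    strand = df[5].astype(str) if df.shape[1] >= 6 else pd.Series("+", index=df.index)
    return [
        GeneModel(
            gene_id=str(r[3]),
            chrom=str(r[0]).removeprefix("chr"),
            start_bp=int(r[1]) + 1,
            end_bp=int(r[2]),
            strand=s,
        )
        for (_, r), s in zip(df.iterrows(), strand)
    ]


def write_gene_models_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start_bp - 1}\t{g.end_bp}\t{g.gene_id}\t0\t{g.strand}\n")


def annotate_snps(
    snp_chrom: np.ndarray,
    snp_pos: np.ndarray,
    genes: list[GeneModel],
    es_column: dict[str, float] | pd.Series,
    flank_bp: int = DEFAULT_FLANK_BP,
    name: str = "celltype",
) -> pd.DataFrame:
    """Max-ES_mu annotation of SNPs by covering gene windows.

    Parameters
    ----------
    snp_chrom, snp_pos
        Parallel arrays in the SNP order of the summary statistics /
        reference panel.
    es_column
        gene_id -> ES_mu in [0, 1]; genes absent from ``genes`` are
        skipped with a warning.

    Returns
    -------
    DataFrame with a constant ``baseline`` column of ones and one
    ``name`` column holding the per-SNP max-ES value (0 off-window),
    indexed like the input order.
    """
    es_column = pd.Series(es_column, dtype=float)
    if ((es_column < -1e-12) | (es_column > 1 + 1e-12)).any():
        raise ValueError("ES values must lie in [0, 1]")
    snp_chrom = np.asarray([str(c).removeprefix("chr") for c in snp_chrom], dtype=object)
    snp_pos = np.asarray(snp_pos, dtype=np.int64)
    n = len(snp_pos)

    gene_ids = {g.gene_id for g in genes}
    missing = set(es_column.index) - gene_ids
    if missing:
        warnings.warn(
            f"{len(missing)} genes in ES column absent from gene models; skipped",
            stacklevel=2,
        )

    values = np.zeros(n)
    # per-chromosome sorted sweep: searchsorted window bounds per gene
    for chrom in np.unique(snp_chrom):
        on_chrom = np.flatnonzero(snp_chrom == chrom)
        order = np.argsort(snp_pos[on_chrom], kind="stable")
        idx = on_chrom[order]
        pos_sorted = snp_pos[idx]
        for g in genes:
            if g.chrom != chrom or g.gene_id not in es_column.index:
                continue
            lo, hi = gene_window(g, flank_bp)
            a = np.searchsorted(pos_sorted, lo, side="left")
            b = np.searchsorted(pos_sorted, hi, side="right")
            if b > a:
                sel = idx[a:b]
                values[sel] = np.maximum(values[sel], es_column[g.gene_id])
    return pd.DataFrame({BASELINE_COL: np.ones(n), name: values})


def annotate_snps_bruteforce(
    snp_chrom, snp_pos, genes, es_column, flank_bp: int = DEFAULT_FLANK_BP, name: str = "celltype"
) -> pd.DataFrame:
    """O(SNPs x genes) per-SNP scan over all gene windows (test oracle)."""
    es_column = pd.Series(es_column, dtype=float)
    snp_chrom = [str(c).removeprefix("chr") for c in snp_chrom]
    snp_pos = np.asarray(snp_pos, dtype=np.int64)
    values = np.zeros(len(snp_pos))
    for j, (c, p) in enumerate(zip(snp_chrom, snp_pos)):
        best = 0.0
        for g in genes:
            if g.chrom != c or g.gene_id not in es_column.index:
                continue
            lo, hi = gene_window(g, flank_bp)
            if lo <= p <= hi:
                best = max(best, float(es_column[g.gene_id]))
        values[j] = best
    return pd.DataFrame({BASELINE_COL: np.ones(len(snp_pos)), name: values})


def write_annotations(annots: pd.DataFrame, snp_ids, path, meta_path=None) -> None:
    out = annots.copy()
    out.insert(0, "snp_id", np.asarray(snp_ids))
    out.to_csv(path, sep="\t", index=False)
    if meta_path is not None:
        meta = {
            "columns": [c for c in annots.columns],
            "baseline_column": BASELINE_COL,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def read_annotations(path) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    snp_ids = df.pop("snp_id").to_numpy(dtype=object)
    return df, snp_ids
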