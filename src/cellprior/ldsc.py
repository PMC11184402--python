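"""Partitioned LD scores and stratified heritability-enrichment regression.

The discovery statistic: per-SNP GWAS chi-square is regressed on
annotation-partitioned LD scores,

    E[chi2_j] = 1 + N_j * a_int + N_j * sum_C tau_C * l(j, C),

where l(j, C) = sum_k a_C(k) * r2~(j, k) over SNPs k within an LD
window of j, with the bias-corrected squared correlation
r2~ = r2 - (1 - r2) / (n_ref - 2).  tau_C is the change in per-SNP
heritability per unit of annotation C (here: per unit ES_mu).  The
standard error of tau comes from a delete-one-block jackknife over
contiguous SNP blocks, and the reported p is one-tailed for a positive
association (p = 1 - Phi(tau / SE)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import BASELINE_COL

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_WINDOW_CM = 1.0
DEFAULT_N_BLOCKS = 200


@dataclass
class ReferencePanel:
    """Genotype dosages (individuals x SNPs in {0,1,2}) with a SNP map."""

    genotypes: np.ndarray
    snp_map: pd.DataFrame  # columns snp_id, chrom, pos_bp, cm (cm optional)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        n, m = self.genotypes.shape
        if m != len(self.snp_map):
            raise ValueError("genotype columns must match SNP map rows")
        if n < 25:
            raise ValueError("reference panel needs at least 25 individuals")
        key = self.snp_map[["chrom", "pos_bp"]].astype({"pos_bp": np.int64})
        sorted_ok = (
            key.sort_values(["chrom", "pos_bp"], kind="stable").index == key.index
        ).all()
        if not sorted_ok:
            raise ValueError("SNP map must be sorted by (chrom, pos_bp)")

    @property
    def n_ref(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


def write_panel(panel: ReferencePanel, dosage_path, map_path) -> None:
    """Plain-text toy panel format: dosage TSV (individuals x SNPs, header =
    snp ids) and a map TSV (snp_id, chrom, pos_bp[, cm])."""
    pd.DataFrame(
        panel.genotypes.astype(int), columns=panel.snp_map["snp_id"]
    ).to_csv(dosage_path, sep="\t", index=False)
    panel.snp_map.to_csv(map_path, sep="\t", index=False)


def read_panel(dosage_path, map_path) -> ReferencePanel:
    dosages = pd.read_csv(dosage_path, sep="\t")
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    return ReferencePanel(dosages.to_numpy(dtype=float), snp_map)


def _standardize(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardized dosages; monomorphic columns zeroed with warning."""
    g = np.asarray(genotypes, dtype=float)
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    mono = sd == 0
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic SNPs: r2 contributions set to 0",
            stacklevel=3,
        )
    z = (g - mu) / np.where(mono, 1.0, sd)
    z[:, mono] = 0.0
    return z, mono


def ld_scores(
    panel: ReferencePanel,
    annots: pd.DataFrame,
    window_bp: int | None = None,
    window_cm: float | None = None,
    chunk: int = 256,
) -> pd.DataFrame:
    """Windowed partitioned LD scores for every annotation column.

    For SNP j and annotation C:
    l(j,C) = sum over same-chromosome SNPs k with |pos_k - pos_j| <=
    window of a_C(k) * r2~(j,k), self term included, where
    r2~ = r2 - (1-r2)/(n_ref-2) is the standard small-panel bias
    correction.  The window is genetic (cM) when the map has a ``cm``
    column and ``window_cm`` is requested, else physical (bp, default
    1 Mb).
    """
    if annots.shape[0] != panel.n_snps:
        raise ValueError("annotation rows must match panel SNPs")
    use_cm = window_cm is not None and "cm" in panel.snp_map.columns
    if not use_cm and window_bp is None:
        window_bp = DEFAULT_WINDOW_BP

    z, mono = _standardize(panel.genotypes)
    n_ref = panel.n_ref
    a = annots.to_numpy(dtype=float)
    out = np.zeros_like(a)

    chroms = panel.snp_map["chrom"].to_numpy(dtype=object)
    coord = (
        panel.snp_map["cm"].to_numpy(dtype=float)
        if use_cm
        else panel.snp_map["pos_bp"].to_numpy(dtype=float)
    )
    extent = window_cm if use_cm else float(window_bp)

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        c = coord[idx]
        for s in range(0, len(idx), chunk):
            block = idx[s : s + chunk]
            lo = np.searchsorted(c, coord[block[0]] - extent, side="left")
            hi = np.searchsorted(c, coord[block[-1]] + extent, side="right")
            neigh = idx[lo:hi]
            r = (z[:, block].T @ z[:, neigh]) / n_ref
            r2 = r**2
            r2_adj = r2 - (1.0 - r2) / (n_ref - 2.0)
            # restrict each row to its own window and zero monomorphic pairs
            in_win = np.abs(coord[neigh][None, :] - coord[block][:, None]) <= extent
            valid = in_win & ~mono[neigh][None, :] & ~mono[block][:, None]
            r2_adj = np.where(valid, r2_adj, 0.0)
            out[block, :] = r2_adj @ a[neigh, :]
    return pd.DataFrame(out, columns=annots.columns)


def ld_scores_bruteforce(
    panel: ReferencePanel,
    annots: pd.DataFrame,
    window_bp: int | None = None,
    window_cm: float | None = None,
) -> pd.DataFrame:
    """O(M^2) double loop over all SNP pairs (test oracle)."""
    use_cm = window_cm is not None and "cm" in panel.snp_map.columns
    if not use_cm and window_bp is None:
        window_bp = DEFAULT_WINDOW_BP
    extent = window_cm if use_cm else float(window_bp)
    coord = (
        panel.snp_map["cm"].to_numpy(dtype=float)
        if use_cm
        else panel.snp_map["pos_bp"].to_numpy(dtype=float)
    )
    chroms = panel.snp_map["chrom"].to_numpy(dtype=object)
    z, mono = _standardize(panel.genotypes)
    n_ref = panel.n_ref
    a = annots.to_numpy(dtype=float)
    m = panel.n_snps
    out = np.zeros_like(a)
    for j in range(m):
        for k in range(m):
            if chroms[j] != chroms[k] or abs(coord[j] - coord[k]) > extent:
                continue
            if mono[j] or mono[k]:
                continue
            r2 = (float(z[:, j] @ z[:, k]) / n_ref) ** 2
            r2_adj = r2 - (1.0 - r2) / (n_ref - 2.0)
            out[j, :] += r2_adj * a[k, :]
    return pd.DataFrame(out, columns=annots.columns)


def write_ld_scores(ld: pd.DataFrame, snp_ids, path) -> None:
    out = ld.copy()
    out.insert(0, "snp_id", np.asarray(snp_ids))
    out.to_csv(path, sep="\t", index=False)


@dataclass
class PrioritizationResult:
    """Stratified-regression outcome for one cell-type annotation."""

    cell_type: str
    tau: float
    se: float
    p_one_tailed: float
    significant_bonferroni: bool = False
    tau_all: dict[str, float] = field(default_factory=dict)
    intercept: float = float("nan")

    @property
    def beta_effect(self) -> float:
        """Reported effect size: change in per-SNP heritability per unit ES_mu."""
        return self.tau


def _wls_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def make_blocks(n_snps: int, n_blocks: int) -> list[np.ndarray]:
    """Contiguous near-equal-size SNP index blocks."""
    if n_blocks < 2 or n_blocks > n_snps:
        raise ValueError("need 2 <= n_blocks <= number of SNPs")
    edges = np.linspace(0, n_snps, n_blocks + 1).astype(int)
    blocks = [np.arange(edges[b], edges[b + 1]) for b in range(n_blocks)]
    if any(len(b) == 0 for b in blocks):
        raise ValueError("a jackknife block has zero SNPs")
    return blocks


def block_jackknife(
    fit: Callable[[np.ndarray], float], n_snps: int, n_blocks: int
) -> float:
    """Delete-one-block jackknife SE of a statistic.

    ``fit`` maps a boolean keep-mask over SNPs to the statistic; SE =
    sqrt((B-1)/B * sum_b (t_(-b) - mean)^2).
    """
    blocks = make_blocks(n_snps, n_blocks)
    estimates = np.empty(n_blocks)
    for b, block in enumerate(blocks):
        keep = np.ones(n_snps, dtype=bool)
        keep[block] = False
        estimates[b] = fit(keep)
    centered = estimates - estimates.mean()
    return float(np.sqrt((n_blocks - 1) / n_blocks * np.sum(centered**2)))


def default_n_blocks(n_snps: int, n_blocks: int | None = None) -> int:
    if n_blocks is not None:
        return n_blocks
    return int(min(DEFAULT_N_BLOCKS, max(2, n_snps // 10)))


def stratified_regression(
    stats: pd.DataFrame,
    ld: pd.DataFrame,
    baseline_cols: Sequence[str] = (BASELINE_COL,),
    test_col: str = "celltype",
    n_blocks: int | None = None,
) -> PrioritizationResult:
    """Stratified LD-score regression for one tested annotation.

    ``stats`` is a canonical sumstats table (needs chi2 and n); ``ld``
    holds the partitioned LD scores in the same SNP order.  The model
    chi2 - 1 = N*a_int + sum_C tau_C * N*l(j,C) is fit by single-pass
    weighted least squares with weights 1/max(l_baseline, 1); the
    jackknife SE and one-tailed p refer to tau of ``test_col``.
    """
    if len(stats) != len(ld):
        raise ValueError("stats and LD scores must share SNP order")
    if test_col in baseline_cols:
        raise ValueError("test_col must not be among baseline_cols")
    cols = list(baseline_cols) + [test_col]
    missing = set(cols) - set(ld.columns)
    if missing:
        raise ValueError(f"LD score table lacks columns {sorted(missing)}")

    chi2 = stats["chi2"].to_numpy(dtype=float)
    n = stats["n"].to_numpy(dtype=float)
    L = ld[cols].to_numpy(dtype=float)
    y = chi2 - 1.0
    X = np.column_stack([n, n[:, None] * L])  # free intercept term N*a_int first

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design; check collinearity among {cols}")

    base_ld = (
        ld[BASELINE_COL].to_numpy(dtype=float)
        if BASELINE_COL in ld.columns
        else L[:, 0]
    )
    w = 1.0 / np.maximum(base_ld, 1.0)

    coef = _wls_fit(X, y, w)
    test_ix = X.shape[1] - 1
    tau = float(coef[test_ix])

    nb = default_n_blocks(len(y), n_blocks)

    def refit(keep: np.ndarray) -> float:
        return float(_wls_fit(X[keep], y[keep], w[keep])[test_ix])

    se = block_jackknife(refit, len(y), nb)
    if se > 0:
        p = float(norm.sf(tau / se))
    else:
        # degenerate: all blocks identical; call the sign
        p = 0.0 if tau > 0 else 1.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return PrioritizationResult(
        cell_type=test_col,
        tau=tau,
        se=se,
        p_one_tailed=p,
        tau_all={c: float(coef[i + 1]) for i, c in enumerate(cols)},
        intercept=float(coef[0]),
    )


def prioritize_all(
    stats: pd.DataFrame,
    ld: pd.DataFrame,
    cell_type_cols: Sequence[str],
    baseline_cols: Sequence[str] = (BASELINE_COL,),
    alpha: float = 0.05,
    n_blocks: int | None = None,
) -> list[PrioritizationResult]:
    """One stratified regression per cell type, Bonferroni-flagged,
    sorted by p ascending."""
    T = len(cell_type_cols)
    if T < 1:
        raise ValueError("need at least one cell type")
    threshold = alpha / T
    results = []
    for col in cell_type_cols:
        res = stratified_regression(
            stats, ld, baseline_cols=baseline_cols, test_col=col, n_blocks=n_blocks
        )
        res.significant_bonferroni = res.p_one_tailed < threshold
        results.append(res)
    results.sort(key=lambda r: r.p_one_tailed)
    return results


def results_table(results: Sequence[PrioritizationResult]) -> pd.DataFrame:
    """TSV-ready table mirroring the prioritization report layout."""
    return pd.DataFrame(
        {
            "cell_type": [r.cell_type for r in results],
            "beta": [r.beta_effect for r in results],
            "se": [r.se for r in results],
            "p": [r.p_one_tailed for r in results],
            "significant": [r.significant_bonferroni for r in results],
        }
    )
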