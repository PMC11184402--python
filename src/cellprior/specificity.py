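"""Single-cell expression specificity: four ES metrics combined into ES_mu.

A raw count matrix with cell-type labels is normalized per cell to a
common transcript count (default 10,000) and log1p-transformed.  Four
specificity metrics are then computed per gene and cell type:

* gene enrichment score (GES) — within-type mean over global mean,
* expression proportion (EP) — within-type mean over the row sum of
  within-type means,
* normalized specificity index (NSI) — rank-based index of the
  within-type mean relative to every other type,
* differential-expression t statistic (DET) — Welch t of the type's
  cells against all remaining cells.

Each metric is turned into a significance-gated, rank-scaled weight
ES_w in [0, 1] using an empirical one-sided permutation null over
cell-type labels; ES_mu is the elementwise mean of the four ES_w
matrices.  High ES_mu marks genes whose expression is specific to a
cell type, the quantity both prioritization routes regress on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

EPS = 1e-9  # ratio-denominator guard; does not perturb rankings of expressed genes
DEFAULT_SCALE = 10_000.0
DEFAULT_GATE_ALPHA = 0.05
DEFAULT_N_PERMS = 1000

MetricFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class ExpressionMatrix:
    """Raw single-cell counts (genes x cells) with per-cell type labels."""

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_type: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        g, c = self.counts.shape
        if len(self.gene_ids) != g or len(self.cell_ids) != c or len(self.cell_type) != c:
            raise ValueError("counts shape inconsistent with gene/cell metadata")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(np.unique(self.cell_type)) < 2:
            raise ValueError("need at least two cell types")

    @property
    def cell_types(self) -> np.ndarray:
        return np.unique(self.cell_type)

    @classmethod
    def from_anndata(cls, adata, cell_type_key: str = "cell_type") -> "ExpressionMatrix":
        """Build from an AnnData (cells x genes) with labels in ``.obs``."""
        x = adata.X
        if sparse.issparse(x):
            x = x.toarray()
        return cls(
            counts=np.asarray(x).T,
            gene_ids=np.asarray(adata.var_names, dtype=object),
            cell_ids=np.asarray(adata.obs_names, dtype=object),
            cell_type=np.asarray(adata.obs[cell_type_key], dtype=object),
        )


@dataclass
class ESMatrix:
    """Genes x cell-types ES_mu plus the four per-metric ES_w matrices."""

    es_mu: pd.DataFrame
    per_metric_esw: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.es_mu.to_numpy(dtype=float)
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("es_mu must lie in [0, 1]")

    def column(self, cell_type: str) -> pd.Series:
        return self.es_mu[cell_type]


class OrthologMapError(ValueError):
    pass


def load_ortholog_map(path) -> dict[str, str]:
    """Two-column TSV (source_gene, target_gene) restricted to 1-1 pairs."""
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"], dtype=str)
    return validate_ortholog_map(dict(zip(df["source"], df["target"])))


def validate_ortholog_map(pairs: dict[str, str]) -> dict[str, str]:
    targets = list(pairs.values())
    if len(set(targets)) != len(targets):
        raise OrthologMapError("ortholog map is not injective: duplicated target gene")
    return pairs


def map_orthologs(x: ExpressionMatrix, pairs: dict[str, str]) -> ExpressionMatrix:
    """Keep genes with a 1-1 ortholog and rename them to target identifiers."""
    validate_ortholog_map(pairs)
    keep = np.array([g in pairs for g in x.gene_ids], dtype=bool)
    return ExpressionMatrix(
        counts=x.counts[keep],
        gene_ids=np.array([pairs[g] for g in x.gene_ids[keep]], dtype=object),
        cell_ids=x.cell_ids,
        cell_type=x.cell_type,
    )


def normalize(x: ExpressionMatrix, scale: float = DEFAULT_SCALE) -> np.ndarray:
    """Scale each cell to a common transcript count, then natural-log(x+1).

    All-zero cells are left all-zero (with a warning) rather than NaN.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    counts = np.asarray(x.counts, dtype=float)
    totals = counts.sum(axis=0)
    zero_cells = totals == 0
    if zero_cells.any():
        warnings.warn(f"{int(zero_cells.sum())} all-zero cells left unnormalized", stacklevel=2)
    safe = np.where(zero_cells, 1.0, totals)
    return np.log1p(counts * (scale / safe))


def _encode_labels(labels: np.ndarray, types: np.ndarray) -> np.ndarray:
    """Cells x types one-hot indicator."""
    return (labels[:, None] == types[None, :]).astype(float)


def group_means(xnorm: np.ndarray, labels: np.ndarray, types: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cell-type mean of the normalized expression, genes x types."""
    labels = np.asarray(labels, dtype=object)
    if types is None:
        types = np.unique(labels)
    ind = _encode_labels(labels, types)
    means = (xnorm @ ind) / ind.sum(axis=0)
    return pd.DataFrame(means, columns=types)


def metric_ep(mean_expr: np.ndarray) -> np.ndarray:
    """Expression proportion: each row rescaled to sum to one (0 rows stay 0)."""
    mean_expr = np.asarray(mean_expr, dtype=float)
    row = mean_expr.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(row > 0, mean_expr / row, 0.0)
    return out


def metric_ges(xnorm: np.ndarray, labels: np.ndarray, types: np.ndarray | None = None) -> np.ndarray:
    """Gene enrichment score: within-type mean over global mean."""
    labels = np.asarray(labels, dtype=object)
    if types is None:
        types = np.unique(labels)
    m = group_means(xnorm, labels, types).to_numpy()
    global_mean = xnorm.mean(axis=1, keepdims=True)
    return m / (global_mean + EPS)


def metric_nsi(mean_expr: np.ndarray) -> np.ndarray:
    """Normalized specificity index from pairwise expression-ratio ranks.

    For target type c and each other type c', genes are ranked descending
    by mean(g,c)/(mean(g,c')+eps) with average-rank ties; the specificity
    index SI(g,c) is the mean rank over c'!=c, mapped to [0,1] via
    1 - (SI-1)/(G-1) so the most specific gene scores 1.
    """
    mean_expr = np.asarray(mean_expr, dtype=float)
    n_genes, n_types = mean_expr.shape
    if n_types < 2 or n_genes < 2:
        raise ValueError("need >=2 genes and >=2 cell types")
    out = np.empty_like(mean_expr)
    for c in range(n_types):
        others = [cp for cp in range(n_types) if cp != c]
        ratios = mean_expr[:, [c]] / (mean_expr[:, others] + EPS)
        # descending rank: rank 1 = largest ratio
        ranks = rankdata(-ratios, axis=0, method="average")
        si = ranks.mean(axis=1)
        out[:, c] = 1.0 - (si - 1.0) / (n_genes - 1.0)
    return out


def metric_det(xnorm: np.ndarray, labels: np.ndarray, types: np.ndarray | None = None) -> np.ndarray:
    """Welch t statistic per gene: cells of each type vs all other cells."""
    labels = np.asarray(labels, dtype=object)
    if types is None:
        types = np.unique(labels)
    ind = _encode_labels(labels, types)
    n1 = ind.sum(axis=0)
    n_cells = xnorm.shape[1]
    n2 = n_cells - n1

    s1 = xnorm @ ind
    sq1 = (xnorm**2) @ ind
    s_tot = xnorm.sum(axis=1, keepdims=True)
    sq_tot = (xnorm**2).sum(axis=1, keepdims=True)
    s2 = s_tot - s1
    sq2 = sq_tot - sq1

    out = np.zeros((xnorm.shape[0], len(types)))
    for c in range(len(types)):
        if n1[c] < 2 or n2[c] < 2:
            warnings.warn(
                f"cell type {types[c]!r} or its complement has <2 cells; t set to 0",
                stacklevel=2,
            )
            continue
        m1 = s1[:, c] / n1[c]
        m2 = s2[:, c] / n2[c]
        v1 = (sq1[:, c] - n1[c] * m1**2) / (n1[c] - 1)
        v2 = (sq2[:, c] - n2[c] * m2**2) / (n2[c] - 1)
        v1 = np.maximum(v1, 0.0)
        v2 = np.maximum(v2, 0.0)
        denom = np.sqrt(v1 / n1[c] + v2 / n2[c])
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
        out[:, c] = t
    return out


# The four metrics as (xnorm, labels, types) -> genes x types callables.
def _ep_fn(xnorm, labels, types):
    return metric_ep(group_means(xnorm, labels, types).to_numpy())


def _nsi_fn(xnorm, labels, types):
    return metric_nsi(group_means(xnorm, labels, types).to_numpy())


METRICS: dict[str, Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]] = {
    "ges": metric_ges,
    "ep": _ep_fn,
    "nsi": _nsi_fn,
    "det": metric_det,
}


def esw_from_metric(
    metric: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    xnorm: np.ndarray,
    labels: np.ndarray,
    n_perms: int = DEFAULT_N_PERMS,
    seed: int = 0,
    gate_alpha: float = DEFAULT_GATE_ALPHA,
    types: np.ndarray | None = None,
) -> np.ndarray:
    """Significance-gated, rank-scaled ES weight for one metric.

    Per cell type, each gene's observed metric value is compared with an
    empirical null built by permuting the cell-type labels (``n_perms``
    label shuffles, seeded).  Genes with one-sided empirical
    p >= ``gate_alpha`` get ES_w = 0; the retained genes are assigned
    rank/#retained so the largest metric value maps to 1.
    """
    if n_perms < 100:
        raise ValueError("n_perms must be at least 100")
    labels = np.asarray(labels, dtype=object)
    if types is None:
        types = np.unique(labels)
    observed = np.asarray(metric(xnorm, labels, types), dtype=float)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_perms):
        perm = metric(xnorm, rng.permutation(labels), types)
        exceed += (perm >= observed)
    pvals = (1.0 + exceed) / (n_perms + 1.0)

    esw = np.zeros_like(observed)
    for c in range(observed.shape[1]):
        retained = pvals[:, c] < gate_alpha
        k = int(retained.sum())
        if k == 0:
            continue
        ranks = rankdata(observed[retained, c], method="average")
        esw[retained, c] = ranks / k
    return esw


def combine_es_mu(esw: dict[str, np.ndarray], gene_ids, types) -> ESMatrix:
    """Elementwise mean of the four ES_w matrices."""
    mats = list(esw.values())
    if len({m.shape for m in mats}) != 1:
        raise ValueError("ES_w matrices must share one shape")
    for name, m in esw.items():
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ValueError(f"ES_w matrix {name!r} outside [0, 1]")
    mu = np.mean(mats, axis=0)
    per_metric = {
        name: pd.DataFrame(m, index=gene_ids, columns=types) for name, m in esw.items()
    }
    return ESMatrix(
        es_mu=pd.DataFrame(mu, index=gene_ids, columns=types),
        per_metric_esw=per_metric,
    )


def compute_es(
    x: ExpressionMatrix,
    scale: float = DEFAULT_SCALE,
    n_perms: int = DEFAULT_N_PERMS,
    seed: int = 0,
    gate_alpha: float = DEFAULT_GATE_ALPHA,
) -> ESMatrix:
    """Full specificity pipeline: normalize -> 4 metrics -> ES_w -> ES_mu."""
    xnorm = normalize(x, scale=scale)
    types = x.cell_types
    child_seeds = np.random.SeedSequence(seed).spawn(len(METRICS))
    esw = {}
    for (name, metric), ss in zip(METRICS.items(), child_seeds):
        esw[name] = esw_from_metric(
            metric, xnorm, x.cell_type,
            n_perms=n_perms, seed=ss.generate_state(1)[0] % (2**31),
            gate_alpha=gate_alpha, types=types,
        )
    return combine_es_mu(esw, x.gene_ids, types)


# ---------------------------------------------------------------------------
# I/O

def write_es(es: ESMatrix, path, per_metric_prefix=None) -> None:
    es.es_mu.rename_axis("gene_id").to_csv(path, sep="\t")
    if per_metric_prefix is not None:
        for name, m in es.per_metric_esw.items():
            m.rename_axis("gene_id").to_csv(f"{per_metric_prefix}.{name}.tsv", sep="\t")


def read_es_mu(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def load_expression_mtx(mtx_path, genes_path, cells_path, labels_path) -> ExpressionMatrix:
    """MatrixMarket counts (genes x cells) + one-column gene/cell TSVs +
    two-column (cell_id, cell_type) label TSV."""
    counts = spio.mmread(mtx_path)
    if sparse.issparse(counts):
        counts = counts.toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy(dtype=object)
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].to_numpy(dtype=object)
    labels = pd.read_csv(labels_path, sep="\t", header=None, names=["cell_id", "cell_type"])
    label_map = dict(zip(labels["cell_id"], labels["cell_type"]))
    try:
        cell_type = np.array([label_map[c] for c in cells], dtype=object)
    except KeyError as e:
        raise ValueError(f"cell {e.args[0]!r} missing from label table") from None
    return ExpressionMatrix(np.asarray(counts), genes, cells, cell_type)


def load_expression_tsv(counts_path, labels_path) -> ExpressionMatrix:
    """Dense TSV (rows=genes, columns=cells) + two-column label TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", header=None, names=["cell_id", "cell_type"])
    label_map = dict(zip(labels["cell_id"].astype(str), labels["cell_type"]))
    cells = df.columns.to_numpy(dtype=object)
    cell_type = np.array([label_map[str(c)] for c in cells], dtype=object)
    return ExpressionMatrix(df.to_numpy(), df.index.to_numpy(dtype=object), cells, cell_type)
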