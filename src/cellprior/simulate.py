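"""Seeded generators for inputs with the structure the analysis assumes.

The pieces mirror the real study's data types without any downloads:

* a genotype reference panel with block-wise AR(1) LD (Gaussian-copula
  haplotypes thresholded at a per-SNP MAF),
* GWAS summary statistics drawn from the stratified generative model
  the regression fits — per-SNP causal variance linear in an
  annotation, marginal z per LD block from the exact MVN implied by
  the block correlation,
* negative-binomial single-cell counts with disjoint planted marker
  sets per cell type,
* an eQTL-exposure / GWAS-outcome instrument pair with a known causal
  effect for MR.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import GeneModel
from .ldsc import ReferencePanel
from .specificity import ExpressionMatrix

logger = logging.getLogger(__name__)

SNP_SPACING_BP = 10_000
MARKER_FRACTION = 0.10


@dataclass
class SimConfig:
    """Study conditions for the synthetic analysis.

    Defaults give a desk-scale version of the real design: a 2,000-SNP
    panel in 20 independent LD blocks, a 50,000-sample GWAS with half
    the trait variance from common SNPs, 8 kidney-like cell types with
    10% planted markers each at 20-fold expression, and heritability
    enrichment concentrated on one designated causal cell type.
    """

    seed: int = 0
    n_ref: int = 500
    n_gwas: int = 50_000
    n_blocks: int = 20
    snps_per_block: int = 100
    rho: float = 0.9
    n_genes: int = 200
    n_celltypes: int = 8
    n_cells_per_type: int = 40
    causal_celltype: int = 0
    enrichment_theta: float = 4.0
    h2: float = 0.5
    nb_dispersion: float = 2.0
    marker_fold: float = 20.0

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must be in [0, 1)")
        if self.enrichment_theta < 0:
            raise ValueError("enrichment_theta must be >= 0")

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block


def simulate_panel(cfg: SimConfig, rng: np.random.Generator | None = None) -> ReferencePanel:
    """Blockwise AR(1)-LD genotypes on one synthetic chromosome.

    Within each block, latent Gaussians with corr rho^|i-j| are
    thresholded at per-SNP MAF ~ U(0.05, 0.5) into haplotypes; a
    genotype is the sum of two haplotypes.  Blocks are mutually
    independent; map positions are spaced 10 kb with cm = bp / 1e6.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    m, b = cfg.n_snps, cfg.snps_per_block
    maf = rng.uniform(0.05, 0.5, size=m)
    thresh = norm.ppf(maf)

    haps = np.empty((2 * cfg.n_ref, m))
    for blk in range(cfg.n_blocks):
        sl = slice(blk * b, (blk + 1) * b)
        eps = rng.standard_normal((2 * cfg.n_ref, b))
        x = np.empty_like(eps)
        x[:, 0] = eps[:, 0]
        scale = np.sqrt(1.0 - cfg.rho**2)
        for i in range(1, b):
            x[:, i] = cfg.rho * x[:, i - 1] + scale * eps[:, i]
        haps[:, sl] = x[:, : b]
    alleles = (haps < thresh[None, :]).astype(float)
    genotypes = alleles[0::2] + alleles[1::2]

    pos = SNP_SPACING_BP * (1 + np.arange(m))
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos_bp": pos.astype(np.int64),
            "cm": pos / 1e6,
        }
    )
    return ReferencePanel(genotypes, snp_map)


def simulate_sc_counts(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, dict]:
    """Negative-binomial counts with disjoint planted marker sets.

    Baseline gene means are log-normal; each cell type's marker set
    (10% of genes, disjoint across types) has its mean multiplied by
    ``marker_fold`` in that type only.  Per-cell log-normal size
    factors add library-size variation.  Returns the matrix and a
    truth table mapping each cell type to its marker gene ids.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    g, t, cpt = cfg.n_genes, cfg.n_celltypes, cfg.n_cells_per_type
    n_marker = int(MARKER_FRACTION * g)
    if n_marker * t > g:
        raise ValueError("too many cell types for disjoint 10% marker sets")

    gene_ids = np.array([f"g{i}" for i in range(g)], dtype=object)
    types = np.array([f"ct{i}" for i in range(t)], dtype=object)
    perm = rng.permutation(g)
    markers = {types[c]: sorted(gene_ids[perm[c * n_marker : (c + 1) * n_marker]])
               for c in range(t)}
    marker_ix = {types[c]: perm[c * n_marker : (c + 1) * n_marker] for c in range(t)}

    base_mean = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=g)
    cell_type = np.repeat(types, cpt)
    n_cells = t * cpt
    size_factor = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)

    mu = np.tile(base_mean[:, None], (1, n_cells))
    for c in range(t):
        cells_c = np.flatnonzero(cell_type == types[c])
        mu[np.ix_(marker_ix[types[c]], cells_c)] *= cfg.marker_fold
    mu *= size_factor[None, :]

    r = cfg.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    x = ExpressionMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=np.array([f"cell{i}" for i in range(n_cells)], dtype=object),
        cell_type=cell_type,
    )
    truth = {
        "markers": {str(k): [str(gid) for gid in v] for k, v in markers.items()},
        "causal_celltype": str(types[cfg.causal_celltype]),
        "marker_fold": cfg.marker_fold,
    }
    return x, truth


def tile_genes(panel: ReferencePanel, n_genes: int, span_bp: int = 20_000) -> list[GeneModel]:
    """Tile gene models evenly over the panel's SNP span (one chromosome)."""
    pos = panel.snp_map["pos_bp"].to_numpy()
    chrom = str(panel.snp_map["chrom"].iloc[0])
    starts = np.linspace(pos.min(), max(pos.max() - span_bp, pos.min()), n_genes).astype(int)
    return [
        GeneModel(gene_id=f"g{i}", chrom=chrom, start_bp=int(s), end_bp=int(s) + span_bp)
        for i, s in enumerate(starts)
    ]


def simulate_gwas(
    cfg: SimConfig,
    panel: ReferencePanel,
    annot: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """GWAS z-scores from the stratified generative model.

    Standardized per-SNP causal effects b_j ~ N(0, s2_j) with
    s2_j = h2 * (1 + theta * a_j) / sum_i (1 + theta * a_i); per LD
    block, the marginal z vector is drawn from the exact
    MVN(sqrt(N) * R * b, R) implied by the block's empirical genotype
    correlation R.  Returns a canonical sumstats table plus the truth
    (per-SNP heritability intercept/slope tau0, tau1 implied by the
    model, so E[chi2_j] = 1 + N * (tau0 * l_baseline + tau1 * l_annot)).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    a = np.asarray(annot, dtype=float)
    m = panel.n_snps
    if len(a) != m:
        raise ValueError("annotation must align with panel SNPs")

    weight = 1.0 + cfg.enrichment_theta * a
    total = weight.sum()
    s2 = cfg.h2 * weight / total
    tau0 = cfg.h2 / total
    tau1 = cfg.enrichment_theta * cfg.h2 / total

    b = rng.standard_normal(m) * np.sqrt(s2)
    z = np.empty(m)
    bs = cfg.snps_per_block
    g = panel.genotypes
    for blk in range(cfg.n_blocks):
        sl = slice(blk * bs, (blk + 1) * bs)
        gb = g[:, sl]
        sd = gb.std(axis=0)
        zb = (gb - gb.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        zb[:, sd == 0] = 0.0
        R = (zb.T @ zb) / panel.n_ref
        np.fill_diagonal(R, 1.0)
        mean = np.sqrt(cfg.n_gwas) * (R @ b[sl])
        L = np.linalg.cholesky(R + 1e-8 * np.eye(R.shape[0]))
        z[sl] = mean + L @ rng.standard_normal(R.shape[0])

    stats = pd.DataFrame(
        {
            "snp_id": panel.snp_map["snp_id"],
            "chrom": panel.snp_map["chrom"],
            "pos_bp": panel.snp_map["pos_bp"],
            "a1": "A",
            "a2": "G",
            "z": z,
            "n": float(cfg.n_gwas),
        }
    )
    stats["chi2"] = stats["z"] ** 2
    truth = {"tau0": float(tau0), "tau1": float(tau1),
             "theta": cfg.enrichment_theta, "h2": cfg.h2}
    return stats, truth


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def simulate_mr_pair(
    true_effect: float,
    n_instruments: int = 30,
    f_target: float = 100.0,
    outcome_se: float = 0.02,
    noise: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure/outcome records for a two-sample MR with known effect.

    Independent instruments with true exposure effects ~ N(0.3,
    0.05^2) (per SD of expression), exposure SE set to 0.3 /
    sqrt(f_target) so instrument strength is about ``f_target``;
    outcome effect = true_effect * exposure effect plus noise at the
    outcome SE.  Outcome allele orientation is randomized (with the
    matching sign flip) to exercise harmonization; ``noise=False``
    removes both sampling noises so IVW returns ``true_effect``
    exactly.
    """
    if n_instruments < 1:
        raise ValueError("need at least one instrument")
    rng = np.random.default_rng(seed)
    gamma = rng.normal(0.3, 0.05, size=n_instruments)
    se_exp = np.full(n_instruments, 0.3 / np.sqrt(f_target))
    se_out = np.full(n_instruments, outcome_se)

    beta_exp = gamma + (rng.standard_normal(n_instruments) * se_exp if noise else 0.0)
    beta_out = true_effect * gamma + (
        rng.standard_normal(n_instruments) * se_out if noise else 0.0
    )

    pair_ix = rng.integers(0, len(_ALLELE_PAIRS), size=n_instruments)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_ix], dtype=object)
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_ix], dtype=object)
    snp_id = np.array([f"iv{i}" for i in range(n_instruments)], dtype=object)

    exposure = pd.DataFrame(
        {"snp_id": snp_id, "a1": a1, "a2": a2, "beta": beta_exp, "se": se_exp}
    )
    flip = rng.random(n_instruments) < 0.5
    outcome = pd.DataFrame(
        {
            "snp_id": snp_id,
            "a1": np.where(flip, a2, a1),
            "a2": np.where(flip, a1, a2),
            "beta": np.where(flip, -beta_out, beta_out),
            "se": se_out,
        }
    )
    return exposure, outcome


@dataclass
class DiscoveryBundle:
    """Everything one synthetic end-to-end discovery run needs."""

    cfg: SimConfig
    panel: ReferencePanel
    expression: ExpressionMatrix
    genes: list[GeneModel]
    sumstats: pd.DataFrame
    causal_annotation: np.ndarray
    truth: dict = field(default_factory=dict)


def simulate_discovery_bundle(
    cfg: SimConfig,
    es_n_perms: int = 300,
    flank_bp: int = 100_000,
) -> DiscoveryBundle:
    """Counts -> ES_mu -> causal-cell-type annotation -> GWAS, seeded.

    The GWAS heritability enrichment is planted on the annotation
    derived from the causal cell type's own ES_mu column, closing the
    loop between the generator and the regression model.
    """
    from .annotation import annotate_snps
    from .specificity import compute_es

    ss = np.random.SeedSequence(cfg.seed)
    s_panel, s_counts, s_es, s_gwas = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))

    panel = simulate_panel(cfg, np.random.default_rng(s_panel))
    expr, sc_truth = simulate_sc_counts(cfg, np.random.default_rng(s_counts))
    es = compute_es(expr, n_perms=es_n_perms, seed=s_es)
    genes = tile_genes(panel, cfg.n_genes)

    causal = sc_truth["causal_celltype"]
    annots = annotate_snps(
        panel.snp_map["chrom"], panel.snp_map["pos_bp"], genes,
        es.es_mu[causal], flank_bp=flank_bp, name=causal,
    )
    a = annots[causal].to_numpy()
    stats, gwas_truth = simulate_gwas(cfg, panel, a, np.random.default_rng(s_gwas))

    bundle = DiscoveryBundle(
        cfg=cfg, panel=panel, expression=expr, genes=genes,
        sumstats=stats, causal_annotation=a,
        truth={**sc_truth, **gwas_truth, "es_n_perms": es_n_perms},
    )
    bundle.truth["es_mu"] = es  # reused downstream to avoid recomputation
    return bundle


def write_bundle(bundle: DiscoveryBundle, outdir) -> None:
    """Write a bundle in the package's standard on-disk formats."""
    import os

    from scipy import io as spio
    from scipy import sparse

    from .annotation import write_gene_models_bed
    from .ldsc import write_panel
    from .sumstats import write_sumstats

    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    write_panel(bundle.panel, p("panel.dosage.tsv"), p("panel.map.tsv"))
    write_sumstats(bundle.sumstats, p("gwas.sumstats.tsv"))
    write_gene_models_bed(bundle.genes, p("genes.bed"))
    spio.mmwrite(p("counts.mtx"), sparse.csr_matrix(bundle.expression.counts))
    pd.Series(bundle.expression.gene_ids).to_csv(p("genes.tsv"), sep="\t", index=False, header=False)
    pd.Series(bundle.expression.cell_ids).to_csv(p("cells.tsv"), sep="\t", index=False, header=False)
    pd.DataFrame(
        {"cell_id": bundle.expression.cell_ids, "cell_type": bundle.expression.cell_type}
    ).to_csv(p("cell_labels.tsv"), sep="\t", index=False, header=False)
    truth = {k: v for k, v in bundle.truth.items() if k != "es_mu"}
    truth["config"] = asdict(bundle.cfg)
    with open(p("truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
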