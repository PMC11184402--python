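"""End-to-end orchestration: munge -> ES_mu -> annotate -> LD scores ->
prioritize, with a config object, seeded runs and a reproducibility
manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation import BASELINE_COL, GeneModel, annotate_snps, read_gene_models_bed
from .ldsc import (
    ReferencePanel,
    ld_scores,
    prioritize_all,
    read_panel,
    results_table,
    write_ld_scores,
)
from .magma import compute_gene_stats, prioritize_all_magma
from .specificity import (
    ESMatrix,
    compute_es,
    load_expression_mtx,
    load_expression_tsv,
    write_es,
)
from .sumstats import munge, qc_filter, read_raw_sumstats, write_sumstats

logger = logging.getLogger(__name__)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class RunConfig:
    """Paths and parameters of one discovery run.

    Defaults follow the analysis conventions: 100 kb gene windows,
    10,000-transcript normalization scale, Bonferroni at alpha = 0.05
    over the number of cell types tested.
    """

    out_dir: str = "cellprior_run"
    sumstats: str | None = None
    snp_whitelist: str | None = None
    counts_mtx: str | None = None
    counts_genes: str | None = None
    counts_cells: str | None = None
    counts_tsv: str | None = None
    cell_labels: str | None = None
    gene_bed: str | None = None
    panel_dosage: str | None = None
    panel_map: str | None = None
    apply_qc: bool = True
    qc_min_n_frac: float = 0.67
    qc_max_chi2: float | None = None  # None -> max(80, 0.001 * median N)
    flank_bp: int = 100_000
    scale: float = 10_000.0
    alpha: float = 0.05
    n_blocks: int | None = None
    ld_window_bp: int = 1_000_000
    es_n_perms: int = 1000
    seed: int = 0
    method: str = "ldsc"  # {ldsc, magma, both}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def align_to_panel(stats: pd.DataFrame, panel: ReferencePanel) -> tuple[pd.DataFrame, np.ndarray]:
    """Restrict stats and panel to shared SNPs, in panel order.

    Returns the aligned stats table and the integer indices of the
    retained panel SNPs.
    """
    panel_ids = panel.snp_map["snp_id"]
    stats_ix = stats.set_index("snp_id")
    shared = panel_ids[panel_ids.isin(stats_ix.index)]
    if shared.empty:
        raise ValueError("no SNPs shared between summary statistics and panel")
    aligned = stats_ix.loc[shared].reset_index()
    keep_ix = np.flatnonzero(panel_ids.isin(shared).to_numpy())
    return aligned, keep_ix


def _subset_panel(panel: ReferencePanel, keep_ix: np.ndarray) -> ReferencePanel:
    return ReferencePanel(
        panel.genotypes[:, keep_ix], panel.snp_map.iloc[keep_ix].reset_index(drop=True)
    )


def discovery_from_objects(
    stats: pd.DataFrame,
    es: ESMatrix,
    panel: ReferencePanel,
    genes: Sequence[GeneModel],
    flank_bp: int = 100_000,
    alpha: float = 0.05,
    n_blocks: int | None = None,
    ld_window_bp: int = 1_000_000,
    method: str = "ldsc",
) -> dict[str, pd.DataFrame]:
    """Run prioritization on in-memory inputs; the library-level core.

    Returns ``{"ldsc": table}`` and/or ``{"magma": table}`` depending
    on ``method``, each a (cell_type, beta, se, p, significant) table
    sorted by p.
    """
    if method not in {"ldsc", "magma", "both"}:
        raise ValueError("method must be one of ldsc, magma, both")
    stats, keep_ix = align_to_panel(stats, panel)
    panel = _subset_panel(panel, keep_ix)
    out: dict[str, pd.DataFrame] = {}

    cell_types = [str(c) for c in es.es_mu.columns]
    if method in {"ldsc", "both"}:
        cols = {}
        for ct in cell_types:
            ann = annotate_snps(
                panel.snp_map["chrom"], panel.snp_map["pos_bp"], list(genes),
                es.es_mu[ct], flank_bp=flank_bp, name=ct,
            )
            cols[ct] = ann[ct]
        annots = pd.DataFrame({BASELINE_COL: np.ones(panel.n_snps), **cols})
        ld = ld_scores(panel, annots, window_bp=ld_window_bp)
        results = prioritize_all(
            stats, ld, cell_types, alpha=alpha, n_blocks=n_blocks
        )
        out["ldsc"] = results_table(results)
        out["_ld_scores"] = ld
    if method in {"magma", "both"}:
        gene_stats = compute_gene_stats(stats, panel, list(genes), flank_bp=flank_bp)
        out["magma"] = prioritize_all_magma(gene_stats, es.es_mu, alpha=alpha)
        out["_gene_stats"] = gene_stats
    return out


def run_discovery(cfg: RunConfig) -> dict:
    """Path-based end-to-end run; writes result tables and a manifest.

    Stages: munge (+QC) -> ES_mu -> annotate -> LD scores ->
    prioritize via the chosen method(s).  Any stage error aborts with
    the stage name in the message.  Reruns with the same config and
    seed produce byte-identical outputs.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    t0 = time.time()
    stage = "setup"
    inputs = {
        k: getattr(cfg, k)
        for k in (
            "sumstats", "snp_whitelist", "counts_mtx", "counts_genes",
            "counts_cells", "counts_tsv", "cell_labels", "gene_bed",
            "panel_dosage", "panel_map",
        )
        if getattr(cfg, k)
    }
    try:
        stage = "munge"
        raw = read_raw_sumstats(cfg.sumstats)
        whitelist = None
        if cfg.snp_whitelist:
            with open(cfg.snp_whitelist) as fh:
                whitelist = {line.strip() for line in fh if line.strip()}
        stats, report = munge(raw, whitelist)
        if cfg.apply_qc:
            stats = qc_filter(stats, min_n_frac=cfg.qc_min_n_frac, max_chi2=cfg.qc_max_chi2)
        write_sumstats(stats, os.path.join(cfg.out_dir, "munged.sumstats.tsv"))
        with open(os.path.join(cfg.out_dir, "munge_report.json"), "w") as fh:
            fh.write(report.to_json())

        stage = "expression specificity"
        if cfg.counts_tsv:
            expr = load_expression_tsv(cfg.counts_tsv, cfg.cell_labels)
        else:
            expr = load_expression_mtx(
                cfg.counts_mtx, cfg.counts_genes, cfg.counts_cells, cfg.cell_labels
            )
        es = compute_es(expr, scale=cfg.scale, n_perms=cfg.es_n_perms, seed=cfg.seed)
        write_es(es, os.path.join(cfg.out_dir, "es_mu.tsv"),
                 per_metric_prefix=os.path.join(cfg.out_dir, "esw"))

        stage = "inputs"
        genes = read_gene_models_bed(cfg.gene_bed)
        panel = read_panel(cfg.panel_dosage, cfg.panel_map)

        stage = "prioritization"
        tables = discovery_from_objects(
            stats, es, panel, genes,
            flank_bp=cfg.flank_bp, alpha=cfg.alpha, n_blocks=cfg.n_blocks,
            ld_window_bp=cfg.ld_window_bp, method=cfg.method,
        )
        stage = "write results"
        for name in ("ldsc", "magma"):
            if name in tables:
                tables[name].to_csv(
                    os.path.join(cfg.out_dir, f"prioritization_{name}.tsv"),
                    sep="\t", index=False,
                )
        if "_ld_scores" in tables:
            aligned, keep_ix = align_to_panel(stats, panel)
            write_ld_scores(
                tables["_ld_scores"], aligned["snp_id"],
                os.path.join(cfg.out_dir, "ld_scores.tsv"),
            )
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "input_hashes": {k: _sha256(v) for k, v in inputs.items()},
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("discovery run complete in %.1fs", manifest["elapsed_s"])
    return manifest
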