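"""Score cell-type expression specificity (ES_mu) on synthetic counts.

Simulates a small negative-binomial count matrix in which each cell
type has a planted set of marker genes expressed 20-fold higher, then
runs the full specificity pipeline (normalize -> four ES metrics ->
permutation-gated ES_w -> ES_mu) and shows that the planted markers
dominate the top of their cell type's ES_mu ranking.
"""

import cellprior as cp

cfg = cp.SimConfig(seed=0, n_genes=100, n_celltypes=4, n_cells_per_type=30)
expr, truth = cp.simulate_sc_counts(cfg)
es = cp.compute_es(expr, n_perms=300, seed=0)

ct = truth["causal_celltype"]
markers = set(truth["markers"][ct])
top = es.es_mu[ct].sort_values(ascending=False).head(8)

print(f"top ES_mu genes for cell type {ct} (planted markers flagged *):")
for gene, score in top.items():
    flag = "*" if gene in markers else " "
    print(f"  {flag} {gene:>5}  ES_mu = {score:.3f}")

in_mean = es.es_mu[ct].loc[sorted(markers)].mean()
out_mean = es.es_mu[ct].drop(index=sorted(markers)).mean()
print(f"\nmean ES_mu: markers {in_mean:.3f} vs non-markers {out_mean:.3f}")
print("ES_mu near 1 marks genes specific to the type; non-markers are "
      "gated to ~0 by the permutation null.")
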