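# Methods

This note documents the statistical models implemented in `cellprior`,
the parameters that matter, the synthetic data the tests run on, and the
numerical choices made where the design was open.

## Expression specificity (ES_μ)

Raw counts (genes × cells, non-negative integers, every cell labelled
with one of T ≥ 2 cell types) are normalized per cell to a common
transcript count (`scale`, default 10,000) and transformed as
log(x + 1) (natural log). All-zero cells are left at zero with a
warning rather than producing NaNs. Mouse-to-human (or any cross-set)
gene translation keeps only genes with one-to-one ortholog pairs; the
map must be injective in both directions.

Four metrics are computed on the log-normalized matrix, all per gene g
and cell type c, with per-type means taken on the log-normalized values
(normalize → log → specificity, in that order):

* **GES** (gene enrichment score): mean(g, cells in c) / (mean(g, all
  cells) + ε).
* **EP** (expression proportion): mean(g, c) / Σ_c' mean(g, c'); rows
  with zero total mean are set to 0, and nonzero rows sum to 1 across
  cell types.
* **NSI** (normalized specificity index): for each competitor type c',
  genes are ranked descending by mean(g, c)/(mean(g, c') + ε) with
  average-rank ties; the mean rank over c' ≠ c is mapped to [0, 1] by
  1 − (SI − 1)/(G − 1), so the most specific gene scores 1.
* **DET**: Welch two-sample t of the type's cells against all other
  cells; a type (or complement) with fewer than 2 cells yields a zero
  column with a warning.

ε = 1e-9 guards ratio denominators without affecting the ranking of
expressed genes.

Each metric becomes a weight **ES_w** via an empirical one-sided
permutation null: cell-type labels are shuffled (`n_perms`, default
1,000, minimum 100; seeded), the per-gene-per-type empirical p is
(1 + #{null ≥ observed}) / (n_perms + 1), genes with p ≥ 0.05 are set
to 0, and retained genes get rank/#retained (average-rank ties), the
largest metric value mapping to 1. **ES_μ** is the elementwise mean of
the four ES_w matrices and lies in [0, 1] by construction.

A practical note on the permutation gate: genes with identical metric
values (e.g. EP = 1 for genes expressed in exactly one type) share one
average-rank weight, and a lowly-expressed gene can pass the gate by
sampling noise. Specificity at low expression is intrinsically noisy;
the gate bounds, but cannot eliminate, such false entries.

## SNP annotation

Gene coordinates are 1-based closed intervals everywhere; BED input
(0-based half-open) is converted on read. A gene's window is
[max(1, start − flank), end + flank] with `flank_bp` = 100,000 by
default, symmetric and strand-agnostic, clipped at position 1. A SNP's
annotation value is the maximum ES_μ over the genes whose windows cover
it, and 0 when uncovered, so every SNP enters the regression with a
defined value; an all-ones baseline column is always present. The
sorted-sweep implementation is checked against an exhaustive per-SNP
scan in the tests.

## Stratified LD-score regression

The reference panel is a dosage matrix (individuals × SNPs in {0,1,2})
with a (chrom, pos, cM) map, minimum 25 individuals; the on-disk format
is a plain TSV pair (PLINK readers are out of scope). LD scores for
annotation C are ℓ(j, C) = Σ_k a_C(k)·r̃²(j, k) over same-chromosome
SNPs within the LD window (1 cM when a genetic map is used, else 1 Mb
physical; self term included), where r̃² = r² − (1 − r²)/(n_ref − 2)
is the standard small-panel bias correction and monomorphic SNPs
contribute 0 with a warning.

The regression model is E[χ²_j] = 1 + N_j·a_int + N_j·Σ_C τ_C·ℓ(j, C),
fit as single-pass weighted least squares of (χ² − 1) on
[N_j, N_j·ℓ(j, C)…] with weights 1/max(ℓ_baseline, 1) — a
heteroskedasticity and over-counting proxy. Full LDSC iterates
heritability-dependent weights; the single-pass weight preserves
consistency of the point estimate (weighting never biases a correctly
specified mean model) and keeps every refit cheap enough for an exact
delete-one-block jackknife. The intercept is free (not constrained to
1), and per-SNP N supports varying-N meta-analyses.

Standard errors use a delete-one-block jackknife over contiguous,
near-equal SNP blocks: SE² = (B − 1)/B · Σ_b (τ₍₋b₎ − τ̄)². `n_blocks`
defaults to min(200, M/10). The reported p is one-tailed for a positive
τ, p = 1 − Φ(τ/SE); when the jackknife SE is exactly zero (noise-free
inputs) the p is called by the sign of τ. Bonferroni significance uses
α/T over the T cell types tested; with α = 0.05 and T = 33 the
threshold is 0.001515.

Degenerate inputs: a rank-deficient design raises an error naming the
collinear columns; an empty jackknife block raises.

## Gene-property (MAGMA-style) route

For each gene, the SNPs of the summary statistics that fall in its
window and match the panel give S = mean(χ²). Under the null, the SNP
z-vector is MVN(0, R) with R the local LD correlation, so k·S ~
Σλ_i·χ²₁ with λ_i the eigenvalues of R (ridge jitter 1e-8 repairs
marginally non-PSD matrices; genuinely non-PSD input raises). The tail
probability is computed by Imhof's characteristic-function inversion,
which is accurate through the body of the distribution; when the
positive eigenvalues are equal (rank-1 LD or independent SNPs) the
scaled-chi-square form is exact and used directly, and below p ≈ 1e-8,
where the oscillatory integral loses precision, the Satterthwaite
moment-matched scaled chi-square takes over. Two-moment matching alone
was measured at ~0.03 absolute error in the body on rough correlation
matrices, short of the ±0.01 agreement with a Monte-Carlo null this
package holds itself to — hence the inversion default. p is floored at
1e-300 before the probit z_gene = Φ⁻¹(1 − p).

The property regression is OLS of z_gene on [intercept, ES_μ, gene
size (window bp), gene density (SNPs/kb), mean per-SNP N, inverse mean
minor-allele count, and the natural logs of each], requiring ≥ 10
shared genes; zero-variance covariates are dropped (collinear with the
intercept), a zero-variance ES column raises. The p is one-tailed for
a positive ES_μ coefficient from the t distribution.

## Two-sample Mendelian randomization

Harmonization aligns outcome effects to the exposure's effect allele,
sign-flipping where the alleles are swapped, and drops palindromic
(A/T, C/G) SNPs unconditionally — conservative, since no allele
frequencies are assumed. Instrument independence (LD clumping) is the
caller's responsibility. The estimator is fixed-effect IVW over Wald
ratios r_i = β_out/β_exp with first-order SE σ_i = SE_out/|β_exp|;
a multiplicative random-effects scaling max(1, √(Q/(k−1))) of the SE
is available behind a flag. Instruments with β_exp = 0 are excluded
with a warning.

## Synthetic data: what it emulates, and what it does not

The generator produces the study's data types at desk scale with a
known truth:

* **Panel**: per block, latent Gaussians with AR(1) correlation
  ρ^|i−j| (default ρ = 0.9) are thresholded at per-SNP MAF ~
  U(0.05, 0.5) into haplotypes; genotypes are sums of two haplotypes.
  Default 20 independent blocks × 100 SNPs spaced 10 kb, n_ref = 500.
* **GWAS**: standardized per-SNP effects b_j ~ N(0, s²_j) with s²_j ∝
  1 + θ·a_j normalized to total h² (defaults h² = 0.5, θ = 4,
  N = 50,000); per block, marginal z ~ MVN(√N·R·b, R) with R the
  block's empirical correlation — so the summary statistics are
  internally consistent with the panel's LD and the regression's mean
  model holds exactly in expectation (the tests verify this loop
  closes).
* **Counts**: log-normal baseline means, disjoint planted marker sets
  (10% of genes per type, default 8 types × 40 cells) multiplied by
  `marker_fold` (default 20) in their own type, log-normal per-cell
  size factors, negative-binomial sampling with dispersion 2.
* **MR pair**: independent instruments with true exposure effects ~
  N(0.3, 0.05²), exposure SE 0.3/√F_target (default F ≈ 100), outcome
  noise at the outcome SE (default 0.02), allele orientation
  randomized to exercise harmonization.

Simulation studies in the tests and the acceptance script use
`es_n_perms = 300` permutations per metric and the 2,000-SNP default
panel — sizes chosen so a full discovery run completes in about a
second while the permutation p resolution (1/301) remains far below
the 0.05 gate.

Not emulated: realistic human MAF/LD spectra, population structure,
confounding, assortative mating, pleiotropy, ambient RNA/doublets, or
batch effects. Passing tests therefore demonstrate correctness of the
estimators under their own assumptions and calibrated inference under
the stated generative model — not robustness to the full messiness of
real GWAS and atlas data. Note also that at desk scale per-SNP
heritability is large, so genuine associations can exceed the
conventional χ² > 80 munging cap; the pipeline's QC step is
configurable (`RunConfig.apply_qc`) for exactly this reason, and the
cap should stay on for real data.

## Known limitations

* The four ES metrics are concrete, self-consistent renderings of the
  published metric family; no bit-compatibility with any external
  specificity toolkit is claimed (gating details differ).
* Only the all-ones baseline annotation ships; richer baseline stacks
  (functional categories, MAF bins) can be supplied as extra columns
  but are not generated here.
* The gene statistic implements the mean-χ² ("snp-wise mean") model
  only; top-SNP and set-based competitive tests are out of scope.
* MR offers IVW only — no Egger, weighted-median, or colocalization
  diagnostics — and assumes pre-clumped instruments.
* Heritability totals and enrichment fold-changes are not reported;
  the discovery statistic is τ (per-SNP heritability per unit ES_μ)
  with its jackknife SE and one-tailed p.
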