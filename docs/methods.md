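# Methods

## Overview

`scptwas` tests gene–trait association at the cell-type level in three
stages: (1) predict a cell type's pseudobulk expression from per-gene
epigenomic feature vectors with a small MLP; (2) distil that predictor into
per-gene cis-SNP elastic nets by fitting an in-silico expression panel;
(3) score genes against GWAS summary statistics with the summary-based
PrediXcan statistic, aggregate across cell types with ACAT, and summarize.
This note records the models, their assumptions, the defaults and why, and
what the synthetic benchmarks do and do not establish.

## Pseudobulk and expression targets

Cells pass QC when total counts are strictly below 10,000 (doublet guard)
and the mitochondrial fraction strictly below 10%; both thresholds are
strict inequalities. Counts are summed per (gene, individual) for one cell
type; a type must contribute at least 125 cells in total (the floor used for
training data), and individuals with no cells of the type are dropped.

The MLP's training target is a *cross-gene rank percentile*: per-gene counts
are averaged across individuals, ranked over genes (average ranks on ties),
and mapped by (rank−1)/(m−1) so the range is exactly [0, 1]. For
across-individual evaluation an observed per-individual value is needed; the
cross-gene transform yields only one number per gene, so we use the minimal
consistent extension — genes ranked *within* each individual's pseudobulk
profile with the same percentile convention. Ranking covers all genes in the
matrix; callers who want only expressed genes should subset first (genes
with zero total count carry no usable signal either way).

## The expression MLP

Architecture: linear D→64, ReLU, dropout 0.05, then three identical 64→64
blocks, then an unconstrained linear 64→1 head. At D = 5313 this is 352,641
parameters. The loss is MSE with L2 weight decay 5 × 10⁻⁴. Genes are split
train/validation/test by whole chromosomes, because neighbouring genes share
sequence context and random splits would leak. The default split assignment
targets roughly 73/14/12% of genes.

Training choices the problem does not pin down, fixed as package defaults:
Adam (β₁ = 0.9, β₂ = 0.999), learning rate 10⁻⁴ (synthetic benchmarks use
3 × 10⁻³ — at their scale of tens of training genes the smaller rate
underfits before early stopping triggers), minibatch 64, epoch cap 80,
early stopping on validation MSE with patience 10, best-validation
checkpoint returned. The output head is unbounded: MSE on percentiles needs
no link function, and clipping is left to reporting code. Inference disables
dropout and is deterministic. The network and optimizer are implemented
directly on numpy arrays; the model is small enough that autograd frameworks
add nothing.

## Linearization

The MLP applied to personalized features of a reference genotype panel
yields an in-silico gene × individual expression matrix containing only
genetically driven variation. Per gene, expression is regressed on cis SNP
dosages (TSS ± 1 Mb) with an elastic net, mixing parameter α = 0.5,
penalty selected at the minimum of 10-fold cross-validated MSE over a
50-point grid reaching down to 10⁻⁵ of the largest useful penalty (the
default 10⁻³ floor leaves visible shrinkage on noise-free signals).
Dosages are standardized for fitting and weights back-transformed to
per-allele scale, so stored predictors apply directly to dosages. CV folds
are assigned by hashing individual ids with the run seed: balanced,
deterministic, and invariant to input order.

A gene *converges* when the selected model has at least one nonzero weight
**and** positive out-of-fold correlation with its target. The second clause
matters: with penalty-at-CV-minimum, ~a third of pure-noise genes receive a
nonzero model by chance, which would make "a predictor exists" nearly
meaningless; requiring the predictor to track held-out data restores the
intended semantics (the canonical pipeline applies a comparable
performance filter before use).

Converged predictors and their per-gene SNP covariances (unstandardized
dosage covariance on the reference panel) are stored in the community
PredictDB dialect: SQLite `weights`/`extra` tables plus gzipped
`GENE RSID1 RSID2 VALUE` covariance text.

Linearization fidelity is measured as the per-gene Spearman correlation
between the nonlinear predictions and *out-of-fold* linear predictions.
Spearman on discrete dosage support is depressed by tie-breaking noise even
for perfect fits; the fidelity benchmark therefore plants five causal SNPs
per gene so the prediction support is fine-grained.

The same fitting code applied to observed pseudobulk expression
(within-individual rank percentiles) is the canonical baseline (PEN). It
converges for far fewer genes because observed expression adds
environmental and sampling noise and is limited to the study's sample size —
the synthetic contrast in the test suite reproduces this qualitatively.

## Association

For gene g, Z_g = Σ_l ω_{g,l} (σ̂_l/σ̂_g)(β̂_l/se(β̂_l)). σ̂_l and
σ̂_g = √(ωᵀΓ_gω) come from the stored reference-panel covariance: SNP and
predicted-expression variances are not recoverable from summary statistics,
so the reference panel is the only consistent source. GWAS rows are joined
to model SNPs by (chrom, pos, allele pair); β̂ is re-signed onto the model's
effect allele; strand-ambiguous (A/T, C/G) variants are dropped by default;
unmatched model SNPs are simply omitted (no imputation) and reported via
`n_snps_used`. P-values are 2Φ(−|z|), switching to a log-space tail beyond
|z| = 8 so values down to ~10⁻⁴⁸ survive double precision.

ACAT combines dependent p-values with equal weights via
T = mean(tan((0.5−p)π)); p < 10⁻¹⁵ uses the surrogate 1/(pπ) and very large
T returns 1/(πT). Identical inputs are a fixed point. Genes
Bonferroni-significant in exactly one cell type are classified from the
ACAT-aggregated non-focal p-value: below the aggregated test's own
Bonferroni threshold → "unique-bonferroni"; below 0.05 → "unique-enriched";
otherwise "unique-specific". The aggregated threshold is a separate
parameter because the equal-weight ACAT value is bounded below by roughly
the smallest input; with the per-type thresholds applied to the aggregate,
the first class would be unreachable.

## Evaluation statistics

π₀ is estimated as #{p > λ}/(m(1−λ)) over λ = 0.05…0.95, smoothed with a
natural cubic *smoothing* spline (GCV-selected penalty) and read at
λ = 0.95; π₁ = 1 − π̂₀ clipped to [0, 1], m1 = π₁·m. An interpolating spline
would simply reproduce the noisiest raw point at the endpoint, which is why
smoothing is essential. A fixed-λ = 0.5 estimator is available
(`method="fixed"`).

LD-block yield assigns each significant gene to the approximately
independent block containing its TSS (blocks read from 0-based half-open
BED, held 1-based inclusive internally, so a TSS at a BED end coordinate
belongs to the next block) and counts distinct blocks hit. QQ coordinates
can pad a method's p-values with seeded Uniform(0,1) draws up to a common
gene universe so methods that converge for different gene sets are
comparable. Sharing summaries and precision/recall are straightforward
counting, percentages at one decimal.

## The synthetic generator

The generator emulates the statistical structure the framework assumes, not
the biology it measures:

* **Genotypes** — per gene, a block of cis SNPs from AR(1) latent-Gaussian
  haplotypes thresholded at Φ⁻¹(MAF) and summed; adjacent-SNP dosage
  correlation then has a closed tetrachoric form used as a test oracle.
  MAFs are uniform on [0.05, 0.5]; adjacent-SNP latent correlation 0.5 by
  default. Gene blocks sit 3 Mb apart so ±1 Mb cis windows never overlap,
  spread over 22 chromosome labels so chromosome-wise splitting works.
* **Cis architecture** — per gene, a few causal SNPs (2 by default, drawn
  effects N(0, 1)) define the latent genetic expression
  g_i = Σ effect × standardized dosage (population standardization, so the
  same weights apply to any cohort from the process).
* **Features** — x_{g,i} = u_g·s(b_g + g_i) + ε with s(u) = u + c·tanh(u),
  u_g a shared direction plus per-gene jitter, b_g a per-gene baseline and
  ε i.i.d. Gaussian (reference vectors receive their own noise draw,
  representing extraction noise). The shared direction and baseline term
  are deliberate extensions of the obvious "per-gene loading times signal"
  design: with purely gene-specific loadings and no baseline, reference
  features carry no cross-gene information and no expression predictor
  could be trained across genes at all.
* **Single-cell counts** — per cell, gene proportions softplus(b_g + g_i)
  normalized, scaled by a lognormal library size (mean 2000), negative
  binomial with dispersion 2 (Poisson in the infinite-dispersion limit).
* **GWAS** — a fresh cohort from the same LD process; trait
  y = Σ γ_g g + noise scaled to heritability h² = 0.2; per-SNP exact
  marginal OLS β̂ and se. Planted gene effects have random sign and
  magnitude floored at half the nominal scale — unfloored Gaussian effects
  can be ≈0, making the "causal" label vacuous for recovery tests.

All randomness flows from one seed through named substreams (crc32 of the
stream name), so outputs are bit-identical across processes.

What passing synthetic benchmarks does **not** show: that real epigenomic
track summaries are (nearly) one-dimensional functions of cis genotype, that
real effect sizes match the planted scales, or that population structure,
trans effects and LD mismatch between GWAS and reference cohorts are
harmless — none of these are modelled.

## Benchmark problem sizes

The verification suite (`scptwas.benchmarks`, reported by
`scripts/acceptance.py`) uses desk-scale study conditions chosen to make
each property measurable in minutes on one CPU: the z-score oracle uses 200
genes × 500 individuals with the same cohort as GWAS sample and covariance
reference (so the two routes estimate the same quantity); type-I
calibration uses 1000 genes, a 462-individual reference panel and a
2000-individual null cohort; fidelity uses 20 genes × 200 individuals with
noise-free features; the end-to-end ranking uses the reference conditions
(20 genes, 5 causal, 30 SNPs/gene, 462-individual panel, 64-dim features,
2000-individual GWAS cohort). Feature width is configurable; benchmarks run
at D = 16–64 while the architecture default remains D = 5313.

## Known limitations

* Direction of effect is not interpreted: sequence-trained feature
  extractors are known to produce sign inconsistencies, so downstream
  analyses should use p-values/|z|, not signs.
* Only cis regulation (TSS ± 1 Mb) is modelled; trans effects are out of
  scope.
* Missing GWAS variants are dropped rather than imputed from LD.
* The file-backed feature extractor consumes precomputed track matrices;
  running a sequence-to-epigenome model is outside the package.
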