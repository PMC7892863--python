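# Methods

## Model

All association tests are Wald tests of fixed effects in a single-random-
effect linear mixed model fitted per gene (and, for eQTL scans, per
gene–variant pair):

    y = X β + u + ε,   u ~ N(0, σg² K),   ε ~ N(0, σe² I)

where `y` is one gene's log2 expression across samples, `X` collects an
intercept, the selected expression principal components, and the terms of
the scan at hand (binary group indicator; SNP dosage; SNP + environment +
SNP×environment; SNP + cell-type score + SNP×score), and `K` is the
identity-by-state similarity between samples,

    K_ij = 1 − Σ_m |g_im − g_jm| / (2 M_ij)

over the `M_ij` variants non-missing in both samples.  Two biopsies from
the same individual have identical genotypes, so `K_ij = 1` exactly: the
random effect `u` simultaneously absorbs repeated measures and genetic
relatedness.  `K` is computed on all QC-passing variants; if its smallest
eigenvalue falls below −1e−8 a diagonal ridge restores positive
semidefiniteness (with rescaling back to unit diagonal) and is logged.

### Fitting

`K = U D U'` is eigendecomposed once per sample set and every response and
design column is rotated by `U'`; the covariance of the rotated data is
diagonal, `σe² (λ D + I)` with `λ = σg²/σe²`, so each candidate `λ` costs
one weighted least squares.  The restricted likelihood is profiled over
`λ` on a 22-point grid (`λ = 0` plus 21 log-spaced points in
[1e−5, 1e5], evaluated in one batched linear-algebra pass) and the best
interior grid point is refined by bounded Brent search on log10 λ to
1e−6.  `σe²` is floored at `1e−10 · var(y)`.  Wald `t = β̂/se(β̂)` is
referred to a t distribution on `n − rank(X)` degrees of freedom; `λ` is
estimated under the alternative model, once per fit.  With `K = I` the fit
reproduces ordinary least squares exactly (the profile is flat in `λ`),
which the test suite checks against a closed-form GLS/OLS oracle to 1e−6.

### Multiple testing and classification

Benjamini–Hochberg step-up adjustment ("q") is applied pooled across all
tests of a scan.  The inflammation-interaction scan is two-stage: stage 1
pools BH over the interaction p-values of all cis pairs; stage 2 keeps the
most significant pair per significant eGene and recomputes BH separately
for the genotype, environment and interaction coefficients across those
top pairs (a flag widens this universe to all stage-1-significant pairs).
Classification at α = 0.05: *interaction_only* iff q_interaction < α and
q_genotype > α; *genotype_and_interaction* iff q_interaction < α and
q_genotype ≤ α; otherwise *not_significant*.

The permutation check reruns stage 1 with inflammation labels permuted
across samples (default; a mode permuting whole individuals is available)
and counts pairs whose interaction p falls below the largest p that was
significant in the real scan; the threshold is *adequate* when the mean
permuted count is below α times the real significant-pair count.  Permuted
scans reuse the covariate set (including the excluded PC) of the real scan.

## Covariates

PCA is run on gene-centered normalized expression across samples.  Samples
beyond 4 SD (configurable) on PC1 or PC2 are flagged as outliers and PCA is
recomputed without them — a formalization of visual outlier removal.  The
number of PCs used as covariates is the scree curve's inflection: the index
`i ≤ max_pcs` (default 18) maximizing the *relative* second difference
`(v_i − 2 v_{i+1} + v_{i+2}) / v_i` of the explained-variance curve, ties
to the smallest index; a flat curve falls back to a configured default with
a warning.  The relative form is scale-invariant, picks index 1 for
geometric decay, and selects exactly `k` when `k` strong components sit
above a noise floor.

PCs enter the models as fixed covariates (not pre-regressed out).  For a
scan whose variable of interest is itself a major expression axis (e.g.
inflammation), the selected PC most rank-correlated with that variable is
excluded from the covariates so the signal is not regressed away.  In the
motivating cohort design these are the first PC (biopsy location) for
location/diagnosis contrasts and the second PC (inflammation) for
inflammation contrasts; detecting the aligned PC rather than hard-coding
its index keeps the rule correct when components reorder.

## Normalization

Raw counts are scaled by trimmed-mean-of-M-values factors: reference =
sample whose upper-quartile count fraction is closest to the mean; per
sample, log ratios `M` against the reference are trimmed 30 % two-sided
and intensities `A` 5 %, with inverse-asymptotic-variance weights; genes
with a zero count in either member of a pair are excluded from that pair's
factor estimation; factors are rescaled to geometric mean 1.  Output is
`log2(count / (library size × factor) × 1e6 + 0.5)`; the pseudocount is
configurable.  log2 is applied to TMM-scaled counts-per-million; all-zero
genes take `log2(pseudocount)` everywhere.

## Genotype QC conventions

Call rate = fraction non-missing; MAF from non-missing dosages;
Hardy–Weinberg is a 1-df chi-square goodness-of-fit test at the sample
allele frequency (monomorphic variants return p = 1).  Defaults: call rate
≥ 0.99, MAF ≥ 0.05, HWE p ≥ 1e−6.  Kinship uses pairwise-complete
variants; for design matrices missing dosages are mean-imputed per
variant.  Cis pairs: gene center = `floor((start + end)/2)` of the 0-based
half-open annotation converted to 1-based, window ±500 kb inclusive.

## Downstream statistics

**Colocalization.**  Per-variant Wakefield log approximate Bayes factor
`0.5 log(1−r) + 0.5 r z²` with `r = w/(w + se²)`, prior effect sd
`sqrt(w) = 0.15` per trait (configurable).  When a trait provides only
(p, MAF, N), `z` is recovered from the two-sided p and
`se ≈ 1/sqrt(2 maf (1−maf)(N + z²))`.  The five hypothesis sums use the
standard enumeration (H3 over ordered distinct variant pairs) in log space;
`colocalized` iff PP4 > 0.5.

**Replication.**  Pairs matched on (variant, gene); when allele columns
are present, swapped alleles flip the external sign and mismatched allele
pairs are dropped and counted.  Percent = 100 × concordant/overlap,
reported to two decimals from the exact ratio (the package reports 82.98
for 39/47 rather than rounding to a printed 83.00).

**Heterogeneity.**  Fixed-effect Cochran Q with inverse-variance weights,
chi-square on k−1 df.

**Co-expression.**  All genes OLS-residualized on the selected PCs; target
residuals Spearman-correlated with every other gene; BH across genes; kept
iff |r| > 0.5 and q < 0.05.

**Cohort table.**  Categorical: Pearson chi-square, Yates continuity
correction iff 2×2 (this reproduces the printed location/diagnosis/sex
p-values from their contingency tables); continuous: two-sided Wilcoxon
rank-sum with normal approximation, tie and continuity correction.

## The synthetic-data generator

`simulate_dataset` emulates the repeated-biopsy cohort the analysis is
designed for: 165 individuals each contributing 1–2 biopsies (expected
1.7, ≈280 samples), inflammation drawn per sample at rate 0.4 so many
individuals carry both states; individual-level dosages
`Binomial(2, MAF)` with MAF ~ U(0.05, 0.5); genes spaced 1 Mb apart with
variants placed within ±400 kb of their host gene's center.

Expression (log2 scale) = gene baseline
+ location-aligned component + inflammation-aligned component
+ further dense random components
+ planted effects + per-individual random intercept + Gaussian noise.
The two structured components use *sparse* gene loadings (a strong
response in 15 % of genes, variance-matched), mirroring tissue data where
location and inflammation strongly affect a minority of genes; genes
carrying planted inflammation-context effects are kept free of the
inflammation component so the truth table's effect sizes are exact.
Cell-type scores are Beta(2, 5) in [0, 1] with mean shifts in inflamed
samples for effector populations (M1 macrophages, plasma cells,
neutrophils, Th2, Tregs up; M2 macrophages, basophils down); out-of-range
values are clipped and logged.

Defaults: `noise_sd = 0.8` and `individual_random_sd = 0.8`, i.e. a true
variance ratio σg²/σe² of exactly 1 and total residual sd ≈ 1.13 log2
units.  These were chosen by a power calculation so that the package's
stated recovery targets (e.g. a genotype×inflammation effect of 1.0 log2
units per allele at MAF 0.3 and n ≈ 280 detected at interaction FDR < 0.05
in ≥ 80 % of replicates) are attainable by design rather than borderline;
no cohort-level estimate of this decomposition exists to copy.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: linkage disequilibrium between variants
(variants are independent), count-level mean–variance structure (expression
is generated directly on the log scale; the TMM path is exercised on
separately generated counts), population stratification beyond the
individual random intercept, cell-type scores derived from the expression
itself, and any dependence of missingness or QC failure on phenotype.

## Numerical and bookkeeping conventions

Gene annotation is BED-like 0-based half-open; variant positions 1-based.
Monomorphic variants are skipped per scan (counted in the report); designs
that become collinear (e.g. a variant polymorphic in only one inflammation
stratum making SNP×status collinear with SNP) are skipped with a reason.
Top-eSNP ties break by smaller distance to the gene center, then
lexicographic variant id, making outputs order-independent.  All output
TSVs carry `#key=value` metadata headers (seed, thresholds) and encode
missing values as `NA`; pipeline reruns at a fixed seed are byte-identical.

Problem sizes used in the test suite and acceptance script — e.g. 5000
null fits for type-I error, 102 replicates for interaction recovery, 200
for variance-ratio recovery, a 300-sample × 2000-gene × 5000-variant
fixture for the end-to-end run — were chosen as the smallest sizes at
which the corresponding Monte-Carlo error is well inside the asserted
bands.

## Known limitations

One variance ratio is estimated per fit; there is no per-gene null-model
reuse, no multiple random effects, and no trans-eQTL or conditional
secondary-signal mapping.  The Wald t with `n − rank(X)` df is a
convention, not exact under estimated variance components (its type-I
error is verified empirically to sit in [0.04, 0.06] at nominal 0.05).
Colocalization assumes at most one causal variant per trait per region.
The xCell-style enrichment scores are inputs; the package does not compute
them.  VCF reading requires cyvcf2 and converts GT to dosage only
(biallelic records; no imputation dosage field).
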