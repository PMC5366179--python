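# Methods

`celest` implements a biomarker-discovery pipeline for multi-class,
multi-batch expression cohorts such as large multicentre leukaemia studies:
preprocessing, batch-effect adjustment with verification, adaptive
mixture-based gene filtering, assumption-routed multi-group differential
testing, class-enhanced DEG (CE-DEG) / biomarker selection, set-similarity
statistics, and a repeated cross-validation classification study. This note
records the models, the defaults and why they were chosen, and what the
synthetic studies do and do not demonstrate.

## Data model and cohort structure

The pipeline operates on a genes × samples matrix of log2 intensities with a
per-sample annotation (subtype, merged main class, preparation-centre batch).
The built-in class table mirrors the Stage-I multicentre leukaemia cohort:
18 subtypes totalling 2096 bone-marrow samples prepared in 11 centres. The
deterministic subtype → main-class merge collapses 8 ALL subtypes (750
samples) and 6 AML subtypes (542 samples); CLL (448), CML (76), MDS (206)
and the non-leukaemia control group CTR (74) map to themselves.

## Preprocessing

Background correction uses the normal + exponential convolution model
(observed X = S + B, signal S ~ Exp(θ), optical/background noise
B ~ N(μ, σ²)) fitted per array by the method of moments (θ from the third
central moment, σ² and μ from the lower ones) and inverted to the posterior
expectation E[S | X], which is strictly positive and order-preserving within
an array. Frozen reference parameter vectors are deliberately not used:
all parameters are estimated from the cohort at hand, so the pipeline can
also ingest already-summarised matrices and skip this stage entirely.

Quantile normalisation forces every column onto the across-column mean of
order statistics; ties receive the mean of the tied reference values, which
makes the operation idempotent.

Summarisation is Tukey median polish per probeset (tolerance 1e-6, at most
20 sweeps, lower-median tie rule for determinism); the per-sample summary is
the overall effect plus the column effect. The decomposition
overall + row + column + residual reconstructs the input exactly by
construction.

## Batch-effect adjustment and verification

Batch structure is first visualised by PCA on mean-centred samples. The
adjustment is the parametric empirical-Bayes location/scale model (ComBat):
gene-wise least squares on batch indicators plus class-covariate dummies;
standardisation by the fitted non-batch effects and pooled SD; per-batch
per-gene location (γ) and scale (δ²) estimates shrunk toward batch-level
priors (normal on γ, inverse-gamma on δ²; hyperparameters by method of
moments) through the coupled posterior equations iterated to 1e-4 (capped at
100 iterations). Class is included as a covariate so class-mean differences
are preserved in expectation. The implementation was validated against the
reference R implementation (sva::ComBat) to ~1e-5 on shared fixtures; the
in-repo cross-check uses scanpy's ComBat on the batch-only model, because
scanpy's design matrix is only full rank without categorical covariates.

Removal is verified two ways: a vectorised tie-corrected Kruskal–Wallis test
of every gene against batch (genes with constant values get p = 1 by
convention), and a per-gene two-way ANOVA (batch × subtype with interaction)
using Type-II sums of squares, appropriate for the heavily unbalanced
design. After adjustment the batch-significant fraction drops essentially
to zero — below the nominal α — because the EB recentring removes the batch
group differences themselves, not merely their excess over chance; this
matches the near-total removal seen in large cohorts and is the expected
behaviour of the estimator, so the verification asserts "at most α-level",
not a two-sided band around α.

## Adaptive mixture filtering

Instead of discarding a fixed fraction of low-signal genes, whole mixture
components are kept or rejected. The per-gene statistic for the amplitude
step is the mean log2 expression ("signal amplitude"); a 1-D Gaussian
mixture is fitted by EM (best of 10 seeded k-means++-style restarts,
log-likelihood tolerance 1e-8, at most 500 iterations, variance floor
1e-6 × sample variance), the component count k ∈ {1..6} is chosen by BIC
(ties to smaller k), and genes MAP-assigned to the min(3, k−1) highest-mean
components are retained. The variance step fits the same machinery to log
per-gene variance and rejects the lowest-mean (lowest-variance) component;
zero-variance genes are rejected outright, and a k = 1 fit removes nothing.
BIC and hard MAP assignment were chosen as the simplest reproducible rules;
the per-gene summary statistic (rather than pooled probe intensities) is the
assumed substrate. Note that the filter is data-adaptive: on a cohort whose
log-variance distribution is merely skewed rather than bimodal, BIC may
still split off a low-variance component and remove it, which is the
intended "adaptive threshold" behaviour rather than an error.

## Multi-group testing and routing

Assumptions are checked per gene with Shapiro–Wilk normality in every group
(groups under 3 observations count as non-normal) and Brown–Forsythe
(median-centred Levene) homogeneity. Routing is per analysis: the checks
run on a seeded subsample of at most 200 genes, and the parametric branch
is used iff at least half of them pass both checks. The one-half rule makes
the decision deterministic and robust: clean Gaussian data pass both checks
at ≈ (1−α)^(k+1) ≈ 70–80% per gene, while even mildly heavy-tailed noise
drives the pass rate near zero, so the two regimes are far from the
boundary.

* Parametric branch: a classic one-way ANOVA gate (keep p < α) followed by
  Dunnett many-to-one comparisons against the control group. Dunnett
  adjusted p-values come from the equicorrelated multivariate-t null
  (correlations λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀)), pooled df) sampled by seeded
  Monte Carlo (10⁵ draws); since group sizes are shared across genes, one
  null sample serves the whole matrix.
* Non-parametric branch: a tie-corrected Kruskal–Wallis gate followed by
  Games–Howell pairwise post-hoc tests — Welch t statistics with
  Satterthwaite df, referred to the studentized-range distribution for the
  full group count (p = P(Q_{k,df} ≥ t√2)).

For genome-scale batches the studentized-range tail is evaluated through a
bicubic spline over a (q, 1/df) grid of exact values (≈1600 exact
evaluations per call, interpolation error ~1e-6 on the p scale, validated
against the exact evaluation in the tests); small batches call the exact
routine directly. No across-gene multiplicity correction is applied beyond
the per-gene family-wise post-hoc control; the default per-gene α is 0.05.

## CE-DEGs, biomarkers, similarity and enrichment

A CE-DEG for class c is a gene significant for *every* pair (c, c′); a gene
may be a CE-DEG for several classes. A biomarker for c is a CE-DEG for c
showing no significant difference between any pair of the remaining
classes; biomarker sets are therefore disjoint. The all-pairwise reading of
"differentiates from all other groups" is used (a pooled one-vs-rest gate
is not claimed equivalent and is not the default). Case-control DEG sets
use the Dunnett-adjusted p against the control, with direction from the
sign of the mean difference.

Set similarity is the Dice coefficient 2|A∩B|/(|A|+|B|) (0 for two empty
sets) with a gene-level bootstrap percentile CI (resample the universe with
replacement, recompute on induced memberships, 2000 replicates, seeded) —
a distribution-free stand-in for analytic CI formulas. Overrepresentation
of a query set in user-supplied term sets uses the two-sided Fisher exact
test on the 2×2 table over the universe of filter-surviving genes, with the
conditional maximum-likelihood odds ratio.

## Classification study

The baseline feature set is the union of each class pair's top-100 genes by
two-sample t-test; candidates then pass a greedy decorrelation scan that
keeps a gene only if |Pearson r| < 0.5 (the conventional large-effect
threshold) against every gene already kept, preserving priority order. The
number of features is chosen by minimum CV error over a log-spaced prefix
grid (ties to the smallest count). The classifier is a linear-kernel SVM
(C = 1, one-vs-one), the convention for p ≫ n expression data. The study
runs stratified k-fold CV (default k = 30) repeated 3 times with feature
selection re-run inside each training fold; classes smaller than k appear
in a subset of test folds. Integer confusion counts are accumulated per
repetition and divided by the repetition count, giving fractional cells;
per-class sensitivity is the diagonal over the class total, the weighted
average sensitivity weights by class totals, and its 95% CI is the normal
approximation on reps × total Bernoulli trials (a deliberate, simple
approximation; the repetition-level dependence makes it indicative rather
than exact).

## Synthetic data

The generator emulates the cohort's structure:
x_gs = μ_g + β_{g,k(s)} + γ_{g,b(s)} + δ_{g,b(s)}·ε_{g,s}, with

* μ_g from a four-component Gaussian mixture (weights .35/.30/.20/.15,
  means 4/6.5/8.5/10.5, SDs .35/.6/.6/.7 on the log2 scale) — one
  low-intensity background component plus three signal components, matching
  the qualitative shape of log2 microarray intensity distributions;
* default class profile: the 18-subtype cohort scaled down tenfold with a
  floor of 10 samples per class (preserving the imbalance at desk scale),
  11 batches assigned round-robin after a seeded shuffle so batch and class
  are never confounded;
* batch effects: additive shifts γ ~ N(0, batch_sd_add²) and multiplicative
  factors δ ~ Gamma(shape, shape) with mean 1 (shape 50 by default), the
  generative form the EB adjustment assumes — deliberately, so parameter
  recovery is a fair test of the implementation, not of model robustness;
* planted truth: single-class biomarker genes (±effect_size in exactly one
  class) and two-class CE-DEGs (opposite shifts in two classes — each
  shifted class separates from everything, but the gene is unique to
  neither, so it must never be selected as a biomarker);
* residual noise: N(0, noise_sd²) with noise_sd = 0.5 (typical log2
  residual spread), reduced by a factor 0.3 for background genes so the
  variance filter has a genuine low-variance component; designated classes
  can instead receive t(3) noise scaled to the same SD to trigger the
  non-parametric route;
* probe-level expansion adds per-probe affinities (drawn once, centred on
  their lower median so median-polish summaries are unbiased and the
  affinities still sum to ≈0) plus optional measurement noise.

What passing the synthetic studies shows: each stage recovers exactly the
structure it models — EB batch recovery under the matched generative model,
component recovery when the baseline really is a Gaussian mixture, biomarker
recovery when effects are clean mean shifts. What it does not show:
robustness to probe-level artefacts, mixed effect shapes, correlated genes,
label noise, or batch models unlike the additive/multiplicative one. The
headline gene counts of the real cohort (e.g. the number of filter-surviving
genes) are data-dependent and are not acceptance quantities.

## Problem sizes and numerical choices

The bundled studies run at desk scale, chosen to estimate each quantity with
useful precision: batch study 2000 genes × 3 classes × 60 samples × 4
batches (60/class keeps the batch-noise contamination of the before/after
class-effect comparison well under the 10% bound being checked); filter
study 4000 genes; biomarker recovery 5 seeds × 200 genes × 4 classes × 30
samples at effect = 2 residual SDs; post-hoc error control 4000–10000 null
families with unequal variances and sizes; classification study 6 balanced
classes of 25 with in-fold selection. Degenerate inputs follow fixed
conventions: constant genes get p = 1, zero-variance genes go straight to
the filter's removal set, a single-batch matrix is returned unadjusted, and
a k = 1 mixture filter is a no-op.

## Known limitations

* The non-parametric branch controls the per-gene family-wise error only;
  genome-wide error control (FDR across genes) is intentionally out of
  scope, mirroring the analysis design this package implements.
* Dunnett p-values are Monte-Carlo estimates (SE ≈ 1.5e-3 at 10⁵ draws);
  seeded, hence reproducible, but not exact quadrature.
* The bootstrap Dice CI treats gene membership as exchangeable and ignores
  inter-gene correlation.
* ComBat assumes every batch contains several samples of mixed classes;
  batch/class confounding is rejected rather than resolved.
* The CV confidence interval ignores dependence between repetitions.
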