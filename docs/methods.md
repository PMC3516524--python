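# Methods

This note records the models implemented in `ancestryx`, the defaults
and numerical choices behind them, what the bundled simulator does and
does not emulate, and the design decisions taken where more than one
reasonable implementation existed.

## Exposure spaces and clustering

**Marker panel.** PCA markers are selected by removing long-range-LD
regions (a bundled 24-region hg19 BED, always overridable) and then
running a sliding-window pairwise-r² pruner with the widely used
defaults r² ≤ 0.2, window 50 markers, slide 5. r² is the squared Pearson
correlation of 0/1/2 dosages over pairwise-complete samples. Greedy
removal inside a window needs a deterministic tie-break: of a violating
pair we drop the lower-MAF member, and on ties the later-positioned one.

**PCA normalisation.** Each marker column is centred by its mean dosage
and scaled by √(p̂(1−p̂)) with the shrunk frequency estimate
p̂ = (1+Σg)/(2+2n_called); missing genotypes are mean-imputed (zero
after centring) before decomposition; monomorphic markers are dropped
with a warning. This is the standard normalisation for genotype PCA:
it weights markers by the inverse of their binomial sampling noise.
Scores are the normalised matrix times the loadings; a fitted basis
stores its marker panel, centring, scaling, and loadings so new samples
are projected without refitting (used to check that components reflect
ancestry rather than a within-study artefact). Components carry a
deterministic sign convention (largest-|loading| entry positive). For
large matrices the decomposition uses seeded randomized SVD; small
matrices use exact SVD.

**Number of components.** Two, by default: in the motivating setting
only the two leading components separated the populations. Configurable.

**Cluster count selection.** k-means (k-means++ initialisation, 25
seeded restarts, best within-cluster SSE kept) is run for each k in
[k_min, k_max] (defaults 2–6; heterogeneity testing needs at least two
clusters) and each hard clustering is scored with the BIC of a Gaussian
mixture under its classification likelihood: multinomial weights
n_c/N, one shared **diagonal** covariance (per-dimension pooled
within-cluster variances), and k·d + d parameters. Two modelling points
matter here:

* the multinomial weight term is essential — without it the distortion
  gain from extra centres always beats the ln N penalty and BIC
  over-splits structureless data;
* a diagonal rather than spherical shared variance is required for PC
  scores, whose dimensions are decorrelated by construction but have
  very different scales (the leading component mixes between-population
  separation with small within-population noise, later components are
  pure noise at a larger within-cluster scale). A single spherical
  variance rewards splitting clusters along their widest axis; with the
  per-dimension model an extra split only improves the likelihood in
  the one dimension it subdivides.

**Switch rate.** The disagreement between two equal-K clusterings is
the fraction of samples whose labels differ, minimised over one-to-one
label matchings (computed exactly via the Hungarian algorithm on the
cross-tabulation). It doubles as the mislabelling probability in the
replication power analysis.

## The heterogeneity test

Per marker, the heterogeneous model (cluster-specific intercepts α_c
and genetic effects β_c, shared covariate effects γ) is compared with
the null model (same intercepts, one shared β) by
T = BIC_null − BIC_het with BIC = −2logL + p·ln n. The null nests both
"no association" (β = 0) and "homogeneous association", so T targets
*heterogeneity* specifically rather than marginal association.
Covariates enter with a single shared effect vector, matching the
single-γ form of the model; they are supplied by the caller and never
auto-selected. D = T_A − T_B compares two clusterings of the same
samples on the same marker.

Numerical choices:

* GLM fitting is in-package IRLS (logit) / least squares (identity):
  convergence at relative log-likelihood change < 1e-8, at most 100
  iterations; the calibration stage runs on the order of 10⁵ small
  fits, so the inner loop is plain dense linear algebra with no
  per-fit object overhead. Cross-checked against statsmodels in the
  test suite.
* Complete separation (e.g. a marker monomorphic within a small
  cluster) caps |coefficients| at 15 on the log-odds scale and flags
  the fit non-converged instead of raising, so genome scans complete.
* Rank-deficient designs raise an error naming the collinear columns
  (via pivoted QR); the scan records such markers as skipped.
* Samples with a missing dosage at the tested marker are dropped from
  *both* models for that marker only, keeping the two BICs on an
  identical sample subset; no imputation. A marker is skipped when any
  cluster retains fewer than two observed samples.
* Identity-link BICs count the residual variance as one parameter in
  both models; the term cancels in T but keeps each BIC well-defined.
* Quantitative traits use the identity link; odds ratios are exposed
  only for the logit link.

## Null calibration

D has no theoretical null distribution. Thresholds are estimated by
retrospective simulation: phenotype, covariates and both clusterings
stay fixed at their observed values (appropriate for case-control
ascertainment) while marker genotypes are drawn i.i.d. in
Hardy–Weinberg proportions, independent of everything. Defaults follow
the calibrated procedure: MAF grid 0.05–0.50 in steps of 0.05, 10,000
simulations per MAF, pooling all 10×10,000 D values and taking the
empirical 99th centile, with exceedance defined strictly greater.
Because the null D distribution is invariant to MAF (checked by
pairwise Kolmogorov–Smirnov tests across strata in the acceptance
suite), pooling across the grid is legitimate. The lower 1% centile is
also reported for screens enriched in collection heterogeneity, and a
single-clustering mode thresholds T instead. Sub-streams are keyed by
(seed, MAF value, replicate index), so thresholds are invariant to grid
order and each stratum is independently reproducible. Calibration is
per dataset: thresholds depend on n, the clusterings, and the
covariates, so they are re-estimated for every phase rather than
shared.

## Scan, filtering, and replication

The scan computes T_anc, T_coll, D per marker (deterministic and
embarrassingly parallel), filters on D > d_threshold, ranks candidates
by T_anc descending, and reports the chance expectation
⌊M·(1−centile/100)⌋ alongside. With two discovery phases, candidates
must pass the D filter in both and agree in effect direction; direction
is checked in the discovery-driving cluster (largest |β̂|), mapped
across phases by an optional cluster correspondence (independent
clusterings carry arbitrary labels).

Replication in cohorts without genome-wide genotypes fits phenotype ~
dosage + covariates within each proxy-label group and reports a Wald CI
plus a one-sided p in the direction pre-registered at discovery
(two-sided at discovery itself); no multiple-testing adjustment is
applied in single-marker targeted replication. Pooled meta-analysis
concatenates datasets with free per-source intercepts — the same
philosophy as the cluster-intercept null model — and a shared β;
inverse-variance combination is provided as a cross-check only.
`pvalue_from_or_ci` back-computes normal-approximation p-values from a
reported OR and 95% CI (SE = (ln hi − ln lo)/(2·1.96)); its agreement
is limited by the rounding of published intervals, roughly ±5·10⁻⁴.

## Switch-rate power

Power for proxy-label replication is estimated by Monte Carlo. At
switch rate s, a "group-1-labelled" individual is truly group 1 with
probability 1−s; genotypes are drawn per case/control stratum from the
Bayes inversion of the logistic model at the group's OR, the MAF, and a
baseline (genotype-0) prevalence defaulting to 0.05 — a value in the
range typical of common cancers, supplied explicitly because the power
depends on it only weakly through the retrospective genotype
distributions. Power is the fraction of simulations with a one-sided
Wald p below α in the labelled group; the Monte-Carlo standard error
√(p(1−p)/sims) is reported per grid point. A closed-form Wald power
(expected Fisher information of the sampled genotype mixture) anchors
the s = 0 end; the simulation and the closed form are independent
routes and are compared in the tests. Power curves are monotone
non-increasing in s up to Monte-Carlo error — label noise attenuates
the observable effect roughly as exp((1−s)·ln OR).

## The simulator

`synthgen` emulates the two-cohort design end to end: ancestral
frequencies uniform on (0.05, 0.5); population frequencies
Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) under the Balding–Nichols model with
default F = 0.005 (weak, within-country differentiation — enough for
two principal components to separate the populations at genome scale
while cohorts overlap heavily at small marker counts); HWE genotypes
within population; disease from a logistic model with per-population
baseline prevalence (default 5%) and per-population odds ratios at
designated causal markers; case/control quotas filled by rejection
sampling (matching the retrospective framing; an infeasible quota
raises with advice rather than looping forever); collection labels
equal to true population flipped independently at a default 20% switch
rate. Causal markers may pin their MAF exactly for clean
parameter-recovery experiments, and an artefact mode attaches the
causal effect to the *collection* label instead of the true population,
producing the mirrored negative-D signature. Only causal genotypes are
drawn inside the rejection loop; non-causal markers are conditionally
independent of status given population and are filled in afterwards,
which is exact because markers are simulated without LD.

What the simulator does **not** emulate — and hence what passing tests
do not establish about real data: linkage disequilibrium between
markers (each marker is independent given population), admixture beyond
a two-population mixture, genotyping error and missingness patterns,
batch effects, cryptic relatedness, and ascertainment that differs
between collections. The D statistic's robustness to those features
must be judged on real data; here the simulator's role is to verify the
statistical machinery against known truth.

## Problem sizes in the shipped checks

The acceptance suite runs the calibrated-threshold check at n = 1,000
samples with 2,000 simulations per MAF (20,000 pooled null draws)
validated against 20,000 freshly seeded null markers; the
cluster-count check at n = 2,000 samples × 20,000 markers with ten
clustering reseeds; the χ²₁ null check at 10,000 simulations; effect
recovery at n = 10,000 over 50 replicates; and the power curve at 400
simulations per switch rate. These sizes give Monte-Carlo error
comfortably inside each check's tolerance while keeping the default
test run quick on a single core.

## Known limitations

* Hard cluster assignments ignore membership uncertainty near cluster
  boundaries; a probabilistic-clustering extension would propagate it.
* The BIC model for cluster-count selection assumes axis-aligned
  within-cluster covariance shared across clusters; strongly tilted or
  unequal-shape clusters may mis-select K.
* The per-marker test assumes within-cluster homogeneity; residual
  structure inside a cluster is absorbed into, not separated from, the
  cluster effect.
* Wald intervals and the separation cap are crude for very rare
  genotypes in small clusters; such markers surface as flagged or
  skipped rather than being rescued.
* Variable selection for the exposure space (how many components, or
  model-based alternatives to k-means) is out of scope; the component
  count is a user choice.
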