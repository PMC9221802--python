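# Methods

This note records the statistical models, conventions and numerical choices
behind `rtae`, what the synthetic data does and does not emulate, and the
known limitations.

## Setting

The package models a single-institution HCC cohort design: 51 cirrhotic
patients with unifocal, treatment-naïve HCC imaged with hepatocyte-specific
contrast MRI before transarterial embolization. Response at one month is
graded with mRECIST on viable (enhancing) tumor; two binary endpoints are
derived — complete response (CR, prevalence 14/51) and objective response
(CR+PR, 29/51). Predictors are per-phase tables of 854 radiomics features
(first-order, GLCM, GLDM, GLRLM, GLZLM, NGTDM, shape, wavelet families),
12 clinical variables, and 19 LI-RADS qualitative imaging columns (lesion
size plus 18 binary features). Since no patient data are distributed, the
package ships a generator that reproduces this structure exactly and plants
effects of known size for calibration.

## mRECIST classification

`cohort_stats.mrecist_classify` grades one target lesion from pre/post
arterial enhancement (%) and diameter (mm):

- CR: post-treatment enhancement exactly 0;
- PD: size increase ≥ 20% of baseline;
- PR: enhancement decrease ≥ 30% of baseline;
- SD: none of the above.

Precedence is CR > PD > PR > SD. The category definitions leave the
conflict case (enhancement down ≥ 30% *and* size up ≥ 20%) unspecified;
we resolve it deterministically in favor of progression, since SD is
defined residually and progression is the clinically conservative call.
Boundaries are inclusive. Baselines must be positive.

## Group-comparison statistics

`compare_groups` mirrors a baseline-characteristics table: continuous
variables as median (IQR) with a two-sided Mann–Whitney U test (exact
enumeration when n ≤ 12 without ties, otherwise the tie-corrected normal
approximation); binary variables as counts (%) with Fisher's exact test
when any expected cell is < 5 and Pearson's χ² (no continuity correction)
otherwise. The two-sided Fisher p-value follows the point-probability
summation convention — the sum of hypergeometric probabilities of all
tables with fixed margins whose point probability does not exceed the
observed one (relative tolerance 1 + 1e-7); this is scipy's convention and
reproduces 40 of the 42 published categorical p-values in the reference
tables to three decimals (one row was evidently tested with Fisher despite
all expected cells ≥ 5; one differs by a terminal rounding digit).
Constant variables are reported untestable. No multiplicity correction is
applied, matching the source analysis. A packaged fixture
(`rtae/data/tables_1_2_counts.csv`) carries the published counts.

## Synthetic cohorts

`synthetic_cohort.generate_feature_table` draws radiomics features from an
equicorrelated-block Gaussian model: blocks of `correlation_block_size`
(default 10) columns share pairwise correlation ρ (default 0.6), and blocks
are independent. This stands in for the strong within-family redundancy of
wavelet features — the property the elastic-net and decorrelation steps
exist to handle. Labels are placed by exact count (`round(prevalence · n)`
positives) rather than Bernoulli draws so the published prevalences 14/51
and 29/51 are reproduced exactly; the full CR/PR/SD/PD mix is allocated by
largest remainder against the published 14/15/19/3 counts. A planted
feature j with effect δ receives a class-conditional mean shift of δ pooled
standard deviations, giving the closed-form single-feature AUC Φ(δ/√2)
used to calibrate recovery (checked at n = 5000 within 0.02).

Clinical labs are log-normal, parameterized by published medians and IQRs
(σ = (ln q₃ − ln q₁)/(2·0.6745)): strictly positive and right-skewed like
platelet count and AFP. Binary clinical and LI-RADS columns are Bernoulli
at the published cohort prevalences; "iron sparing" is never present, so
the untestable-variable path is exercised. Feature names are family-tagged
(`original_glcm_*`, `wavelet-LLH_*`, …). The stated family sizes sum to
853, not the stated total of 854; the generator honors the total and lets
the wavelet family absorb the remainder — names are a labelling convention
only, since synthetic features are statistical stand-ins, not computed from
images.

What the generator does **not** emulate: scanner- or vendor-specific
intensity distributions, inter-feature correlation *across* families,
non-Gaussian radiomics marginals, and any real association between the
clinical/LI-RADS columns and outcome (they are generated independently of
the labels unless planted). Passing tests therefore demonstrate the
correctness and no-leakage behavior of the pipelines, not the clinical
attainability of any particular AUC.

`generate_lesion_volume` produces spherical lesions (physical-radius mask
on an anisotropic grid) filled with mean + smoothed Gaussian noise rescaled
to a target SD, for end-to-end extraction tests; digitized ball volumes
match (4/3)πr³ within 5% at the default resolutions.

## Feature extraction

A bounded, documented subset of the standard (IBSI-style) families;
GLDM/GLRLM/GLZLM/NGTDM are out of scope and no numerical parity with any
specific extractor is claimed.

- **Discretization.** Fixed bin width (default 25 intensity units):
  level = ⌊(x − min)/width⌋ + 1; or fixed bin count: equal-width bins over
  [min, max] with the maximum clamped into the top bin. Constant regions
  map to a single level.
- **First order** (18): mean, median, min, max, range, population variance,
  skewness and Pearson (non-excess) kurtosis (undefined for constant
  input), energy, total energy (voxel-volume weighted), histogram entropy
  and uniformity (base-2, on discretized levels), 10th/90th percentiles,
  IQR, mean absolute deviation, robust MAD (within the 10–90 percentile
  band), RMS.
- **GLCM** (14): autocorrelation, cluster prominence/shade, contrast,
  correlation, difference average/entropy, dissimilarity, joint energy,
  joint entropy, inverse difference, inverse difference moment, sum
  average, sum entropy. Conventions: 13 unique 3D directions at distance 1,
  co-occurrence counts symmetrized and normalized per direction, feature
  values averaged over directions with at least one valid pair; fewer than
  two valid pairs overall flags every GLCM feature undefined. The
  correlation of a single-level (constant) matrix is defined as 1.
- **Shape** (4): voxel volume; surface area by exposed-face counting;
  sphericity π^(1/3)(6V)^(2/3)/A; maximum 3D diameter as the largest
  center-to-center distance (convex-hull reduction, then exact pairwise).
  Face counting is exact for axis-aligned boxes (a cube's sphericity is
  (π/6)^(1/3) to machine precision) but overestimates smooth surfaces: a
  digitized ball's staircase area tends to 3/2 the true area, so ball
  sphericity converges to ≈ 2/3 rather than 1 and is not monotone in
  radius. This bias is accepted for a dependency-free subset extractor and
  asserted in the tests rather than hidden.
- **Wavelet.** Single-level orthonormal tensor-product 3D Haar transform
  (PyWavelets, periodization mode; odd dimensions edge-padded to even), 8
  half-size sub-bands LLL…HHH satisfying Parseval's identity to 1e-10.
  Each sub-band is re-extracted with first-order + GLCM on the
  half-resolution mask (a coarse voxel is inside if any voxel of its 2×2×2
  block is inside); shape is geometry-only and computed once. The full
  vector is 18 + 14 + 4 + 8·(18 + 14) = 292 features per volume.

## Hybrid selection (model 2 front end)

Point-biserial correlation r_pb is the Pearson correlation of a feature
with the 0/1 outcome; constant features get r_pb = 0 and rank last, and
ties in |r_pb| break by ascending original column order so the ranking is a
deterministic permutation. The add-one loop fits a logistic regression on
the top-i features at iteration i and compares the iteration p-value with
the previous one, stopping at the first non-decrease; the first-ranked
feature is always retained. "The" p-value is implemented two ways:

- `lrt` (default): 1-df likelihood-ratio test of model i against the
  nested model i−1 (the intercept-only model before the first feature) —
  well defined at every step and directly expressing "compared with the
  previous iteration";
- `wald`: the Wald p of the newly added coefficient.

Features are z-scored before fitting (r_pb is scale-invariant, so the
ranking is unaffected; the fit gains numerical stability). The logistic
fitter is IRLS with step-halving; quasi-complete separation is detected by
any |coefficient| exceeding 30 (on standardized inputs, odds ratios beyond
e³⁰ are numerically meaningless), clamped and flagged so the selection
loop always terminates. On pure-noise tables the median number of retained
features over 100 seeds is ≤ 3 — the overfitting guard this greedy rule is
meant to provide.

## Penalized models (model 1)

The elastic-net logistic objective (unpenalized intercept, standardized
features) is minimized by a majorize-minimize coordinate descent: each
outer iteration bounds the logistic loss by the quadratic with curvature
(1/4)XᵀX/n (the Lipschitz matrix of the logistic gradient) and the inner
loop solves the penalized quadratic exactly by cyclic soft-thresholding on
a precomputed Gram matrix (numba-compiled). The MM argument makes the true
objective non-increasing across outer iterations — asserted in tests — and
the solution matches a derivative-free numeric optimizer to 1e-6 and
sklearn's saga solver to 1e-4 on toys. λ_max = max_j |Σᵢ x_ij(yᵢ − ȳ)|/(nα)
is the KKT threshold at which all penalized coefficients vanish; paths are
log-spaced from λ_max down to 0.01·λ_max (25 points) and warm-started, with
the Gram shared across the entire (α, λ) grid per CV fold.

Tuning: α ∈ {0.5, 0.6, …, 1.0}, λ by minimum mean 5-fold cross-validated
binomial deviance (deviance rather than AUC, matching standard elastic-net
practice). If the CV-optimal λ selects nothing, λ steps down the path until
the selection is non-empty, with a warning — the elastic net is preferred
to the lasso precisely to reduce the chance of empty selections. The 80/20
split is stratified by outcome (at prevalence 14/51 an unstratified 10-
patient test set is frequently class-degenerate); test size is
round(0.2n) = 10 at n = 51. Standardization uses training-set statistics
applied unchanged to the test set. The ridge refit re-tunes λ by the same
CV on the selected columns only.

## LDA and cross-validation (model 2 back end)

LDA uses pooled within-class covariance scatter/(n−2), empirical class
priors (preserving the 14-vs-37 imbalance the classifier is chosen to
tolerate), and Gaussian class-conditional posteriors; a singular covariance
receives a diagonal ridge ε = 1e-6·trace/d and a flag. Posteriors match an
explicit Gaussian Bayes-rule oracle to 1e-8 and sklearn's LDA to 1e-6.

`model2_pipeline` runs stratified, disjoint 5-fold cross-validation
(n = 51 with 14 positives yields fold sizes {11,10,10,10,10} and positives
{3,3,3,3,2}); within each fold the *training portion only* is standardized,
ranked, selected and fit — the held-out fold never touches selection, and
the permuted-label tests pin the resulting null AUC to chance. Per-fold
sensitivity/specificity/accuracy/AUC are arithmetic means across folds
("performance averaged"); the AUC over pooled out-of-fold scores is also
reported, since a single cross-validated ROC is the other common
convention, and the two agree within 0.1 on planted-signal cohorts.

## Evaluation

AUC is the pairwise concordance probability with ties at 1/2 (equal to the
trapezoidal ROC area). The 95% CI uses DeLong's placement-value variance
by default (a stratified percentile bootstrap is available and agrees
within ~0.02 on 30-sample toys); the p-value against AUC = 0.5 is
normal-theory on the DeLong scale, and degenerate-variance cases clamp the
CI into [0, 1] around the point estimate. Reported operating points
maximize Youden's J = sensitivity + specificity − 1 with ties broken
toward the lower threshold (higher sensitivity); for honest test-set and
held-out-fold metrics the threshold is chosen on training scores only and
applied unchanged.

## Problem sizes and defaults

Generator defaults are the published cohort dimensions (51 patients, 854
features, 12 clinical, 19 LI-RADS, prevalence 14/51). Calibration checks
use n = 5000 for the single-feature AUC (Monte-Carlo error ≪ the 0.02
tolerance). Pipeline recovery and null checks use n = 300 patients with
100 radiomics features and δ = 2 — a dimensionality at which 5-fold CV is
meaningful while keeping the full (α, λ) grid search and the 20-seed null
affordable on one CPU; the acceptance script completes in a few minutes.
Null-label checks for model 1 in the unit tests use a smaller toy
(n = 120, 20 features, shortened λ path) since 20 full grid searches add
no information about leakage beyond the pipeline contract.

## Known limitations

- The published per-phase AUCs (e.g. 0.791 on the portal venous phase for
  objective response) were computed on the unavailable 51-patient cohort;
  they are structural templates here, not reproduction targets. Synthetic
  cohorts say nothing about clinically attainable performance.
- The feature extractor is a documented subset; no GLDM/GLRLM/GLZLM/NGTDM,
  no multi-level wavelets, no resampling of anisotropic volumes, no parity
  guarantee with any production extractor.
- Surface area (hence sphericity) carries the exposed-face bias described
  above.
- Model 1 reports a single split, not repeated splits or nested CV; the
  post-selection inference step sometimes layered on ridge refits is out
  of scope.
- The Fisher/χ² router reproduces the published tables except where the
  original row-level test choice deviated from the expected-cell rule (one
  row), and exact-test p-values can differ from asymptotic ones at small n
  by design, not by defect.
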