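# rtae

Radiomics modelling pipelines for predicting hepatocellular carcinoma (HCC)
response to transarterial embolization (TAE) from pre-treatment MRI features,
together with the cohort statistics that accompany such a study and a
synthetic-cohort generator that makes every stage testable without patient
data.

## Who this is for

Imaging researchers who want a transparent, fully tested reference
implementation of two common radiomics modelling strategies at small-cohort
scale (tens of patients, hundreds of correlated features):

- **Model 1 — penalized logistic regression.** On a stratified 80/20 split,
  features are selected by logistic regression with an elastic-net penalty
  (α grid on [0.5, 1], λ tuned by 5-fold cross-validated binomial deviance
  along a warm-started path from λ_max), then re-fit with a ridge penalty
  (λ re-tuned by CV) and scored on both sets. The objective is the glmnet
  one, with an unpenalized intercept:

  f(β₀, β) = −(1/n)·ℓ(β₀, β) + λ[α‖β‖₁ + (1−α)‖β‖₂²/2]

- **Model 2 — hybrid descriptive-inferential selection + LDA.** Features are
  ranked by |r_pb| (point-biserial correlation with the binary outcome),
  added one at a time to a logistic regression, and the loop stops the first
  time the iteration p-value (1-df likelihood-ratio test against the previous
  model) fails to decrease. The retained features feed a linear discriminant
  analysis (pooled within-class covariance, empirical priors), evaluated by
  stratified, disjoint 5-fold cross-validation with fold-averaged
  sensitivity/specificity/accuracy/AUC and a pooled out-of-fold ROC.

Supporting modules cover mRECIST response classification (CR/PR/SD/PD and the
complete/objective response endpoints), baseline-table group comparisons
(two-sided Fisher exact, Pearson χ², Mann–Whitney U), ROC/AUC with DeLong
95% confidence intervals and Youden operating points, a bounded IBSI-style
feature extractor (18 first-order, 14 GLCM, 4 shape, single-level 3D Haar
wavelet sub-bands) for NIfTI image/mask volumes, and the synthetic cohort
generator.

## Worked example

Generate a 300-patient synthetic cohort with one planted discriminative
feature (class-conditional mean shift of δ = 2 pooled standard deviations,
single-feature Bayes AUC Φ(2/√2) ≈ 0.921) and run the cross-validated
hybrid-selection + LDA pipeline:

```python
from rtae.synthetic_cohort import SyntheticCohortConfig, generate_feature_table
from rtae.lda_classifier import model2_pipeline

cfg = SyntheticCohortConfig(
    n_patients=300, n_radiomics=100, prevalence=0.3,
    planted_features=[(0, 2.0)], seed=42,
)
ds = generate_feature_table(cfg)
res = model2_pipeline(ds, endpoint="cr", k=5, seed=0)
perf = res["averaged"]
print(f"fold-averaged AUC : {perf.auc:.3f}")
print(f"pooled-score AUC  : {res['pooled_auc']:.3f} "
      f"(95% CI {res['pooled_ci'][0]:.3f}-{res['pooled_ci'][1]:.3f})")
print(f"sensitivity       : {perf.sensitivity:.1f}%")
print(f"specificity       : {perf.specificity:.1f}%")
```

prints

```
fold-averaged AUC : 0.927
pooled-score AUC  : 0.923 (95% CI 0.891-0.956)
sensitivity       : 82.2%
specificity       : 85.7%
```

The fold-averaged AUC sits just above the 0.921 single-feature ceiling's
finite-sample scatter because selection occasionally adds a second useful
column; the planted feature is chosen in every training fold. A cohort with
no planted effect drops to chance (AUC ≈ 0.5) — the tests assert this
no-leakage property over 20 seeds.

Cohort statistics work on plain counts:

```python
from rtae.cohort_stats import ContingencyTable2x2, fisher_exact_2x2
fisher_exact_2x2(ContingencyTable2x2(0, 4, 14, 33))   # -> 0.565
```

A thin CLI mirrors the library (`rtae simulate`, `rtae extract`,
`rtae select`, `rtae model1`, `rtae model2`, `rtae stats`); run
`rtae --help` for details.

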