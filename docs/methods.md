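# Methods

## Problem and data model

Field asymmetric ion mobility spectrometry (FAIMS) of a urine sample's
headspace yields, per measurement ("run"), two detected-current grids —
one per ion polarity — over a sweep of compensation voltage (512 steps,
+6 V to −6 V) by dispersion-field magnitude (51 steps).  Each sample is
measured three consecutive times.  The classification task is binary
(disease case vs healthy control), with four demographic covariates per
sample (sex, age, alcohol units/week, BMI) available as potential
features and potential confounders.

A run linearises to a single vector: the positive grid flattened
row-major (compensation-voltage rows first), then the negative grid —
2 × 512 × 51 = 52,224 features.  The concatenation order is a package
convention (either order is defensible); it is fixed so feature
identifiers, which encode (polarity, CV step, dispersion step), are
stable across the toolchain.

## Wavelet features

The feature extractor reshapes the vector back into a 512 × 102 grid
(positive columns then negative columns), optionally crops to the top
512, 256 or 128 compensation-voltage rows, zero-pads columns (and rows
if needed) on the high side to a dyadic square, and applies a
full-depth separable 2-D discrete wavelet transform with Daubechies'
least-asymmetric family (``sym10``, 10 vanishing moments — the default
of the wavelet software family this pipeline descends from) and
periodic boundary handling.  Zero padding only adds coefficients of
exactly zero variance across samples, which the exclusion stage removes.

The 2-D feature vector concatenates, for each scale from coarsest
decomposition step to last, all four subbands — smooth, horizontal,
vertical, diagonal — plus the final smooth constant.  Recording the
smooth band at every scale is deliberately redundant (each smooth band
is further decomposed); the convention gives 4·(4^L − 1)/3 + 1 features
for a 2^L square: 349,525 (512²), 87,381 (256²), 21,845 (128²).  The
non-redundant subset (details at every scale + final constant) is the
orthonormal transform: it conserves energy and supports exact inversion
(`dwt2_inverse`), which the tests exploit.

A 1-D variant zero-pads the 52,224-vector to 65,536 = 2^16 and returns
the full-depth decimated coefficient set (length 2^16).  No standard
decimated convention reproduces a coefficient count of 52,395 for this
input; 2^J is this package's documented convention.

`feature_support` maps any 2-D coefficient back to the grid region it
responds to, by inverse-transforming a unit impulse at that coefficient
and thresholding at 1% of the peak magnitude.  The exact numerical
support of periodised `sym10` covers the whole grid at coarse scales,
so the *effective* support is the meaningful notion for asking whether
a selected feature sits on a planted peak.

## Feature exclusion and selection

* **SD exclusion** retains features whose sample standard deviation
  (n−1 denominator) is strictly greater than `sigma` (default 0), so
  the default removes exactly the zero-variance padding features.
* **Filter selection** ranks features by the two-sided Wilcoxon
  rank-sum p-value between classes, computed on the training fold only,
  and keeps the `nKeep` smallest (default 2), ties broken by ascending
  feature index.  The p-value is exact (full enumeration of the
  rank-sum null) when both groups have ≤ 25 members and no ties occur;
  otherwise the normal approximation with tie and continuity
  corrections.  For the ~10^5-feature tables the per-column test is
  hand-vectorised (one argsort per column; tie-averaged ranks are only
  materialised for columns that actually contain ties), verified
  against the scalar reference implementation.
* **PCA** (comparison mode) is covariance PCA centred on training
  means, keeping the fewest components reaching 95% cumulative
  variance, never fewer than 2; before PCA the filter caps the feature
  count at the training-set size.  Test scores reuse training loadings.
* **Wrapper** (comparison mode) is stepwise search over a binomial GLM:
  from `wrapper_n_start` = 5 seeded random features, repeatedly apply
  the single add-or-drop move that most decreases AIC = 2k − 2 ln L,
  stopping at a local minimum.  Candidates whose fit fails are skipped
  with a warning.  Because the full feature set is computationally
  infeasible for stepwise search, the wrapper mode prescreens with the
  filter (`nkeep` acts as the prescreen size).
* **Embedded** (comparison mode) passes all SD-retained features to the
  models and relies on their built-in sparsity (lasso, forest).

## Classifiers and cross-validation

Five classifiers, fixed hyperparameters: random forest (500 trees),
sparse logistic regression (L1 penalty, penalty weight by inner
cross-validated deviance on the training fold), RBF-kernel SVM with
k(x,y) = exp(−σ‖x−y‖²), σ = 0.05, cost C = 5 and Platt-calibrated
probabilities, a neural network with a single logistic hidden unit, and
a binary Gaussian-process classifier with the same fixed RBF kernel on
unscaled inputs.  Implementation choices worth noting:

* Inputs are standardised on training-fold statistics for the lasso,
  the SVM and the neural net; the GP is deliberately unscaled (its
  stated configuration) and the forest is scale-invariant.  Without
  standardisation the single hidden unit saturates on raw wavelet
  magnitudes and the neural net is uninformative.
* The neural net trains with L-BFGS; if training fails to produce
  finite probabilities the model degrades to predicting the training
  prevalence (logged) rather than aborting the cross-validation.
* The SVM's probability calibration is scikit-learn's internal 5-fold
  Platt scaling.
* The sparse-logistic penalty path (10 values, 5 inner folds) is a
  package decision; only the lasso form itself is fixed upstream.

Cross-validation is 10-fold, stratified by class, seeded.  *Every*
data-dependent step — SD exclusion, filter/wrapper/embedded selection,
optional PCA — runs inside the training fold, so out-of-fold
probabilities are an honest generalisation estimate.  With 115 samples
the stratified folds give training sizes of exactly 103 or 104.  A
degenerate draw with a single-class training split is redrawn (logged)
up to five times.  Demographic covariates, when combined with spectral
features, are appended after in-fold selection.

Run-combination modes: single run (run 2 is the recommended default),
element-wise subtraction of runs 1 and 3, element-wise mean of the
three runs, and the probability ensemble (per-model mean of the three
runs' out-of-fold probabilities).

## Evaluation

AUC is the Mann–Whitney statistic (ties ½), identical to trapezoidal
ROC area.  The 95% CI is the percentile interval over 2000 stratified
bootstrap replicates (cases and controls resampled independently);
percentile rather than BCa because it is the simplest defensible
choice and documented as such.  The operating threshold maximises
(SE − 1 + SP)² + (SP − 1 + SE)² ≡ 2(SE + SP − 1)² over candidate
thresholds (midpoints of adjacent distinct scores plus sentinels;
score ≥ threshold ⇒ case), i.e. a Youden-index extremum; ties are
broken by higher specificity then lower threshold.  Sensitivity and
specificity get exact Clopper–Pearson intervals, always reported on
the same scale as the point estimate.  Single demographic covariates
can be evaluated as biomarkers (orientation-corrected AUC, flip
logged), and two sets of prediction probabilities can be compared with
an unpaired two-sided rank-sum test.

## Synthetic cohorts

No clinical cohort is distributed with the package; the generator
emulates the data's structure so the pipeline is testable end to end:

* Grids are a low baseline (0.02) plus a strong reactant-ion ridge
  plus 6 analyte peaks — anisotropic Gaussians (σ = 12 rows × 6
  columns) whose row centre drifts 1.5 rows per dispersion-field
  column, mimicking the curved traces of real dispersion plots.  Peak
  positions and polarities are cohort-level (shared chemistry);
  per-sample amplitudes vary lognormally (CV 0.15); pixel noise is
  Gaussian (SD 0.05) and grids are clipped at zero.
* Two marker peaks carry the class signal: case amplitudes are
  multiplied by 1 + `effect_size` (default 0.5).  The same two peaks
  are volatile: amplitude × 0.85 per successive run, emulating sample
  degradation across the three measurements.
* Demographics reproduce the pilot cohort's class-dependent moments —
  BMI 38.3 ± 10.5 (cases) vs 28.1 ± 5.96 (controls), mean ages 57 vs
  45 (SD 12, not reported upstream, chosen as a typical adult-cohort
  spread), alcohol gamma-distributed with means 2 vs 5 units/week, male
  fractions 43/72 vs 17/43 — interpolated toward the pooled moments by
  the `confounding` knob (1 = full pilot-cohort mismatch, 0 = none).

What the generator does *not* model: real peak shapes and chemistry,
inter-peak interactions, instrument drift between samples, missing or
censored metadata.  Passing tests therefore demonstrate that the
pipeline is correct and leak-free and that it recovers localised
class signal of plausible magnitude — not that any particular clinical
AUC is reproducible.

## Test and verification scales

Unit tests run on miniature grids (16–64 rows).  The statistical
acceptance checks use study-scale conditions: planted-signal recovery
and demographic confounding on 60 + 60 cohorts at the instrument grid
(512 × 51, full 2-D DWT, 349,525 features), and the no-leakage check
on 20 label-permuted 30 + 30 cohorts with all five models.  Bootstrap
CIs use the default 2000 replicates throughout.

## Numerical choices and edge cases

* Rank-sum exact/asymptotic switch at 25 per group; p clipped to (0, 1].
* Filter tie-break by feature index (stable argsort); documented,
  deterministic.
* AIC improvement threshold 1e−9 (strict decrease) for stepwise moves.
* Probabilities clipped to [0, 1] after calibration.
* A constant covariate gets AUC 0.5 with a warning rather than an error.
* All randomness flows through explicit seeds: cohort generation uses
  per-purpose seed streams, fold draws and model fits derive per-fold
  seeds from the CV seed.

## Known limitations

* The wrapper stepwise search is greedy and seed-dependent; it is a
  comparison mode, not the recommended path.
* GP probabilities on unscaled wavelet features are compressed toward
  0.5 (tiny kernel values at σ = 0.05 on large distances); rankings —
  and hence AUC — remain informative.
* Under label permutation the pooled out-of-fold AUC is unbiased
  (mean ≈ 0.5) but over-dispersed: across null cohorts its standard
  deviation (~0.12 at 30 + 30) exceeds the ~0.075 an iid sample of the
  same size would show, because different training folds select
  different chance features and the pooled predictions inherit that
  fold-to-fold randomness.  The stratified percentile bootstrap, which
  resamples the pooled predictions as if iid, is well calibrated on iid
  scores (~94–95% coverage, verified) but covers 0.5 in only ~75–80%
  of null cross-validation repetitions.  Consumers wanting calibrated
  null inference should permute labels and repeat the *whole*
  cross-validation rather than relying on the per-run bootstrap CI.
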