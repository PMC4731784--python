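# Methods

This note documents the statistical machinery implemented in
`breathdiscrim`, the defaults and why they were chosen, and what the test
suite's green checkmarks do and do not establish.

## Problem setting

A breathomics case–control study of chronic liver disease: breath samples
from patients with compensated cirrhosis (CIR), chronic liver disease
without cirrhosis (CLD), and healthy controls (HC) are measured by GC-MS,
preprocessed into a samples × compounds matrix of relative VOC abundances,
and mined for a small compound panel that discriminates CIR from CLD. The
statistical contrast of interest is always binary (CIR vs CLD by default;
HC contrasts run through the same machinery pairwise).

## Data model and scales

Peak areas are strictly positive and right-skewed; the package models them
as log-normal. All modelling (PLS-DA, sMC, rMANOVA) operates on **log
abundances** followed by **autoscaling** (per-compound mean 0, variance 1) —
the standard metabolomics choice. Both are configurable
(`FeatureMatrix.log_abundances()`, `scaling="center"`), but the defaults
define the package's stated behaviour: a "standardized effect of d" always
means a d-standard-deviation shift on the log scale.

## PLS-DA

NIPALS with a single response. Class membership is coded y ∈ {0, 1}
(positive class = CIR). Per latent variable: w ∝ X'y (normalised),
t = Xw, p = X't/(t't), q = y't/(t't), then X and y are deflated by t. The
regression vector is b = W(P'W)⁻¹q, so ŷ = X_scaled b + ȳ equals the score
path Tq + ȳ identically (asserted to 1e-10 on every fit in the suite).
Initialisation is deterministic (w from X'y), convergence tolerance 1e-12,
at most 500 iterations per component (single-response NIPALS converges in
one step; the loop exists for the contract). There is no randomness in the
estimator.

**Number of latent variables.** The source analysis displays two latent
variables but states no selection rule. Default: fixed n_lv = 2 in the
validation loops (cheap, deterministic, matches the displayed model);
`n_lv="auto"` selects by 10-fold cross-validated misclassification with
deterministic stratified folds, ties toward the smaller model. This is a
reconstruction choice, flagged as such.

**Class probabilities.** The probability transform is likewise unstated in
the source; the package fits one Gaussian per class to the training
predictions and returns the equal-prior posterior, which makes the two
class probabilities sum to one exactly — the stated contract. If a training
class has zero variance the transform degenerates and a distance-based
softmax is used (with a warning).

## sMC variable selection

Let ŷ = X_scaled b be the model's prediction direction. For each compound
j, the scaled column x_j is regressed on ŷ by least squares;
SSR_j = ‖x̂_j‖², SSE_j = ‖x_j − x̂_j‖², and

    F_j = (SSR_j / 1) / (SSE_j / (n − 2))

is referred to the upper tail of F(1, n−2). The projection is orthogonal per
compound, so SSR_j + SSE_j equals the compound's total sum of squares
(asserted to 1e-10 against an explicit-loop oracle). A compound with
SSE_j = 0 is flagged and reported as F = ∞, p = 0.

**Calibration.** The F(1, n−2) reference is exact only when the prediction
direction is independent of the compound being tested; because b is
estimated from the same data, each compound's own contribution inflates its
F slightly. The bias is small at realistic dimensions — pooled over 50 null
cohorts of 200 compounds × 54 samples, the Kolmogorov–Smirnov distance of
the p-values from uniform is ≈ 0.016, passing a KS test at α = 0.01 but not
far from the boundary. Null-calibration results should be read as
"approximately uniform", not exact.

**Panel rule.** The source reports fixed panel sizes (11 VOCs for CIR vs
CLD) without a stated cutoff. Default: Benjamini–Hochberg FDR at α = 0.05
over all compounds (Bonferroni available); `top_k` forces a fixed panel size
(k = 11 mirrors the source design). Selection runs inside the training set
by default; a `paper_mode` switch selects on the full dataset to mimic the
apparent original workflow — clearly labelled optimistic, since it leaks
validation information into selection.

## Validation

**Splits.** Repeated stratified holdout: per repeat, 27+27 training and 7+7
validation-1 samples drawn without replacement; the majority class's
remaining samples (53 CLD at the default cohort) form a fixed validation-2
set drawn once per plan, never eligible for training, identical across
repeats, and disjoint from every repeat's training and validation-1 sets.

**ROC.** Probabilities are swept as cutoffs (call positive when
P(CIR) ≥ cutoff); AUC by the trapezoid rule, which equals the Mann–Whitney
U statistic divided by n₁n₂ (asserted exactly on random instances). The
optimal cutoff maximises Youden's J, ties broken toward the cutoff nearest
0.5. Rates with zero denominators (e.g. NPV when nothing is called
negative) are reported as missing, never as 0.

**Aggregation.** The source reports one ROC from 1000 repeats without
stating the aggregation; default is to pool all repeats' validation-1
probabilities (per-repeat averaging available). Sensitivity/specificity are
reported both at the pooled optimal cutoff and as per-repeat means, since
the source's convention is ambiguous.

**Permutation test.** Statistic: aggregated AUC (misclassification rate
available). Each of B permutations shuffles the class labels over all
samples and re-runs fit-and-validate on one fresh split;
p = max(1, #{null ≥ observed})/B, chosen because the source's reported
0.001 and 0.002 equal 1/1000 and 2/1000. Using a single split per
permutation keeps the null B× cheaper than nested full re-runs. One
consequence, measured in the suite: if the observed statistic is computed
from many pooled repeats while the null uses single splits, the two are not
exchangeable and the test is strictly conservative (measured type-I error
≈ 0.01 at α = 0.05 under the null) — valid, but under-powered; with the
observed statistic computed by the same single-split procedure the test is
exactly calibrated (type-I within [0.02, 0.09] over 200 null replicates).
A strongly separated cohort drives the p-value to its 1/B floor regardless.

## Cohort statistics

Continuous characteristics: Mann–Whitney U, exact enumeration for
n₁+n₂ ≤ 12 without ties, otherwise the normal approximation with midrank
tie correction; two-tailed throughout, α = 0.05. Dichotomous
characteristics: Pearson chi-square on the 2×2 table **without** continuity
correction — this reproduces the published sex comparison (21/13 vs 47/40,
p = 0.440); a Yates-corrected variant is available. The published smokers'
p-value (0.191) is not reproduced by either chi-square variant on the
printed counts and no attempt is made to match it.

**rMANOVA.** On the autoscaled panel, between-group scatter B and
within-group covariance S_w are formed; S_w is shrunk toward its own
diagonal, S(λ) = (1−λ)S_w + λ diag(S_w), with λ chosen analytically
(Schäfer–Strimmer-style ratio of estimated covariance-of-covariances to
squared off-diagonal mass, clipped to [0,1]; recomputed per permutation).
The statistic is trace(S(λ)⁻¹B); at λ = 1 it reduces to the sum of
per-compound standardized between-group variances (verified numerically).
Significance by permuting factor labels with the same max(1, count)/B
convention. This is a reconstruction of a shrinkage-MANOVA from its cited
description; only its p-values were published.

## Synthetic data generator

The generator is a stated world, not a fit to data:

* cohort sizes 34 CIR / 87 CLD / 31 HC, 3718 compounds, an 11-compound
  discriminatory panel with signed directions (3 reduced, 8 elevated in
  CIR) — all configurable, reduced dimensions used in tests for speed;
* log-normal abundances; class effects act additively on the log scale,
  split symmetrically between the contrast classes; the default effect
  magnitude of 1.5 within-class SD is a free parameter (the source reports
  directions only, no magnitudes or variances) chosen to give a strong but
  imperfect classifier;
* inter-compound correlation through signed latent block factors (a block
  realises pairwise correlation s_i s_j ρ; inconsistent signs across
  overlapping blocks are rejected), emulating the observed
  positive/negative loading geometry;
* covariates (age, BMI, sex, smoking, etiology, drug flags) drawn per class
  near the published cohort table, independent of the features by default —
  the source found no covariate effect on the selected VOCs; an optional
  confounding hook injects covariate→feature effects for rMANOVA power
  studies;
* chromatograms: one Gaussian peak per compound (area = feature value,
  evenly spaced apexes, widths 1.5–4 s), per-sample retention jitter, slow
  sinusoidal drift, a monotone bleed ramp, white noise.

Not emulated: the mass-spectral (m/z) dimension, co-eluting/overlapping
peaks, heteroscedastic detector noise, missingness mechanisms other than
below-prominence peaks, and batch effects. A green round-trip test
therefore establishes that the preprocessing chain inverts the artifact
model it states — not that it would invert any real instrument's.

## Preprocessing defaults

Savitzky–Golay window 11, polyorder 3; asymmetric least squares with
asymmetry 0.01, stiffness 1e7, ≤ 20 reweighting iterations (non-convergence
returns the last iterate, flagged); alignment segments of 500 grid points,
max shift 20 points, shifts interpolated linearly between segment centers
(edge segments use the trimmed overlap); peak calling by prominence with
boundaries at flanking minima and trapezoidal areas; registry by gap-based
clustering of pooled apexes within the match tolerance; absent peaks
imputed as 0 (half-minimum available); an optional minimum detection
fraction drops registry features seen in too few samples (off by default).
All thresholds live in the config; none are hidden.

## Known limitations

* The headline clinical performance numbers of the motivating study are not
  reproducible here: its breath dataset was never released. All quantitative
  guarantees are therefore properties and self-contained statistics.
* sMC p-values are approximately, not exactly, F-distributed under the null
  (see above); panels near the FDR boundary should be read accordingly.
* The permutation test with a many-repeat observed statistic is
  conservative by construction (never anti-conservative).
* Multiclass problems are handled pairwise; there is no single multiclass
  PLS-DA model, and no sparse/orthogonal PLS variants.
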