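# Methods

This note documents the statistical model behind `ppi-flutter`, the
estimator and design choices made where the problem left them open, what the
synthetic cohort generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

The unit of analysis is one ECG record's series of P-to-P intervals in
milliseconds — the times between consecutive atrial (P-wave) peaks — with a
mechanism label, focal (FAFL) or macroreentrant (MAFL). Upstream waveform
processing (filtering, peak detection, T-wave overlap handling) is out of
scope; the package starts from interval series and provides only a trivial
peaks→intervals first-difference converter as plumbing.

Intervals above 300 ms are treated as artefacts of missed peaks (not true
consecutive P-P intervals) and removed. "Above" is read strictly: exactly
300 ms is kept. Intervals are stored as real-valued milliseconds; at a 2 kHz
acquisition rate the native 0.5 ms resolution is exactly representable, so
no quantisation is imposed. One record contributes one concatenated series;
sub-series from different R-R groups are not kept separate.

## Oversampling and the variance correction

All three samplers operate per minority record: for each original series,
anchors are drawn uniformly from the series and one synthetic interval is
generated per original interval, so the synthetic series has the source's
length; the augmentation rate in percent divided by 100 gives the number of
synthetic series per original record (800% balances a 41:5 cohort exactly).

**SMOTE.** `s = x_j + α(x_k − x_j)` with `α ~ U(0,1)`. The neighbourhood is
the entire pool minus the anchor instance (`k = N − 1`), so no k-NN search
is involved. By default the pool is the source record's own series
(per-record generation); a pooled-minority neighbour mode exists behind a
flag. Writing `s = (1 − cα)x_j + cα x_k` with i.i.d. `x` of variance σ²,

```
Var[s] = E[(1 − cα)² + c²α²]·σ² = (1 − c + (2/3)c²)·σ²
```

which at `c = 1` gives the classic-SMOTE variance shrinkage factor 2/3.

**Modified SMOTE.** The unique positive root of `1 − c + (2/3)c² = 1` is
`c = 3/2`; `solve_variance_coefficient` exposes both the closed form and a
bracketed numeric root-find of the same moment expression (they agree to
1e-12), and the interpolation uses that coefficient so the synthetic
variance matches the original while the mean is preserved. The draw can
extrapolate past the neighbour by up to half the segment length, hence
occasionally past the 300 ms ceiling.

**Smoothed bootstrap.** Resample with replacement and add a Gaussian kernel
shift `h·z`. The kernel family is a design choice (only "a nonparametric
kernel density" is prescribed); Gaussian with Silverman's rule-of-thumb
bandwidth `0.9·min(sd, IQR/1.34)·n^(−1/5)` is the default, with a fixed
bandwidth available. Bandwidth 0 degenerates to the classic bootstrap. The
synthetic variance is inflated by exactly `h²` in expectation.

**Out-of-range synthetic values.** Synthetic intervals outside (0, 300] ms
are kept by default (`bounds_policy="none"`): any clamping or redrawing
breaks the moment identities above, which are the method's point. A
`"redraw"` policy (resample until in range, counts logged at debug level)
is provided for users who need closed support. Consequently the strict
positivity invariant of interval series is enforced for original series
only; synthetic series merely require finite values.

## Validation battery

Augmented minority data are compared to the original pooled minority
intervals with four criteria, averaged over independently generated
replicate datasets (default 100): maximum absolute difference of binned
empirical CDFs (5 ms bins), absolute quartile differences (linear
interpolation between order statistics — quartile definitions differ, so
this is fixed and documented), the two-sample asymptotic Kolmogorov–Smirnov
p-value as a similarity score (two-sample, because two empirical samples
are compared), and signed percent differences of mean, sample variance and
adjusted Fisher–Pearson skewness, `100·(augmented − original)/original`. A
zero original moment falls back to a flagged absolute difference. The
"augmented dataset" pools original plus synthetic intervals, replicates are
pooled per augmented dataset, and techniques are ranked per criterion on
the oriented values (largest KS p best; smallest everything else), ties
sharing the better rank.

## Features

Ten order-insensitive statistics per series: mean, median, mode, standard
deviation, variance, skewness, kurtosis, maximum, minimum, sum. Estimators:
sample (n−1) variance/standard deviation; adjusted Fisher–Pearson skewness
(population form at n = 2, where the adjustment divides by n−2); Pearson
non-excess kurtosis in the population form `m4/m2²` (the bias-adjusted form
is undefined below n = 4, and the population form is defined for every
n ≥ 2); mode after rounding to the nearest millisecond with ties broken to
the smallest value. A constant series has zero variance and undefined shape
statistics; both are reported as 0 with a degeneracy flag so constant
synthetic series remain usable. Features require n ≥ 2 intervals.

The feature indexing follows the feature list (F8 = maximum, F9 = minimum);
the source material is internally inconsistent about F8's meaning
(elsewhere describing a successive-difference quantity), and no
successive-difference feature is invented here.

## Feature selection

The filter method is the two-sided Wilcoxon rank-sum test per feature.
Exact enumeration is used when both groups have ≤ 10 samples *and* the
pooled sample is tie-free (the exact null distribution does not account for
ties); otherwise the tie-corrected normal approximation. An all-constant
feature short-circuits to p = 1.

The wrapper evaluates every non-empty feature subset (2^p − 1; 1023 for
p = 10, guarded to p ≤ 20) with one classifier and a fixed stratified
5-fold split reused across subsets. At each subset length the members of
the maximum-accuracy subset are credited one point (ties go to the
lexicographically first subset, deterministically); a feature's score is
its credit divided by p. Whether the original study's wrapper used
resubstitution or cross-validated accuracy is unstated; cross-validated
accuracy was chosen to match the evaluation protocol, and this is a
recorded decision, not an inference about the original. A subset on which
the classifier fails scores 0 with a warning rather than being dropped.
The combined relevance rule flags features whose wrapper score reaches 0.8
for a majority of classifiers, ordered by mean wrapper score then filter p.

## Classifier evaluation

Three linear models behind per-training-fold standardisation: LDA (SVD
solver, pooled covariance), logistic regression with minimal regularisation
(L2, C = 10⁴ — a finite C keeps the optimiser bounded on separable folds
while being far past the point where the penalty influences the decision
boundary), and a linear SVM with unit cost. Settings are fixed and embedded
in every report. Nonlinear classifiers are deliberately out of scope (too
little data to control overfitting).

MAFL is the positive class everywhere: sensitivity = MAFL recall,
specificity = FAFL recall. Cross-validation is stratified 5-fold over the
original records; every synthetic series is assigned to its source record's
fold, so no fold ever tests a record whose synthetic offspring were trained
on — an information-leak guard the original protocol does not address. An
ungrouped mode exists behind a flag for sensitivity analysis. Folds missing
a class raise a validation error advising fewer folds.

The best augmentation rate is selected from per-rate specificity curves
(maximum cross-validated specificity per feature-subset length): the
average curve is the pointwise mean over rates, each rate's Euclidean
distance to it is computed, and the argmin wins with ties resolved to the
smallest rate (preferring the minimum synthetic ratio). Euclidean distance
is a design choice; only "overall distance" is prescribed.

## Synthetic cohort generator

The generator emulates the *structure* of the clinical cohort, not its
records: 5 FAFL vs 41 MAFL records, 40–120 intervals per record, class
cycle lengths 230 ± 22.36 ms (FAFL) and 248.10 ± 39.38 ms (MAFL) read as
record-level base-cycle parameters (they are tachycardia cycle lengths per
record, not population moments of pooled intervals), and within-record
Gaussian jitter that is larger in FAFL than MAFL.

Two modelling choices deserve emphasis:

* **Calibrated truncation.** Intervals must live in (0, 300] to survive the
  artefact filter, but a normal base-cycle draw with the MAFL parameters
  exceeds 300 ms for ~9% of records, which would make naive rejection
  sampling infeasible and naive truncation would bias the realised MAFL
  mean by about −7 ms. Base cycles are therefore drawn from a normal
  truncated to (0, 300] whose location is calibrated by root-finding so the
  truncated mean equals the class target; generated cohorts recover the
  nominal cycle-length means without bias.
* **Jitter heterogeneity.** Each record's jitter is lognormal around the
  class scale (median 12 ms FAFL / 3 ms MAFL, geometric log-sd 1.0 by
  default; 0 gives deterministic per-class jitter). Fixed per-class jitter
  would make the two classes linearly separable on the dispersion features
  alone, and the imbalance-induced specificity collapse that motivates the
  whole augmentation study could then never occur; clinically, patients
  differ in rhythm stability and univariate dispersion features do *not*
  cleanly separate the mechanisms. The heterogeneity restores that overlap
  while keeping FAFL stochastically more variable, so the record-level
  variance feature still separates the classes in distribution.

What the generator does **not** emulate: serial correlation within a series
(wander of a focal path), P-wave morphology, inter-lead information,
non-Gaussian jitter, or any biophysical propagation model. Tests passing on
synthetic cohorts therefore demonstrate that the pipeline's statistics,
contracts and protocol arithmetic are correct and that the imbalance
pathology behaves as theory predicts — they do not certify clinical
performance on real ECGs.

## Reproducibility and problem sizes

Every stochastic component takes either a `numpy` Generator or a seed;
pipeline stages derive independent substreams from one master seed (CRC of
the stage tokens into a `SeedSequence`), so stages can be re-run in
isolation and full runs are byte-identical. The acceptance script verifies
the Monte-Carlo variance contracts with 100 000 draws from a 10 000-point
pool (sampling error ≈ 0.005, comfortably inside the ±0.02 bands),
averages the specificity trend over 20 replicate cohorts, and runs the
validation battery with 50 replicates; the test suite uses smaller sizes
(30–50 k draws, 30 replicates) chosen to keep each contract's Monte-Carlo
error an order of magnitude below the asserted tolerance.

## Known limitations

* The clinical tables (per-technique performance values, printed p-values)
  are not reproducible without the original ECG data, which is not
  deposited; only data-independent quantities and qualitative behaviours
  are asserted.
* The exact rank-sum path silently switches to the normal approximation in
  the presence of ties, which at very small n can shift borderline
  p-values by a few hundredths.
* Modified SMOTE's variance identity holds for i.i.d. data; per-record
  interval series are approximately i.i.d. under this generator but real
  series with serial correlation would see a different effective ratio.
* The wrapper's exhaustive search is exponential in the feature count and
  guarded to 20 features.
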