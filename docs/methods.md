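# Methods

This note documents the models, estimators and numerical choices behind
`neurobag`, a pipeline for detecting and classifying group differences in
brain-wide, frequency-resolved neuronal coupling estimated from
source-level MEG-like recordings.

## Overview of the analysis chain

1. **Spectral estimation.** Source signals are decomposed with Morlet
   wavelets on a geometric frequency grid (quarter-octave steps spanning
   2.8–128 Hz at study scale: 23 carrier frequencies).
2. **Coupling estimation.** At each carrier frequency two coupling modes
   are computed for every source pair: the orthogonalized amplitude-envelope
   correlation (amplitude coupling) and the weighted phase-lag index
   (phase coupling). Both reject instantaneous (zero-lag) mixing, the
   signature of volume conduction. The upper triangle of each symmetric
   coupling matrix is vectorized and z-scored within subject ("coupling
   profile").
3. **Dimensionality reduction.** For each (mode, frequency) a PCA basis is
   fit on the coupling profiles of an independent reference cohort; study
   subjects are projected onto the leading 30 components. At study scale
   this reduces ~4.8 million coupling values per subject to 1380 component
   scores (a >3000-fold reduction).
4. **Feature bagging.** Random subsets of 10 components are drawn
   (2×10⁷ at study scale; 2×10⁵ by default here); each bag is scored by
   leave-one-out cross-validated accuracy of a linear classifier. A
   component's *classification score* is the fraction of top-quartile bags
   that contain it.
5. **Permutation statistics.** Group labels are permuted (sizes preserved)
   and the entire bagging stage is rerun per permutation with fresh bags;
   all permuted scores pool into one feature-independent null. Per-feature
   p-values are FDR-corrected (Benjamini–Hochberg); a global count test
   compares the number of significant components against the permutation
   counts.
6. **Confidence and accuracy.** A subject's classification confidence is
   the difference of squared Mahalanobis distances to the control and
   patient feature distributions (leave-self-out moments); severity scores
   are correlated with confidence across patients. Unbiased accuracy comes
   from a second-level leave-one-out loop that refits the entire selection
   stage per held-out subject, with Gaussian fits to the signed,
   SD-normalized boundary distances yielding sensitivity, specificity and
   their group-size-weighted accuracy.

## Spectral analysis

The wavelet bandwidth is one spectral standard deviation of 0.5 octaves,
interpreted symmetrically in log frequency: `sigma_f = f·(2^(b/2) −
2^(−b/2))/2 ≈ 0.174·f` at `b = 0.5`, with `sigma_t = 1/(2π·sigma_f)`.
Coefficients are subsampled every `sigma_t/2`. Numerical choices:

* The kernel is truncated at ±8 temporal SDs. This is stricter than
  accuracy alone requires, but keeps truncation sidelobes below ~1e−13 of
  the passband peak so the Gaussian transfer function is reproduced
  faithfully even an octave away from the center (attenuation ~7e−8),
  where a ±4 SD kernel's sidelobes (~3e−4) would dominate.
* Signals are reflection-padded before FFT convolution and coefficients
  whose kernel support touches the padding are dropped. Reflection padding
  is a documented implementation choice, not a property of the method.
* The kernel is normalized so a unit sinusoid at the center frequency
  yields unit-magnitude coefficients.

## Coupling metrics

**Amplitude coupling.** For each ordered pair (X → Y) the component of
Y's complex coefficient orthogonal to X's instantaneous phase is retained
(`imag(Y·conj(X)/|X|)`), its log squared magnitude is correlated with X's
log power, and the two directed values are averaged into one symmetric
estimate (averaging is the documented convention here; a single value per
unordered pair is the alternative). Squared residuals below (1e−10 × RMS
amplitude)² are clamped before the log so exactly collinear signals yield
a constant column; the zero-variance guard then maps such degenerate pairs
to 0 with a logged warning rather than a missing value, so downstream
linear algebra never sees gaps.

Note that a constant global phase rotation of one channel changes the
per-sample orthogonalized residual (the imaginary part extracts a
phase-referenced component); the correlation estimate is invariant only in
distribution, which holds when the relative phase drifts across the circle
— the generic situation for non-phase-locked narrow-band signals.

**Phase coupling.** With `S(t) = X(t)·conj(Y(t))`, the weighted phase-lag
index is `|mean Im S| / mean |Im S|`, the plain magnitude-weighted form
(not the debiased squared variant). Zero-lag mixtures have `Im S ≡ 0` and
return 0 under the same degeneracy guard. wPLI is invariant to positive
per-channel amplitude rescaling and lies in [0, 1].

**Profiles.** Upper triangle, row-major (i < j), with an explicit
connection-index map; z-scoring across connections uses the population-SD
convention (divide by n). Both conventions (ddof 0/1) differ only by a
constant factor, which the downstream correlation- and projection-based
statistics ignore.

## Connection-wise statistics

Two-tailed Mann-Whitney U-tests per connection (exact enumeration for
group sizes ≤ 8 without ties, tie-corrected normal approximation
otherwise), BH-FDR within frequency. The sign-asymmetry test computes the
proportion of positive signs among nominally significant connections,
rescales it to `k = round(proportion·df)` successes in `df = 40` trials
(the rank of a typical MEG forward model, a conservative bound on the
number of independent sources) and applies an exact two-tailed binomial
test against 0.5 using the minimum-likelihood convention; binomial
p-values are FDR-corrected across frequencies within mode. Mapping the
sign distribution onto df trials by rounding the proportion is the
documented convention here.

## Component space

The PCA basis per (mode, frequency) is fit by SVD of the centered
reference profile matrix (subject-side computation); eigenvalues are
component score variances across reference subjects (ddof = 1). Reference
profiles are z-scored per subject exactly like study profiles, and
projection subtracts the reference mean profile by default (standard PCA
projection); `center=False` reproduces a bare eigenvector product. Sign
alignment flips any component whose patient mean score is below the
control mean, so positive loadings read as coupling increases in patients;
band summaries average loading vectors normalized by their absolute 98th
percentile (linear-interpolation percentile convention) over canonical
bands (delta 2.8–3.4, theta 4–6.7, alpha 8–13, beta 16–27, low gamma
32–54, high gamma 64–128 Hz), plus an absolute-loading summary split at
35 Hz (above which MEG coupling largely reflects residual muscle
activity).

A caveat that matters for interpreting simulations: PCA eigenvectors are
estimated with noise, so a group effect planted along one generative
component spreads across neighboring estimated components when
eigenvalues are close. Recovery analyses therefore identify a planted
component with the estimated component whose loadings align best with the
generative loading vector, the standard matching in factor-recovery
studies.

## Feature bagging and selection

* **Classifier.** The default linear classifier is a least-squares SVM:
  ridge regression of ±1 labels with unit penalty on the weights and an
  unpenalized intercept, classifying by sign. Its leave-one-out
  predictions are exact in closed form through the PRESS identity for
  linear smoothers, which is what makes exhaustive bagging (millions of
  bag × fold evaluations) tractable; a numba kernel evaluates one bag in
  a few thousand floating-point operations, gathering per-bag normal
  equations from a precomputed feature Gram matrix. Alternative families:
  hinge-loss SVM (scikit-learn; slow, used as a cross-check — per-bag
  accuracies of the two SVM variants correlate strongly), diagonal-
  covariance LDA, nearest centroid, and a decision-stump voting ensemble.
  5-fold and 10-fold cross-validation are available alternatives to
  leave-one-out.
* **Standardization.** Features are standardized once per cohort
  (label-free), not per training fold: fold-wise standardization would
  break the closed-form LOO identity, and a label-free transform cannot
  bias group classification — the permutation null shares it exactly.
  Inside the nested accuracy loop, standardization uses the in-fold
  subjects only, so the held-out subject never influences any part of the
  fit.
* **Bags** are drawn without replacement within a bag (Floyd's algorithm,
  unbiased) and independently across bags; permutations draw fresh bags.
* **Threshold.** Bags at or above the chosen accuracy percentile
  (default 75) are selected, ties included; with LOO over 34 subjects
  accuracies are multiples of 1/34, so ties are common and the selected
  fraction is reported. Scores sum to the bag size exactly (each selected
  bag contributes `bag_size` memberships), an identity asserted in code.
* **p-values** use the add-one (never-zero) permutation convention
  `p = (1 + #null ≥ s)/(1 + N)`. Per-permutation significant counts are
  computed against the same pooled null; the global p is the add-one rank
  of the observed count among permutation counts.

Within a single finite cohort the classification scores of truly
uninformative features are *not* all equal — chance-level separability
spreads them around `bag_size/n_features` (their mean, an exact identity).
Equality holds in expectation over cohorts, and the permutation null
reproduces the within-cohort spread, which is exactly why selection is
calibrated against permutations rather than against the uniform value.

## Confidence and unbiased accuracy

The Mahalanobis distance is used in its squared form (no square root),
with the subject excluded from its own group's mean and covariance. The default feature subset is the FDR-significant components
(a covariance over all 1380 components from 17 subjects would be
singular). The default covariance is the plain sample covariance; when it
is singular or ill-conditioned (subset dimension close to group size) a
diagonal-loading shrinkage toward the average variance (γ = 0.1) is
applied and logged, and a Ledoit–Wolf option (`covariance="lw"`) is
available for small-sample, higher-dimensional subsets. Severity
correlations are product-moment (BH-corrected across the scores tested,
missing values dropped pairwise). Because the confidence statistic passes
the planted severity signal through leave-one-out moment estimates at
n ≈ 16, it attenuates the recoverable correlation: with severity noise at
SNR 1 the population correlation cannot exceed ~0.71 and the realized one
is ~0.5–0.6, so detection power at n = 16 is ~60–75%, not higher — a
property of the statistic, not a bug.

Nested leave-one-out accuracy refits feature selection per held-out
subject (the reference-cohort basis stays fixed — it never sees study
subjects). Per fold the selected features are, by default, the `bag_size`
best-scoring components (`selection="top"`); the permutation-FDR rule per
fold exists (`selection="fdr"`, with the top-s fallback when nothing
survives) but multiplies the cost by the fold count times the permutation
count and is not the default at desk scale. Distances of in-sample
subjects to the decision boundary are pooled over both groups and their
SD (ddof = 1) normalizes the held-out distance; the sign is positive when
the subject is classified as a patient. Gaussian fits per group then give
sensitivity (patient mass above 0), specificity (control mass below 0)
and the group-size-weighted accuracy, which satisfies the weighting
identity exactly; a zero-SD group degenerates to a step function with a
logged warning.

The least-squares-SVM LOO on a balanced 17 + 17 cohort carries a small
pessimistic bias (~0.03–0.04 below 0.5 on pure noise): each training fold
is imbalanced against the held-out subject's class and the intercept
follows the majority. The permutation null carries the identical bias, so
all calibrated comparisons are unaffected.

## Synthetic cohorts

The generator replaces the study's recordings (17 patients + 17 controls;
95-subject reference cohort) with two kinds of synthetic data whose
defaults define the desk-scale study conditions: 30 sources
(435 connections), six carrier frequencies at octave spacing from 2.83 Hz
(one per canonical band, all below the 125 Hz Nyquist of the 250 Hz
default rate), 60 s per subject.

**Time-series level.** Per carrier frequency each source is an
amplitude-modulated sinusoid: log-normal envelope (`sd_log = 0.5`) driven
by an Ornstein–Uhlenbeck process with a five-cycle time constant;
envelope correlations are imposed via a Gaussian copula on the
log-envelopes (Cholesky factor of the target matrix, which must be
positive semi-definite — infeasible targets are rejected with the minimum
eigenvalue in the diagnostic). Every phase process is a free-running
random walk (2 rad per √cycle), so uncoupled sources at the same carrier
decohere within ~10 cycles instead of staying spuriously phase-locked;
phase-coupled groups share one walk plus small per-member OU jitter
(0.3 rad) and fixed pairwise lags (default π/4, since wPLI is blind to
zero lag), with offsets assigned by breadth-first traversal of the
coupling graph. Instantaneous mixing by any full-rank real matrix
emulates volume conduction. The generator controls coupling *structure*;
measured coupling values are calibrated against Monte-Carlo oracles
(averages over independent realizations), not analytic targets — the
orthogonalization deliberately discounts part of the envelope
correlation.

**Profile level** (fast path for the statistical stages): per (mode,
frequency), profile = mean pattern + orthonormal loading basis Q (30
components) × subject scores with a geometric variance spectrum
(decay 0.75, scale 0.3) + isotropic noise (SD 0.1). Patient profiles are
shifted along planted components by `effect_size × SD_ref`, where
`SD_ref` is the reference cohort's component-score SD implied by the
model — so effect sizes are in reference-SD units, and a 2-SD plant
yields a population AUC of Φ(√2) ≈ 0.92 for the planted score.
Severity scores for patients are a standardized sum of their realized
planted-component deviations plus unit Gaussian noise (SNR 1), mapped to
an EDSS-like 0–7 scale and an MSFC-like scale already mirrored so higher
means more severe; controls and reference subjects carry no severity.

What the generator does **not** emulate: 1/f background spectra,
realistic head geometry or forward-model correlation structure between
connections, artifacts (muscle, cardiac, eye), non-stationarity across a
session, or realistic spatial smoothness of coupling maps. Passing tests
therefore demonstrate the statistical machinery — calibration under the
null, recovery of planted effects, insensitivity to zero-lag mixing — not
performance on real MEG data.

## Problem sizes and defaults

Desk-scale defaults keep a full selection run (one observed bagging pass
plus 200 permutations at 2×10⁴ bags each) under ~20 s and the complete
test suite in the tens of minutes: 360 features (2 modes × 6 frequencies
× 30 components) from 34 study subjects. The study-scale values
(23 frequencies, 1380 features, 2×10⁷ bags, 1000 permutations) remain
plain configuration changes. `scripts/acceptance.py` reruns the whole
chain at desk scale and writes its measured quantities as JSON.

## Known limitations

* The nested-LOO default selection rule (top-s by score) departs from the
  per-fold FDR rule at study scale; both are implemented, and on null
  cohorts the default is calibrated (mean accuracy ≈ 0.5).
* Permutation p-values inherit the granularity of the score distribution;
  at desk scale (~70k pooled null values) this is negligible for
  selection but visible to very large-sample uniformity tests.
* The Mahalanobis confidence at n ≈ 16 is a noisy readout (see above);
  severity correlations of moderate size (~0.45–0.5) sit near its
  detection boundary.
* `generate_timeseries_cohort` holds all recordings in memory
  (~3.6 MB/subject at defaults); the pipeline streams subjects to disk
  when persisting, but very large cohorts should lower the duration or
  rate.
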