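# Methods

## Problem and model

The package recognizes posture transitions (sit↔stand, sit↔lie, stand↔lie)
from a single wrist-worn 6-axis IMU, against two rejection classes:
*no movement* and *other movement* (wrist-intensive activities of daily
living that mimic transitions). Eight classes in total. The pipeline is a
classical feature-engineering chain: filter → window → 175-entry feature
bank → univariate information-gain ranking → kernel SVM → subject-wise
cross-validation. Nothing in the chain is recurrent or stateful, so a
window's prediction depends only on that window.

Axis convention (watch on the left wrist): y toward the hand, x up when
looking at the face, z out of the face. Accelerometer units are g,
gyroscope units °/s; values beyond the ±2 g / ±300 °/s sensor ranges are
clipped at ingest and counted rather than rejected, since posture
transitions are gentle movements for which the ranges are not limiting.

## Preprocessing

* **Filter.** Causal (trailing) moving average, 1 s long, applied to the
  continuous stream before windows are cut. Causal rather than centered so
  the identical filter could run in a real-time recognizer; 1 s tracks the
  sampling rate (100/50/10 taps at 100/50/10 Hz). Filtering the stream
  versus filtering each window separately differ only in the first second
  of a window, and only at recording edges (the unit tests pin the exact
  equivalence away from edges).
* **Windows.** 5 s, centered on the annotation midpoint (the annotation
  fixes only the transition's extent, not its alignment); windows at a
  recording edge are zero-padded and flagged. 5 s × rate gives 500/250/50
  samples at the three supported rates.
* **Decimation.** Rate reduction keeps every k-th sample after the filter
  (the filter is the anti-alias stage), matching what an on-device
  low-rate sensor poll would deliver; timestamps are regenerated on the
  target grid to avoid drift.

## Feature bank (25 × 7 = 175)

Seven channels: ax, ay, az, gx, gy, gz, and the acceleration magnitude
‖a‖. Conventions chosen once and fixed so results are bit-stable:

* sample variance and standard deviation use the n−1 denominator; skewness
  m₃/m₂^1.5 and excess kurtosis m₄/m₂²−3 use 1/n central moments, with 0
  as the constant-series fallback; quantiles (median, IQR) use linear
  interpolation.
* "average difference" is the mean absolute difference over all n(n−1)/2
  unordered pairs, computed by the exact sorted prefix-sum identity
  (O(n log n)); the tests verify equality with the brute-force double loop.
* crossing rates count strictly opposite-sign adjacent pairs over n−1;
  exact zeros do not count; the mean-crossing rate is the zero-crossing
  rate of the mean-removed series.
* spectral features use the one-sided DFT amplitudes |X_k|,
  k = 1..⌊n/2⌋. The DC bin is excluded everywhere: posture windows are
  dominated by the ~1 g gravity offset, which would otherwise swamp every
  spectral aggregate. Spectral peaks are strict local maxima ranked by
  amplitude (frequency ascending on ties); peak features default to 0 when
  too few peaks exist. The dominant frequency is rate·k*/n with the lowest
  bin winning ties, 0 for an empty spectrum.
* three features are inherently triad-level and are mapped into per-channel
  slots to preserve the 25 × 7 bookkeeping: covariance eigenvalues
  (accel λ₁≥λ₂≥λ₃ → ax/ay/az, gyro analogously, accel total variance →
  the ‖a‖ slot); the gravity/heading correlation (gravity = normalized
  window-mean accel, heading = dominant eigenvector of the covariance of
  the gravity-orthogonal projection, correlation of the two scalar
  projections; accel value replicated into ax/ay/az/‖a‖, gyro construction
  into gx/gy/gz); and the mean rotation angle of each sample vector to the
  window-mean vector (same slot assignment). All orientation features fall
  back to 0 when the window-mean vector or a projection variance is zero.
  A gyro-magnitude channel would be a natural eighth channel but is not
  used: the bank is fixed at 7 channels, with gyro-triad quantities
  carried in the gyro slots.

Every vector is checked finite; degenerate inputs resolve to the documented
0 fallbacks rather than NaN.

## Feature selection

Information gain in bits over bins from recursive entropy-minimizing binary
splitting with the minimum-description-length stop: a split of segment S
(N samples, k classes, entropy H) into S₁/S₂ is accepted iff

    gain > [log₂(N−1) + log₂(3^k−2) − (k·H − k₁·H₁ − k₂·H₂)] / N.

Candidate cuts are midpoints between adjacent distinct values; the best cut
minimizes the weighted child entropy (leftmost on ties). A feature with no
accepted cut has IG = 0 — uninformative at this sample size. The
discretizer is implemented here because no installed library provides it;
an equal-frequency 10-bin fallback is selectable. Ranking sorts by IG
descending with ties broken by the matrix's canonical column order, and is
always computed inside the training folds of cross-validation — ranking on
the full matrix would leak the held-out subject.

The 10:1 samples-to-features budget counts unique subject × action
combinations (repetitions excluded): 20 × 7 / 10 = 14 features for a linear
SVM, doubled to 28 for the non-linear kernel. The default k = 30 sits just
above that; both are exposed.

## Classifier

Pearson VII universal kernel
K = 1/[1 + 4(2^{1/ω}−1)‖u−v‖²/σ²]^ω with ω = σ = 1 (the conventional
defaults), C = 100; RBF (γ default 1/#features) for comparison. Features
are min-max scaled to [0, 1] from training rows only; constant features map
to 0; test rows are clamped to the training box. The quadratic program is
delegated to libsvm (scikit-learn `SVC`, precomputed Gram, tolerance 1e-3);
multiclass decisions re-implement the one-vs-one vote explicitly so the
tie-break is specified: majority vote, then aggregate signed decision
value, then class order. (The binary decision function is sign-flipped
relative to the pairwise columns; the wrapper accounts for that.) Models
persist as a single versioned joblib archive.

The ADL baseline mode replaces the 175-feature bank with the classic
activity-recognition set: per-axis mean, standard deviation and spectral
energy plus the three inter-axis correlations (12 features; 24 with the
gyroscope), with no ranking step.

## Evaluation

Leave-one-subject-out: each fold holds out all windows of one subject and
re-runs ranking, scaling and training on the rest; a fold audit records
train/test subject overlap (always zero) in the report. Per-class precision
TP/(TP+FP) and recall TP/(TP+FN) (0 on empty denominators) are averaged
with equal weight over classes present in the truth; the pooled (micro)
variant is reported alongside and coincides with the class-averaged one
under the balanced design. Per subject F = 2PR/(P+R) (0 when P+R = 0); the
headline number is the unweighted mean of subject F-scores. A subject whose
class is absent from the training folds is still scored (those windows
count as false negatives) and the event is logged in the report.

The posture timeline is a 3-state machine over {sit, stand, lie}: each
classified transition moves to its destination state at its timestamp; an
event whose source disagrees with the current state still moves to the
destination (the classifier's best estimate) and increments an
inconsistency counter. Only the six transition labels generate events.
Occupancy durations partition the evaluated span exactly: the telescoping
sum is exact in real arithmetic, and the float representation is made
exactly conservative by re-deriving the last summand and nudging it in
single-ulp steps (with an upstream one-ulp phase shift in the rare
round-half-even tie), so `sum(occupancy) == span` holds bitwise.

## Synthetic study generator

The generator emulates a supervised laboratory protocol: 20 subjects × 10
repetitions of each of the 8 classes, 5-s windows, 100 Hz default (50/10 Hz
selectable), ±2 g / ±300 °/s ranges.

* **Postures.** Canonical gravity directions in the sensor frame —
  standing arm-down: +y (toward the hand); sitting, forearm on lap: +z;
  lying, arm across the body: +x — jittered per subject by a random
  rotation of up to 15°. These are simulator parameters, not claims about
  any real study.
* **Transitions.** The gravity vector rotates between the two posture
  orientations about the geodesic axis with a raised-cosine angular-rate
  profile ω(t) = (θ/T)(1 − cos 2πt/T), which starts and ends at rest and
  integrates exactly to θ. Nominal duration 2 s (divided by the subject's
  speed factor, drawn once from 0.8–1.2), centered in the 5-s window so
  static context surrounds the movement. The accelerometer reads the
  rotated gravity vector; the gyroscope reads the exact kinematic angular
  velocity −φ̇·n̂ (no bias-drift model).
* **Confounders.** Static posture gravity plus a kind-specific 1–4 Hz
  oscillation (0.15 g, 40 °/s, scaled by the subject's amplitude factor)
  on an axis transverse to gravity; labeled other_movement. no_movement is
  pure static gravity plus noise. The eight classes are kept balanced:
  other_movement gets the same per-subject count as every other class,
  cycling through the configured confounder kinds (a balanced design is
  what makes the equal-weight class averaging unbiased).
* **Noise.** Each sensor's noise is white Gaussian plus a per-window
  constant bias, both with scale `noise_sd_*` (defaults 0.03 g, 2 °/s —
  ordinary consumer-MEMS figures). The bias term models bias instability
  and unmodeled motion artifact; it is what makes the noise scale a real
  difficulty knob, since pure white noise averages out of the window-mean
  features as sd/√n. The degraded-sensor regime used in the tests scales
  both sensors by the same relative factor (accel 0.03 → 0.5 g, gyro
  2 → 33.3 °/s): the class geometry is redundantly encoded in the
  gyroscope (each transition has a distinct rotation axis and sign), so
  degrading one sensor alone leaves the pipeline nearly unimpaired.
* **Determinism.** One `SeedSequence` per study, spawned per subject; the
  same config and seed reproduce every sample bitwise.

**What the simulator does not capture.** Real wrist data have soft-tissue
artifacts, unconstrained arm use, gyroscope drift, inter-subject variation
far beyond a 15° pose jitter, and genuinely confusable transition pairs.
The synthetic classes are geometrically much cleaner: at the default
settings the full pipeline reaches a mean F above 0.95, and even the
simpler ADL baseline saturates near 1.0. Passing the recovery tests
therefore shows the chain is implemented correctly and has subject-level
generalization power under realistic signal structure — it does not
reproduce, and cannot be compared to, F-scores measured on laboratory data,
nor the relative ordering of kernels and baselines observed there.

## Test and verification scales

The recovery checks run the full default study (20 subjects, 1600 windows)
at 10 Hz — the rate at which an all-day logger would run — with three
LOSOCV passes (default, permuted labels, degraded sensors), about half a
minute each. Oracle suites verify the spectral features against a direct
O(n²) DFT, the pairwise-difference formula against the double loop, the
information-gain extremes against hand tabulation, and kernel Gram matrices
for symmetry and positive semidefiniteness.

## Known limitations

* No automatic segmentation: windows come from annotations; an online
  change-point detector is out of scope.
* No probability calibration or incremental training.
* The information-gain ranking is univariate; redundant features (e.g. σ
  and variance of the same channel) rank together and consume budget.
* The MDL stopping rule is conservative at small n: on very small studies
  many features get IG = 0 and the ranking falls back to column order.
* Watch and phone streams can be evaluated jointly only by concatenating
  their feature matrices window-by-window; no clock-synchronization logic
  is provided.
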