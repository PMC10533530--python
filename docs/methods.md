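# Methods

## Problem and scope

Given synchronized inertial recordings from six candidate body locations
(trunk at L5, right wrist, both thighs, both shanks), the package asks: what
is the smallest subset of locations whose signals let a classifier
distinguish walking over seven real-world irregular surfaces (flat uneven,
banked left/right, stair up/down, slope up/down), each surface with a
per-class recall ("correct classification rate", CCR) above 90%? The
pipeline enumerates all 63 non-empty location subsets, builds fixed-size
walk patterns for each, screens channels with Welch ANOVA, trains a small 1D
causal-convolution network under a 90-split cross-validation protocol, and
applies the all-surface CCR > 90% selection rule.

## Data model

A trial holds 36 channels — per location a 3-axis accelerometer (m/s²) and
3-axis gyroscope (rad/s) in the vertical / mediolateral /
anterior–posterior axes — sampled at 100 Hz. The canonical channel order is
locations in the order trunk, wrist, left thigh, right thigh, left shank,
right shank; within a location accel(v, ml, ap) then gyro(v, ml, ap). The
order is a package convention (nothing upstream fixes one); fixing it makes
matrices reproducible.

A *walk pattern* is the (6n × 400) matrix obtained by restricting the first
4 s (400 samples) of a trial to a combination of n locations. The window
start is a parameter (default 0) so window-placement sensitivity can be
probed. The emulated design — 10 participants × 6 trials × 7 surfaces —
yields 420 patterns per combination (60 per surface), and 4200 (600 per
surface) after 10× rotation augmentation.

The 63 combinations carry a fixed catalogue numbering (e.g. 21 = left
shank + right shank, 20 = right thigh + right shank, 63 = all six) so that
reported combination numbers are stable across runs; the catalogue is
hard-coded rather than derived from an enumeration order.

Augmentation counts follow the *replace* convention: factor a produces a
copies per original and drops the original (60 → 600 per surface at a = 10).
`keep_original=True` keeps the original plus a−1 copies, which yields the
same totals; the difference is immaterial for counts and selectable for
anyone who cares about retaining unrotated patterns.

## Synthetic gait generator

The generator is a harmonic proxy, not a biomechanical simulation. Each
channel is

    x_c(t) = baseline_c + A_c · Σ_{h=1..4} (1/h) sin(2π h f t + φ_{c,h}) + ε(t)

with f = 1.67 steps/s (≈ self-selected 1.5 m/s walking) times a
surface-specific cadence multiplier and a ±2% per-trial jitter. The
amplitude A_c = base(sensor) × gain(location) × axis multiplier(surface) ×
participant multiplier, where base is 2.0 m/s² (accel) / 1.5 rad/s (gyro),
the location gains are shank 1.0, thigh 0.8, trunk 0.5, wrist 0.05 (the
planted discriminability hierarchy), and participant multipliers are
lognormal with σ = 0.1. Surface signatures:

| surface      | axis amp (v, ml, ap) | cadence | extra                         |
|--------------|----------------------|---------|-------------------------------|
| flat uneven  | 1.00, 1.00, 1.00     | 1.00    | —                             |
| banked left  | 1.00, 1.15, 1.00     | 0.97    | +0.6 m/s² ML offset (legs)    |
| banked right | 1.00, 1.15, 1.00     | 0.97    | −0.6 m/s² ML offset (legs)    |
| stair up     | 1.30, 1.00, 1.20     | 0.80    | impact transient, weight 1.0  |
| stair down   | 1.40, 1.00, 1.10     | 0.85    | impact transient, weight 1.3  |
| slope up     | 1.15, 1.00, 0.95     | 0.90    | vertical/AP reweight +25%     |
| slope down   | 0.95, 1.00, 1.15     | 0.95    | vertical/AP reweight −25%     |

Banked surfaces differ only in the sign of the mediolateral offset, and
that offset carries its own location weighting (`ml_offset_gain`: shanks
1.0, thighs 0.8, trunk and wrist 0.0) — a walker's trunk stays upright over
a cross-slope and the arm swings freely, so the signed lean is a
lower-limb feature. This is what makes a leg sensor necessary: a trunk
sensor resolves stairs and slopes (cadence and amplitude cues) but cannot
tell banked left from banked right. Slopes
re-weight vertical versus anterior–posterior amplitude in opposite
directions; stairs add a per-step Gaussian transient (σ = 0.06 cycle) on the
vertical and AP accelerometers. The vertical accelerometer carries gravity
(9.81 m/s²). The wrist sensor's whole frame is rotated by a per-(participant,
trial-index) random posture rotation (Euler angles uniform in ±60°) to mimic
arm-posture variability; the draw is independent of the surface, so setting
the wrist gain and noise to zero makes wrist channels identical across
surfaces — a construction check the tests exercise. Measurement noise is
i.i.d. Gaussian, σ = 0.3, on every channel. All randomness flows through
NumPy `SeedSequence` children of the config seed; trials are bit-identical
for a fixed config.

What this generator does *not* emulate: soft-tissue artefacts, gait-event
timing asymmetries, inter-step variability beyond noise, sensor drift, or
any overweight-specific kinematics beyond the gain hierarchy. Passing
recovery tests therefore show that the *pipeline* recovers a planted
placement structure, not that the specific accuracy numbers transfer to
real recordings.

## Filtering

Recordings are smoothed with a 2nd-order 6 Hz low-pass Butterworth filter.
The default is zero-phase (forward–backward `filtfilt`, the usual offline
gait-smoothing practice; squared magnitude, −6 dB at cutoff). A causal
single-pass mode is provided because phase handling is a genuinely open
choice; its contract is the textbook analog magnitude
|H(f)| = (1+(f/f_c)^4)^{−1/2} (−3 dB at 6 Hz, ≈ 0.040 at 30 Hz). At a 100 Hz
sample rate no standard IIR discretization honours that contract far above
the cutoff (the bilinear transform gives 0.019 at 30 Hz, impulse invariance
0.054), so the causal mode applies the analog prototype's transfer
function — whose impulse response is causal — to the band-limited signal via
FFT with one second of edge padding. DC is preserved exactly in both modes.

## Rotation augmentation

Sensor re-donning misaligns IMU axes, so each walk pattern is expanded with
randomly rotated copies: per copy and per IMU one proper rotation matrix is
drawn and applied at every time step to the accelerometer triplet and, with
the same matrix, to the gyroscope triplet (one rigid housing). Default:
independent rotations per IMU, Euler angles uniform in ±15° — realistic
re-donning error; unbounded rotations would scramble the gravity axis and
change the learning problem. A uniform axis-angle mode (axis uniform on the
sphere, angle uniform in [0, max]) bounds the total rotation angle by the
configured maximum; in the Euler mode the bound is per-axis and the total
angle can reach up to three times it. Rotations are isometries, so
per-sample triplet norms are preserved to machine precision — the suite's
main structural check.

## Significance screening

The unit of analysis is a per-trial scalar summary of each channel's
400-sample window — RMS by default (amplitude-sensitive, sign-robust), mean
and SD selectable. This reduction is the module's largest interpretive
choice and is exposed in config. Two schedules are run: across surfaces
within a location (21 surface pairs × 6 outputs × 6 locations = 756
comparisons) and across locations within a surface (15 pairs × 6 × 7 = 630).
Per cell a Welch heteroscedastic one-way ANOVA (weights n_i/s_i², Welch–
Satterthwaite df₂) is computed by the package and cross-checked in tests
against `pingouin.welch_anova` to 1e−8; pairwise post hoc contrasts are
Welch t tests with Bonferroni correction over the within-ANOVA family (21
or 15 pairs; a global-family option exists), labelled Significant iff the
adjusted p < 0.001. A "repeated-measures Welch ANOVA" is a contradiction in
terms (Welch's correction assumes independent groups), so the
independent-groups form on trial summaries is what is implemented.
Assumption diagnostics (normality, homoscedasticity, sphericity) are not
run; they would gate nothing in this pipeline.

Type-I calibration is asserted empirically: under H₀ with k = 7 groups of
n = 6, the 5% Welch test rejects in 5% ± 1% over 10,000 simulations.

## Classifier

Input (6n × 400) → conv1D(32 filters, kernel 3, causal padding) → ReLU →
layer normalization → conv1D(64, 3, causal) → ReLU → layer norm → global
average pooling over time → dense(7) → softmax, cross-entropy loss. Causal
padding puts k−1 = 2 zeros on the past side, preserving length and making
every activation independent of future samples (asserted by perturbation).
Layer normalization acts over the channel dimension at each time step;
frameworks differ here, so the choice is documented and tested (pre-affine
mean ≈ 0, variance ≈ 1). Parameter count: 96·C + 6887 for C input channels.

The network is implemented directly on NumPy (float32, im2col GEMMs, manual
backpropagation). Training uses Adam with learning rate 0.001,
squared-gradient decay 0.99, first-moment decay 0.9 (unstated upstream; the
common default), ε = 1e−8, global-L2 gradient clipping at 0.9, batch size
64, 500 epochs in the full profile and 50 in the test profile, and no
shuffling: batch order follows the dataset order. To keep fixed-order
batches class-balanced, the canonical dataset order interleaves surfaces
(sorted by participant, trial, augmentation index, then surface) — a
class-blocked order under shuffle=never makes most batches nearly
single-class and destabilizes the final epochs' class biases. Inputs are
standardized per channel with training-split statistics. Validation
accuracy is logged each epoch and influences nothing (no early stopping —
none is specified). Training is deterministic for a fixed seed and thread
configuration; bit-reproducibility across BLAS builds is not promised.
Prediction ties break toward the lowest class index.

## Cross-validation and selection

The dataset is partitioned once into 10 class-stratified folds (seeded).
Every ordered (test fold, validation fold) pair with test ≠ validation is a
split: 10 × 9 = 90 splits at 80/10/10 proportions — the only reading of
"90 combinations of train/validation/test subsamples" consistent with 10
folds. Stratification is by surface; `grouping="by_source_trial"`
additionally keeps all augmented copies of one source trial in one fold.
The ungrouped mode mirrors the original protocol and lets augmented
siblings straddle train and test — a leakage risk; recovery runs use the
grouped mode.

Per split, CA = trace/total of the test confusion matrix and CCR_s =
diagonal_s / row-sum_s, reported in percent as mean ± SD over splits. A
combination passes when its *mean* CCR exceeds 90% on all seven surfaces
(a per-split-minimum variant is available). Selection filters passing
combinations, groups them by cardinality, and reports the minimal
cardinality with its combinations ranked by mean CA; an empty passing set
is reported explicitly, never an error.

## Scaled-down profiles

Full-protocol cost (63 combinations × 90 splits × 500 epochs) is a
cluster-scale computation. The package's recovery profile — used by the
test suite and the acceptance script — evaluates five informative
combinations (wrist-only, trunk-only, shank+shank, right thigh + right
shank, all six) on the unaugmented 420-pattern datasets with grouped
splits, 50 epochs, and the first 3 of the 90 splits per combination. These
sizes are the package's own choice of a single-CPU-friendly slice; the
bookkeeping quantities (420/4200 patterns, 756/630 comparisons, 90 splits)
are always computed at full size. The monotonicity check (all-six ≥
wrist-only mean CA) reuses the same single-seed run.

## Numerical choices and degenerate inputs

- Welch ANOVA refuses zero-variance groups (weights undefined) and groups
  smaller than 2.
- Bonferroni adjustment is min(1, p·family); labels can only flip from
  Significant to Insignificant under correction.
- Trials shorter than window_start + 400 samples raise an error naming the
  required and available lengths; datasets missing a surface class raise an
  error listing the absent classes.
- Fold construction refuses n_folds larger than the per-class source-trial
  count and warns when counts are not divisible.
- Layer-norm ε = 1e−5; softmax is computed with max-subtraction; Glorot
  uniform initialization throughout.

## Known limitations

- The synthetic generator's separability is designed, not estimated from
  real data; absolute CA/CCR values on it say nothing about field accuracy.
- The NumPy trainer is single-threaded-BLAS friendly but has no GPU path;
  the full 500-epoch × 90-split × 63-combination protocol is out of its
  intended range.
- The figshare-deposited recordings the design emulates are not parsed;
  only the CSV/manifest layout documented in the I/O module is read.
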