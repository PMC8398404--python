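# Methods

`aclscreen` re-implements, as a tested pipeline, a sensor-based screening
method for anterior-cruciate-ligament (ACL) injury risk: from a shank-worn
IMU (1000 Hz; ±16 g accelerometer, ±2000 °/s gyroscope) and an
optical-gate contact signal, it derives per-repetition indices of leg
stability, load absorption and leg mobility during two single-leg tasks —
five monopodalic countermovement jumps (mCMJ) and five single-leg squats
(SLS) — then evaluates inter-session reliability on a control group and
runs the injured-athlete-vs-controls screening statistics.  Because raw
recordings of this kind are available only on request from study authors, a
synthetic trial generator with exact ground truth is a first-class
component: it defines the conditions under which every stage is validated.

## Orientation estimation

The world frame is Z up, X antero-posterior (AP), Y medio-lateral (ML).
A 10 s upright-stance window calibrates the sensor: the window-mean
accelerometer direction is mapped to world +Z and the horizontal projection
of the sensor long axis (which is close to, but not exactly, vertical on a
shank) fixes the heading, so the AP direction is subject-anchored rather
than mount-anchored.  Calibration is rejected if the gyroscope RMS in the
window exceeds 10 °/s.

Per-sample orientation comes from an explicit complementary (Mahony)
filter: gyroscope integration by a first-order quaternion exponential at
the sampling rate, corrected toward the accelerometer-measured gravity
direction with error `e = a_meas × v_est`, feedback `kp·e + ki·∫e`.
Defaults `kp = 1.0`, `ki = 0.1` (1/s); these trade drift suppression
against acceleration-induced tilt error and are not critical at 1000 Hz
with a 10 s calibrated start.  Samples whose acceleration magnitude departs
from g by more than 40 % (free flight, landing impact) carry no gravity
information and receive no correction.  The magnetometer is not used: yaw
is observable only up to the calibration heading, which is exactly the
invariance the indices need.  The accelerometer sign convention is
reaction-positive: at rest it reads +g along world Z.

Consequences worth knowing: (i) a 1 °/s gyro bias produces < 2° steady
tilt error (bounded by the gravity correction) while yaw drifts slowly;
(ii) the squat-phase detector consumes Euler angles of the motion
*relative to the calibration pose*, because world-frame angles contain the
arbitrary heading constant, which would corrupt the angle-module threshold.

## Events

**Jump segmentation.**  The gate contact series is debounced (runs shorter
than 50 ms merged into their context) and each flight→contact transition
yields a repetition with initial flight time `FT_i`, initial contact time
`CT_i`, flight and contact durations `ΔFT`, `ΔCT`.

**Stabilization time `Ts`.**  The Euclidean norm of the three gyro
channels ("absolute angular velocity") is zero-phase low-pass filtered
(4th-order Butterworth, 10 Hz — a first minimum is ill-posed on raw 1000 Hz
noise) and `Ts` is the delay from `CT_i` to the first strict local minimum
inside the contact window.  If the filtered magnitude decreases
monotonically across the whole contact, `Ts` falls back to `ΔCT` and the
repetition is flagged.

**Squat descending phase.**  The angle module
`m = ‖(θx, θy, θz)‖` is thresholded against its quiet baseline: threshold =
baseline mean of `m` plus the mean of the three per-axis SDs over the first
2 s (multiplier and the 5-sample run length are configurable).  "Overcome"
is read as an upward crossing.  `detect_descending_phase` implements the
plain forward rule (first sustained supra-threshold run).  The
multi-repetition segmenter (`segment_squats`) anchors the same rule per
repetition: repetitions are localized as prominent θy peaks (≥ 5°
prominence, ≥ 1 s apart), the supra-threshold run containing each peak is
walked back to its start, and the onset is refined by back-extrapolating
the local rise of `m` to the baseline mean (correction capped at 50 ms).
The refinement removes the threshold-crossing delay, which otherwise
biases `DP_i` late by roughly (threshold − baseline)/onset-slope.  The
forward rule alone is not usable across a multi-rep trial: between
repetitions the orientation estimate wanders on the scale of the (small)
baseline SD, so a global forward search false-triggers.  `DP_e` is the θy
argmax within the repetition; `θ_ymax = θy(DP_e)` is the mobility index.

## Indices

The leg axis (sensor long axis in world coordinates) is intersected with a
horizontal plane 1 cm from the sensor; the intersection point
`(AP, ML) = (−d·u_x/u_z, −d·u_y/u_z)` in cm traces the sway path.  On the
stabilization window `[CT_i, CT_i+Ts]` (jumps) or the descending phase
`[DP_i, DP_e]` (squats):

* path length `PL = Σ √(ΔAP² + ΔML²)`; directional components use one
  coordinate at a time, `PL_AP = Σ|ΔAP|`, `PL_ML = Σ|ΔML|`;
* ellipse area `EA = 2π · F_0.05[2, N−2] · √(s²_AP·s²_ML − s²_APML)`, the
  95 % bivariate confidence ellipse from the sample (co)variances.  The
  method's source text describes the ellipse as containing "at least 99 %"
  of the path while printing the 95 % F quantile; the printed formula is
  implemented.  A singular covariance yields EA = 0 with a warning.

All four are divided by `Ts` (jumps) or `T_DP` (squats), giving cm/s and
cm²/s.  Load absorption (jumps only): measured acceleration rotated to the
world frame, gravity subtracted; `RMS_z` of the vertical and `RMS_xy` of
the horizontal-plane magnitude over the landing window `[CT_i, CT_i+Ts]`,
each divided by the jump duration `ΔFT + ΔCT` (m/s³).  The source text
states the normalization but not the integration window or the definition
of jump duration; both are explicit, documented defaults here and
configurable.  The sway window for jumps (the stabilization interval) is
likewise a made-explicit choice.

## Reliability

Valid repetitions are averaged within subject-session cells
(complete-case subjects only; dropped rows counted).  The inter-session ICC
is the single-measure, absolute-agreement, two-way mixed-effects form,

    ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E)),

computed from the two-way ANOVA mean squares of the n-subjects × k-sessions
table (verified against pingouin's ICC(A,1) to machine precision).
Single-measure rather than average-measure because sessions are compared
directly; negative estimates are reported as computed and banded "poor".
Bands: poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent; an index is
acceptable for screening at ICC ≥ 0.60.

This estimator carries a small-sample downward mean bias: at n = 12,
k = 3 the Monte-Carlo mean estimate is below the variance-component ratio
by ≈ 0.02–0.035 across the 0.3–0.9 range (largest mid-range).  The
bias is a property of the ANOVA ratio estimator, not of this
implementation; tests that demand mean recovery within ±0.02 at n = 12
therefore fail honestly at mid-range ICC.

## Case-study statistics

Per index (reliability-gated): Welch two-sample two-sided t-tests of the
athlete's five repetition values against the 12 control subjects'
session means (unequal n and variances make the pooled form
inappropriate; the observational units on each side are a documented
choice, switchable to summary mode).  Longitudinally, a one-way ANOVA
across the athlete's sessions per index; only when the omnibus test is
significant are all pairwise Welch tests run with Bonferroni correction
(raw p × number of pairs, capped at 1).  α = 0.05 throughout; machine
outputs encode significance as booleans.

Under the null, the Bonferroni-protected pairwise family on the
three-session design holds its family-wise error near 0.04 (slightly
conservative, as Bonferroni is); with more groups it grows more
conservative (≈ 0.033 for four groups of five).

A single-case comparison has an irreducible caveat: the athlete's personal
(subject-level) deviation enters the t statistic whole, so an athlete who
is atypical on an uninjured index will "star" it.  The synthetic case
study therefore models the athlete as a population-typical subject whose
injury alters specific movement parameters.

## The synthetic generator

Signal-level realism only: no muscle/joint dynamics, no ballistic
consistency between flight and landing, and noise is white Gaussian per
channel clipped to the sensor ranges (gyro 0.5 °/s, accel 0.05 m/s²,
consumer-MEMS magnitude).  What it does emulate, with exact ground truth:

* **Jump trials** — 10 s quiet calibration prefix, then per repetition a
  flight (gate off, accelerometer ≈ 0) and a contact.  After landing the
  sensor spins about its long axis at
  `base + A·e^(−t/τ)·cos(ωt)` (400 + 400 °/s, τ = 0.5 s) with ω solved so
  the first minimum of the rate falls exactly at the blueprint `Ts`; a
  rotation about the long axis does not move the leg axis, so the spin is
  free to carry the `ω_min` oracle.  Simultaneously the leg axis sways on
  a damped quadrature (near-circular Lissajous) orbit, amplitudes
  0.075/0.068 cm at the 1 cm plane, 2.5 Hz — near-circular so the
  tilt-rate magnitude is almost constant and the angular-velocity-norm
  minimum stays put.  A half-sine impact transient (80 m/s² vertical,
  0.85× horizontal, 80 ms) follows touch-down.  A constant 3° forward
  shank lean anchors the calibration heading; without it the AP/ML
  decomposition of the estimated path mixes by a random angle per trial.
* **Squat trials** — θy rises as a half-sine to `θ_ymax` (nonzero onset
  slope, so the onset is sharp) and returns symmetrically; quiet postural
  micro-sway (0.25° tilt wobble at ~0.5 Hz) is present throughout and is
  what gives the baseline SD its realistic scale.  Squats below the
  angle-noise floor are rejected at blueprint construction.
* **Cohorts** — index-level values `mean + b_s + c_j + e_sj` with
  specified variance components (theoretical ICC =
  σ²_subject/(σ²_subject+σ²_session+σ²_error)); and signal-level study
  cohorts with multiplicative log-normal subject (CV 12 %), session (5 %)
  and repetition (13 %) factors — repetition CVs follow the magnitude of
  the published per-repetition SDs for such indices.

Sway amplitudes and impact scale were chosen once to land the indices in
the magnitude regime reported for such tasks (PL ≈ 1 cm/s, RMS ≈ tens of
m/s³); they are defaults, not calibrated claims, and the reliability ICCs
of a simulated cohort are whatever the chosen variance components imply —
they are not fitted to any published reliability figure.

**Injured profile.**  The case athlete's jump sway gains a high-frequency
AP component (12 Hz at 0.40× the carrier amplitude, carrier rebalanced
×0.92): frequency-content elevation raises `PL`/`PL_AP` (×1.4/×1.8, the
published case ratios) while leaving excursion variance — hence `EA` — and
the ML component unchanged, reproducing the observed dissociation in which
path length separates the injured athlete but ellipse area does not.
Landing impact ×1.5; `θ_ymax` 21.8° (SD 1.5); stabilization time untouched.

What passing tests do **not** show about real data: detector tolerances
(±5 ms on `Ts`, ±20 ms on `DP_i`, 1° on `θ_ymax`) hold under this
generator's noise model and event shapes, not under soft-tissue artifact,
sensor saturation or atypical landing strategies; and the SLS directional
path lengths inherit an ill-defined heading (near-vertical long axis at
calibration), which is why their synthetic ICCs are poor — only their
rotation-invariant combinations (PL, EA) and θ_ymax are trustworthy there.

## Numerical choices and degenerate inputs

Uniform sampling enforced to |Δt − 1/fs| < 1 µs; channel ranges enforced
at load.  Quaternions renormalized every step (unit norm to 1e−9).
Filtering is zero-phase (`sosfiltfilt`) so detected times are not
phase-shifted.  Local minima must be strict; plateau or monotone windows
flag the repetition rather than guessing.  Empty gates warn and return no
segments; degenerate EA returns 0 with a warning; zero-variance ICC tables
report as degenerate; sessions with fewer than two valid values are
excluded from tests with a report rather than silently imputed.

## Problem sizes

Validation sizes used by the test suite and the acceptance script: 100
simulated trials per task for event recovery; 10⁴–10⁵ points for the
path-length and ellipse oracles; 500 Monte-Carlo cohorts per ICC level;
5000 null replicates for the family-wise-error calibration; a 12-subject
control cohort (three sessions in the analysis drivers, one in the
acceptance pattern check) plus one case athlete for the end-to-end study.

## Known limitations

* Yaw is anchored only by the static calibration; trials with a truly
  vertical sensor long axis have an undefined AP direction.
* The RMS window and "jump duration" definitions are defensible defaults,
  not facts of the source method.
* The ICC mean-recovery bias discussed above; confidence intervals and
  SEM/MDC are out of scope.
* The generator's flight phases freeze the tilt state; takeoff dynamics
  and countermovement are not modelled.
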