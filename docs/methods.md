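# Methods

`stairpower` implements a complete wearable-sensor pipeline for the
four-step Stair Climb Power Test (SCPT): from a lumbar-worn six-axis IMU
it detects stair-climbing foot contacts, estimates stair climb power
(SCP), classifies stair walking against level gait (and ascent against
descent) from windowed signal features, and quantifies agreement between
sensor-derived and stopwatch-derived SCP. A synthetic signal generator
with known ground truth makes every stage testable end to end.

## Signal model and conventions

Recordings are uniformly sampled (native 128 Hz, any rate ≥ 50 Hz
accepted), with the accelerometer in m/s² and gravity retained on the
vertical axis (x); y is medial-lateral and z anterior-posterior. Event
intervals are half-open `[start, end)` and sample *i* sits at `i/fs`, so
slicing and 50%-overlap windowing are unambiguous. Downsampling to the
common 50 Hz analysis rate uses zero-phase polyphase FIR resampling with
a Kaiser (β = 14) window and per-channel demeaning: the high β keeps the
passband flat to ~1e-7 so that repeated resampling composes
consistently, and demeaning prevents the filter's (slightly non-unity)
DC gain from biasing the gravity offset.

## Windowing and features

Labeled events are cut into 1.5 s windows with 50% overlap, applied per
event so windows never mix activities. At 50 Hz the window is 75 samples
and the exact half-window hop (37.5) is floored to 37 samples, keeping
the realized overlap ≥ 50%.

Each window yields a fixed named feature vector: per axis and sensor,
23 statistics (moments, order statistics, RMS, entropies, lag-1
autocorrelation, dominant frequency, FFT energy, IQR, mean absolute
deviation, mean-crossing count) plus the 3 cross-axis Pearson
correlations — 72 features per sensor. The accelerometer adds per-axis
range and a vertical-axis "step-band" energy (continuous
Gaussian-derivative wavelet response at a 0.5 s pseudo-period), for 76
accelerometer features and 148 in total. The per-axis list beyond the
classically cited statistics (mean, min, max, variance, RMS, std,
entropy, autocorrelation, correlation, dominant frequency, range,
wavelet measures) was fixed once to meet the 72/76/148 totals with
statistics standard in the activity-recognition literature. Windows are
*not* detrended first: orientation/gravity content on the vertical and
anterior-posterior axes is exactly what separates ascent from descent.

Conventions for degenerate windows: zero-variance input has entropy 0,
autocorrelation 0, correlation 0, dominant frequency 0 Hz. Histogram
entropy uses 10 equal-width bins over `[min, max]` (max inclusive).
These choices, like the autocorrelation lag, are exposed rather than
hidden.

## Initial-contact detection

Contacts are detected on the vertical axis only, by a chain in the
family of continuous-wavelet gait-event detectors:

1. **Detrend** — subtract a coarse Gaussian-smoothed component
   (kernel std = detrend scale / 4; default scale 1.5 s, i.e. a ~0.5 Hz
   effective cutoff) to remove gravity and posture drift.
2. **Low-pass** — zero-phase 4th-order Butterworth at 5 Hz; step
   content at natural pace sits below this.
3. **Integrate** — cumulative composite-trapezoid integration to
   vertical velocity; each foot strike's net impulse becomes a step-like
   velocity increment.
4. **Wavelet** — continuous Gaussian-derivative (gaus1) transform at a
   0.35 s pseudo-period, which peaks at the velocity steps.
5. **Peak detection** — minimum separation 0.3 s; absolute prominence
   floor 0.5× the std of the transformed signal; then a *relative* gate
   discarding candidates below 0.5× the median prominence of the
   strongest `expected_steps` candidates; finally, if more than
   `expected_steps` candidates survive, the most prominent are kept (in
   time order). Polarity is resolved at runtime by choosing the sign
   with the larger total peak prominence, since mounting conventions
   flip the vertical axis.

The relative gate exists because the most-prominent-k rule alone will
"fill in" a genuinely missed foot strike with the best noise peak,
hiding the gap that the interval filter is designed to flag. The gate
value (0.5) was selected from a parameter scan on the synthetic
generator at its stated noise levels — at σ = 0.3 m/s² it leaves
four-contact recovery at ~99% while letting 90%+ of single-missed-step
trials surface as 3 contacts with an implausible gap.

All chain constants are engineering defaults collected in
`DetectorConfig`; the only physiologically anchored constant is the
**misdetection threshold**: inter-contact intervals above 1.2 s are
implausible for alternating-step stair ascent and are flagged invalid
(boundary inclusive: 1.2 s is valid). The transform runs on a
reflect-padded copy of the event (one detrend scale per side) so no
stage sees an artificial boundary step; padding is trimmed before peak
search.

## Stair climb power

The stopwatch (clinical) formula is `P = m·g·h/t` with g = 9.81 m/s²
and h the staircase height (~0.6 m for four 0.154 m steps). The sensor
formula uses the detected contacts t₁..t₄: because the stopwatch
interval includes the unobservable "go"-to-first-contact time, that
time is imputed as t₀ = mean of the detected step intervals, giving

    P = m·g·h₄·4 / (t₀ + (t₂−t₁) + (t₃−t₂) + (t₄−t₃))

which reduces algebraically to `m·g·h₄ / mean(intervals)`. The reduced
form is the implementation, because it extends naturally to partial
detections: intervals flagged by the 1.2 s rule are simply dropped from
the mean. Both forms are kept in the code and asserted equal to 1e-12
on complete detections. An optional additive calibration offset (watts)
is available but defaults to 0 — the uncorrected estimate is arguably
the better estimate of true power, and a constant offset cancels in
within-subject change over time.

## Classification protocol

Two binary problems: stair walking (ascent+descent) vs. level gait, and
ascent vs. descent; each for accelerometer-only, gyroscope-only and
combined features. The protocol is:

1. balance classes 1:1 by subsampling negatives within each
   (subject, visit) stratum (strata that cannot be balanced are dropped
   with a warning);
2. drop features with |Pearson r| > 0.90 to any already-retained
   feature, scanning in canonical order;
3. optionally reduce further by recursive feature elimination scored
   with grouped 5-fold CV accuracy under a random-forest ranker;
4. grouped 10-fold outer cross-validation, folds partitioned by
   *subject* so no subject contributes to both sides of a fold
   (asserted at runtime), with a hyperparameter grid search
   (grouped 3-fold) nested inside each training fold;
5. four models: k-NN (k ∈ {3,5,7,11}), random forest (trees ∈
   {100,300}, depth ∈ {∞,10}), logistic regression (C ∈ {0.1,1,10}),
   and a soft-voting ensemble of the three tuned base models. Features
   are z-scored on the training side of each fold only.

Metrics are accuracy, sensitivity (recall on the positive class) and
specificity, reported as mean (std) over folds. Random-forest impurity
importances are fold-averaged and normalized to sum to 1. A one-shot
80/20 subject-level holdout (`holdout_evaluate`) is provided as an
alternative evaluation mode.

## Agreement statistics

Sensor vs. stopwatch SCP agreement is quantified per subject
(trial-averaged values) with: Pearson r (two-sided t-based p); ICC(2,1)
— two-way random effects, absolute agreement, single measurement — from
the subjects × methods ANOVA mean squares, with a 95% CI by the
McGraw–Wong F-distribution method (verified against pingouin to 1e-9);
Bland–Altman bias and 95% limits of agreement (bias ± 1.96·sd of the
differences, difference direction fixed as stopwatch − sensor, CIs with
SE(bias) = sd/√n and SE(LoA) = sd·√(3/n)); and Welch unequal-variance
t tests with fractional Welch–Satterthwaite df for group effects.

## Synthetic generator

The generator emulates the in-clinic protocol, not real biomechanics:

* **Ascent**: vertical axis = 9.81 + one impact transient per contact +
  band-limited (20 Hz) Gaussian noise (σ = 0.3 m/s² default). Contact
  times: first contact uniform 0.4–0.9 s after "go" (matching a
  reported mean go-to-first-step time of ~0.64 s), then steps uniform
  0.4–1.0 s. Each impact is a Gaussian-enveloped (0.06 s) 8 Hz carrier
  with a 0.4-fraction unipolar weight-acceptance component — a foot
  strike transfers momentum, so its transient must carry net impulse;
  a pure zero-mean burst would leave nothing for the integration stage
  of any velocity-based detector to act on. Anterior-posterior lean
  oscillation (0.8 m/s²) and a +0.3 rad/s trunk-pitch gyro bias.
* **Descent**: larger (4.5 m/s²) and sharper (0.035 s) impacts,
  opposite-phase lean, −0.3 rad/s pitch bias.
* **Gait**: sustained two-harmonic vertical periodicity at 1.5–2.2 Hz
  with mild (1 m/s²) heel-strike transients, no pitch bias.

Every between-class parameter is linearly interpolated between a common
ascent-like base process and its class value by a single
`class_contrast` knob: at 0, ascent and descent are draws from exactly
the same process and ascent-vs-descent classification falls to chance
(the stairs-vs-gait comparison retains a small amount of trial-length
structure — the quiet lead-in fraction of a 4 s stair trial — and is
nulled with permuted labels instead). Multi-subject datasets draw
subject-level random effects (habitual step time, amplitude multiplier,
gait cadence), which makes grouped CV measurably different from pooled
CV and makes subject-leakage bugs detectable.

Ground truth carried per trial: contact times and the true SCP computed
from the drawn step times by the same reduced formula. What passing
tests on this generator show is that the *computations* are correct and
the detector recovers parameters under the stated noise; they do not
show field accuracy on real signals, which contain turning, handrail
use, pauses, soft-tissue artifacts and stopwatch error that the
generator deliberately omits.

## Problem sizes and numerical choices

The packaged experiments run at desk scale: parameter-recovery suites
use 200 simulated trials; the simulated agreement cohort uses 64
subjects × 3 trials; classification experiments use 12 subjects × 2
trial blocks (~700 windows before balancing). Tolerances: formula
equivalences at 1e-12; oracle comparisons for the agreement statistics
at 1e-9; detector timing at ±60 ms (3 samples at 50 Hz). Ties in peak
prominence are resolved by time order; constant inputs raise an
explicit detection failure rather than returning noise-driven contacts.

## Known limitations

* The detector assumes alternating steps at a roughly constant pace on
  a four-step staircase; pauses and irregular stepping violate the
  1.2 s heuristic.
* The classifier is trained on structured activities only; free-living
  negatives (standing, running, turning) are out of scope.
* Descent step timing and final-contact (toe-off) detection are not
  implemented.
* The synthetic agreement study contains no stopwatch (human-timing)
  error, so its agreement statistics are optimistic relative to any
  clinical comparison.
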