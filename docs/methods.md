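# Methods

## Measurement model

A MEMS IMU mounted at the centre of the cage floor (the anti-node of the
floor's membrane-like mode) measures tri-axial acceleration at 4500
samples/s with a 1248 Hz 3 dB bandwidth, 61.04 µg/LSB quantization and a
±2 g full scale, plus tri-axial angular rate (7.63 mdps/LSB). Impulsive
forces from the animal's movements excite the cage's natural modes; the
sensor sees them as rapidly decaying oscillations superimposed on a white
noise floor of RMS `noise_density × √bandwidth`: 190 µg/√Hz × √1248 Hz ≈
6.7 mg for the accelerometer and 15 mdps/√Hz × √12106 Hz ≈ 1.65 dps for the
gyroscope. The gyroscope carries no detectable activity signal and is
modelled (and carried through I/O) as noise only; its datasheet bandwidth
exceeds the Nyquist frequency of the sample rate and is used solely in the
closed-form noise figure. The accelerometer full scale is not printed on the
sensor summary we model; ±2 g is the value consistent with 61.04 µg/LSB over
a signed 16-bit range, and out-of-range samples are clipped on simulation
and flagged on read.

## Activity classes and the reference labeler

Three classes cover the common behaviour patterns: **resting** (sleep-like
immobility), **stationary activity** (grooming, digging, stretching,
rotating on the spot) and **locomotion** (walking through the cage).
Activity is evaluated on 15-s windows because bouts shorter than about 15 s
are rare and frame-level labels are unreliable.

Ground truth comes from three tracked head points (right ear, left ear,
headbase — the head is rigidly coupled to the skull and leads most
movements). Per-frame point speeds are 2-D Euclidean frame differences times
fps, in pixel space (no px→mm calibration; the tracked animal spans ≈ 200 px).
The head velocity is the per-frame **minimum** of the three point speeds,
which suppresses the large spikes caused by single-point misdetections at
the cost of underestimating rotation — underestimation is the preferred
error direction. Window means are thresholded at 1 px/s and 50 px/s; the
interval [1, 50] px/s is read as closed, so boundary ties go to the middle
class (stationary activity).

Two gating parameters are not fixed by the velocity definition and are
package choices: a point detection is invalid below likelihood 0.9 (pose
estimators emit a per-point likelihood; some cutoff is unavoidable), and a
window is invalid when fewer than 50% of its frame intervals are valid.
Both are keyword arguments throughout.

## Feature set

Each axis of a window is mean-removed (so gravity on Z never dominates) and
transformed with one rectangular-window real FFT over the full 15 s. At
Δf = 0.067 Hz, leakage is negligible relative to the ≥ 4 Hz-wide bands, so no
taper or Welch averaging is used. Magnitudes are RMS-per-bin scaled:
`Σ magnitude² = mean((x−x̄)²)` exactly (the Nyquist bin is not doubled), so a
sinusoid of amplitude A contributes A/√2 in its bin.

Eleven predictors per window: for each band — X 23–27 Hz, Y 62–80 Hz,
Z 80–120 Hz, Z 60–180 Hz — the *absolute* average (mean bin magnitude,
band edges inclusive) and the *relative* average, plus the time-domain RMS
per axis. "Relative" is defined here as the band mean divided by the
whole-spectrum (DC-excluded) mean magnitude: it is exactly 1 on a flat
spectrum, ≈ 1 on the white noise floor, amplitude-invariant, and > 1 when
the in-band mode is ringing. Alternative normalizations (per-bin maximum,
power share) were considered and rejected as either less stable per window
or not noise-referenced; averaging squared magnitudes instead of magnitudes
is available via a `power` switch. All features are non-negative; scaling a
window by c > 0 scales absolute/RMS features by c and leaves relative
features unchanged.

## Classifier

One data point = (11 features, velocity label) for one window; features and
labels are inner-joined on window index and invalid windows dropped. The
test set is withheld by plain uniform sampling without replacement
(stratification optional but off, matching the observed share drift between
train and test in the original study design). Training runs a seeded random
search over two scikit-learn tree-ensemble families — bagged
(`RandomForestClassifier`: trees, depth, feature fraction) and boosted
(`HistGradientBoostingClassifier`: iterations, learning rate, depth) — each
candidate scored by stratified 5-fold cross-validated accuracy; the winner
is refit on all training rows. Trees are scale-free, so no feature scaling
or class rebalancing is applied. Evaluation reports the 3×3 confusion matrix
(rows truth, columns prediction, class order resting/stationary/locomotion),
per-class TPR (diagonal over row sums) and PPV (diagonal over column sums),
overall accuracy, and the binary resting-vs-active accuracy obtained by
collapsing the two active classes. The ablation harness retrains the
identical pipeline on the feature subsets {all, X+Z, X, Y, Z} over one fixed
split. Models persist as a versioned archive of hyperparameters plus the
fitted estimator; loading refuses on a feature-name mismatch.

## Continuous monitoring

A stream is segmented into consecutive 15-s windows (anchored at the stream
start, trailing partial window discarded), each classified independently and
stamped with its start time. Summaries count per-class occurrence in 30-min
bins aligned to absolute wall-clock half-hours (configurable to
stream-relative); per-class totals are window counts × 15 s with no internal
rounding, so class hours sum to monitored hours exactly. Gaps (sensor
detachment) are represented as missing records and never imputed: bins
overlapping a gap report fewer windows, empty bins report count 0.

## Synthetic-data generator

The generator emulates the study conditions end to end so the pipeline is
testable without recordings.

* **Schedule**: a Markov chain over bouts; durations are minimum 15 s plus
  an exponential tail with class means 120 / 140 / 50 s, transitions
  symmetric between the other two classes. The implied long-run dwell
  fractions (≈ 39 / 45 / 16 %) match the class shares of the real training
  data.
* **Vibrations**: impulses arrive as Poisson processes at 0.05 / 1.2 / 3.0
  events/s for resting / stationary / locomotion (steps are the dominant
  impulse source; 2–5 steps/s during locomotion, occasional twitches while
  resting). Each impulse excites each mode with a class-conditional
  probability, adding `A·exp(−t/τ)·sin(2πft+φ)` with τ = 0.1 s and A
  log-normal (σ_log = 0.75) around the mode's base amplitude. Default modes:
  X 24–26 Hz peaked at 25 Hz, 4 mg base, excited by 30/90/90 % of impulses
  per class (X vibrations accompany any activity); Y 75–80 Hz, 1.5 mg,
  5/15/20 % (weak and infrequent); Z 80–250 Hz triangular-peaked at 120 Hz
  (the floor membrane mode), 5 mg, 10/30/65 % (mostly locomotion). Rare
  strong events (0.01/s during activity only) ring 500–1000 Hz on Z at
  12 mg, and a permanent weak 1 mg 100 Hz Z tone persists regardless of
  activity. Sensor noise, LSB quantization and full-scale clipping close the
  model. No amplitude figures exist for the real activity-induced
  vibrations; these defaults place the signals near the 6.7 mg noise floor
  so that separability is real but imperfect (locomotion TPR < 100 %), and
  a single `amplitude_scale` knob moves the whole signal-to-noise ratio.
* **Pose**: `duration·fps` per-frame speeds are drawn from the active
  class's velocity distribution (normal truncated at 0); the head moves by
  speed/fps in a uniformly random direction, reflected at the camera-frame
  walls, and the three points ride the common trajectory at fixed
  anatomical offsets. The min-of-three rule and likelihood gating are
  exercised by injected single-frame misdetection spikes (0.001/point/frame,
  100–600 px, confidently wrong) and low-likelihood dropouts
  (0.002/point/frame). Per-frame coherence jitter defaults to 0: independent
  per-frame positional noise of even 1 px would add ~25 px/s of apparent
  speed at 30 fps and contradict the 0.45 px/s resting distribution the
  generator must reproduce; static offsets plus misdetections model the
  same tracker behaviour without corrupting the speed statistics.

What the generator does **not** model: physically derived modal parameters
(frequencies/decays are stipulated, not computed from cage geometry),
bedding contact mechanics, the unexplained < 10 Hz Y-axis energy and
broadband artefacts seen in real recordings (available as off-by-default
nuisance hooks only in spirit — not implemented), multi-animal cages, and
any coupling between movement direction and which mode is excited. Passing
tests therefore demonstrate that the pipeline is correct and that the
method separates classes under the stated vibration physics — not that the
specific accuracies transfer to real recordings, whose headline numbers
depend on the original dataset.

## Determinism and numerics

Every stochastic operation takes an explicit integer seed
(`numpy.random.default_rng`); identical (config, seed) gives bit-identical
outputs. Damped sinusoids are truncated after 8 decay times (amplitude
< 4·10⁻⁴ of peak). Window counts use `floor(n_samples / (15·rate))`; window
boundaries are exact sample indices, so concatenating windows reproduces the
stream prefix sample for sample. Velocity classification rejects negative
or NaN means as contract violations rather than guessing. The all-zero
spectrum defines the relative band average as 0.

## Problem sizes used in the tests

The shipped suite exercises the full cycle at desk scale: the combined
train/eval acceptance check uses 4 h of simulated data (960 windows, test
n = 250), the axis-fusion ordering averages 10 seeds of 1 h each, the shared
monitoring model trains on 1.5 h, and bookkeeping checks on hour-scale
streams run at a reduced 20 Hz sample rate because the windowing rule
depends only on `duration × rate`. These sizes are the package's chosen
defaults for its own verification; all scale linearly if larger runs are
wanted.

## Known limitations

* The three-class taxonomy is an approximation of behaviour; atypical
  activities (e.g., manipulating cage objects) are not represented.
* The min-of-three velocity underestimates rotational movement by design.
* The classifier's locomotion/stationary boundary is intrinsically soft —
  both the velocity distributions and the vibration statistics of the two
  classes overlap.
* Wall-clock bin alignment assumes a correct `start_time` on the stream;
  no clock-drift correction between IMU and camera is attempted.
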