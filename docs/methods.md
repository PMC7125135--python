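# Methods

## The problem

Hip-worn accelerometers record whether a person moves, not whether the device
is worn. Minutes in which the device lies on a table are statistically close
to minutes in which the wearer sleeps or sits still, and mislabelling one as
the other biases every downstream physical-activity summary. This package
implements four published non-wear detection algorithms, a dual-device
procedure for constructing minute-resolution ground truth, the minute-wise
scoring used to compare them, and a synthetic dual-device generator so the
whole pipeline is testable end to end with known truth.

Throughout, the minute grid is zero-based and half-open (minute *i* covers
`[start + 60 i, start + 60 (i+1))` seconds), non-wear is the positive class,
and acceleration is in gravitational units (1 g = 9.81 m·s⁻²; 1 mg = 10⁻³ g).

## Detection algorithms

**Hecht** (`hecht`) votes per minute on the 60-s vector-magnitude count (VMU =
√(cx²+cy²+cz²)): (1) VMU > 5, (2) ≥ 2 of the following 20 minutes exceed 5,
(3) ≥ 2 of the preceding 20 minutes exceed 5; wear iff at least two conditions
hold. Windows truncated by the recording boundary are evaluated over the
minutes that exist, so the first and last minutes of a recording are still
classified.

**Troiano** (`troiano`) scans a single count axis (or the VMU) for maximal
runs of zero-count minutes, tolerating up to 2 "artificial movement" spike
minutes with counts strictly between 0 and 100 per run, cumulatively; a
minute at or above the upper bound terminates the run. Runs of ≥ 60 minutes
are non-wear, spike minutes included. When the lower spike bound is raised
above 0, values at or below it count as "zero" — this is what lets a tuning
grid explore the minimum spike threshold as a hyperparameter.

**Choi** (`choi`) scans for zero-count runs of ≥ 90 minutes and may absorb a
burst of up to 2 consecutive non-zero minutes, but only when the 30 minutes
immediately upstream and downstream of the burst contain no non-zero minute
(window spike allowance 0 by default). Scanning is a single left-to-right
pass; absorbed bursts are not re-examined. Flank windows truncated at the
recording boundary are evaluated over the minutes that exist.

**van Hees** (`hees`) works on the raw signal: windows of 60 minutes are
placed at every multiple of the 15-minute step; a window is flagged when ≥ 2
of 3 axes have a standard deviation < 3 mg *or* ≥ 2 of 3 axes have a value
range < 50 mg. A minute is non-wear iff at least one flagged window covers it
(union rule). The union rule is stated explicitly because overlapping flagged
windows need a resolution convention and the union maximizes boundary
sensitivity; some raw-data toolchains instead trim to window cores, which is
a known divergence risk. The trailing partial window is not evaluated.
Window statistics use the population standard deviation: windows contain
tens of thousands of samples, so the sample/population distinction is
far below the 3 mg threshold, and the population form matches a streaming
sum/sum-of-squares implementation exactly (accumulated in float64).

## Surrogate activity counts

Commercial raw-to-count conversions are proprietary, so the package defines
its own (`surrogate_counts`), fully specified: per axis, subtract a 1-s
centered moving average (gravity removal), rectify, zero everything below a
10 mg deadband, sum per epoch, scale by 100 and round. 10-s epochs are summed
to the 60-s epochs the count algorithms expect (`sum_epochs`). Stillness maps
to exactly zero counts; counts grow monotonically with movement amplitude
above the deadband; adding a constant offset to an axis leaves counts
unchanged (an abrupt offset *step* leaks about half the step height into the
1-s neighbourhood of the boundary, so only steps below twice the deadband are
count-free). These counts are internally consistent across the package but
make no claim of magnitude equivalence with any vendor's scale.

## Signal preparation

ENMO (Euclidean norm minus one, `max(√(x²+y²+z²) − 1, 0)`, clamped at zero)
is the amplitude metric for raw streams. Sample-rate conversion is
band-limited sinc filtering implemented as polyphase resampling
(`scipy.signal.resample_poly`, linear-trend padding so gravity offsets pass
the edges); the contract is behavioural — a 1 Hz sinusoid converted from
100 Hz to 32 Hz stays within 10⁻³ g of the analytic signal away from the
edges — rather than a particular kernel. Two streams are synchronized by
resampling the faster one to the slower rate and trimming both to the
overlapping span (`synchronize`).

## Dual-device gold standard

A 4 mg per-minute standard-deviation threshold on all three hip axes defines
quiescent minutes; maximal quiescent runs are *candidate* non-wear episodes
(`detect_candidates`). The threshold sits just above the modelled
accelerometer noise floor; requiring all three axes (rather than an
aggregate) is stated explicitly as the package's convention.

Candidates are disambiguated with the chest device: worn stillness shows a
heart rate and closely coupled acceleration on both devices; hip-off time
shows chest activity the hip never saw; both-off time silences the heart-rate
channel. Each candidate is summarized by 41 features: ten statistics (mean,
SD, min, max, excess kurtosis, signal-to-noise ratio = mean/SD, mode, median,
range, variance) for each of hip ENMO, chest ENMO and heart rate (30), one
inter-device DTW lower bound (1), and the hip−chest difference of the ten
ENMO statistics (10). The count works out only if the DTW term is a single
pairwise feature rather than a per-stream statistic, which is also the only
reading consistent with DTW being a two-sequence quantity. Conventions the
feature list does not fix are pinned here: SNR and kurtosis of a constant
stream are 0; the mode is computed on values rounded to 3 decimals (mg
resolution for ENMO in g), smallest value winning ties.

The DTW lower bound is the Keogh envelope bound: the squared exceedance of
one sequence outside the running min/max envelope of the other, summed, with
the envelope half-width a Sakoe-Chiba band of 10 s of samples, symmetrized as
`max(LB(a,b), LB(b,a))`. It lower-bounds the exact DTW distance restricted to
warping paths inside the same band — the property the test suite verifies
against a full dynamic program. Identical sequences give exactly 0.

The episode classifier is a contract, not a prescribed family: any binary
classifier over the (standardized, degree-2 polynomial-expanded) feature
space. The reference implementation is a regularized logistic regression in
an sklearn `Pipeline`, so the scaler and expansion fitted on training data
are replayed identically at prediction time. Long (> 120 min) candidates
classified as wear are flagged for review rather than silently accepted or
auto-corrected: long quiescent candidates are overwhelmingly true non-wear,
and a flag keeps the human in the loop without hard-coding an override.

## Evaluation and tuning

Scoring is minute-wise with non-wear positive: accuracy (TP+TN)/total,
precision TP/(TP+FP), recall TP/(TP+FN), F1 the harmonic mean. Degenerate
denominators resolve to 0, which penalizes empty predictions consistently.
Pooling across recordings is micro-averaged — confusion counts are summed
before ratios are taken — matching the minute-level framing and avoiding the
averaging-of-ratios pitfall; whether to pool or average per recording is a
genuine design fork and the pooled choice is asserted by a dedicated test.
The day-phase filter restricts scoring to minutes whose clock time falls in
[07:00, 23:00).

Grid sweeps (`run_grid`) enumerate the cartesian product of per-parameter
value lists in lexicographic order, pool counts over the dataset per
combination, and report per-metric argmax rows with first-row tie-breaking.
Tuning (`tune_cv`) performs k = 10 repetitions of recording-level stratified
70/30 holdouts (stratified on whether a recording contains any non-wear;
recordings, the participant analogue, never straddle a split), picks the
F1-argmax parameters on each training side, scores them on the held-out
side, and reports the modal winner (ties → highest mean test F1). The
source literature describes this step as "10-fold cross-validation with
70/30 splits", an internally contradictory phrase (10 folds imply 90/10);
repeated stratified holdouts are what those proportions admit, and the
implementation says so in its docstring.

## The synthetic generator

`simulate_dual_recording` emulates the statistical structure of free-living
dual-device data: a 100 Hz hip stream, a 32 Hz chest stream, a 1 Hz
heart-rate channel (0 bpm encodes "no wearer"), and minute-level ground
truth. Key parameters (units, defaults):

| parameter | default | role |
|---|---|---|
| `duration_hours` | 24 | one free-living day |
| `hip_rate` / `chest_rate` | 100 / 32 Hz | device sampling rates |
| `n_short_episodes` / `n_long_episodes` | 2 / 0 | planted non-wear per day |
| `short_duration_mean` (SD) | 11 (9.9) min | log-normal, truncated to [1, 60) |
| `long_duration_mean` (SD) | 355 (204.1) min | normal, truncated to [60, 720) |
| `short_peak_window` | 06:00–08:00 | morning showers etc. |
| `long_peak_window` | 00:00–08:00 | devices removed for sleep |
| `wear_burst_amplitude` | 0.3 g | band-limited (0.5–3 Hz) movement |
| `sedentary_noise_sd` | 2 mg | worn noise floor (< 4 mg ⇒ worn stillness is candidate-quiescent) |
| `nonwear_noise_sd` | 1 mg | unworn noise floor |
| `turnover_interval_mean` | 20 min | sleep posture changes |
| `gentle_turnover_frac` / `gentle_amplitude` | 0.6 / 4 mg | movements near the count deadband |
| `sedentary_bout_mean` / `active_bout_mean` | 30 / 10 min | daytime alternation |
| `drift_deg_per_min` | 0.2° | worn orientation random walk |

Duration families: the short/long means and SDs and the time-of-day windows
parametrize the generator; the log-normal (right-skewed) versus truncated
normal (broad) family assignment reflects the qualitative shapes of observed
free-living episode-duration histograms — the histograms themselves are not
data here. Durations are drawn exactly from the moment-matched family
discretized to integer minutes (probability ∝ F(k+1) − F(k), renormalized on
the truncation support), so degenerate supports need no rejection loops.
Episode start minutes are rejection-sampled from the peak windows; when start
resampling alone deadlocks (a long episode that cannot avoid already-placed
short ones), the duration is redrawn from its family every 50 attempts, and
after 1000 attempts the configuration is rejected as infeasible. The default
configuration yields on average ≈ 1.7% non-wear per day, matching the share
reported for free-living cohorts; the benchmark configuration used to compare
algorithms (`evaluation_config`) adds one long night episode.

The signal model encodes one physical asymmetry that the entire problem
hinges on: **a worn device is never flat at the hour scale**. While worn, the
gravity orientation performs a slow random walk plus two incommensurate slow
oscillations (35- and 45-min periods, ~4–5° amplitude, random phases), built
from per-minute angle increments; within one minute this contributes ~1 mg —
far below the 4 mg candidate threshold, so sleep and sedentary minutes are
correctly quiescent — but across a 60-min window it moves each axis by tens
of mg, so worn stillness fails the raw algorithm's std/range gates. Unworn
stretches freeze the orientation (increments zeroed, hence no boundary
jumps) and drop to the 1 mg noise floor: flat at every scale. The base tilt
is kept between 35° and 55° so no axis degenerates to second-order
sensitivity.

Sleep contains posture changes every ~20 min; 60% are *gentle* (≈4 mg, at
the surrogate-count deadband), producing occasional small count values — the
artificial-movement spikes that Troiano's tolerance merges across (inflating
its false episodes) while Choi's clean-flank rule refuses to absorb them.
The remaining strong turnovers produce large counts that terminate runs for
both. During hip-off episodes the chest stream keeps its movement (plus
intermittent bursts on ~30% of minutes) and the heart-rate channel stays
active, so the inter-device contrast that the gold standard exploits is
present by construction.

What the generator does *not* emulate: realistic activity-intensity
distributions, device calibration error and axis cross-talk, temperature
drift, autocorrelated heart-rate physiology beyond an AR(1) wander, idle
sleep modes, and the visual-inspection labelling noise of real gold-standard
construction. Passing the pipeline tests therefore demonstrates internal
correctness and the qualitative precision/recall structure of the four
algorithms under the modelled regime — not their numeric scores on any real
cohort, which depend on cohort-specific movement statistics.

## Numerical choices

Generation is float32 (a day of 100 Hz triaxial data at float64 would double
memory for no modelled benefit: the noise floor is 1–2 mg, float32 resolution
near 1 g is ~0.1 µg); all statistics are accumulated in float64. Interpolated
gravity knots 0.3° apart deviate from unit norm by < 4 × 10⁻⁶ g, so
renormalization is skipped. Movement noise is band-passed at 8 Hz and
linearly interpolated to the device rate (content is 0.5–3 Hz). Minute
windows take `round(60 × rate)` samples; trailing partial epochs/groups are
dropped with a logged warning.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` exercise: exact oracle agreement
on 1000 random count series (≤ 300 min); the DTW bound on 500 random pairs
(≤ 50 samples); metric identities on 1000 random label pairs; candidate
recall on 100 simulated days; algorithm comparison pooled over 6 days
(micro-averaged, the multi-participant analogue — single days are dominated
by their one long episode and noisier); and a 400-episode classifier set
with an 80/20 split. These sizes give stable statistics at interactive
runtimes; all scale linearly if enlarged.

## Known limitations

* The surrogate count scale is package-internal; tuned count thresholds
  (e.g. spike bounds) are not transferable to vendor counts.
* `hees` labels whole minutes via full flagged windows; boundary precision is
  limited by the 15-min step, and the union rule differs from toolchains
  that trim to window cores.
* The Choi implementation is single-pass; an iterative re-examination of
  absorbed bursts could differ on adversarial series.
* The episode classifier is trained on clean single-scenario episodes;
  candidates that straddle a scenario change (e.g. a short hip-off episode
  embedded in sleep merging with flanking quiescent sleep minutes) are
  genuinely ambiguous and are where its errors concentrate.
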