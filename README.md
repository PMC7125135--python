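# nonwear

Detection and evaluation of accelerometer **non-wear time** — the minutes in
which a body-worn activity monitor is not actually on the body. Non-wear
minutes that slip into an analysis masquerade as sedentary time and bias
every physical-activity summary derived from the recording, so epidemiology
pipelines must label and remove them before computing anything else.

The package is aimed at researchers processing hip-worn actigraphy
(epidemiological cohorts, validation studies) and provides, as a plain
Python library:

* the four classic detection algorithms — **Hecht**, **Troiano** and
  **Choi** on 60-s activity-count epochs, and **van Hees** on raw
  acceleration — each with its published default hyperparameters exposed as
  tunable dataclasses;
* the **dual-device gold-standard construction**: candidate non-wear
  episodes from quiescent hip-signal minutes, disambiguated from sleep and
  sedentary time by a 41-feature classifier that compares the hip stream
  against a simultaneously worn chest device with a heart-rate channel;
* **minute-wise evaluation** (accuracy / precision / recall / F1, non-wear
  positive, micro-averaged across recordings), day-phase filtering, grid
  sensitivity sweeps and cross-validated hyperparameter tuning;
* a **synthetic dual-device generator** with known minute-level ground
  truth, so the full pipeline is testable without access-restricted cohort
  data.

## The algorithms in brief

With `c` the per-minute counts and VMU = √(cx² + cy² + cz²):

* **Hecht** — minute `m` is wear iff ≥ 2 of: VMU(m) > 5; ≥ 2 of the next 20
  minutes have VMU > 5; ≥ 2 of the previous 20 minutes do.
* **Troiano** — non-wear = maximal runs ≥ 60 min of zero-count minutes,
  tolerating ≤ 2 spike minutes with 0 < c < 100 per run.
* **Choi** — non-wear = zero-count runs ≥ 90 min; a ≤ 2-min non-zero burst
  is absorbed only if the 30 min up- and downstream are spike-free.
* **van Hees** — on raw data: 60-min windows every 15 min; a window is
  flagged if ≥ 2 axes have SD < 3 mg or ≥ 2 axes have range < 50 mg; a
  minute is non-wear iff some flagged window covers it.

The scientific crux is that worn stillness (sleep, sitting) and true
non-wear are nearly indistinguishable minute-by-minute, but differ at the
hour scale: a worn device always drifts (posture, breathing), an unworn one
is flat. The raw-signal algorithm can see this; count-based algorithms
cannot, which is why their false-positive behaviour differs so sharply —
and why a second device plus heart rate is needed to build ground truth at
all.

## Worked example

```python
import nonwear as nw

# one simulated free-living day: 100 Hz hip + 32 Hz chest + 1 Hz heart rate,
# with short morning and long night non-wear planted on the hip device
hip, chest, heart_rate, truth = nw.simulate_dual_recording(nw.evaluation_config(seed=1))

counts60 = nw.sum_epochs(nw.surrogate_counts(hip, epoch_length=10.0), factor=6)
for name, labels in [("hecht", nw.hecht(counts60)), ("troiano", nw.troiano(counts60)),
                     ("choi", nw.choi(counts60)), ("hees", nw.hees(hip))]:
    counts, m = nw.score_minutes(truth.minute_labels, labels)
    print(f"{name:8s} precision={m.precision:.3f} recall={m.recall:.3f} f1={m.f1:.3f}")
```

prints

```
hecht    precision=0.356 recall=1.000 f1=0.525
troiano  precision=0.417 recall=0.901 f1=0.570
choi     precision=0.582 recall=1.000 f1=0.736
hees     precision=0.991 recall=0.896 f1=0.941
```

Read: this day has 365 true non-wear minutes (one 329-min night episode,
two short morning ones). The count-based scanners find essentially all of
it (high recall) but also flag large parts of sleep (low precision), Hecht
worst because it flags every still minute, Choi least because of its longer
interval and flank checks. The raw-signal algorithm keeps precision near 1 —
worn sleep is never flat over a full hour — and loses a little recall at
episode boundaries because it labels whole 60-min windows on a 15-min step.

The `examples/` directory holds one narrative script per capability:
simulation, detection/scoring, gold-standard construction, and
sensitivity/tuning. A thin CLI mirrors the pipeline for shell use
(`nonwear simulate | epochs | detect | export-truth | evaluate | tune`).

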