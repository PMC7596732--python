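# cagewatch

Continuous home-cage monitoring platforms read two vital signs straight out of
cage video: **body motion** (locomotor speed, mm/s, from dense optical flow)
and **breathing rate** (breaths/min, from periodic chest motion while the
animal is still). In longitudinal toxicology and pharmacology studies — for
example paraquat-induced lung injury in rats — these digital readouts track
injury onset and progression hour by hour, without handling the animal.

`cagewatch` is a tested, reusable implementation of that analysis chain for
scientists who want to validate, extend, or reanalyse such readouts:

1. **Motion extraction** — per-second speed from frame pairs:
   `v = |mean flow over animal pixels| × mm/px × fps`, with the animal
   segmented by background subtraction against a rolling median frame.
2. **Breathing detection** — maximal runs of > 30 s below a stationarity
   threshold; within them, the chest region is localised as the dominant
   cluster of band-limited (1–3 Hz ≙ 60–180 bpm) temporal power, and each
   30 s window's periodogram peak is read out as bpm when the peak RMS
   amplitude of the band-passed component exceeds a calibrated threshold.
3. **Circadian aggregation** — per-study-day means (day 06:00–18:00 /
   night 18:00–06:00 for motion; full 06:00→06:00 day for breathing rate),
   baseline-normalised by each animal's acclimation mean (Days −5..−2;
   body weight and temperature against the single Day −7 value).
4. **Study statistics** — noncentral-*t* design power
   (power of the two-sample *t* at Δ = 0.30·107 bpm, σ = 13, n = 8/group,
   α = 0.05), Welch contrasts with Satterthwaite df, Pearson correlation and
   least-squares regression of endpoint breathing rate against pathology,
   and the ≥ 20 % body-weight-loss humane-endpoint rule.

Because no public cage-video dataset accompanies this kind of platform, the
package ships a first-class **synthetic generator**: a two-state (rest/active)
behaviour chain with photoperiod-dependent occupancy, a rendered rat (soft
ellipse with a chest disc whose radius oscillates at the true breathing
frequency), and cohort-level daily/endpoint tables with a configurable
correlation between final-day breathing rate and a lung-weight proxy. Every
pipeline stage is validated against this ground truth.

## Worked example

```python
import cagewatch as cw

# a 90 s clip of a resting rat in a 240x180 mm cage
cfg = cw.SimConfig(duration_s=90, cage_w_mm=240, cage_h_mm=180,
                   body_len_mm=110, body_wid_mm=40, chest_r_mm=10,
                   rest_prob_day=1.0, rest_prob_night=1.0, seed=3)
frames, truth = cw.simulate_session(cfg)

trace = cw.motion_trace(frames)                       # per-second mm/s
samples = cw.breathing_series(frames, trace, cw.DetectionConfig())
for _, s in samples.iterrows():
    print(f"{s.window_start:%H:%M:%S}  {s.bpm:6.1f} bpm  "
          f"power {s.peak_rms_power:5.2f}  significant={s.significant}")
print(f"true breathing rate: {truth.per_second.bpm.mean():.1f} bpm")
print(f"design power: {cw.power_two_sample_t(cw.PowerSpec()):.3f}")
```

prints

```
06:00:00   101.6 bpm  power  4.38  significant=True
06:00:30   101.9 bpm  power  4.42  significant=True
06:01:00   101.0 bpm  power  4.30  significant=True
true breathing rate: 101.5 bpm
design power: 0.996
```

Each line is one 30 s analysis window inside the detected stationary
interval: the read-out rate sits within ~0.5 bpm of this animal's true rate
(its baseline was drawn from Normal(107, 13)), and the peak RMS power is far
above the 0.5 significance threshold. The design power is the probability
that a two-sample *t*-test at α = 0.05 detects a 30 % breathing-rate increase
with 8 animals per group — the basis for the n = 8 design.

A command-line interface covers the same stages
(`cagewatch simulate | extract-motion | detect-breathing | aggregate | stats
| run-all`); `run-all --config cfg.yaml --out DIR` chains everything on a
synthetic fixture plus a simulated two-group cohort and writes all CSV/JSON
artifacts.

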