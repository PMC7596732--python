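# Methods

This note documents the models behind `cagewatch`, the parameters that
matter, the synthetic data the pipeline is validated on, and the numerical
choices made where the design was genuinely open.

## Body-motion readout

Consecutive grayscale frames are registered with iterative Lucas–Kanade
dense optical flow (`skimage.registration.optical_flow_ilk`, radius 5,
3 warps). Both frames are mean-subtracted first, which makes the estimate
exactly invariant to global additive illumination changes (day/night
background shifts). Flow is estimated only inside the animal's bounding box.

The animal mask is the union of two background-subtraction cues against a
rolling median frame (60 s window, 1 fps samples): deviation from the median
frame itself (a moving animal against any static scene) and deviation from
the scene's flat-field level, taken as the median intensity of the background
frame. The second cue keeps a long-resting animal segmented after the
temporal median has absorbed it; the first cue is gated at half-threshold
against the flat-field level to suppress "ghost" pixels where the median
still contains an animal that has moved away. The intensity threshold
defaults to 25 (8-bit units).

Per-frame-pair speed is `|mean flow vector over the mask| × mm/px × fps`.
The mean **vector** (rather than the mean of per-pixel magnitudes) is used
because local flow in textureless body interiors is essentially noise with
random direction: for rigid translation the two statistics coincide, while
incoherent noise largely cancels in the vector mean (≈ 0.07 px vs ≈ 0.16 px
on static scenes at pixel-noise SD 4). The magnitude-mean alternative remains
available via `MotionConfig.speed_stat = "magnitude_mean"`, and a whole-frame
mode (no mask) via `whole_frame=True`. Per-second speed is the unweighted
mean of the pair speeds inside that second; seconds with an empty mask carry
NaN, never zero.

## Breathing-rate readout

Stationary intervals are maximal runs of consecutive seconds with speed
below 5 mm/s lasting strictly more than 30 s; NaN seconds and timestamp gaps
break runs. The 5 mm/s default leaves roughly half the noise-floor margin of
the optical-flow speed on resting fixtures (~3 mm/s).

Within an interval, the chest is localised from per-pixel temporal spectra
over (up to) the first 120 s: pixels whose power in the breathing band
(default 60–180 bpm = 1–3 Hz, bracketing the ~107 bpm control baseline) is
above 10 % of the peak (capped at the 97th percentile) are clustered; the
connected component with the most band power, morphologically closed and
hole-filled (the oscillating chest boundary traces a ring), is the ROI. If no
pixel's band-power fraction reaches 0.35 the window is flagged empty — pure
noise without periodic motion never advances to rate estimation. The chest
signal is the linearly detrended per-frame mean ROI intensity.

Each 30 s window (stride 30 s, non-overlapping) is detrended and searched
over the band in its Hann-windowed periodogram. The peak is refined by
quadratic interpolation of log power (errors ≪ one 2 bpm bin on noiseless
input) and read out as bpm. Exact periodogram ties resolve to the lower
frequency. The significance statistic is the RMS amplitude of the signal
band-passed ±0.15 Hz around the peak ("peak RMS power"); a window is
significant when it exceeds `power_threshold`. A pure spectral-peak-height
alternative (`power_mode="peak_height"`) estimates the same RMS from the
Hann periodogram peak.

`power_threshold = 0.5` (8-bit intensity units) was calibrated on
breathing-free noise signals at the chest-ROI noise scale of the default
render (ROI-mean noise SD up to 1.0): the 99th percentile of the noise peak
RMS is ≈ 0.25, so the threshold sits 2× above the noise ceiling while a
sinusoid at signal-to-noise ratio 3 carries RMS ≈ 1.3, 2.6× above it. False
significant windows on noise are therefore far below the 1 % design rate.
The threshold is global, not per-animal adaptive; it is an intensity-scale
quantity, so recordings with very different contrast or ROI sizes should be
recalibrated (the band-power-fraction gate is scale-free and provides the
first line of specificity).

## Circadian aggregation and baselines

Photoperiods are half-open: day = [06:00, 18:00), night otherwise. Study
days run 06:00→06:00 with Day 0 starting at the 06:00 boundary at or before
induction; this single boundary is used for body motion and breathing alike
(the breathing-rate day is defined 06:00-to-06:00, and using the lights-on
boundary for motion keeps each night bout within one study day). Daily means
are unweighted over available samples; counts are reported and nothing is
imputed. Baselines are the unweighted mean of study days −5..−2; missing
acclimation days simply drop out, and a fully empty window is an error.
Weight/temperature changes subtract the single Day −7 measurement. The clock
is a fixed study-local label; no DST handling.

Two identities follow and are asserted in tests: with all four acclimation
days present the acclimation-window deltas average to exactly zero, and
adding a constant to all raw values shifts baselines but no delta.

## Study statistics

Design power is the power of the two-sided two-sample pooled *t*-test via
the noncentral-*t* distribution with df = 2n−2 and noncentrality
Δ/(σ√(2/n)); a vectorised Monte-Carlo mode (default 10⁵ replicates) agrees
with the closed form to < 0.005. Defaults (107 bpm, σ = 13, n = 8, 30 %
increase, α = 0.05) give power 0.996. Sidedness is a flag; the pooled test
is used for design (the power statement predates any variance inequality),
while the actual group contrasts use Welch's *t* with Satterthwaite df.
Two zero-variance groups with equal means return p = 1 by convention.
Pearson r uses the *t*-transform for its two-sided p; zero-variance inputs
yield a flagged undefined result. No multiplicity correction is applied by
default (per-day contrasts are reported unadjusted); Holm adjustment is
available. The humane-endpoint rule flags the first day weight falls to
≤ 80 % of the Day 0 reference — the comparison is done on weights, not on a
rounded loss fraction, so a loss of exactly 20 % flags — and stays on.
Day 0 is used as the reference because dosing-day weight is the last value
before the insult.

## Synthetic generator

The generator is the package's test bed; its defaults are the study
conditions the pipeline is validated under.

**Behaviour.** Rest/active alternation is a continuous-time two-state chain.
`rest_prob_day`/`rest_prob_night` are per-minute probabilities of entering
rest while active, converted to hazards −ln(1−p)/60 s⁻¹ (so p = 1 means
immediate rest and a whole-timeline rest bout); rest bouts are
Exp(300 s) regardless of photoperiod; active hazards are re-drawn at
photoperiod boundaries (memoryless). Defaults (0.60/min day, 0.067/min
night) give rest occupancies of ≈ 0.82 (day) and ≈ 0.26 (night), putting
≈ 76 % of rest time — and therefore of breathing-rate captures — in the
lights-on hours, matching the day-dominant capture pattern of home-cage
systems with nocturnal rodents. During active bouts the centroid walks at
100 mm/s (log-normal CV 0.25, heading diffusion 0.6 rad/s) with reflecting
cage walls; at rest it is fixed.

**Breathing.** Each animal's baseline is Normal(107, 13) bpm; around it a
slow Ornstein–Uhlenbeck wander (SD 3 bpm, τ = 600 s) and a ±2.5 bpm
square-wave circadian term (higher at night). The lung-injury effect is zero
until 16 h post-induction, rises linearly to its peak (default 32 bpm
≈ 30 % of baseline) at Day 2, then decays exponentially (τ = 4 d) toward a
positive plateau (25 % of peak) so the elevation persists through Day 14.
Per-animal effect size scales with a latent severity
(CV 0.30), which also drives weight loss, motion suppression, and the
histology-score proxies.

**Rendering.** The cage is a flat background (120 day / 40 night, 8-bit);
the rat is a soft-edged ellipse (220×70 mm at 2 mm/px by default; the test
fixtures use a 110×40 mm juvenile in a 240×180 mm cage to keep flow fast)
of intensity 200 with a brighter chest disc (r = 16 mm) centred 45 % along
the front semi-axis. The disc radius oscillates sinusoidally at the
instantaneous true frequency with amplitude `chest_amp_px` (default 0.5 px;
0.15 px puts the extracted chest-signal SNR near 3 at the default pixel
noise SD 4). The breathing phase integrates the per-second frequency, so
rate changes are continuous. Night is a scalar background change only.
Everything is deterministic given the seed.

**Cohort tables.** Daily per-animal breathing means are baseline +
day-to-day noise (SD 5 bpm) + the injury delta averaged over the
06:00→06:00 day; motion means follow the chain's photoperiod occupancies
suppressed by up to 50 % at peak injury; weights grow 2 g/day with
severity-scaled loss. The endpoint lung-weight proxy is constructed against
the *measured* final-day breathing rate using the generator's analytic
population moments, so the population correlation equals `endpoint_r`
(default 0.7) exactly and Fisher-z interval coverage is nominal.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: fur texture and non-rigid posture change (flow
on real video is noisier than on rendered ellipses), camera distortion and
perspective, bedding disturbance and enrichment occlusion, multi-animal
housing, sniffing/grooming micro-movements that contaminate stationarity,
and breathing waveform asymmetry (the rendered chest is purely sinusoidal).
The detection thresholds validated here should be treated as a starting
point for real recordings, not as transferable constants.

## Numerical choices and scaled-down problem sizes

Ties, degenerate inputs, and edge conventions: periodogram ties break to the
lower frequency; all-constant windows are never significant; an empty animal
mask is missing data, not zero speed; exactly-30 s runs are *not* stationary
intervals (strict inequality); the 06:00 boundaries are half-open.

The test suite and the acceptance script run everything at desk scale as the
package's own validation sizes: 45–90 s rendered fixtures in a small cage,
24 h behaviour simulations without rendering, 200 replicate cohorts for the
Day 2 contrast and 500 for correlation coverage, and 10⁵ Monte-Carlo
replicates for power. Group time courses at full in-vivo scale (weeks of
video per animal) are out of scope for the bundled validation, as are pose
estimation, tidal volume, apnea detection, and plethysmographic
cross-validation.
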