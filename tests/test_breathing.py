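"""Tests of stationarity gating and spectral breathing-rate detection."""

import numpy as np
import pandas as pd
import pytest

import cagewatch as cw
from cagewatch.breathing import (
    breathing_series,
    detect_breathing_rate,
    extract_chest_signal,
    find_stationary_intervals,
)
from cagewatch.motion import trace_from_truth
from cagewatch.synthetic import FrameSequence, day_mask_for_seconds, simulate_behavior

T0 = pd.Timestamp("2024-03-01 06:00:00")


def _trace(speed, t0=T0):
    speed = np.asarray(speed, dtype=float)
    return pd.DataFrame(
        {
            "timestamp": t0 + pd.to_timedelta(np.arange(len(speed)), unit="s"),
            "speed_mm_s": speed,
            "frames_used": 24,
            "animal_present": np.isfinite(speed),
        }
    )


def brute_force_intervals(speed, thresh, min_s):
    """O(n^2) reference scanner: all maximal sub-threshold runs longer than min_s."""
    ok = [np.isfinite(v) and v < thresh for v in speed]
    out = []
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j < len(ok) and ok[j]:
                j += 1
            if j - i > min_s:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


class TestStationaryIntervals:
    def test_uniform_zero_speed_is_one_interval(self, det):
        ivs = find_stationary_intervals(_trace(np.zeros(60)), det)
        assert len(ivs) == 1 and ivs[0].duration_s == 60

    def test_alternating_speed_never_exceeds_min_duration(self, det):
        speed = np.tile([0.0] * 10 + [50.0] * 10, 6)
        assert find_stationary_intervals(_trace(speed), det) == []

    def test_exactly_thirty_seconds_is_not_enough(self, det):
        speed = np.concatenate([np.full(30, 1.0), np.full(5, 50.0)])
        assert find_stationary_intervals(_trace(speed), det) == []
        speed = np.concatenate([np.full(31, 1.0), np.full(5, 50.0)])
        assert len(find_stationary_intervals(_trace(speed), det)) == 1

    def test_missing_seconds_break_runs(self, det):
        speed = np.zeros(50)
        speed[25] = np.nan  # splits into 25 s + 24 s runs, both too short
        assert find_stationary_intervals(_trace(speed), det) == []
        speed = np.zeros(50)  # without the gap: one 50 s interval
        assert len(find_stationary_intervals(_trace(speed), det)) == 1

    def test_matches_brute_force_scanner_on_random_traces(self, det):
        """Interval finder agrees with an O(n^2) all-runs reference."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(40, 160))
            speed = rng.exponential(8.0, n)
            speed[rng.random(n) < 0.05] = np.nan
            got = [
                (iv.start_index, iv.start_index + int(iv.duration_s))
                for iv in find_stationary_intervals(_trace(speed), det)
            ]
            want = brute_force_intervals(
                speed, det.speed_threshold_mm_s, det.min_stationary_s
            )
            assert got == want


class TestDetectBreathingRate:
    def _sine(self, bpm, n=720, fps=24.0, amp=5.0, phase=0.3):
        t = np.arange(n) / fps
        return amp * np.sin(2 * np.pi * (bpm / 60.0) * t + phase)

    def test_pure_sinusoid_read_within_half_bpm(self, det):
        s = detect_breathing_rate(self._sine(120.0), 24.0, det)
        assert s.significant
        assert s.bpm == pytest.approx(120.0, abs=0.5)

    def test_white_noise_below_threshold_is_not_significant(self, det):
        rng = np.random.default_rng(1)
        s = detect_breathing_rate(rng.normal(0, 0.3, 720), 24.0, det)
        assert not s.significant

    def test_constant_signal_is_not_significant(self, det):
        s = detect_breathing_rate(np.full(720, 7.5), 24.0, det)
        assert not s.significant and np.isnan(s.bpm)

    def test_detection_invariant_to_linear_trend(self, det):
        base = self._sine(95.0) + np.random.default_rng(2).normal(0, 1, 720)
        trended = base + 4.0 + 0.02 * np.arange(720)
        a = detect_breathing_rate(base, 24.0, det)
        b = detect_breathing_rate(trended, 24.0, det)
        assert a.bpm == pytest.approx(b.bpm, abs=1e-9)
        assert a.peak_rms_power == pytest.approx(b.peak_rms_power, rel=1e-9)

    def test_noiseless_error_within_one_bin_across_band(self, det):
        """After interpolation the error stays under one periodogram bin
        (2 bpm at 30 s windows) across the whole detection band."""
        bin_bpm = 60.0 * 24.0 / 720
        for bpm in np.arange(65.0, 176.0, 7.37):
            s = detect_breathing_rate(self._sine(bpm), 24.0, det)
            assert abs(s.bpm - bpm) <= bin_bpm

    def test_median_error_at_snr3_within_two_bpm(self, det):
        """Monte-Carlo recovery of the 107 bpm baseline at SNR 3."""
        rng = np.random.default_rng(3)
        sd = 1.0
        amp = 3.0 * sd * np.sqrt(2.0)  # RMS ratio (SNR) = 3
        errs = []
        for _ in range(100):
            x = self._sine(107.0, amp=amp) + rng.normal(0, sd, 720)
            errs.append(abs(detect_breathing_rate(x, 24.0, det).bpm - 107.0))
        assert np.median(errs) <= 2.0

    def test_raising_threshold_never_adds_detections(self, det):
        rng = np.random.default_rng(4)
        signals = [
            self._sine(107.0, amp=a) + rng.normal(0, 0.5, 720)
            for a in np.linspace(0.05, 3.0, 30)
        ]
        counts = []
        for thr in [0.1, 0.3, 0.5, 1.0, 2.0]:
            cfg = det.model_copy(update={"power_threshold": thr})
            counts.append(
                sum(detect_breathing_rate(s, 24.0, cfg).significant for s in signals)
            )
        assert counts == sorted(counts, reverse=True)

    def test_wrong_window_length_raises(self, det):
        with pytest.raises(cw.InputError):
            detect_breathing_rate(np.zeros(100), 24.0, det)

    def test_band_beyond_nyquist_raises(self, det):
        cfg = det.model_copy(update={"band_hi_bpm": 200.0, "window_s": 30.0})
        with pytest.raises(cw.InputError):
            detect_breathing_rate(np.zeros(int(30 * 6.0)), 6.0, cfg)

    def test_peak_height_mode_reads_same_frequency(self, det):
        cfg = det.model_copy(update={"power_mode": "peak_height"})
        s = detect_breathing_rate(self._sine(130.0), 24.0, cfg)
        assert s.bpm == pytest.approx(130.0, abs=0.5)
        # Hann-periodogram amplitude estimate recovers the sinusoid RMS
        assert s.peak_rms_power == pytest.approx(5.0 / np.sqrt(2), rel=0.05)


class TestChestSignal:
    def test_roi_overlaps_true_chest_region(self, rest_session, rest_trace, det):
        frames, truth = rest_session
        iv = find_stationary_intervals(rest_trace, det)[0]
        _sig, roi = extract_chest_signal(frames, iv, det)
        true_mask = truth.chest_mask_at(int(iv.duration_s // 2))
        iou = (roi & true_mask).sum() / (roi | true_mask).sum()
        assert iou > 0.3

    def test_uniform_noise_without_animal_flags_empty(self, det):
        rng = np.random.default_rng(5)
        stack = rng.normal(120, 4, (40 * 24, 60, 80)).astype(np.uint8)
        frames = FrameSequence(frames=stack, t0=T0, fps=24.0, mm_per_px=2.0,
                               day=np.ones(len(stack), bool))
        iv = find_stationary_intervals(_trace(np.zeros(40)), det)[0]
        sig, roi = extract_chest_signal(frames, iv, det)
        assert sig is None and roi is None

    def test_noiseless_roi_signal_is_sinusoidal(self, det):
        cfg = cw.SimConfig(duration_s=40, rest_prob_day=1.0, rest_prob_night=1.0,
                           noise_sd=0.0, br_baseline_bpm=107.0, br_sd_bpm=0.0,
                           br_within_sd_bpm=0.0, circadian_amp_bpm=0.0, seed=6,
                           cage_w_mm=240.0, cage_h_mm=180.0, body_len_mm=110.0,
                           body_wid_mm=40.0, chest_r_mm=10.0)
        frames, truth = cw.simulate_session(cfg)
        trace = trace_from_truth(truth.per_second["speed_mm_s"].to_numpy(), frames.t0)
        iv = find_stationary_intervals(trace, det)[0]
        sig, _roi = extract_chest_signal(frames, iv, det)
        t = np.arange(len(sig)) / cfg.fps
        f = 107.0 / 60.0
        design = np.column_stack(
            [np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t), np.ones_like(t)]
        )
        coef, *_ = np.linalg.lstsq(design, sig, rcond=None)
        resid = sig - design @ coef
        r2 = 1.0 - resid.var() / sig.var()
        assert r2 > 0.99


class TestBreathingSeries:
    def test_continuous_locomotion_yields_no_samples(self, rest_session, det):
        frames, _ = rest_session
        fast = _trace(np.full(90, 80.0))
        samples = breathing_series(frames, fast, det)
        assert len(samples) == 0

    def test_ninety_second_bout_gives_three_windows(self, rest_session, rest_trace, det):
        frames, truth = rest_session
        samples = breathing_series(frames, rest_trace, det)
        assert len(samples) == 3
        assert samples["significant"].all()
        true_bpm = truth.per_second["bpm"].to_numpy()[:90].reshape(3, 30).mean(axis=1)
        assert np.abs(samples["bpm"].to_numpy() - true_bpm).max() < 2.0

    def test_no_sample_overlaps_an_active_bout(self, mixed_session, det):
        """Significant windows never cover ground-truth active seconds."""
        cfg, frames, truth, trace = mixed_session
        samples = breathing_series(frames, trace, det)
        rest = truth.per_second["bout"].to_numpy() == "rest"
        for _, row in samples[samples["significant"]].iterrows():
            s0 = int((row["window_start"] - frames.t0).total_seconds())
            assert rest[s0 : s0 + int(det.window_s)].all()

    def test_day_dominant_rest_gives_day_dominant_samples(self, det):
        """Over a simulated 24 h day, most significant readings fall in the
        lights-on hours when rest occupancy is day-dominant."""
        cfg = cw.SimConfig(duration_s=86400.0, seed=21)
        b = simulate_behavior(cfg, with_trajectory=True)
        rng = np.random.default_rng(22)
        trace = trace_from_truth(b.speed, pd.Timestamp(cfg.start_time),
                                 noise_sd=1.0, rng=rng)
        day = day_mask_for_seconds(cfg, 86400)
        n_day = n_night = 0
        t = np.arange(int(det.window_s * cfg.fps)) / cfg.fps
        for iv in find_stationary_intervals(trace, det):
            for w0 in range(0, int(iv.duration_s - det.window_s) + 1,
                            int(det.window_stride_s)):
                sec = iv.start_index + w0
                sig = 3.0 * np.sin(2 * np.pi * (107 / 60.0) * t) \
                    + rng.normal(0, 0.5, len(t))
                if detect_breathing_rate(sig, cfg.fps, det).significant:
                    if day[sec]:
                        n_day += 1
                    else:
                        n_night += 1
        assert n_day + n_night > 100
        assert n_day / (n_day + n_night) > 0.5
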