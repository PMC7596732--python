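"""Breathing-rate detection from periodic chest motion during stationary bouts.

The readout follows the continuous-monitoring recipe: find maximal >30 s runs
where the animal's speed stays below a stationarity threshold, localise the
chest region as the pixels with the highest band-limited temporal power,
average them into a 1-D signal, and in each 30 s analysis window compare the
peak RMS amplitude of the band-limited periodic component against a threshold.
Where the periodic motion is significant, the interpolated periodogram peak
frequency (x60) is the breathing rate in breaths/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing, binary_fill_holes
from scipy.signal import detrend
from skimage.measure import label as cc_label

from .config import DetectionConfig, InputError
from .synthetic import FrameSequence

BREATH_COLUMNS = ["window_start", "window_end", "bpm", "peak_rms_power", "significant"]


@dataclass(frozen=True)
class StationaryInterval:
    """A maximal run of consecutive seconds below the speed threshold."""

    start: pd.Timestamp
    end: pd.Timestamp          # exclusive (start of the first second after the run)
    duration_s: float
    start_index: int           # row index into the motion trace


@dataclass(frozen=True)
class BreathSample:
    """One 30 s-window breathing-rate reading."""

    window_start: pd.Timestamp
    window_end: pd.Timestamp
    bpm: float
    peak_rms_power: float
    significant: bool


def find_stationary_intervals(
    trace: pd.DataFrame, cfg: DetectionConfig
) -> list[StationaryInterval]:
    """Maximal runs of seconds with speed < threshold, strictly longer than 30 s.

    Missing seconds (NaN speed, absent animal, or timestamp gaps) break runs.
    """
    ts = pd.DatetimeIndex(trace["timestamp"])
    speed = trace["speed_mm_s"].to_numpy(dtype=float)
    present = (
        trace["animal_present"].to_numpy(dtype=bool)
        if "animal_present" in trace
        else np.ones(len(trace), dtype=bool)
    )
    ok = np.isfinite(speed) & present & (speed < cfg.speed_threshold_mm_s)
    if len(ts) > 1:
        gap = np.concatenate(
            ([False], np.diff(ts.asi8) != int(1e9))
        )  # non-contiguous seconds end a run
    else:
        gap = np.zeros(len(ts), dtype=bool)

    intervals: list[StationaryInterval] = []
    run_start = None
    for i in range(len(ok) + 1):
        inside = i < len(ok) and ok[i] and not (gap[i] and run_start is not None)
        if inside and run_start is None:
            run_start = i
        elif not inside and run_start is not None:
            n = i - run_start
            if n > cfg.min_stationary_s:
                intervals.append(
                    StationaryInterval(
                        start=ts[run_start],
                        end=ts[run_start] + pd.Timedelta(seconds=n),
                        duration_s=float(n),
                        start_index=run_start,
                    )
                )
            run_start = None
            if i < len(ok) and ok[i]:  # a gap both ends and starts a run
                run_start = i
    return intervals


# ---------------------------------------------------------------------------
# Chest-signal extraction
# ---------------------------------------------------------------------------


def _band_power_map(stack: np.ndarray, fps: float, cfg: DetectionConfig):
    """Per-pixel band power and total AC power over a frame stack."""
    x = stack.astype(np.float32)
    x = x - x.mean(axis=0)
    spec = np.abs(np.fft.rfft(x, axis=0)) ** 2
    freqs = np.fft.rfftfreq(x.shape[0], d=1.0 / fps)
    band = (freqs >= cfg.band_lo_bpm / 60.0) & (freqs <= cfg.band_hi_bpm / 60.0)
    band_power = spec[band].sum(axis=0)
    total = spec[1:].sum(axis=0)  # exclude DC
    return band_power, total


def extract_chest_signal(
    frames: FrameSequence,
    interval: StationaryInterval,
    cfg: DetectionConfig,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Chest ROI signal over one stationary interval.

    Localisation: within the interval, the animal's bounding box is found from
    the median frame; per-pixel band power (in the breathing band) is computed
    over up to ``roi_fit_max_s`` seconds, and the dominant contiguous region of
    top band-power pixels (above ``roi_peak_frac`` of the peak, capped at the
    ``roi_quantile`` quantile) is taken as the chest ROI.  The returned
    signal is the linearly detrended mean ROI intensity per frame.

    Returns ``(signal, roi_mask)``; ``(None, None)`` flags an empty signal
    (no animal, or no pixel with a dominant band-limited component).
    """
    fps = frames.fps
    i0 = int(round((interval.start - frames.t0).total_seconds() * fps))
    i1 = int(round((interval.end - frames.t0).total_seconds() * fps))
    if i0 < 0 or i1 > len(frames):
        raise InputError("stationary interval is not fully covered by the frames")
    stack = frames.frames[i0:i1]

    med = np.median(stack[:: max(int(fps), 1)].astype(np.float32), axis=0)
    bgval = np.median(med)
    fg = np.abs(med - bgval) > 20.0
    if fg.sum() < cfg.min_roi_px:
        return None, None
    ys, xs = np.nonzero(fg)
    pad = 3
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, stack.shape[1])
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, stack.shape[2])

    n_fit = min(len(stack), int(cfg.roi_fit_max_s * fps))
    band_power, total = _band_power_map(stack[:n_fit, y0:y1, x0:x1], fps, cfg)
    with np.errstate(invalid="ignore", divide="ignore"):
        band_frac = np.where(total > 0, band_power / total, 0.0)
    if band_frac.max() < cfg.min_band_frac:
        return None, None

    thresh = min(
        np.quantile(band_power, cfg.roi_quantile),
        cfg.roi_peak_frac * band_power.max(),
    )
    cand = band_power >= thresh
    labels = cc_label(cand, connectivity=2)
    if labels.max() == 0:
        return None, None
    # pick the component with the highest total band power
    sums = np.bincount(labels.ravel(), weights=band_power.ravel())
    sums[0] = 0.0
    best = int(np.argmax(sums))
    comp = labels == best
    # the oscillating chest boundary forms a ring; close and fill it so the
    # ROI covers the whole chest region rather than its rim
    comp = binary_fill_holes(binary_closing(comp, structure=np.ones((3, 3))))
    if comp.sum() < cfg.min_roi_px:
        return None, None

    roi = np.zeros(frames.frames.shape[1:], dtype=bool)
    roi[y0:y1, x0:x1] = comp
    sig = stack[:, y0:y1, x0:x1][:, comp].mean(axis=1).astype(np.float64)
    return detrend(sig, type="linear"), roi


# ---------------------------------------------------------------------------
# Spectral rate detection
# ---------------------------------------------------------------------------


def detect_breathing_rate(
    signal: np.ndarray,
    fps: float,
    cfg: DetectionConfig,
    window_start: pd.Timestamp | None = None,
) -> BreathSample:
    """Read the breathing rate out of one analysis window.

    The detrended signal's periodogram (Hann window) is searched over the
    configured band; the peak frequency is refined by quadratic interpolation
    of log power and read out as bpm.  ``peak_rms_power`` is the RMS amplitude
    of the signal band-passed in a narrow band (+-``rms_halfwidth_hz``) around
    the peak; the window is significant iff it exceeds ``power_threshold``.
    Exact periodogram ties break toward the lower frequency.
    """
    x = np.asarray(signal, dtype=float)
    n_expected = int(round(cfg.window_s * fps))
    if len(x) != n_expected:
        raise InputError(
            f"signal length {len(x)} != window_s*fps = {n_expected}"
        )
    if cfg.band_hi_bpm / 60.0 >= fps / 2:
        raise InputError("detection band exceeds the Nyquist frequency")
    ws = window_start if window_start is not None else pd.Timestamp(0)
    w_end = ws + pd.Timedelta(seconds=cfg.window_s)

    x = detrend(x, type="linear")
    if np.allclose(x, 0.0):
        return BreathSample(ws, w_end, float("nan"), 0.0, False)

    n = len(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    hann = np.hanning(n)
    spec = np.abs(np.fft.rfft(x * hann)) ** 2
    band = np.flatnonzero(
        (freqs >= cfg.band_lo_bpm / 60.0) & (freqs <= cfg.band_hi_bpm / 60.0)
    )
    if band.size == 0:
        raise InputError("no periodogram bins fall inside the detection band")
    k = band[int(np.argmax(spec[band]))]  # argmax takes the first (lowest) bin on ties

    # quadratic interpolation of log power around the peak
    f_peak = freqs[k]
    if 0 < k < len(freqs) - 1 and spec[k - 1] > 0 and spec[k + 1] > 0 and spec[k] > 0:
        la, lb, lc = np.log(spec[k - 1]), np.log(spec[k]), np.log(spec[k + 1])
        denom = la - 2 * lb + lc
        if denom < 0:
            delta = 0.5 * (la - lc) / denom
            f_peak = freqs[k] + np.clip(delta, -0.5, 0.5) * (freqs[1] - freqs[0])

    if cfg.power_mode == "peak_height":
        # amplitude of the fitted sinusoid from the (Hann) periodogram peak
        amp = 2.0 * np.sqrt(spec[k]) / hann.sum()
        rms = amp / np.sqrt(2.0)
    else:
        # RMS amplitude of the narrow-band component around the peak
        full = np.fft.rfft(x)
        keep = np.abs(freqs - f_peak) <= cfg.rms_halfwidth_hz
        keep[0] = False
        nb = np.fft.irfft(np.where(keep, full, 0.0), n=n)
        rms = float(np.sqrt(np.mean(nb**2)))

    return BreathSample(
        window_start=ws,
        window_end=w_end,
        bpm=60.0 * f_peak,
        peak_rms_power=float(rms),
        significant=bool(rms > cfg.power_threshold),
    )


def breathing_series(
    frames: FrameSequence,
    trace: pd.DataFrame,
    cfg: DetectionConfig,
) -> pd.DataFrame:
    """All breathing-rate readings for a frame sequence + motion trace.

    Slides ``window_s`` windows at ``window_stride_s`` through every
    stationary interval; one row per evaluated window.  Downstream
    aggregation uses only rows with ``significant == True``.
    """
    rows = []
    for interval in find_stationary_intervals(trace, cfg):
        sig, _roi = extract_chest_signal(frames, interval, cfg)
        if sig is None:
            continue
        fps = frames.fps
        wlen = int(round(cfg.window_s * fps))
        stride = int(round(cfg.window_stride_s * fps))
        for start in range(0, len(sig) - wlen + 1, stride):
            ws = interval.start + pd.Timedelta(seconds=start / fps)
            sample = detect_breathing_rate(sig[start : start + wlen], fps, cfg, ws)
            rows.append(
                {
                    "window_start": sample.window_start,
                    "window_end": sample.window_end,
                    "bpm": sample.bpm,
                    "peak_rms_power": sample.peak_rms_power,
                    "significant": sample.significant,
                }
            )
    return pd.DataFrame(rows, columns=BREATH_COLUMNS)
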