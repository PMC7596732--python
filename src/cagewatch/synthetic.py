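"""Synthetic single-rat home-cage fixtures with full ground truth.

Generates everything the analysis pipeline consumes, with known truth at every
stage: a two-state (rest/active) behaviour schedule, a bounded random-walk
trajectory, a per-second true breathing-rate series (optionally carrying a
lung-injury effect curve), rendered grayscale video frames with an oscillating
chest region, and cohort-level daily/endpoint tables with a configurable
correlation between final-day breathing rate and a lung-weight proxy.

The rendering model is deliberately minimal — a soft-edged ellipse on a flat
background whose chest disc radius oscillates at the true breathing frequency.
It exercises optical-flow speed extraction and spectral breathing detection
without attempting photorealism.
"""

from __future__ import annotations

import os
import shutil
import tempfile
import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import ConfigurationError, InjuryCurve, SimConfig

# ---------------------------------------------------------------------------
# Clock helpers
# ---------------------------------------------------------------------------


def _clock_seconds(hhmm: str) -> int:
    hh, mm = hhmm.split(":")
    return int(hh) * 3600 + int(mm) * 60


def _start_second_of_day(start_time: str) -> int:
    t = datetime.fromisoformat(start_time)
    return t.hour * 3600 + t.minute * 60 + t.second


def day_mask_for_seconds(cfg: SimConfig, n_seconds: int) -> np.ndarray:
    """Boolean lights-on mask per simulated second (half-open [on, off))."""
    sod = (_start_second_of_day(cfg.start_time) + np.arange(n_seconds)) % 86400
    on, off = _clock_seconds(cfg.lights_on), _clock_seconds(cfg.lights_off)
    if on <= off:
        return (sod >= on) & (sod < off)
    return (sod >= on) | (sod < off)


# ---------------------------------------------------------------------------
# Behaviour: two-state rest/active chain + bounded random walk
# ---------------------------------------------------------------------------


@dataclass
class BehaviorTruth:
    """Ground-truth behaviour of one simulated animal.

    ``positions`` holds per-second waypoints (n+1 rows, mm); the animal moves
    linearly between consecutive waypoints, so true per-second speed is the
    waypoint displacement and per-frame centroids are linear interpolants.
    """

    bouts: pd.DataFrame              # columns: state, start_s, end_s
    rest: np.ndarray                 # bool per second
    day: np.ndarray                  # bool per second (lights on)
    positions: np.ndarray | None     # (n+1, 2) mm, or None
    speed: np.ndarray                # mm/s per second

    @property
    def n_seconds(self) -> int:
        return len(self.rest)


def rest_occupancy(cfg: SimConfig, day: bool) -> float:
    """Stationary rest-state probability of the two-state chain in one photoperiod."""
    h_in = cfg.rest_entry_hazard(day)
    h_out = 1.0 / cfg.mean_rest_bout_s
    if np.isinf(h_in):
        return 1.0
    return h_in / (h_in + h_out)


def _next_phase_boundary(t: float, cfg: SimConfig) -> float:
    """Seconds-from-start of the next lights-on/off switch strictly after t."""
    sod0 = _start_second_of_day(cfg.start_time)
    marks = sorted({_clock_seconds(cfg.lights_on), _clock_seconds(cfg.lights_off)})
    sod = (sod0 + t) % 86400
    deltas = [(m - sod) % 86400 for m in marks]
    deltas = [d if d > 1e-9 else 86400.0 for d in deltas]
    return t + min(deltas)


def simulate_behavior(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    with_trajectory: bool = True,
) -> BehaviorTruth:
    """Simulate the rest/active bout schedule and centroid trajectory.

    Bout dynamics: while active the animal enters rest with per-minute
    probability ``rest_prob_day``/``rest_prob_night`` (continuous hazard
    -ln(1-p)/60 per second, so p=1 means instantaneous rest); rest bouts last
    Exp(``mean_rest_bout_s``) independent of photoperiod.  Active-bout hazards
    are re-drawn at photoperiod boundaries (memoryless).  During active bouts
    the centroid performs a smooth bounded random walk at
    ``active_speed_mm_s``; during rest it is fixed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    T = float(int(round(cfg.duration_s)))
    n = int(T)
    if n < 1:
        raise ConfigurationError("duration_s must round to at least 1 second")

    day_sec = day_mask_for_seconds(cfg, n)
    h_out = 1.0 / cfg.mean_rest_bout_s

    # --- continuous-time bout sequence ---
    is_day0 = bool(day_sec[0])
    state_rest = rng.random() < rest_occupancy(cfg, is_day0)
    t = 0.0
    raw: list[tuple[str, float, float]] = []
    while t < T:
        if state_rest:
            end = min(t + rng.exponential(cfg.mean_rest_bout_s), T)
            raw.append(("rest", t, end))
            t = end
            state_rest = False
        else:
            start = t
            while True:
                sod = (_start_second_of_day(cfg.start_time) + t) % 86400
                on, off = _clock_seconds(cfg.lights_on), _clock_seconds(cfg.lights_off)
                is_day = (sod >= on) & (sod < off) if on <= off else (sod >= on) | (sod < off)
                h_in = cfg.rest_entry_hazard(bool(is_day))
                if np.isinf(h_in):
                    break  # zero-length active bout: rest resumes immediately
                boundary = min(_next_phase_boundary(t, cfg), T)
                if h_in <= 0:
                    t = boundary
                else:
                    e = rng.exponential(1.0 / h_in)
                    if t + e < boundary:
                        t = t + e
                        break
                    t = boundary
                if t >= T:
                    break
            end = min(t, T)
            if end > start:
                raw.append(("active", start, end))
            state_rest = True

    # --- quantise to per-second labels (state at second midpoint) ---
    rest_sec = np.zeros(n, dtype=bool)
    for state, s, e in raw:
        if state == "rest":
            lo = int(np.ceil(s - 0.5))
            hi = int(np.ceil(e - 0.5))
            rest_sec[max(lo, 0) : min(hi, n)] = True

    # rebuild maximal per-second bouts from the quantised labels
    edges = np.flatnonzero(np.diff(rest_sec.astype(int))) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [n]))
    bouts = pd.DataFrame(
        {
            "state": np.where(rest_sec[starts], "rest", "active"),
            "start_s": starts.astype(float),
            "end_s": ends.astype(float),
        }
    )

    # --- trajectory ---
    speed = np.zeros(n)
    positions = None
    if with_trajectory:
        mx = cfg.body_len_mm / 2 + 2 * cfg.mm_per_px
        my = cfg.body_wid_mm / 2 + 2 * cfg.mm_per_px
        lo = np.array([mx, my])
        hi = np.array([cfg.cage_w_mm - mx, cfg.cage_h_mm - my])
        if np.any(hi <= lo):
            raise ConfigurationError("cage too small for the animal footprint")
        positions = np.empty((n + 1, 2))
        positions[0] = rng.uniform(lo, hi)
        heading = rng.uniform(0, 2 * np.pi)
        sig = cfg.speed_cv
        for i in range(n):
            if rest_sec[i]:
                positions[i + 1] = positions[i]
                continue
            heading += rng.normal(0.0, cfg.turn_sd_rad)
            step = cfg.active_speed_mm_s * rng.lognormal(-0.5 * sig * sig, sig)
            p = positions[i] + step * np.array([np.cos(heading), np.sin(heading)])
            for k in range(2):
                if p[k] < lo[k]:
                    p[k] = 2 * lo[k] - p[k]
                    heading = np.pi - heading if k == 0 else -heading
                elif p[k] > hi[k]:
                    p[k] = 2 * hi[k] - p[k]
                    heading = np.pi - heading if k == 0 else -heading
            p = np.clip(p, lo, hi)
            positions[i + 1] = p
            speed[i] = float(np.hypot(*(p - positions[i])))

    return BehaviorTruth(
        bouts=bouts, rest=rest_sec, day=day_sec, positions=positions, speed=speed
    )


# ---------------------------------------------------------------------------
# Breathing-rate schedule and the injury effect curve
# ---------------------------------------------------------------------------


def injury_delta(
    curve: InjuryCurve, t_post_s: np.ndarray | float, peak_delta_bpm: float | None = None
) -> np.ndarray:
    """Breathing-rate increase (bpm) at time(s) ``t_post_s`` after induction.

    Zero before onset, linear rise to the peak at ``peak_day``, exponential
    decay toward ``plateau_frac * peak`` afterwards (always positive past
    onset, through study end).
    """
    peak = curve.peak_delta_bpm if peak_delta_bpm is None else peak_delta_bpm
    t = np.asarray(t_post_s, dtype=float)
    onset = curve.onset_h * 3600.0
    t_peak = curve.peak_day * 86400.0
    tau = curve.decay_tau_days * 86400.0
    plateau = curve.plateau_frac * peak
    rise = peak * (t - onset) / (t_peak - onset)
    decay = plateau + (peak - plateau) * np.exp(-(t - t_peak) / tau)
    out = np.where(t < onset, 0.0, np.where(t <= t_peak, rise, decay))
    return out


def simulate_breathing_schedule(
    cfg: SimConfig,
    group: str = "control",
    n_seconds: int | None = None,
    induction_offset_s: float = 0.0,
    rng: np.random.Generator | None = None,
    baseline_bpm: float | None = None,
    severity: float | None = None,
) -> np.ndarray:
    """Per-second true breathing rate (bpm) for one animal.

    The series is a per-animal baseline Normal(``br_baseline_bpm``,
    ``br_sd_bpm``) plus a slow Ornstein-Uhlenbeck wander
    (sd ``br_within_sd_bpm``, time constant ``br_within_tau_s``), a square-wave
    circadian term (+amp/2 at night, -amp/2 in the day), and, for
    ``group="injured"``, the injury effect curve whose per-animal peak is
    ``peak_delta_bpm * (1 + severity_delta_cv * severity)``.

    ``induction_offset_s`` is the simulation time at which induction occurs
    (may be negative if the animal was dosed before the recording starts).
    """
    if group not in ("control", "injured"):
        raise ValueError(f"unknown group {group!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s)) if n_seconds is None else int(n_seconds)

    base = rng.normal(cfg.br_baseline_bpm, cfg.br_sd_bpm) if baseline_bpm is None else baseline_bpm
    rho = np.exp(-1.0 / cfg.br_within_tau_s)
    z = rng.standard_normal(n)
    wander = lfilter(
        [np.sqrt(1 - rho * rho) * cfg.br_within_sd_bpm], [1.0, -rho], z
    )
    wander += rng.normal(0.0, cfg.br_within_sd_bpm) * rho ** np.arange(n)

    day = day_mask_for_seconds(cfg, n)
    circ = np.where(day, -0.5, 0.5) * cfg.circadian_amp_bpm

    bpm = base + wander + circ
    if group == "injured":
        if cfg.injury is None:
            raise ConfigurationError("group='injured' requires cfg.injury to be set")
        if severity is None:
            severity = float(rng.standard_normal())
        peak = max(cfg.injury.peak_delta_bpm * (1 + cfg.severity_delta_cv * severity), 0.0)
        t_post = np.arange(n, dtype=float) - induction_offset_s
        bpm = bpm + injury_delta(cfg.injury, t_post, peak_delta_bpm=peak)

    if np.any(bpm <= 0):
        raise ConfigurationError(
            "breathing schedule reached a non-positive bpm; check br_* parameters"
        )
    return bpm


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------


@dataclass
class FrameSequence:
    """Ordered grayscale frames with spatial/temporal calibration."""

    frames: np.ndarray            # (n, H, W) uint8
    t0: pd.Timestamp              # wall-clock time of frame 0
    fps: float
    mm_per_px: float
    day: np.ndarray               # bool per frame (lights on)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) stack")
        if len(self.day) != len(self.frames):
            raise ValueError("illumination flags must match frame count")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.t0 + pd.to_timedelta(np.arange(len(self)) / self.fps, unit="s")

    def slice(self, i0: int, i1: int) -> "FrameSequence":
        return FrameSequence(
            frames=self.frames[i0:i1],
            t0=self.t0 + pd.to_timedelta(i0 / self.fps, unit="s"),
            fps=self.fps,
            mm_per_px=self.mm_per_px,
            day=self.day[i0:i1],
        )


def _soft_ellipse(xx, yy, cx, cy, a, b, softness=0.25):
    d = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    return np.clip((1.0 - d) / softness, 0.0, 1.0)


def chest_center_px(cfg: SimConfig, x_mm: float, y_mm: float) -> tuple[float, float]:
    """Chest-disc centre (px) for an animal centred at (x_mm, y_mm)."""
    a_px = cfg.body_len_mm / 2 / cfg.mm_per_px
    return (x_mm / cfg.mm_per_px + cfg.chest_frac * a_px, y_mm / cfg.mm_per_px)


def true_chest_mask(cfg: SimConfig, x_mm: float, y_mm: float) -> np.ndarray:
    """Boolean mask of the true chest disc, for ROI-localisation validation."""
    H, W = cfg.frame_shape
    ccx, ccy = chest_center_px(cfg, x_mm, y_mm)
    r = cfg.chest_r_mm / cfg.mm_per_px
    yy, xx = np.mgrid[0:H, 0:W]
    return (xx - ccx) ** 2 + (yy - ccy) ** 2 <= r * r


def render_frames(
    behavior: BehaviorTruth,
    bpm: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> FrameSequence:
    """Render the trajectory + breathing schedule into grayscale video frames.

    The animal is a soft-edged filled ellipse; a brighter chest disc (offset
    toward the front of the body) has its radius modulated sinusoidally at the
    instantaneous true breathing frequency with amplitude ``chest_amp_px``.
    Night frames use a lower flat background.  Additive Gaussian pixel noise
    with SD ``noise_sd``; fully deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if behavior.positions is None:
        raise ValueError("behavior must carry a trajectory (with_trajectory=True)")
    if cfg.chest_amp_px == 0:
        warnings.warn(
            "chest_amp_px is 0: the breathing signal is unrecoverable by design",
            stacklevel=2,
        )
    n_sec = min(behavior.n_seconds, len(bpm))
    nf = int(round(n_sec * cfg.fps))
    H, W = cfg.frame_shape

    tf = np.arange(nf) / cfg.fps
    sec_idx = np.arange(n_sec + 1, dtype=float)
    cx = np.interp(tf, sec_idx, behavior.positions[: n_sec + 1, 0]) / cfg.mm_per_px
    cy = np.interp(tf, sec_idx, behavior.positions[: n_sec + 1, 1]) / cfg.mm_per_px

    freq_hz = bpm[np.minimum(tf.astype(int), n_sec - 1)] / 60.0
    phase = 2 * np.pi * (np.cumsum(freq_hz) - freq_hz[0]) / cfg.fps + rng.uniform(0, 2 * np.pi)

    day_f = behavior.day[np.minimum(tf.astype(int), n_sec - 1)]
    a_px = cfg.body_len_mm / 2 / cfg.mm_per_px
    b_px = cfg.body_wid_mm / 2 / cfg.mm_per_px
    chest_r = cfg.chest_r_mm / cfg.mm_per_px

    frames = np.empty((nf, H, W), dtype=np.uint8)
    pad = int(np.ceil(a_px + chest_r + cfg.chest_amp_px + 3))
    for i in range(nf):
        bg = cfg.bg_day if day_f[i] else cfg.bg_night
        img = np.full((H, W), bg, dtype=np.float64)
        x0 = max(int(cx[i]) - pad, 0)
        x1 = min(int(cx[i]) + pad + 1, W)
        y0 = max(int(cy[i]) - pad, 0)
        y1 = min(int(cy[i]) + pad + 1, H)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        wb = _soft_ellipse(xx, yy, cx[i], cy[i], a_px, b_px)
        sub = img[y0:y1, x0:x1]
        sub = sub * (1 - wb) + cfg.body_intensity * wb
        r = chest_r + cfg.chest_amp_px * np.sin(phase[i])
        ccx = cx[i] + cfg.chest_frac * a_px
        wc = _soft_ellipse(xx, yy, ccx, cy[i], r, r)
        sub = sub * (1 - wc) + cfg.chest_intensity * wc
        img[y0:y1, x0:x1] = sub
        if cfg.noise_sd > 0:
            img += rng.normal(0.0, cfg.noise_sd, size=(H, W))
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    return FrameSequence(
        frames=frames,
        t0=pd.Timestamp(cfg.start_time),
        fps=cfg.fps,
        mm_per_px=cfg.mm_per_px,
        day=np.asarray(day_f),
    )


# ---------------------------------------------------------------------------
# Ground-truth log and session convenience wrapper
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthLog:
    """Simulator truth for validating every extraction stage."""

    per_second: pd.DataFrame          # timestamp, x_mm, y_mm, speed_mm_s, bpm, bout, photoperiod
    cfg: SimConfig
    endpoints: pd.DataFrame | None = None

    def chest_mask_at(self, second: int) -> np.ndarray:
        row = self.per_second.iloc[second]
        return true_chest_mask(self.cfg, row.x_mm, row.y_mm)


def make_ground_truth(
    behavior: BehaviorTruth, bpm: np.ndarray, cfg: SimConfig
) -> GroundTruthLog:
    n = min(behavior.n_seconds, len(bpm))
    ts = pd.Timestamp(cfg.start_time) + pd.to_timedelta(np.arange(n), unit="s")
    pos = behavior.positions
    per_second = pd.DataFrame(
        {
            "timestamp": ts,
            "x_mm": pos[:n, 0] if pos is not None else np.nan,
            "y_mm": pos[:n, 1] if pos is not None else np.nan,
            "speed_mm_s": behavior.speed[:n],
            "bpm": bpm[:n],
            "bout": np.where(behavior.rest[:n], "rest", "active"),
            "photoperiod": np.where(behavior.day[:n], "day", "night"),
        }
    )
    return GroundTruthLog(per_second=per_second, cfg=cfg)


def simulate_session(
    cfg: SimConfig,
    group: str = "control",
    induction_offset_s: float = 0.0,
    render: bool = True,
) -> tuple[FrameSequence | None, GroundTruthLog]:
    """One-call fixture: behaviour + breathing + (optionally) rendered frames."""
    rng = np.random.default_rng(cfg.seed)
    behavior = simulate_behavior(cfg, rng=rng)
    bpm = simulate_breathing_schedule(
        cfg,
        group=group,
        n_seconds=behavior.n_seconds,
        induction_offset_s=induction_offset_s,
        rng=rng,
    )
    frames = render_frames(behavior, bpm, cfg, rng=rng) if render else None
    truth = make_ground_truth(behavior, bpm, cfg)
    return frames, truth


# ---------------------------------------------------------------------------
# Fixture writing (frames as numbered PNGs + truth/config sidecars)
# ---------------------------------------------------------------------------


def write_fixture(frames: FrameSequence, truth: GroundTruthLog, out_dir) -> None:
    """Write a fixture directory: frames/, ground_truth.csv, meta.yaml, config.yaml.

    The write is staged in a temporary sibling directory and renamed into
    place, so a failed write never leaves stale partial outputs behind.
    """
    import imageio.v3 as iio
    import yaml

    out_dir = os.fspath(out_dir)
    parent = os.path.dirname(os.path.abspath(out_dir)) or "."
    tmp = tempfile.mkdtemp(prefix=".fixture-", dir=parent)
    try:
        fdir = os.path.join(tmp, "frames")
        os.makedirs(fdir)
        for i, frame in enumerate(frames.frames):
            iio.imwrite(os.path.join(fdir, f"frame_{i:06d}.png"), frame)
        meta = {
            "format": "cagewatch-fixture-v1",
            "fps": float(frames.fps),
            "mm_per_px": float(frames.mm_per_px),
            "t0": frames.t0.isoformat(),
            "n_frames": int(len(frames)),
            "lights_on": truth.cfg.lights_on,
            "lights_off": truth.cfg.lights_off,
        }
        with open(os.path.join(tmp, "meta.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
        from .io import write_timeseries_csv

        write_timeseries_csv(
            truth.per_second, os.path.join(tmp, "ground_truth.csv"), "ground_truth"
        )
        with open(os.path.join(tmp, "config.yaml"), "w") as fh:
            yaml.safe_dump(truth.cfg.model_dump(), fh, sort_keys=True)
        if os.path.isdir(out_dir):
            shutil.rmtree(out_dir)
        os.replace(tmp, out_dir)
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise


# ---------------------------------------------------------------------------
# Cohort-level tabular generator (daily metrics + endpoint pathology proxies)
# ---------------------------------------------------------------------------


@dataclass
class CohortTables:
    """Daily per-animal metrics and endpoint pathology for a simulated study."""

    daily: pd.DataFrame
    endpoints: pd.DataFrame


def _daily_mean_delta(curve: InjuryCurve, study_day: int, induction_sod_h: float,
                      day_boundary_h: float = 6.0, peak: float | None = None) -> float:
    """Average injury delta over one 06:00->06:00 study day (hourly trapezoid)."""
    start_h = study_day * 24.0 + day_boundary_h - induction_sod_h
    hours = start_h + np.arange(25.0)
    vals = injury_delta(curve, hours * 3600.0, peak_delta_bpm=peak)
    return float(np.trapezoid(vals) / 24.0)


def simulate_cohort(
    cfg: SimConfig,
    n_control: int = 8,
    n_injured: int = 8,
    first_day: int = -7,
    last_day: int = 14,
    induction_sod_h: float = 10.0,
    rng: np.random.Generator | None = None,
) -> CohortTables:
    """Simulate per-animal daily metrics and endpoint tables for a two-group study.

    Daily breathing-rate means are the animal baseline plus day-to-day noise
    (``br_day_sd_bpm``) plus the daily-averaged injury delta; body-motion
    means follow the photoperiod occupancy of the behaviour chain, suppressed
    during injury by ``bm_suppression_fraction`` times the normalised effect
    shape.  A shared latent severity per animal drives effect magnitude,
    weight loss, and the histology proxies, and the endpoint lung-weight proxy
    is constructed to correlate with measured final-day breathing rate at
    exactly ``endpoint_r`` in population.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if n_injured > 0 and cfg.injury is None:
        raise ConfigurationError("injured animals require cfg.injury to be set")

    days = np.arange(first_day, last_day + 1)
    groups = ["control"] * n_control + ["injured"] * n_injured
    curve = cfg.injury

    occ_day = rest_occupancy(cfg, True)
    occ_night = rest_occupancy(cfg, False)
    bm_day0 = (1 - occ_day) * cfg.active_speed_mm_s
    bm_night0 = (1 - occ_night) * cfg.active_speed_mm_s

    # analytic population moments of the measured final-day BR, per group
    delta_final = (
        _daily_mean_delta(curve, int(days[-1]), induction_sod_h) if curve else 0.0
    )
    var_common = cfg.br_sd_bpm**2 + cfg.br_day_sd_bpm**2
    moments = {
        "control": (cfg.br_baseline_bpm, np.sqrt(var_common)),
        "injured": (
            cfg.br_baseline_bpm + delta_final,
            np.sqrt(var_common + (cfg.severity_delta_cv * delta_final) ** 2),
        ),
    }

    daily_rows, endpoint_rows = [], []
    for idx, group in enumerate(groups):
        aid = f"{group[:3]}-{idx:03d}"
        base = rng.normal(cfg.br_baseline_bpm, cfg.br_sd_bpm)
        sev = float(rng.standard_normal())
        peak = (
            max(curve.peak_delta_bpm * (1 + cfg.severity_delta_cv * sev), 0.0)
            if (curve and group == "injured")
            else 0.0
        )
        w0 = rng.normal(350.0, 15.0)
        bm_scale = rng.lognormal(0.0, 0.15)

        br_final = np.nan
        for d in days:
            if curve and group == "injured":
                dmean = _daily_mean_delta(curve, int(d), induction_sod_h, peak=peak)
                shape = dmean / curve.peak_delta_bpm  # normalised severity shape
            else:
                dmean, shape = 0.0, 0.0
            br = base + dmean + rng.normal(0.0, cfg.br_day_sd_bpm)
            supp = 1.0 - (curve.bm_suppression_fraction if curve else 0.0) * min(shape, 1.0)
            bm_d = bm_day0 * bm_scale * supp * rng.lognormal(0.0, 0.10)
            bm_n = bm_night0 * bm_scale * supp * rng.lognormal(0.0, 0.10)
            growth = 2.0 * (d - days[0])
            loss = w0 * 0.15 * (1 + 0.5 * sev) * min(shape, 1.0) if group == "injured" else 0.0
            weight = w0 + growth - max(loss, 0.0) + rng.normal(0.0, 1.5)
            temp = 37.5 - 1.0 * min(shape, 1.0) + rng.normal(0.0, 0.15)
            daily_rows.append(
                {
                    "animal_id": aid,
                    "group": group,
                    "study_day": int(d),
                    "day_bm_mean": bm_d,
                    "night_bm_mean": bm_n,
                    "br_mean": br,
                    "n_bm_day": 43200,
                    "n_bm_night": 43200,
                    "n_br": int(rng.poisson(400)),
                    "weight_g": weight,
                    "temp_c": temp,
                }
            )
            if d == days[-1]:
                br_final = br

        mu_x, sd_x = moments[group]
        z = (br_final - mu_x) / sd_x
        r = cfg.endpoint_r
        mix = r * z + np.sqrt(max(1 - r * r, 0.0)) * rng.standard_normal()
        mu_l = 0.0095 if group == "injured" else 0.0055
        lung = mu_l + 0.0012 * mix
        if group == "injured":
            damage = int(np.clip(round(2.0 + 1.1 * sev + 0.6 * rng.standard_normal()), 0, 5))
            edema = int(np.clip(round(1.5 + 0.9 * sev + 0.7 * rng.standard_normal()), 0, 5))
            fibrosis = int(np.clip(round(1.0 + 0.6 * sev + 0.7 * rng.standard_normal()), 0, 5))
            inflam = int(np.clip(round(1.5 + 0.9 * rng.standard_normal()), 0, 5))
        else:
            damage = edema = fibrosis = inflam = 0
        endpoint_rows.append(
            {
                "animal_id": aid,
                "group": group,
                "final_br_bpm": br_final,
                "lung_to_body": lung,
                "alveolar_damage": damage,
                "edema": edema,
                "fibrosis": fibrosis,
                "inflammation": inflam,
                "severity": sev,
            }
        )

    return CohortTables(
        daily=pd.DataFrame(daily_rows), endpoints=pd.DataFrame(endpoint_rows)
    )
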