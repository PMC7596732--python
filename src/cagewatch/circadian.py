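"""Circadian aggregation: per-study-day metrics and baseline-normalised deltas.

Study days run 06:00 to 06:00 (the lights-on boundary) with Day 0 the
induction day; body-motion means are computed separately within the lights-on
(06:00-18:00) and lights-off photoperiods of each study day, breathing rate
over the full 06:00-to-06:00 day.  Per-animal baselines are the unweighted
mean of the acclimation days -5..-2, subtracted from every study-day value;
body weight and temperature instead use the single Day -7 measurement as
reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import InputError

BASELINE_DAYS = (-5, -2)  # inclusive acclimation window
METRIC_COLS = ["day_bm_mean", "night_bm_mean", "br_mean"]


def _clock_to_timedelta(hhmm: str) -> pd.Timedelta:
    hh, mm = hhmm.split(":")
    return pd.Timedelta(hours=int(hh), minutes=int(mm))


def assign_photoperiod(
    timestamps, lights_on: str = "06:00", lights_off: str = "18:00"
) -> np.ndarray:
    """Label timestamps 'day' or 'night'; day iff lights_on <= clock < lights_off."""
    ts = pd.DatetimeIndex(timestamps)
    tod = ts - ts.normalize()
    on, off = _clock_to_timedelta(lights_on), _clock_to_timedelta(lights_off)
    if on <= off:
        day = (tod >= on) & (tod < off)
    else:
        day = (tod >= on) | (tod < off)
    return np.where(day, "day", "night")


def study_day(timestamps, induction_time, day_boundary: str = "06:00") -> np.ndarray:
    """Integer study day for each timestamp (Day 0 = induction day).

    Days are delimited at ``day_boundary`` o'clock; the boundary immediately
    at or before the induction instant starts Day 0, so acclimation days are
    negative.
    """
    ts = pd.DatetimeIndex(timestamps)
    ind = pd.Timestamp(induction_time)
    boundary = _clock_to_timedelta(day_boundary)
    day0_start = ind.normalize() + boundary
    if ind < day0_start:
        day0_start -= pd.Timedelta(days=1)
    return np.floor((ts - day0_start) / pd.Timedelta(days=1)).astype(int)


def daily_aggregate(
    motion: pd.DataFrame,
    breaths: pd.DataFrame,
    induction_time,
    lights_on: str = "06:00",
    lights_off: str = "18:00",
    animal_id: str = "animal-0",
) -> pd.DataFrame:
    """Per-study-day metrics for one animal.

    Body-motion means are taken over finite per-second speeds within each
    photoperiod of each study day; the breathing-rate mean uses all
    *significant* breath samples of the 06:00-to-06:00 day regardless of
    photoperiod.  Missing data lowers the counts and leaves the mean NaN —
    nothing is imputed.
    """
    m = motion.copy()
    m["study_day"] = study_day(m["timestamp"], induction_time, lights_on)
    m["photoperiod"] = assign_photoperiod(m["timestamp"], lights_on, lights_off)
    m = m[np.isfinite(m["speed_mm_s"].astype(float))]

    bm = (
        m.groupby(["study_day", "photoperiod"])["speed_mm_s"]
        .agg(["mean", "size"])
        .unstack("photoperiod")
    )

    if len(breaths):
        b = breaths[breaths["significant"].astype(bool)].copy()
        b["study_day"] = study_day(b["window_start"], induction_time, lights_on)
        br = b.groupby("study_day")["bpm"].agg(["mean", "size"])
    else:
        br = pd.DataFrame(columns=["mean", "size"])

    days = sorted(set(m["study_day"]).union(br.index))
    rows = []
    for d in days:
        def _bm(stat, period):
            try:
                v = bm.loc[d, (stat, period)]
            except KeyError:
                return np.nan
            return v

        n_day = _bm("size", "day")
        n_night = _bm("size", "night")
        n_br = int(br.loc[d, "size"]) if d in br.index else 0
        rows.append(
            {
                "animal_id": animal_id,
                "study_day": int(d),
                "day_bm_mean": _bm("mean", "day"),
                "night_bm_mean": _bm("mean", "night"),
                "br_mean": float(br.loc[d, "mean"]) if n_br else np.nan,
                "n_bm_day": int(n_day) if np.isfinite(n_day) else 0,
                "n_bm_night": int(n_night) if np.isfinite(n_night) else 0,
                "n_br": n_br,
            }
        )
    return pd.DataFrame(rows)


def compute_baseline(
    metrics: pd.DataFrame, baseline_days: tuple[int, int] = BASELINE_DAYS
) -> pd.DataFrame:
    """Per-animal acclimation baselines: unweighted mean over Days -5..-2.

    Only study days inside the (inclusive) window contribute; days missing a
    metric simply drop out of that metric's mean.  A window with no data at
    all is an error — the baseline is undefined.
    """
    lo, hi = baseline_days
    window = metrics[(metrics["study_day"] >= lo) & (metrics["study_day"] <= hi)]
    if not len(window) or window[METRIC_COLS].notna().sum().sum() == 0:
        raise InputError(
            f"no acclimation data in study days [{lo}, {hi}]; baseline undefined"
        )
    base = window.groupby("animal_id")[METRIC_COLS].mean()
    base.columns = ["baseline_day_bm", "baseline_night_bm", "baseline_br"]
    return base.reset_index()


def change_from_baseline(
    metrics: pd.DataFrame,
    baseline: pd.DataFrame,
    inlife: pd.DataFrame | None = None,
    reference_day: int = -7,
) -> pd.DataFrame:
    """Baseline-subtracted change series per animal per study day.

    Motion/breathing deltas subtract the acclimation baseline; body weight and
    temperature deltas subtract the animal's single Day ``reference_day``
    measurement (columns ``weight_g`` / ``temp_c``, taken from ``metrics`` or
    a separate ``inlife`` table).
    """
    df = metrics.merge(baseline, on="animal_id", how="left")
    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "study_day": df["study_day"],
            "delta_day_bm": df["day_bm_mean"] - df["baseline_day_bm"],
            "delta_night_bm": df["night_bm_mean"] - df["baseline_night_bm"],
            "delta_br": df["br_mean"] - df["baseline_br"],
        }
    )

    source = inlife if inlife is not None else metrics
    out["delta_weight"] = np.nan
    out["delta_temp"] = np.nan
    for col, dcol in (("weight_g", "delta_weight"), ("temp_c", "delta_temp")):
        if col in source.columns:
            ref = (
                source[source["study_day"] == reference_day]
                .set_index("animal_id")[col]
            )
            vals = source.set_index(["animal_id", "study_day"])[col]
            keys = list(zip(out["animal_id"], out["study_day"]))
            out[dcol] = [
                vals.get(k, np.nan) - ref.get(k[0], np.nan) for k in keys
            ]
    return out
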