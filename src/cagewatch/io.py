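"""Typed CSV readers/writers and fixture (frame-stack) input.

Every tabular artifact carries a versioned schema comment as its first line
(``# cagewatch v1 schema=<name>``); readers reject files whose header does
not match the declared schema exactly, naming the offending column.
Timestamps are ISO-8601; missing values are written as empty fields.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .config import InputError, SchemaError

FORMAT_LINE = "# cagewatch v1 schema={name}"

SCHEMAS: dict[str, list[str]] = {
    "motion_trace": ["timestamp", "speed_mm_s", "frames_used", "animal_present"],
    "breath_samples": [
        "window_start", "window_end", "bpm", "peak_rms_power", "significant",
    ],
    "ground_truth": [
        "timestamp", "x_mm", "y_mm", "speed_mm_s", "bpm", "bout", "photoperiod",
    ],
    "daily_metrics": [
        "animal_id", "study_day", "day_bm_mean", "night_bm_mean", "br_mean",
        "n_bm_day", "n_bm_night", "n_br",
    ],
    "cohort_daily": [
        "animal_id", "group", "study_day", "day_bm_mean", "night_bm_mean",
        "br_mean", "n_bm_day", "n_bm_night", "n_br", "weight_g", "temp_c",
    ],
    "change_series": [
        "animal_id", "study_day", "delta_day_bm", "delta_night_bm", "delta_br",
        "delta_weight", "delta_temp",
    ],
    "endpoints": [
        "animal_id", "group", "final_br_bpm", "lung_to_body", "alveolar_damage",
        "edema", "fibrosis", "inflammation", "severity",
    ],
}

_TIME_COLS = {"timestamp", "window_start", "window_end"}
_BOOL_COLS = {"animal_present", "significant"}


def write_timeseries_csv(table: pd.DataFrame, path, schema: str) -> None:
    """Write a table under its versioned schema header (lossless round-trip)."""
    cols = SCHEMAS.get(schema)
    if cols is None:
        raise SchemaError(f"unknown schema {schema!r}")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SchemaError(f"table is missing schema column {missing[0]!r}")
    df = table[cols].copy()
    for c in cols:
        if c in _TIME_COLS:
            df[c] = pd.DatetimeIndex(df[c]).strftime("%Y-%m-%dT%H:%M:%S.%f")
    with open(path, "w", newline="") as fh:
        fh.write(FORMAT_LINE.format(name=schema) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_timeseries_csv(path, schema: str) -> pd.DataFrame:
    """Read a schema-tagged CSV, validating the header exactly."""
    cols = SCHEMAS.get(schema)
    if cols is None:
        raise SchemaError(f"unknown schema {schema!r}")
    with open(path) as fh:
        first = fh.readline().strip()
        if first != FORMAT_LINE.format(name=schema):
            raise SchemaError(
                f"{path}: expected header {FORMAT_LINE.format(name=schema)!r}, "
                f"got {first!r}"
            )
        df = pd.read_csv(fh, float_precision="round_trip")
    extra = [c for c in df.columns if c not in cols]
    if extra:
        raise SchemaError(f"{path}: unexpected column {extra[0]!r}")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column {missing[0]!r}")
    df = df[cols]
    for c in cols:
        if c in _TIME_COLS:
            df[c] = pd.to_datetime(df[c])
        elif c in _BOOL_COLS:
            df[c] = df[c].astype(bool)
    return df


def read_frame_stack(
    path,
    fps: float | None = None,
    mm_per_px: float | None = None,
    t0=None,
    lights_on: str = "06:00",
    lights_off: str = "18:00",
):
    """Read a fixture directory (or a video file) into a FrameSequence.

    A fixture directory holds ``meta.yaml`` plus ``frames/frame_NNNNNN.png``
    and carries its own calibration; illumination flags are re-derived from
    the timestamps and the light cycle recorded in the metadata.  Bare video
    files need ``fps`` and ``mm_per_px`` (and optionally a wall-clock ``t0``)
    supplied by the caller.  Truncated or inconsistent stacks are input
    errors, raised before any downstream output is written.
    """
    import imageio.v3 as iio
    import yaml

    from .circadian import assign_photoperiod
    from .synthetic import FrameSequence

    path = os.fspath(path)
    if os.path.isdir(path):
        meta_path = os.path.join(path, "meta.yaml")
        if not os.path.exists(meta_path):
            raise InputError(f"{path}: not a fixture directory (no meta.yaml)")
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        n = int(meta["n_frames"])
        frames = []
        for i in range(n):
            fp = os.path.join(path, "frames", f"frame_{i:06d}.png")
            if not os.path.exists(fp):
                raise InputError(f"{path}: truncated frame stack (missing frame {i})")
            frames.append(iio.imread(fp))
        stack = np.stack(frames) if frames else np.empty((0, 1, 1), dtype=np.uint8)
        if stack.ndim == 4:  # grayscale PNGs may decode with a channel axis
            stack = stack[..., 0]
        t0 = pd.Timestamp(meta["t0"])
        fps = float(meta["fps"])
        ts = t0 + pd.to_timedelta(np.arange(n) / fps, unit="s")
        day = (
            assign_photoperiod(ts, meta.get("lights_on", "06:00"),
                               meta.get("lights_off", "18:00")) == "day"
        )
        return FrameSequence(
            frames=stack, t0=t0, fps=fps,
            mm_per_px=float(meta["mm_per_px"]), day=day,
        )

    if fps is None or mm_per_px is None:
        raise InputError(
            f"{path}: bare video files need fps and mm_per_px calibration"
        )
    try:
        stack = np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - any decode failure is an input error
        raise InputError(f"{path}: could not read video ({exc})") from exc
    if stack.ndim == 4:
        stack = stack.mean(axis=-1).astype(np.uint8)
    if stack.ndim != 3:
        raise InputError(f"{path}: expected a multi-frame grayscale video")
    t0 = pd.Timestamp(t0) if t0 is not None else pd.Timestamp("2024-01-01 06:00:00")
    ts = t0 + pd.to_timedelta(np.arange(len(stack)) / fps, unit="s")
    day = assign_photoperiod(ts, lights_on, lights_off) == "day"
    return FrameSequence(
        frames=stack.astype(np.uint8), t0=t0, fps=float(fps),
        mm_per_px=float(mm_per_px), day=day,
    )
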