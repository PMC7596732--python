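"""Configuration schema and validation for the cagewatch pipeline.

All tunables live in pydantic models with ``extra="forbid"`` so that a typo in a
config file is a hard error, not a silently ignored key.  The full pipeline is
driven by a single :class:`PipelineConfig`, serialisable to/from YAML.
"""

from __future__ import annotations

import hashlib
import json
from datetime import time as dtime
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent."""


class SchemaError(ValueError):
    """Raised when a CSV header does not match its declared schema."""


class InputError(ValueError):
    """Raised when operation inputs violate a precondition."""


def _parse_clock(s: str) -> dtime:
    hh, mm = s.split(":")
    return dtime(int(hh), int(mm))


class InjuryCurve(BaseModel):
    """Breathing-rate effect of the lung-injury time course.

    Zero before ``onset_h`` hours post-induction, linear rise to
    ``peak_delta_bpm`` at ``peak_day`` (study days post-induction), then
    exponential decay with time constant ``decay_tau_days`` toward a positive
    plateau ``plateau_frac * peak_delta_bpm``.  Body motion is suppressed by
    ``bm_suppression_fraction`` at the peak, following the same time course.
    """

    model_config = ConfigDict(extra="forbid")

    onset_h: float = 16.0
    peak_day: float = 2.0
    peak_delta_bpm: float = 32.0
    decay_tau_days: float = 4.0
    plateau_frac: float = Field(0.25, ge=0.0, le=1.0)
    bm_suppression_fraction: float = Field(0.5, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "InjuryCurve":
        if self.onset_h < 0 or self.decay_tau_days <= 0:
            raise ConfigurationError("injury curve times must be positive")
        if self.peak_day * 24.0 <= self.onset_h:
            raise ConfigurationError("peak_day must fall after onset_h")
        return self


class SimConfig(BaseModel):
    """Parameters of the synthetic single-rat cage simulation.

    The rest/active alternation is a two-state continuous-time chain:
    ``rest_prob_day`` / ``rest_prob_night`` are the per-minute probabilities of
    entering a rest bout while active (converted internally to hazards), and
    rest bouts last Exp(``mean_rest_bout_s``).  ``mean_active_bout_s``, when
    set, overrides both entry probabilities with a single photoperiod-free
    mean active-bout duration.
    """

    model_config = ConfigDict(extra="forbid")

    fps: float = Field(24.0, gt=0)
    duration_s: float = Field(120.0, gt=0)
    mm_per_px: float = Field(2.0, gt=0)
    cage_w_mm: float = Field(432.0, gt=0)
    cage_h_mm: float = Field(340.0, gt=0)
    start_time: str = "2024-03-01 06:00:00"
    lights_on: str = "06:00"
    lights_off: str = "18:00"

    rest_prob_day: float = Field(0.60, ge=0.0, le=1.0)
    rest_prob_night: float = Field(0.067, ge=0.0, le=1.0)
    mean_rest_bout_s: float = Field(300.0, gt=0)
    mean_active_bout_s: Optional[float] = Field(None, gt=0)
    active_speed_mm_s: float = Field(100.0, gt=0)
    turn_sd_rad: float = Field(0.6, ge=0.0)
    speed_cv: float = Field(0.25, ge=0.0)

    br_baseline_bpm: float = Field(107.0, gt=0)
    br_sd_bpm: float = Field(13.0, ge=0)
    br_within_sd_bpm: float = Field(3.0, ge=0)
    br_within_tau_s: float = Field(600.0, gt=0)
    br_day_sd_bpm: float = Field(5.0, ge=0)
    circadian_amp_bpm: float = Field(5.0, ge=0)
    injury: Optional[InjuryCurve] = None
    severity_delta_cv: float = Field(0.30, ge=0.0)

    body_len_mm: float = Field(220.0, gt=0)
    body_wid_mm: float = Field(70.0, gt=0)
    chest_frac: float = Field(0.45, ge=0.0, le=1.0)
    chest_r_mm: float = Field(16.0, gt=0)
    chest_amp_px: float = Field(0.5, ge=0.0)
    body_intensity: float = 200.0
    chest_intensity: float = 240.0
    bg_day: float = 120.0
    bg_night: float = 40.0
    noise_sd: float = Field(4.0, ge=0.0)

    endpoint_r: float = Field(0.7, ge=-1.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        a = self.body_len_mm / self.mm_per_px
        if a >= min(self.cage_w_mm, self.cage_h_mm) / self.mm_per_px:
            raise ConfigurationError(
                "cage too small for the animal footprint "
                f"({self.body_len_mm} mm body in {self.cage_w_mm}x{self.cage_h_mm} mm cage)"
            )
        _parse_clock(self.lights_on)
        _parse_clock(self.lights_off)
        return self

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (
            int(round(self.cage_h_mm / self.mm_per_px)),
            int(round(self.cage_w_mm / self.mm_per_px)),
        )

    def rest_entry_hazard(self, day: bool) -> float:
        """Hazard (s^-1) of entering rest while active in the given photoperiod."""
        if self.mean_active_bout_s is not None:
            return 1.0 / self.mean_active_bout_s
        p = self.rest_prob_day if day else self.rest_prob_night
        if p >= 1.0:
            return np.inf
        return -np.log1p(-p) / 60.0


class MotionConfig(BaseModel):
    """Optical-flow and segmentation settings for body-motion extraction."""

    model_config = ConfigDict(extra="forbid")

    flow_radius: int = Field(5, ge=1)
    num_warp: int = Field(3, ge=1)
    bg_window_s: float = Field(60.0, gt=0)
    bg_thresh: float = Field(25.0, gt=0)
    min_animal_px: int = Field(20, ge=1)
    whole_frame: bool = False
    flow_stride: int = Field(1, ge=1)
    speed_stat: str = Field("vector_mean", pattern="^(vector_mean|magnitude_mean)$")


class DetectionConfig(BaseModel):
    """Stationarity gating and spectral breathing-rate detection settings.

    The detection band (default 60-180 bpm, i.e. 1-3 Hz) brackets known rodent
    breathing rates; ``power_threshold`` is the peak RMS amplitude (intensity
    units of the chest signal) above which periodic motion is significant.
    """

    model_config = ConfigDict(extra="forbid")

    speed_threshold_mm_s: float = Field(5.0, gt=0)
    min_stationary_s: float = Field(30.0, gt=0)
    band_lo_bpm: float = Field(60.0, gt=0)
    band_hi_bpm: float = Field(180.0, gt=0)
    power_threshold: float = Field(0.5, ge=0)
    window_s: float = Field(30.0, gt=0)
    window_stride_s: float = Field(30.0, gt=0)
    rms_halfwidth_hz: float = Field(0.15, gt=0)
    power_mode: str = Field("rms", pattern="^(rms|peak_height)$")
    roi_quantile: float = Field(0.97, gt=0, lt=1)
    roi_peak_frac: float = Field(0.10, gt=0, lt=1)
    min_roi_px: int = Field(4, ge=1)
    min_band_frac: float = Field(0.35, gt=0, lt=1)
    roi_fit_max_s: float = Field(120.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "DetectionConfig":
        if self.band_lo_bpm >= self.band_hi_bpm:
            raise ConfigurationError("band_lo_bpm must be < band_hi_bpm")
        if self.window_s > self.min_stationary_s:
            raise ConfigurationError("window_s must be <= min_stationary_s")
        return self


class PowerSpec(BaseModel):
    """Inputs to the two-sample design power computation."""

    model_config = ConfigDict(extra="forbid")

    baseline_mean: float = Field(107.0, gt=0)
    pooled_sd: float = Field(13.0, gt=0)
    n_per_group: int = Field(8, ge=2)
    effect_fraction: float = Field(0.30, ge=0)
    alpha: float = Field(0.05, gt=0, lt=1)


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    power: PowerSpec = PowerSpec()
    sided: str = Field("two", pattern="^(one|two)$")
    holm: bool = False
    humane_loss_fraction: float = Field(0.20, gt=0, lt=1)
    humane_reference_day: int = 0


class PipelineConfig(BaseModel):
    """Top-level configuration binding all pipeline stages together."""

    model_config = ConfigDict(extra="forbid")

    sim: SimConfig = SimConfig()
    motion: MotionConfig = MotionConfig()
    detection: DetectionConfig = DetectionConfig()
    stats: StatsConfig = StatsConfig()
    lights_on: str = "06:00"
    lights_off: str = "18:00"
    day_boundary: str = "06:00"
    induction_time: str = "2024-03-08 10:00:00"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if not (
            self.detection.band_lo_bpm
            <= self.sim.br_baseline_bpm
            <= self.detection.band_hi_bpm
        ):
            raise ConfigurationError(
                "sim.br_baseline_bpm lies outside the detection band"
            )
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, logged with every run."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
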