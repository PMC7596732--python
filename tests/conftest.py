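"""Shared synthetic fixtures, rendered once per session.

All fixtures are generated programmatically with fixed seeds; the small cage
keeps optical flow fast while leaving room for the animal to move.
"""

import numpy as np
import pytest

import cagewatch as cw

SMALL_CAGE = dict(
    cage_w_mm=240.0, cage_h_mm=180.0, body_len_mm=110.0, body_wid_mm=40.0,
    chest_r_mm=10.0,
)


@pytest.fixture(scope="session")
def rest_cfg() -> cw.SimConfig:
    """90 s fixture in which the animal rests for the whole recording."""
    return cw.SimConfig(
        duration_s=90, rest_prob_day=1.0, rest_prob_night=1.0, seed=3, **SMALL_CAGE
    )


@pytest.fixture(scope="session")
def rest_session(rest_cfg):
    return cw.simulate_session(rest_cfg)


@pytest.fixture(scope="session")
def rest_trace(rest_session):
    frames, _truth = rest_session
    return cw.motion_trace(frames)


@pytest.fixture(scope="session")
def mixed_session():
    """60 s fixture alternating short rest and active bouts."""
    cfg = cw.SimConfig(
        duration_s=60, active_speed_mm_s=40.0, rest_prob_day=0.9,
        mean_rest_bout_s=12.0, seed=11, **SMALL_CAGE,
    )
    frames, truth = cw.simulate_session(cfg)
    trace = cw.motion_trace(frames)
    return cfg, frames, truth, trace


@pytest.fixture
def det() -> cw.DetectionConfig:
    return cw.DetectionConfig()


def soft_blob(h, w, cx, cy, a=14.0, b=8.0, contrast=80.0, bg=120.0):
    """Soft-edged elliptical blob test pattern (float image)."""
    yy, xx = np.mgrid[0:h, 0:w]
    d = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    return bg + contrast * np.clip((1 - d) / 0.25, 0.0, 1.0)
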