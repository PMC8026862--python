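"""Shared fixtures: ideal synthetic frames and small rendered trials."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import ndtr

from piprtrack import (
    RenderConfig,
    SeedPoint,
    TrajectoryParams,
    render_video,
    synthesize_trajectory,
)


def make_disk(
    h: int,
    w: int,
    cx: float,
    cy: float,
    r: float,
    sigma: float = 0.5,
    pupil: float = 0.08,
    iris: float = 0.55,
) -> np.ndarray:
    """Dark disk on a bright background with a normal-CDF edge profile
    whose steepest gradient sits exactly at radius ``r``."""
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dist = np.hypot(xx - cx, yy - cy)
    return pupil + (iris - pupil) * ndtr((dist - r) / sigma)


@pytest.fixture(scope="session")
def disk_frame() -> np.ndarray:
    """200x200 frame, disk of radius 40 centred at (100, 100)."""
    return make_disk(200, 200, 100.0, 100.0, 40.0)


@pytest.fixture(scope="session")
def disk_center() -> SeedPoint:
    return SeedPoint(100.0, 100.0)


@pytest.fixture(scope="session")
def constant_trial():
    """Noiseless rendered video of a constant 5.6 mm pupil (radius 42 px)."""
    params = TrajectoryParams(
        baseline_diameter_mm=5.6,
        phasic_amplitude_mm=0.0,
        sustained_amplitude_mm=0.0,
        noise_sd_mm=0.0,
        drift_sd_mm=0.0,
        trial_duration_s=2.0,
        seed=11,
    )
    truth = synthesize_trajectory(params, 30.0)
    render = RenderConfig(pixel_noise_sd=0.0, center_jitter_px_sd=0.0)
    frames = render_video(truth, render)
    return truth, render, frames


@pytest.fixture(scope="session")
def frame_center() -> SeedPoint:
    """Centre of the default 128x128 render geometry."""
    return SeedPoint(63.5, 63.5)
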