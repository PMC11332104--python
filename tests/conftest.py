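"""Shared fixtures: a down-scaled screen and small synthetic cohorts.

Most tests run on a 480 x 270 px screen spanning the same 50 x 24 dva as
the study setup (9.6 / 11.25 px per degree), which keeps Gaussian blurs
and leave-one-out loops fast while preserving all angular relationships.
Tests that exercise the study-scale geometry construct it explicitly.
"""

import numpy as np
import pandas as pd
import pytest

from gazebench.geometry import ScreenGeometry
from gazebench.synthetic import SyntheticCohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_geometry() -> ScreenGeometry:
    return ScreenGeometry(width_px=480, height_px=270, width_dva=50.0, height_dva=24.0)


@pytest.fixture(scope="session")
def small_config(small_geometry) -> SyntheticCohortConfig:
    return SyntheticCohortConfig.for_geometry(small_geometry, n_participants=12, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_geometry):
    """12 participants on the down-scaled screen, with ground truth."""
    return simulate_cohort(small_config, small_geometry)


@pytest.fixture(scope="session")
def small_fixations(small_cohort, small_geometry):
    """Detected + selected analysis fixations of the small cohort."""
    from gazebench.preprocess import preprocess_cohort

    recordings, _ = small_cohort
    fixations, _, _ = preprocess_cohort(recordings, small_geometry)
    return fixations


def stationary_recording(points, geometry, rate_hz=60.0, noise_sd_px=0.0, seed=0, pid="p00000"):
    """Recording that dwells at each (x, y, n_samples) point in turn."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for x, y, n in points:
        xs.append(np.full(n, float(x)))
        ys.append(np.full(n, float(y)))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n = len(x)
    if noise_sd_px:
        x = x + rng.normal(0, noise_sd_px, n)
        y = y + rng.normal(0, noise_sd_px, n)
    from gazebench.synthetic import GazeRecording

    return GazeRecording(
        participant_id=pid,
        t_ms=np.arange(n) / rate_hz * 1000.0,
        x_px=x,
        y_px=y,
        valid=np.ones(n, dtype=bool),
    )
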