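import math

import numpy as np
import pytest

from flyphen.climbing import ClimbingCurve
from flyphen.synthetic import CohortParams
from flyphen.trajectory import TrajectorySet


@pytest.fixture
def deterministic_params():
    """All flies move straight up at exactly 9 mm/s with no latency."""
    return CohortParams(
        label="deterministic",
        mean_speed=9.0,
        speed_shape=math.inf,
        heading_sd=0.0,
        pause_prob=0.0,
        startle_latency_mean=0.0,
        hazard_scale=1.72e-4,
        hazard_shape=0.1,
    )


@pytest.fixture
def frozen_params():
    """Zero motion: every fly stays where it starts."""
    return CohortParams(
        label="frozen",
        mean_speed=0.0,
        speed_shape=1.0,
        heading_sd=0.0,
        pause_prob=0.0,
        startle_latency_mean=0.0,
        hazard_scale=1.72e-4,
        hazard_shape=0.1,
    )


def make_static_trajectory(y_values, x=14.0, n_frames=601, **kwargs):
    """Trajectory where each fly sits at a fixed (x, y) for all frames."""
    y = np.asarray(y_values, dtype=float)
    positions = np.zeros((len(y), n_frames, 2))
    positions[:, :, 0] = x
    positions[:, :, 1] = y[:, None]
    return TrajectorySet(positions=positions, **kwargs)


def make_curve(ci, trial_id="t0", group="", n_flies=10):
    return ClimbingCurve(
        ci=np.asarray(ci, dtype=float),
        n_flies=n_flies,
        group=group,
        trial_id=trial_id,
    )


@pytest.fixture
def small_brain():
    """Module-scope-free small synthetic brain for fast tests."""
    from flyphen.synthetic import simulate_brain

    return simulate_brain(
        shape=(64, 100, 120),
        n_vacuoles=3,
        diameter_range=(6.0, 12.0),
        p_neuropil=1.0,
        noise_sd=10.0,
        seed=11,
    )
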