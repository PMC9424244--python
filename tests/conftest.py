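import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spherotrack.trackdata import Assay, Ensemble, Trajectory

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_traj(points, dt=1.0, track_id="t0", assay=Assay.GFA):
    points = np.asarray(points, dtype=float)
    times = dt * np.arange(len(points))
    return Trajectory(track_id, times, points, assay)


def linear_traj(v=(1.0, 0.0), n=10, dt=1.0, start=(0.0, 0.0), **kw):
    """Uniform linear motion at velocity v um/min."""
    v = np.asarray(v, dtype=float)
    pts = np.asarray(start, dtype=float) + np.outer(dt * np.arange(n), v)
    return make_traj(pts, dt=dt, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_walk_traj(rng):
    steps = rng.normal(size=(60, 2))
    return make_traj(np.vstack([[0, 0], np.cumsum(steps, axis=0)]), dt=2.0)
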