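import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from thermodive import HeatModelParams, SimConfig, TagSeries, WaterColumn  # noqa: E402
from thermodive import synth  # noqa: E402

#: two-regime truth at the scale estimated for a large deep-diving mako
MAKO1_TRUTH = HeatModelParams(kind="variable", k_warm=0.052, k_cool=0.0036,
                              tm_dot=0.0062)


@pytest.fixture(scope="session")
def column():
    return WaterColumn(surface_temp=25.0, deep_temp=14.0,
                       thermocline_depth=100.0, transition_scale=10.0)


@pytest.fixture(scope="session")
def truth_params():
    return MAKO1_TRUTH


@pytest.fixture
def deployment(column, truth_params):
    """One noisy 24-h deployment with three deep dives (seed 11)."""
    cfg = SimConfig(seed=11, noise_sd=0.1)
    return synth.simulate_deployment(cfg, column, truth_params)


@pytest.fixture
def noiseless_deployment(column, truth_params):
    cfg = SimConfig(seed=0, noise_sd=0.0)
    return synth.simulate_deployment(cfg, column, truth_params)


def make_series(n=120, step=1.0, depth=None, ta=None, tb=None):
    """Small hand-rolled TagSeries for unit tests."""
    time = np.arange(n) * step
    if depth is None:
        depth = np.zeros(n)
    if ta is None:
        ta = np.full(n, 20.0)
    if tb is None:
        tb = np.full(n, 22.0)
    return TagSeries(time=time, depth=np.asarray(depth, float),
                     ta=np.asarray(ta, float), tb=np.asarray(tb, float))
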