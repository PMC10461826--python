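import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230816)


@pytest.fixture
def small_pair():
    """A deterministic 200-variant independent pair."""
    from gpstest import simulate_independent_null

    return simulate_independent_null(200, seed=7)


def brute_joint_counts(u, v):
    """Quadratic double-loop oracle for the joint 'count <=' ecdf."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    return np.array([
        int(np.sum((u <= u[i]) & (v <= v[i]))) for i in range(u.size)
    ])


def brute_gps_statistic(u, v):
    """Triple-loop evaluation of the weighted sup-norm statistic."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    n = u.size
    best = -np.inf
    for i in range(n):
        fu = np.sum(u <= u[i]) / n
        fv = np.sum(v <= v[i]) / n
        fuv = np.sum((u <= u[i]) & (v <= v[i])) / n
        rad = fu * fv - (fu * fv) ** 2
        if rad <= 0:
            continue
        t = np.sqrt(n / np.log(n)) * abs(fuv - fu * fv) / np.sqrt(rad)
        best = max(best, t)
    return best
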