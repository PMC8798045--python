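import numpy as np
import pytest

from mtkymo.config import SimConfig
from mtkymo.containers import EndTrajectory


@pytest.fixture
def base_config() -> SimConfig:
    return SimConfig(rng_seed=0)


@pytest.fixture
def sawtooth_trajectory() -> EndTrajectory:
    """Noiseless sawtooth: growth 10 nm/s for 300 s, shrink 100 nm/s to zero,
    repeated; corners aligned with the 5 s frame grid."""
    t = np.arange(0.0, 990.1, 5.0)
    period = 330.0  # 300 s growth + 30 s shrink
    pos = np.empty_like(t)
    for i, ti in enumerate(t):
        tau = ti % period
        pos[i] = 10.0 * tau if tau <= 300.0 else 3000.0 - 100.0 * (tau - 300.0)
    truth = []
    for k in range(3):
        truth.append((k * period, k * period + 300.0, "growth"))
        truth.append((k * period + 300.0, (k + 1) * period, "shrink"))
    truth[-1] = (truth[-1][0], t[-1], "shrink")
    truth = [p for p in truth if p[0] < t[-1]]
    return EndTrajectory(t, pos, truth_phases=truth)


@pytest.fixture
def linear_trajectory() -> EndTrajectory:
    t = np.arange(0.0, 600.1, 5.0)
    return EndTrajectory(t, 10.0 * t)
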