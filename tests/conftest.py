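import numpy as np
import pytest

from phagotrack import SimulationConfig, simulate_trajectory


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def short_diffusive_traj():
    """A 30 s forced-diffusive trajectory with localization noise."""
    cfg = SimulationConfig(seed=7, duration=30, forced_state="diffusive",
                           D_diff=1.0e4)
    return simulate_trajectory(cfg)


@pytest.fixture(scope="session")
def short_ballistic_traj():
    """A 30 s forced-directed constant-velocity trajectory."""
    cfg = SimulationConfig(seed=8, duration=30, forced_state="directed",
                           v_mean=500.0, v_sd=0.0, p_reverse=0.0)
    return simulate_trajectory(cfg)


def brute_force_window_msd(x, y, start, window, max_lag):
    """Independent double-loop time-averaged MSD for one window."""
    msd = []
    for k in range(1, max_lag + 1):
        acc = 0.0
        n = 0
        for i in range(start, start + window - k):
            acc += (x[i + k] - x[i]) ** 2 + (y[i + k] - y[i]) ** 2
            n += 1
        msd.append(acc / n)
    return np.array(msd)
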