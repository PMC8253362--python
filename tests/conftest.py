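import numpy as np
import pytest

from tmsnet import synthetic as syn


@pytest.fixture(scope="session")
def small_session():
    """A small synthetic session at a reduced rate, shared across read-only tests."""
    rec, trials = syn.simulate_session(n_trials_per_cell=2, fs=256.0, seed=7)
    return rec, trials


@pytest.fixture()
def step_schedule():
    """3-node step schedule: edge 0->1 switches from 0 to 0.6 at t = 0.75 s."""
    base = np.zeros((2, 3, 3))
    base[0] = np.diag([0.3, 0.3, 0.3])
    stepped = base.copy()
    stepped[0, 1, 0] = 0.6
    return syn.CoeffSchedule([(0.0, base), (0.75, stepped)])


def simulate_step_trials(schedule, n_trials, fs, duration, seed):
    """Independent trials drawn from one tv-VAR schedule (ensemble input)."""
    rng = np.random.default_rng(seed)
    n = schedule.n_channels
    return np.stack([
        syn.simulate_tvmvar(schedule, np.eye(n), duration, fs,
                            seed=int(rng.integers(2**31))).signal
        for _ in range(n_trials)
    ])
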