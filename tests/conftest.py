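import numpy as np
import pytest

from ctesm import BIVARIATE_TRUTH, CTParams, ScheduleConfig, generate_schedule, simulate_cvar
from ctesm.schedule import BeepSchedule
from ctesm.simulate import TimeSeries


@pytest.fixture(scope="session")
def bivariate_truth() -> CTParams:
    return BIVARIATE_TRUTH


def make_equally_spaced_schedule(n: int) -> BeepSchedule:
    """One long 'day' with unit gaps everywhere (no overnight)."""
    return BeepSchedule(
        times=np.arange(n, dtype=float),
        day_index=np.zeros(n, dtype=int),
        is_day_first=np.r_[True, np.zeros(n - 1, dtype=bool)],
    )


def make_white_noise_series(n_days: int, seed: int) -> TimeSeries:
    """iid N(0,1) observations on a realistic beep schedule."""
    sched = generate_schedule(ScheduleConfig(n_days=n_days, seed=seed))
    rng = np.random.default_rng(seed + 1)
    return TimeSeries(
        person_id="wn",
        times=sched.times,
        values=rng.standard_normal((sched.n, 1)),
        day_index=sched.day_index,
    )


@pytest.fixture(scope="session")
def long_univariate_series():
    """1,000-day series at phi = 0.4 (shared across estimation tests)."""
    ct = CTParams.from_phi(0.4)
    sched = generate_schedule(ScheduleConfig(n_days=1000, seed=11))
    return simulate_cvar(ct, sched, seed=7)
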