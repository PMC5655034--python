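"""Signal-contingent experience-sampling beep schedules.

A day's waking span is divided into back-to-back blocks; one beep lands
uniformly at random inside each block.  The interval between two
consecutive beeps in neighbouring blocks is then the sum of two independent
uniforms, i.e. triangularly distributed with lower bound 0, mode one block
and upper bound two blocks.  Designs may additionally forbid very short
same-day intervals (e.g. a 15-min minimum, one sixth of a 90-min block).

All internal times are in *block units*: Delta = 1 means one block, and
t = 0 is the start of day 1's waking span.  Nights are simply unobserved
stretches between the last beep of a day and the first of the next; for
the default 15-h day with ten 90-min blocks the expected overnight gap is
7 blocks (half a block + 6 night blocks + half a block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangularLaw",
    "ScheduleConfig",
    "DelayConfig",
    "BeepSchedule",
    "ConfigError",
    "triangular_stats",
    "generate_schedule",
    "generate_empirical_like_schedule",
    "EMPIRICAL_DAY_BLOCKS",
]

MINUTES_PER_DAY = 24.0 * 60.0


class ConfigError(ValueError):
    """A measurement design that cannot be realized."""


@dataclass(frozen=True)
class TriangularLaw:
    """Triangular distribution on [lower, upper] with the given mode."""

    lower: float
    upper: float
    mode: float

    def __post_init__(self) -> None:
        if not self.lower <= self.mode <= self.upper:
            raise ValueError(
                f"need lower <= mode <= upper, got {self.lower}, {self.mode}, {self.upper}"
            )

    @classmethod
    def within_block(cls, block_length: float) -> "TriangularLaw":
        """Law of the interval between beeps in two consecutive blocks of
        length ``block_length`` (sum of two independent uniforms)."""
        return cls(lower=0.0, upper=2.0 * block_length, mode=block_length)

    def cdf(self, x):
        """Distribution function (vectorized)."""
        a, b, c = self.lower, self.upper, self.mode
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if b > a:
            left = (x > a) & (x <= c)
            right = (x > c) & (x < b)
            if c > a:
                out[left] = (x[left] - a) ** 2 / ((b - a) * (c - a))
            if b > c:
                out[right] = 1.0 - (b - x[right]) ** 2 / ((b - a) * (b - c))
        out[x >= b] = 1.0
        return out


def triangular_stats(law: TriangularLaw) -> tuple[float, float]:
    """Mean and variance of a triangular law.

    mean = (a + b + c) / 3 and
    variance = (a^2 + b^2 + c^2 - ab - ac - bc) / 18, which for the
    within-block design (a = 0, b = 2 l_b, c = l_b) reduce to l_b and
    l_b^2 / 6 (90 min and 1,350 min^2 for 90-min blocks).
    """
    a, b, c = law.lower, law.upper, law.mode
    mean = (a + b + c) / 3.0
    variance = (a * a + b * b + c * c - a * b - a * c - b * c) / 18.0
    return mean, variance


@dataclass(frozen=True)
class ScheduleConfig:
    """Design of a back-to-back-block signal-contingent schedule.

    Defaults follow a standard simulation design: ten 90-min blocks filling
    a 15-h waking day (8:00-23:00), repeated over ``n_days`` days, with an
    optional minimum same-day interval expressed as a fraction of a block
    (1/6 of a 90-min block = 15 min).
    """

    n_days: int = 10
    beeps_per_day: int = 10
    block_minutes: float = 90.0
    day_start_hour: float = 8.0
    day_end_hour: float = 23.0
    min_interval_blocks: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.beeps_per_day < 1:
            raise ConfigError("n_days and beeps_per_day must be positive")
        if self.block_minutes <= 0:
            raise ConfigError("block_minutes must be positive")
        span_min = (self.day_end_hour - self.day_start_hour) * 60.0
        if self.beeps_per_day * self.block_minutes > span_min + 1e-9:
            raise ConfigError(
                f"{self.beeps_per_day} blocks of {self.block_minutes} min do not "
                f"fit in a {span_min / 60.0}-h day"
            )
        if not 0.0 <= self.min_interval_blocks < 1.0:
            raise ConfigError(
                "min_interval_blocks must lie in [0, 1); a minimum of a full "
                "block or more is infeasible for back-to-back blocks"
            )

    @property
    def day_length_blocks(self) -> float:
        """Length of a full 24-h day in block units."""
        return MINUTES_PER_DAY / self.block_minutes


@dataclass(frozen=True)
class BeepSchedule:
    """Realized beep (or response) times, in block units from day 1's start."""

    times: np.ndarray
    day_index: np.ndarray
    is_day_first: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.day_index, dtype=int)
        f = np.asarray(self.is_day_first, dtype=bool)
        if not (t.ndim == 1 and t.shape == d.shape == f.shape):
            raise ValueError("times, day_index and is_day_first must be 1-d and aligned")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("beep times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "day_index", d)
        object.__setattr__(self, "is_day_first", f)

    @property
    def n(self) -> int:
        return self.times.size

    def deltas(self) -> np.ndarray:
        """True intervals between consecutive beeps (block units)."""
        return np.diff(self.times)

    def within_day_deltas(self) -> np.ndarray:
        """Intervals whose two endpoints fall on the same day."""
        return self.deltas()[~self.is_day_first[1:]]


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_schedule(config: ScheduleConfig) -> BeepSchedule:
    """Draw one beep uniformly per block per day.

    When ``min_interval_blocks > 0`` the later beep of any violating
    same-day pair is redrawn within its own block until the constraint
    holds (rejection sampling, preserving per-block uniformity conditional
    on feasibility).  The minimum-interval rule applies within days only;
    overnight gaps are always long.
    """
    day_len = config.day_length_blocks
    times = np.empty(config.n_days * config.beeps_per_day)
    day_index = np.empty_like(times, dtype=int)
    pos = 0
    for day, rng in enumerate(_spawn_rngs(config.seed, config.n_days)):
        base = day * day_len
        prev = None
        for block in range(config.beeps_per_day):
            t = base + block + rng.uniform()
            if config.min_interval_blocks > 0.0 and prev is not None:
                tries = 0
                while t - prev < config.min_interval_blocks:
                    t = base + block + rng.uniform()
                    tries += 1
                    if tries > 100_000:  # pragma: no cover - min < 1 is always feasible
                        raise ConfigError("minimum-interval rejection did not terminate")
            times[pos] = t
            day_index[pos] = day
            prev = t
            pos += 1
    is_day_first = np.zeros(times.size, dtype=bool)
    is_day_first[:: config.beeps_per_day] = True
    return BeepSchedule(times=times, day_index=day_index, is_day_first=is_day_first)


# Empirical-like day structure: a morning block (8-10 AM, 2-h response
# window), six blocks between 10 AM and 8 PM (1.5-h window each), and an
# evening block (8-10 PM, 4-h window).  Entries are
# (start_hour, end_hour, response_window_hours).
EMPIRICAL_DAY_BLOCKS: tuple[tuple[float, float, float], ...] = (
    (8.0, 10.0, 2.0),
    *(
        (10.0 + k * 10.0 / 6.0, 10.0 + (k + 1) * 10.0 / 6.0, 1.5)
        for k in range(6)
    ),
    (20.0, 22.0, 4.0),
)


@dataclass(frozen=True)
class DelayConfig:
    """Response-delay model for an empirical-like schedule.

    Participants answer a beep after a nonnegative delay; delays are
    exponential with mean ``mean_minutes``, truncated at the block's
    response window (and at ``max_minutes`` if given).  ``nonresponse_prob``
    drops a beep entirely.  The delay law is deliberately a free knob:
    real response-time distributions are study-specific.
    """

    mean_minutes: float = 15.0
    max_minutes: float | None = None
    nonresponse_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.mean_minutes < 0:
            raise ConfigError("mean_minutes must be nonnegative")
        if not 0.0 <= self.nonresponse_prob < 1.0:
            raise ConfigError("nonresponse_prob must lie in [0, 1)")
        if self.max_minutes is not None:
            smallest_window = min(w for _, _, w in EMPIRICAL_DAY_BLOCKS) * 60.0
            if self.max_minutes > smallest_window:
                raise ConfigError(
                    f"max_minutes={self.max_minutes} exceeds the shortest "
                    f"response window ({smallest_window} min)"
                )


def _truncated_exponential(
    rng: np.random.Generator, mean: float, lo: float, hi: float
) -> float:
    """Exponential(mean) conditioned on (lo, hi], by inverse CDF."""
    if mean <= 0.0:
        return lo
    p_lo = np.exp(-lo / mean)
    p_hi = np.exp(-hi / mean)
    u = rng.uniform()
    return -mean * np.log(p_lo - u * (p_lo - p_hi))


def generate_empirical_like_schedule(
    config: ScheduleConfig | None = None,
    delay: DelayConfig | None = None,
) -> BeepSchedule:
    """Schedule with response delays mimicking an adolescent-affect design.

    Seven days with at most eight beeps each: one between 8 and 10 AM, six
    between 10 AM and 8 PM, one between 8 and 10 PM.  The *response* time
    (beep plus truncated-exponential delay) is recorded, so consecutive
    observations can fall much closer together than one block; a beep whose
    response cannot be placed after the previous response within its window
    is treated as missed.  Block units use ``config.block_minutes``
    (default 105 min, the design's average block length).
    """
    if config is None:
        config = ScheduleConfig(
            n_days=7, beeps_per_day=8, block_minutes=105.0,
            day_start_hour=8.0, day_end_hour=22.0,
        )
    if delay is None:
        delay = DelayConfig()
    if config.beeps_per_day != len(EMPIRICAL_DAY_BLOCKS):
        raise ConfigError(
            f"empirical-like design has {len(EMPIRICAL_DAY_BLOCKS)} blocks per day"
        )
    origin_min = EMPIRICAL_DAY_BLOCKS[0][0] * 60.0  # t = 0 at 8 AM on day 1
    times: list[float] = []
    day_index: list[int] = []
    is_day_first: list[bool] = []
    prev_min = -np.inf
    for day, rng in enumerate(_spawn_rngs(config.seed, config.n_days)):
        first_of_day = True
        for start_h, end_h, window_h in EMPIRICAL_DAY_BLOCKS:
            if delay.nonresponse_prob > 0.0 and rng.uniform() < delay.nonresponse_prob:
                continue
            beep_min = day * MINUTES_PER_DAY + rng.uniform(start_h, end_h) * 60.0
            cap = window_h * 60.0
            if delay.max_minutes is not None:
                cap = min(cap, delay.max_minutes)
            lo = max(0.0, prev_min - beep_min)
            if lo >= cap:  # cannot respond after the previous response: missed
                continue
            if delay.mean_minutes == 0.0:
                d = 0.0 if lo == 0.0 else lo + 1e-9
            else:
                d = max(_truncated_exponential(rng, delay.mean_minutes, lo, cap),
                        lo + 1e-9)
            resp_min = beep_min + d
            times.append((resp_min - origin_min) / config.block_minutes)
            day_index.append(day)
            is_day_first.append(first_of_day)
            first_of_day = False
            prev_min = resp_min
    return BeepSchedule(
        times=np.asarray(times),
        day_index=np.asarray(day_index, dtype=int),
        is_day_first=np.asarray(is_day_first, dtype=bool),
    )
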