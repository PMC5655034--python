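"""Exact simulation of a stationary CVAR(1) process at scheduled beep times.

The discretization is exact: the first observation is drawn from the
stationary law N(0, Sigma_y), and every subsequent observation uses the
closed-form transition

    y_i = expm(B * Delta_i) @ y_{i-1} + eps_i,
    eps_i ~ N(0, Sigma_y - expm(B D) Sigma_y expm(B D)'),

with the *true* elapsed interval Delta_i, overnight gaps included — the
process keeps evolving, unobserved, through the night.  No Euler stepping
is involved, so there is no discretization error at any interval length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CTParams, innovation_cov_ct, phi_of_delta
from .schedule import BeepSchedule

__all__ = ["TimeSeries", "simulate_cvar"]


@dataclass
class TimeSeries:
    """Timestamped multivariate observations for one person.

    ``values`` has shape (n, K); ``times`` are in block units and strictly
    increasing.  ``truth`` optionally records the generating parameters.
    """

    person_id: str
    times: np.ndarray
    values: np.ndarray
    day_index: np.ndarray
    truth: CTParams | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.size and self.values.shape[1] == self.times.size:
            self.values = self.values.T
        self.day_index = np.asarray(self.day_index, dtype=int)
        if self.values.shape[0] != self.times.size or self.day_index.size != self.times.size:
            raise ValueError("times, values and day_index must be aligned")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def K(self) -> int:
        return self.values.shape[1]

    @property
    def is_day_first(self) -> np.ndarray:
        first = np.ones(self.n, dtype=bool)
        first[1:] = self.day_index[1:] != self.day_index[:-1]
        return first

    def centered(self) -> "TimeSeries":
        """Per-variable sample-mean-centered copy."""
        return TimeSeries(
            person_id=self.person_id,
            times=self.times.copy(),
            values=self.values - self.values.mean(axis=0),
            day_index=self.day_index.copy(),
            truth=self.truth,
        )


def _sqrt_psd(m: np.ndarray) -> np.ndarray:
    """Matrix square root factor L with L L' = m, tolerant of singular m."""
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh((m + m.T) / 2.0)
        return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_cvar(ct: CTParams, schedule: BeepSchedule, seed: int) -> TimeSeries:
    """Simulate the process exactly at the schedule's beep times.

    Transition matrices and innovation Cholesky factors are cached per
    unique interval (schedules with rounded or repeated gaps reuse them).
    Reproducible bitwise from ``seed``.
    """
    if schedule.n == 0:
        raise ValueError("schedule is empty")
    K = ct.K
    rng = np.random.default_rng(seed)
    deltas = schedule.deltas()
    keys = np.round(deltas, 12)
    uniq, inverse = np.unique(keys, return_inverse=True)
    A = np.empty((uniq.size, K, K))
    L = np.empty((uniq.size, K, K))
    for j, d in enumerate(uniq):
        A[j] = phi_of_delta(ct, float(d))
        L[j] = _sqrt_psd(innovation_cov_ct(ct, float(d)).Sigma_eps_delta)
    Ly = _sqrt_psd(ct.Sigma_y)
    z = rng.standard_normal((schedule.n, K))
    values = np.empty((schedule.n, K))
    y = Ly @ z[0]
    values[0] = y
    for i in range(1, schedule.n):
        j = inverse[i - 1]
        y = A[j] @ y + L[j] @ z[i]
        values[i] = y
    if not np.allclose(np.diag(ct.Sigma_y), 1.0):
        import warnings

        warnings.warn(
            "Sigma_y does not have a unit diagonal; downstream summaries "
            "assume standardized variables",
            stacklevel=2,
        )
    return TimeSeries(
        person_id="sim",
        times=schedule.times.copy(),
        values=values,
        day_index=schedule.day_index.copy(),
        truth=ct,
    )
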