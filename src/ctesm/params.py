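"""Continuous- and discrete-time parameterizations of first-order (vector)
autoregressive processes, and the exact translations between them.

The continuous-time model is the (multivariate) Ornstein-Uhlenbeck process,
written here as a CVAR(1): a drift matrix ``B`` (all eigenvalues with
negative real part) together with the stationary covariance ``Sigma_y``
fully determines the discrete-time regression matrix for any elapsed
interval ``delta`` via the matrix exponential,

    Phi(delta) = expm(B * delta),

and the interval-dependent innovation covariance

    Sigma_eps(delta) = Sigma_y - Phi(delta) @ Sigma_y @ Phi(delta).T .

The discrete-time VAR(1) is the special case where every interval is taken
to be one unit.  Going the other way (``Phi -> B``) is only possible when
``Phi`` admits a real matrix logarithm with a stable (negative-real-part)
spectrum; otherwise a :class:`NoCTRepresentationError` is raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, logm

__all__ = [
    "CTParams",
    "DTParams",
    "IntervalInnovation",
    "NonStationaryError",
    "NoCTRepresentationError",
    "phi_of_delta",
    "drift_of_phi",
    "innovation_cov_ct",
    "innovation_cov_dt",
    "diffusion_of",
    "stationary_mean",
]


class NonStationaryError(ValueError):
    """Parameters do not describe a stationary process."""


class NoCTRepresentationError(ValueError):
    """The discrete-time parameters have no continuous-time counterpart."""


def _square(x, name: str) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {arr.shape}")
    return arr


def _check_symmetric_psd(m: np.ndarray, name: str, *, definite: bool = False) -> None:
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh((m + m.T) / 2.0)
    if definite:
        bad = w.min() <= 1e-12
    else:
        bad = w.min() < -1e-10 * max(1.0, float(np.abs(w).max(initial=1.0)))
    if bad:
        kind = "positive definite" if definite else "positive semidefinite"
        raise ValueError(f"{name} must be {kind} (eigenvalues {w})")


def _symmetrize_psd(m: np.ndarray, *, tol: float = 1e-10) -> np.ndarray:
    """Symmetrize and clip tiny negative eigenvalues; larger negativity errors.

    Floating-point guard only: genuine indefiniteness (beyond ``tol`` relative
    to the spectral radius) is a modeling bug and raises.
    """
    sym = (m + m.T) / 2.0
    w, v = np.linalg.eigh(sym)
    scale = max(1.0, float(np.abs(w).max(initial=1.0)))
    if w.min() < -tol * scale:
        raise ValueError(f"matrix is not positive semidefinite (eigenvalues {w})")
    if w.min() < 0.0:
        sym = (v * np.clip(w, 0.0, None)) @ v.T
        sym = (sym + sym.T) / 2.0
    return sym


@dataclass(frozen=True)
class CTParams:
    """Parameters of a stationary CVAR(1) / Ornstein-Uhlenbeck process.

    Parameters
    ----------
    B
        K x K drift matrix (rate per block unit); all eigenvalues must have
        negative real part.
    Sigma_y
        K x K stationary covariance, symmetric positive definite.
    a
        Intercept vector (zero for centered analyses, the default).
    """

    B: np.ndarray
    Sigma_y: np.ndarray
    a: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        B = _square(self.B, "B")
        S = _square(self.Sigma_y, "Sigma_y")
        if B.shape != S.shape:
            raise ValueError("B and Sigma_y must have the same shape")
        eig = np.linalg.eigvals(B)
        if eig.real.max() >= 0.0:
            raise NonStationaryError(
                f"drift eigenvalues must have negative real part, got {eig}"
            )
        _check_symmetric_psd(S, "Sigma_y", definite=True)
        a = np.zeros(B.shape[0]) if self.a is None else np.asarray(self.a, float).ravel()
        if a.shape != (B.shape[0],):
            raise ValueError("intercept a has wrong length")
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "Sigma_y", (S + S.T) / 2.0)
        object.__setattr__(self, "a", a)

    @property
    def K(self) -> int:
        return self.B.shape[0]

    @classmethod
    def from_phi(cls, phi: float, sigma_y: float = 1.0, delta: float = 1.0) -> "CTParams":
        """Univariate convenience: the CT process whose autocorrelation at
        interval ``delta`` equals ``phi`` and whose stationary variance is
        ``sigma_y``."""
        if not 0.0 < phi < 1.0:
            raise NoCTRepresentationError(
                f"phi must lie in (0, 1) for a CT representation, got {phi}"
            )
        return cls(B=[[np.log(phi) / delta]], Sigma_y=[[sigma_y]])


@dataclass(frozen=True)
class DTParams:
    """Parameters of a stationary VAR(1) for a named interval ``delta``."""

    Phi: np.ndarray
    c: np.ndarray = None  # type: ignore[assignment]
    Sigma_eps: np.ndarray = None  # type: ignore[assignment]
    delta: float = 1.0

    def __post_init__(self) -> None:
        Phi = _square(self.Phi, "Phi")
        if np.abs(np.linalg.eigvals(Phi)).max() >= 1.0:
            raise NonStationaryError("spectral radius of Phi must be < 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        c = np.zeros(Phi.shape[0]) if self.c is None else np.asarray(self.c, float).ravel()
        if self.Sigma_eps is not None:
            Se = _square(self.Sigma_eps, "Sigma_eps")
            _check_symmetric_psd(Se, "Sigma_eps")
            object.__setattr__(self, "Sigma_eps", (Se + Se.T) / 2.0)
        object.__setattr__(self, "Phi", Phi)
        object.__setattr__(self, "c", c)

    @property
    def K(self) -> int:
        return self.Phi.shape[0]


@dataclass(frozen=True)
class IntervalInnovation:
    """Innovation covariance attached to a specific elapsed interval."""

    delta: float
    Sigma_eps_delta: np.ndarray


def phi_of_delta(ct: CTParams, delta: float) -> np.ndarray:
    """Regression matrix implied by the drift for an elapsed interval.

    Returns ``expm(B * delta)`` (a K x K array; the univariate case is a
    1 x 1 array holding the scalar exponential ``exp(B * delta)``).
    """
    if delta < 0:
        raise ValueError(f"delta must be nonnegative, got {delta}")
    if ct.K == 1:
        return np.array([[np.exp(ct.B[0, 0] * delta)]])
    return expm(ct.B * delta)


def drift_of_phi(dt: DTParams) -> np.ndarray:
    """Drift matrix whose exponential at interval ``dt.delta`` equals ``Phi``.

    Only the principal matrix logarithm is considered.  If ``Phi`` has no
    real logarithm with a stable spectrum (univariate: ``phi`` outside
    ``(0, 1)``; multivariate: eigenvalues on the closed negative real axis,
    or a logarithm with nonnegative real part), there is no valid
    continuous-time counterpart and :class:`NoCTRepresentationError` is
    raised.
    """
    Phi = dt.Phi
    if dt.K == 1:
        phi = Phi[0, 0]
        if not 0.0 < phi < 1.0:
            raise NoCTRepresentationError(
                f"univariate phi must lie in (0, 1), got {phi}"
            )
        return np.array([[np.log(phi) / dt.delta]])
    eig = np.linalg.eigvals(Phi)
    if np.any((eig.real <= 0.0) & (np.abs(eig.imag) < 1e-12)):
        raise NoCTRepresentationError(
            f"Phi has an eigenvalue on the closed negative real axis ({eig}); "
            "no real matrix logarithm exists"
        )
    L = logm(Phi)
    if np.abs(np.imag(L)).max() > 1e-8:
        raise NoCTRepresentationError("principal logarithm of Phi is not real")
    B = np.real(L) / dt.delta
    if np.linalg.eigvals(B).real.max() >= 0.0:
        raise NoCTRepresentationError(
            "logarithm of Phi does not have a stable (negative real part) spectrum"
        )
    return B


def innovation_cov_ct(ct: CTParams, delta: float) -> IntervalInnovation:
    """Exact innovation covariance for an elapsed interval.

    ``Sigma_eps(delta) = Sigma_y - expm(B d) Sigma_y expm(B d)'``; it is zero
    at ``delta = 0`` and tends to ``Sigma_y`` as ``delta`` grows.
    """
    A = phi_of_delta(ct, delta)
    Se = ct.Sigma_y - A @ ct.Sigma_y @ A.T
    return IntervalInnovation(delta=float(delta), Sigma_eps_delta=_symmetrize_psd(Se))


def innovation_cov_dt(dt: DTParams, Sigma_y) -> np.ndarray:
    """Unit-interval innovation covariance, ``Sigma_y - Phi Sigma_y Phi'``."""
    S = _square(Sigma_y, "Sigma_y")
    _check_symmetric_psd(S, "Sigma_y", definite=True)
    return _symmetrize_psd(S - dt.Phi @ S @ dt.Phi.T)


def diffusion_of(ct: CTParams) -> np.ndarray:
    """Diffusion matrix GG' of the underlying stochastic differential equation.

    Solves the continuous Lyapunov equation ``B Sigma_y + Sigma_y B' + GG' = 0``
    for ``GG'`` (which, with ``GG'`` as the unknown, is simply
    ``-(B Sigma_y + Sigma_y B')``).  Consistency utility only: the pipeline
    parameterizes the process by ``Sigma_y`` directly.
    """
    return _symmetrize_psd(-(ct.B @ ct.Sigma_y + ct.Sigma_y @ ct.B.T))


def stationary_mean(c, Phi) -> np.ndarray:
    """Stationary mean ``(I - Phi)^-1 c`` of a stationary VAR(1)."""
    Phi = _square(Phi, "Phi")
    c = np.asarray(c, float).ravel()
    eye = np.eye(Phi.shape[0])
    try:
        return np.linalg.solve(eye - Phi, c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("I - Phi is singular; no stationary mean") from exc
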