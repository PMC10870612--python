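"""Uniform (compound-symmetry) and exponential (AR(1)-type) correlation.

Both are single-parameter models for the within-participant correlation of
serial outcomes:

* uniform: every pair of occasions has the same correlation ``alpha`` —
  the natural structure under a subject-level random effect, commonly seen
  with patient-reported outcome measures;
* exponential: ``rho_{rr'} = gamma ** |d_r - d_r'|`` decays with the time
  separation, ``gamma`` being the correlation at unit separation.

Both admit closed-form determinants and inverses, which is what makes the
planning variance formulas explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import FollowUpSchedule

__all__ = [
    "CorrelationSpec",
    "CovarianceSpec",
    "corr_matrix",
    "det_uniform",
    "inv_corr_closed",
    "gamma_from_reference",
]


@dataclass(frozen=True)
class CorrelationSpec:
    """Correlation model ``kind`` in {"uniform", "exponential"} with its parameter.

    The parameter (``alpha`` for uniform, ``gamma`` for exponential) must lie
    in ``[0, 1)``; 1 is excluded because the correlation matrix degenerates.
    """

    kind: str
    param: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "exponential"):
            raise ValueError("kind must be 'uniform' or 'exponential'")
        if not 0.0 <= self.param < 1.0:
            raise ValueError("correlation parameter must lie in [0, 1)")


@dataclass(frozen=True)
class CovarianceSpec:
    """Per-occasion outcome standard deviations ``sigma_1 .. sigma_s``."""

    sigma: np.ndarray

    def __init__(self, sigma) -> None:
        arr = np.atleast_1d(np.asarray(sigma, dtype=float))
        if np.any(arr <= 0):
            raise ValueError("all outcome SDs must be positive")
        arr.flags.writeable = False
        object.__setattr__(self, "sigma", arr)

    def covariance(self, corr: CorrelationSpec, sched: FollowUpSchedule) -> np.ndarray:
        """Full covariance ``Sigma = S^{1/2} R S^{1/2}``."""
        if self.sigma.size not in (1, sched.s):
            raise ValueError("sigma must be scalar or match the schedule length")
        sig = np.broadcast_to(self.sigma, (sched.s,))
        R = corr_matrix(corr, sched)
        return R * np.outer(sig, sig)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CovarianceSpec):
            return NotImplemented
        return self.sigma.shape == other.sigma.shape and bool(np.all(self.sigma == other.sigma))

    def __hash__(self) -> int:
        return hash(self.sigma.tobytes())


def corr_matrix(spec: CorrelationSpec, sched: FollowUpSchedule) -> np.ndarray:
    """The ``s x s`` correlation matrix over the follow-up schedule.

    Symmetric, unit diagonal, positive definite for parameters in [0, 1).
    """
    s = sched.s
    if spec.kind == "uniform":
        R = np.full((s, s), spec.param)
        np.fill_diagonal(R, 1.0)
        return R
    sep = np.abs(sched.d[:, None] - sched.d[None, :])
    with np.errstate(divide="ignore"):
        R = np.where(sep == 0, 1.0, spec.param ** sep)
    return R


def det_uniform(m: int, alpha: float) -> float:
    """Determinant of the ``m x m`` compound-symmetry correlation matrix.

    ``det(R_m) = (1 - alpha)^(m-1) (1 + (m-1) alpha)``; positive for
    ``alpha`` in [0, 1).
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    return (1.0 - alpha) ** (m - 1) * (1.0 + (m - 1) * alpha)


def inv_corr_closed(spec: CorrelationSpec, sched: FollowUpSchedule) -> np.ndarray:
    """Closed-form inverse of the correlation matrix.

    Uniform: ``R^{-1} = (I - alpha/(1 + (s-1) alpha) J) / (1 - alpha)`` with
    ``J`` the all-ones matrix. Exponential: the inverse is tridiagonal, built
    from the adjacent-pair correlations ``rho_r = gamma^(d_{r+1} - d_r)`` —
    the Markov property of the AR(1)-type structure.
    """
    s = sched.s
    a = spec.param
    if spec.kind == "uniform":
        if 1.0 - a <= 0:
            raise np.linalg.LinAlgError("uniform correlation matrix singular at alpha=1")
        J = np.ones((s, s))
        return (np.eye(s) - a / (1.0 + (s - 1) * a) * J) / (1.0 - a)
    if a == 0.0:
        return np.eye(s)
    rho = a ** np.diff(sched.d)  # adjacent correlations, length s-1
    one_m = 1.0 - rho**2
    inv = np.zeros((s, s))
    inv[0, 0] = 1.0 / one_m[0]
    inv[-1, -1] = 1.0 / one_m[-1]
    for r in range(1, s - 1):
        inv[r, r] = 1.0 / one_m[r - 1] + 1.0 / one_m[r] - 1.0
    for r in range(s - 1):
        inv[r, r + 1] = inv[r + 1, r] = -rho[r] / one_m[r]
    return inv


def gamma_from_reference(rho_ref: float, d_r: float, d_r_prime: float) -> float:
    """Calibrate the exponential parameter from one known correlation.

    Given the correlation ``rho_ref`` between occasions at times ``d_r`` and
    ``d_r'``, ``gamma = rho_ref ** (1 / |d_r - d_r'|)`` — e.g. a 3-vs-12
    month correlation of 0.5 with d=(1,2,4,6) gives gamma = 0.5**(1/3).
    """
    if not 0.0 < rho_ref < 1.0:
        raise ValueError("reference correlation must lie in (0, 1)")
    if d_r == d_r_prime:
        raise ValueError("reference occasions must be distinct")
    return rho_ref ** (1.0 / abs(d_r - d_r_prime))
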