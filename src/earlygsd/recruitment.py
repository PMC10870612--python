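"""Expected data accrual under simple recruitment-rate models.

Participants enter over a recruitment period of length ``T_R`` under one of
three rate profiles — fixed, linearly increasing or linearly decreasing —
all with the same mean rate ``N / T_R``. A participant recruited at calendar
time ``a`` contributes outcome data at occasion ``r`` from time ``a + d_r``
onward, so the expected number with occasion-``r`` data at calendar time
``t`` is ``N_r(t) = k * g(t - d_r)`` for a model-specific constant ``k`` and
accrual shape ``g``:

=============  =======================  =========================
model          k                        g(u), 0 <= u <= T_R
=============  =======================  =========================
fixed          N / T_R                  u
increasing     N / {T_R (T_R + 1)}      u (u + 1)
decreasing     N / {T_R (T_R + 1)}      u (2 T_R - u + 1)
=============  =======================  =========================

The ``(T_R + 1)`` factors come from the integer-day rate derivation of the
linear models; accrual is nevertheless evaluated as a continuous function of
time, which matches the printed planning quantities to the precision given.
Counts are real-valued expectations and may be fractional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .schedule import FollowUpSchedule

__all__ = [
    "RecruitmentSpec",
    "accrual_g",
    "n_with_outcome",
    "counts_at",
    "recruitment_rate",
    "time_at_tau0",
    "ratio_n",
]

_MODELS = ("fixed", "increasing", "decreasing")


@dataclass(frozen=True)
class RecruitmentSpec:
    """Recruitment model, planned total sample size and recruitment period.

    Parameters
    ----------
    model : {"fixed", "increasing", "decreasing"}
        Rate profile over the recruitment period.
    N : float
        Planned total sample size (participants).
    T_R : float
        Recruitment period length, in the same units as the follow-up
        schedule. Interim analyses on primary-outcome data are only possible
        when ``T_R > d_s`` (the "window of opportunity").
    """

    model: str
    N: float
    T_R: float

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.T_R <= 0:
            raise ValueError("T_R must be positive")

    @property
    def k(self) -> float:
        """Scale constant linking the accrual shape ``g`` to counts."""
        if self.model == "fixed":
            return self.N / self.T_R
        return self.N / (self.T_R * (self.T_R + 1.0))

    def g(self, u):
        """Accrual shape evaluated at elapsed time ``u`` in [0, T_R]."""
        u = np.asarray(u, dtype=float)
        if self.model == "fixed":
            return u
        if self.model == "increasing":
            return u * (u + 1.0)
        return u * (2.0 * self.T_R - u + 1.0)

    def g_prime(self, u):
        """Derivative of the accrual shape (needed for analytic gradients)."""
        u = np.asarray(u, dtype=float)
        if self.model == "fixed":
            return np.ones_like(u)
        if self.model == "increasing":
            return 2.0 * u + 1.0
        return 2.0 * self.T_R + 1.0 - 2.0 * u


def accrual_g(spec: RecruitmentSpec, t, d_r):
    """Clamped accrual shape ``g_r(t, d_r)``.

    Zero before outcome data exist (``t <= d_r``), the model's ``g(t - d_r)``
    during collection, and constant at ``g(T_R)`` once every participant has
    occasion-``r`` data. Non-decreasing in ``t``.
    """
    t = np.asarray(t, dtype=float)
    d_r = np.asarray(d_r, dtype=float)
    if np.any(t < 0) or np.any(d_r < 0):
        raise ValueError("t and d_r must be non-negative")
    u = np.clip(t - d_r, 0.0, spec.T_R)
    return spec.g(u)


def n_with_outcome(spec: RecruitmentSpec, sched: FollowUpSchedule, t, r: int):
    """Expected number of participants with occasion-``r`` data at time ``t``.

    ``r = 0`` addresses recruitment itself (``d_0 = 0``), giving the expected
    number recruited. Counts are expectations and may be fractional; they
    reach ``N`` at ``t >= d_r + T_R``.
    """
    if not 0 <= r <= sched.s:
        raise IndexError(f"occasion index r={r} outside 0..{sched.s}")
    d_r = 0.0 if r == 0 else float(sched.d[r - 1])
    return spec.k * accrual_g(spec, t, d_r)


def counts_at(spec: RecruitmentSpec, sched: FollowUpSchedule, t) -> np.ndarray:
    """Vector ``(N_1(t), ..., N_s(t))`` of expected per-occasion counts."""
    return spec.k * accrual_g(spec, t, sched.d)


def recruitment_rate(spec: RecruitmentSpec, t):
    """Instantaneous recruitment rate (participants per unit time).

    The mean rate over the recruitment period is ``N / T_R`` for all three
    models; the linear models start/end at ``2N/(T_R+1)`` and
    ``2N/{T_R(T_R+1)}`` (or vice versa).
    """
    t = np.asarray(t, dtype=float)
    if spec.model == "fixed":
        return np.broadcast_to(spec.N / spec.T_R, t.shape).copy() if t.ndim else spec.N / spec.T_R
    if spec.model == "increasing":
        return 2.0 * spec.N * t / (spec.T_R * (spec.T_R + 1.0))
    return 2.0 * spec.N * (spec.T_R - t + 1.0) / (spec.T_R * (spec.T_R + 1.0))


def time_at_tau0(spec: RecruitmentSpec, sched: FollowUpSchedule, tau0: float) -> float:
    """Calendar time at which a fraction ``tau0`` has primary-outcome data.

    Inverts ``N_s(t) / N = tau0`` on the interval ``(d_s, d_s + T_R]``:
    closed form for the fixed model, the admissible quadratic root in
    ``u = t - d_s`` for the linear models.
    """
    if not 0.0 < tau0 <= 1.0:
        raise ValueError("tau0 must lie in (0, 1]")
    d_s = sched.d_s
    T_R = spec.T_R
    if spec.model == "fixed":
        return d_s + tau0 * T_R
    c = tau0 * T_R * (T_R + 1.0)
    if spec.model == "increasing":
        # u (u + 1) = c
        u = (-1.0 + math.sqrt(1.0 + 4.0 * c)) / 2.0
    else:
        # u (2 T_R + 1 - u) = c, smaller root lies in (0, T_R]
        b = 2.0 * T_R + 1.0
        u = (b - math.sqrt(b * b - 4.0 * c)) / 2.0
    return d_s + u


def ratio_n(spec: RecruitmentSpec, sched: FollowUpSchedule, t, r: int, r_prime: int) -> float:
    """Count ratio ``n_{rr'}(t) = N_r(t) / N_{r'}(t) = g_r / g_{r'}``.

    Independent of ``N`` and of the allocation weight. Raises if the
    denominator occasion has no data yet.
    """
    num = accrual_g(spec, t, sched.d[r - 1])
    den = accrual_g(spec, t, sched.d[r_prime - 1])
    if den == 0:
        raise ZeroDivisionError(
            f"occasion {r_prime} has no accrued data at t={t}; ratio undefined"
        )
    return float(num / den)
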