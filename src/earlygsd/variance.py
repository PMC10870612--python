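"""Variance of the primary treatment effect and information accrual.

At calendar time ``t`` during a trial, participants contribute a monotone
pattern of longitudinal outcomes: more data at the early occasions than at
the primary occasion ``d_s``. Under a compound-symmetry ("uniform") or
AR(1)-type ("exponential") correlation structure the variance of the GLS
treatment effect at the primary occasion, ``var(beta_s)``, has a closed
form in the per-occasion counts. Dividing by the no-correlation variance
``sigma_s^2 / {k phi (1-phi) g_s(t)}`` defines the variance-reduction
factor ``V_s(t)`` in ``(0, 1]``: ``1/V`` is the proportionate information
gain contributed by the early outcomes, and the information fraction at an
interim is ``tau = tau0 / V`` where ``tau0 = N_s(t)/N`` is the fraction of
participants with primary-outcome data.

The closed forms here are exact (they agree with the brute-force GLS
information-matrix computation, provided as :func:`gls_variance_oracle`),
and the analytic extrema over the placement of the intermediate early
occasions bracket the achievable designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .correlation import CorrelationSpec, CovarianceSpec, corr_matrix
from .recruitment import RecruitmentSpec, accrual_g, counts_at
from .schedule import AllocationSpec, FollowUpSchedule

__all__ = [
    "DesignPoint",
    "InformationSummary",
    "var_beta_counts",
    "var_beta_at",
    "v_factor",
    "uniform_D",
    "v_uniform_extrema",
    "v_exp_max",
    "v_exp_min",
    "information_fraction",
    "gls_variance_oracle",
]


@dataclass(frozen=True)
class DesignPoint:
    """A design evaluated at one calendar time.

    Bundles the calendar time ``t``, follow-up schedule, recruitment and
    correlation models, allocation weight and primary-outcome SD at which
    variance and information are computed. Interim evaluation requires
    ``d_s < t <= d_s + T_R`` so that some, but not necessarily all,
    participants have primary-outcome data.
    """

    t: float
    sched: FollowUpSchedule
    rec: RecruitmentSpec
    corr: CorrelationSpec
    alloc: AllocationSpec = AllocationSpec(0.5)
    sigma_s: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")
        if self.t <= self.sched.d_s:
            raise ValueError(
                f"no primary-outcome data before d_s={self.sched.d_s}; got t={self.t}"
            )


@dataclass(frozen=True)
class InformationSummary:
    """Variance, variance-reduction factor and information fractions at ``t``.

    Attributes
    ----------
    var_beta : variance of the primary treatment effect (outcome units^2).
    V : variance-reduction factor in (0, 1].
    tau0 : information fraction from primary-outcome data alone, N_s(t)/N.
    tau : full information fraction tau0 / V.
    info : statistical information 1 / var_beta.
    """

    var_beta: float
    V: float
    tau0: float
    tau: float
    info: float


def _pair_sums(counts0: np.ndarray, counts1: np.ndarray) -> np.ndarray:
    """Per-occasion ``(N0_r + N1_r) / (N0_r N1_r)`` — the two-sample variance scale."""
    return (counts0 + counts1) / (counts0 * counts1)


def _check_counts(counts0: np.ndarray, counts1: np.ndarray) -> None:
    for c in (counts0, counts1):
        if np.any(c <= 0):
            raise ValueError("all per-occasion arm counts must be positive")
        if np.any(np.diff(c) > 1e-9):
            raise ValueError("counts must be non-increasing across occasions")


def var_beta_counts(
    counts0,
    counts1,
    corr: CorrelationSpec,
    sched: FollowUpSchedule,
    sigma_s: float,
) -> float:
    """Closed-form ``var(beta_s)`` from per-occasion arm counts.

    ``counts0`` / ``counts1`` are the control / treatment counts
    ``N0_1 >= ... >= N0_s > 0`` (fractional expectations allowed). Uses the
    uniform-model telescoping form in the determinant ratios
    ``det(R_{m+1})/det(R_m) = (1 - a)(1 + m a)/(1 + (m-1) a)``, or the
    exponential form built from adjacent-gap correlations.
    """
    c0 = np.asarray(counts0, dtype=float)
    c1 = np.asarray(counts1, dtype=float)
    s = sched.s
    if c0.shape != (s,) or c1.shape != (s,):
        raise ValueError("counts must have one entry per occasion")
    _check_counts(c0, c1)
    w = _pair_sums(c0, c1)  # w_r = (N0_r + N1_r)/(N0_r N1_r)
    a = corr.param
    if corr.kind == "uniform":
        acc = w[0]
        for m in range(1, s):  # m = 1..s-1
            Dm = (1.0 - a) * (1.0 + m * a) / (1.0 + (m - 1) * a)
            acc += Dm * (w[m] - w[m - 1])
        return float(sigma_s**2 * acc)
    # exponential model
    if s == 2:
        rho = a ** (sched.d[1] - sched.d[0])
        return float(sigma_s**2 * (w[1] * (1.0 - rho**2) + w[0] * rho**2))
    d = sched.d
    g2 = a ** (2.0 * np.diff(d))  # gamma^{2 (d_{r+1} - d_r)}, length s-1
    tail = a ** (2.0 * (d[-1] - d))  # gamma^{2 (d_s - d_r)}, length s
    acc = w[-1] * (1.0 - g2[-1])
    for r in range(1, s - 1):  # occasions 2..s-1
        acc += w[r] * (1.0 - g2[r - 1]) * tail[r]
    acc += w[0] * tail[0]
    return float(sigma_s**2 * acc)


def _ratios_to_s(rec: RecruitmentSpec, sched: FollowUpSchedule, t: float) -> np.ndarray:
    """Vector ``n_{s r}(t) = g_s / g_r`` for r = 1..s (last entry 1)."""
    g = accrual_g(rec, t, sched.d)
    if np.any(g <= 0):
        raise ValueError("every occasion must have positive accrual at t")
    return np.asarray(g[-1] / g, dtype=float)


def var_beta_at(point: DesignPoint) -> float:
    """``var(beta_s)`` at a design point, via the expected accrual counts."""
    counts = counts_at(point.rec, point.sched, point.t)
    c0, c1 = point.alloc.split(counts)
    return var_beta_counts(c0, c1, point.corr, point.sched, point.sigma_s)


def uniform_D(s: int, alpha: float) -> float:
    """The uniform-model factor ``D = (1-a)(1+(s-1)a)/(1+(s-2)a)``.

    Governs the weight of the earliest outcome in the minimum-V bound;
    decreasing in ``s`` with limit ``1 - alpha``.
    """
    return (1.0 - alpha) * (1.0 + (s - 1) * alpha) / (1.0 + (s - 2) * alpha)


def v_factor(point: DesignPoint) -> float:
    """Variance-reduction factor ``V_s(t) = var(beta_s) / var(beta_s | rho=0)``.

    Lies in ``[n_s1(t), 1]``; monotone non-increasing in the correlation
    parameter. ``V = 0.8`` means 1.25x the information of a primary-outcome-
    only analysis at the same time.
    """
    n = _ratios_to_s(point.rec, point.sched, point.t)
    a = point.corr.param
    s = point.sched.s
    if point.corr.kind == "uniform":
        acc = n[0]
        for m in range(1, s):
            Dm = (1.0 - a) * (1.0 + m * a) / (1.0 + (m - 1) * a)
            acc += Dm * (n[m] - n[m - 1])
        return float(acc)
    return float(_v_exp_from_ratios(n, point.sched.d, a))


def _v_exp_from_ratios(n: np.ndarray, d: np.ndarray, gamma: float) -> float:
    """Exponential-model V from count ratios ``n_{s r}`` and times ``d``."""
    s = d.size
    if gamma == 0.0:
        return 1.0
    if s == 2:
        rho2 = gamma ** (2.0 * (d[1] - d[0]))
        return float((1.0 - rho2) + n[0] * rho2)
    g2 = gamma ** (2.0 * np.diff(d))
    tail = gamma ** (2.0 * (d[-1] - d))
    acc = 1.0 - g2[-1]
    for r in range(1, s - 1):
        acc += n[r] * (1.0 - g2[r - 1]) * tail[r]
    acc += n[0] * tail[0]
    return float(acc)


def v_uniform_extrema(
    rec: RecruitmentSpec,
    t: float,
    d_1: float,
    d_s: float,
    s: int,
    alpha: float,
) -> tuple[float, float]:
    """Analytic (min, max) of the uniform-model V over intermediate spacings.

    The minimum is attained as all intermediate occasions move to ``d_1``
    (most data), the maximum as they move to ``d_s``:

    ``min = n_s1 + D (1 - n_s1)`` with ``D = (1-a)(1+(s-1)a)/(1+(s-2)a)``,
    ``max = n_s1 + (1 - a^2)(1 - n_s1)``.

    For ``s = 2`` there are no intermediate occasions and min = max.
    """
    n_s1 = float(accrual_g(rec, t, d_s) / accrual_g(rec, t, d_1))
    if s == 2:
        v = n_s1 + (1.0 - alpha**2) * (1.0 - n_s1)
        return v, v
    vmin = n_s1 + uniform_D(s, alpha) * (1.0 - n_s1)
    vmax = n_s1 + (1.0 - alpha**2) * (1.0 - n_s1)
    return vmin, vmax


def v_exp_max(
    rec: RecruitmentSpec,
    t: float,
    d_1: float,
    d_s: float,
    s: int,
    gamma: float,
) -> float:
    """Analytic maximum of the exponential-model V over intermediate spacings.

    Attained as every intermediate occasion collapses onto ``d_1``:
    ``max = n_s1 + (1 - gamma^{2 (d_s - d_1)})(1 - n_s1)``. With the
    cross-model calibration ``gamma = alpha^{1/(d_s - d_1)}`` this coincides
    with the uniform-model maximum.
    """
    n_s1 = float(accrual_g(rec, t, d_s) / accrual_g(rec, t, d_1))
    return n_s1 + (1.0 - gamma ** (2.0 * (d_s - d_1))) * (1.0 - n_s1)


def _v_exp_and_grad(
    d_mid: np.ndarray,
    rec: RecruitmentSpec,
    t: float,
    d_1: float,
    d_s: float,
    gamma: float,
) -> tuple[float, np.ndarray]:
    """Exponential V and its analytic gradient w.r.t. the intermediate times.

    Two routes by which an intermediate time ``d_m`` moves V: it changes the
    amount of accrued data (through ``n_{s m} = g_s / g_m``) and it changes
    the correlation-decay weights through the adjacent gaps
    ``d_m - d_{m-1}`` and ``d_{m+1} - d_m``.
    """
    d = np.concatenate(([d_1], d_mid, [d_s]))
    s = d.size
    u = np.clip(t - d, 0.0, rec.T_R)
    g = rec.g(u)
    gp = np.where((t - d > 0) & (t - d < rec.T_R), rec.g_prime(u), 0.0)
    n = g[-1] / g  # n_{s r}
    # dn_{s r}/dd_r = + g_s g'(u_r)/g_r^2 (later occasion -> less data -> larger ratio)
    dn = g[-1] * gp / g**2
    L2 = 2.0 * math.log(gamma) if gamma > 0 else 0.0

    def q(x):  # gamma^{2x}
        return gamma ** (2.0 * x)

    gaps = np.diff(d)  # Delta_r = d_{r+1} - d_r, index r-1 for pair (r, r+1)
    tail = q(d[-1] - d)  # gamma^{2 (d_s - d_r)}

    value = (1.0 - q(gaps[-1])) + n[0] * tail[0]
    for r in range(1, s - 1):
        value += n[r] * (1.0 - q(gaps[r - 1])) * tail[r]

    grad = np.zeros(s - 2)
    if gamma == 0.0:
        return 1.0, grad
    for m in range(1, s - 1):  # intermediate occasion, 0-based index m
        gm = gaps[m - 1]  # d_m - d_{m-1}
        gn = gaps[m]  # d_{m+1} - d_m
        gterm = 0.0
        # own term: n_m (1 - q(gm)) tail_m
        gterm += dn[m] * (1.0 - q(gm)) * tail[m]
        gterm += n[m] * (-L2 * q(gm)) * tail[m]
        gterm += n[m] * (1.0 - q(gm)) * (-L2 * tail[m])
        # next occasion's gap factor (1 - q(d_{m+1} - d_m)) gains +L2 q(gn)
        factor = 1.0 if m + 1 == s - 1 else n[m + 1] * tail[m + 1]
        gterm += factor * (L2 * q(gn))
        grad[m - 1] = gterm
    return float(value), grad


def v_exp_min(
    rec: RecruitmentSpec,
    t: float,
    d_1: float,
    d_s: float,
    s: int,
    gamma: float,
    tol: float = 1e-10,
    min_gap: float = 1e-6,
) -> tuple[float, np.ndarray]:
    """Numerical minimum of the exponential-model V over intermediate spacings.

    Unlike the uniform model there is no closed form: pulling intermediate
    occasions earlier buys more data but lengthens the correlation gaps to
    the primary occasion. Minimizes over ``d_2 < ... < d_{s-1}`` in
    ``(d_1, d_s)`` by SLSQP with the analytic gradient, starting from equal
    spacing, with strict ordering enforced through a minimum gap.

    Returns ``(min V, argmin intermediate times)``.
    """
    if s < 3:
        raise ValueError("v_exp_min needs at least one intermediate occasion (s >= 3)")
    if gamma == 0.0:
        return 1.0, np.linspace(d_1, d_s, s)[1:-1]
    x0 = np.linspace(d_1, d_s, s)[1:-1]
    m = s - 2

    def fun(x):
        return _v_exp_and_grad(x, rec, t, d_1, d_s, gamma)

    # ordering constraints: d_1 + gap <= x_1, x_j + gap <= x_{j+1}, x_m + gap <= d_s
    cons = []
    A = np.zeros((m + 1, m))
    lb = np.full(m + 1, min_gap)
    A[0, 0] = 1.0
    b0 = np.zeros(m + 1)
    b0[0] = -d_1
    for j in range(1, m):
        A[j, j] = 1.0
        A[j, j - 1] = -1.0
    A[m, m - 1] = -1.0
    b0[m] = d_s
    cons.append(
        {
            "type": "ineq",
            "fun": lambda x: A @ x + b0 - lb,
            "jac": lambda x: A,
        }
    )
    res = minimize(
        fun,
        x0,
        jac=True,
        method="SLSQP",
        constraints=cons,
        options={"maxiter": 500, "ftol": tol},
    )
    if not res.success:
        raise RuntimeError(f"V^exp minimization failed to converge: {res.message}")
    v_equal, _ = _v_exp_and_grad(x0, rec, t, d_1, d_s, gamma)
    if res.fun <= v_equal + 1e-12:
        return float(res.fun), np.asarray(res.x)
    return float(v_equal), x0  # defensive: equal spacing beat the optimizer


def information_fraction(point: DesignPoint) -> InformationSummary:
    """Variance, V, and information fractions at a design point.

    ``tau0 = N_s(t)/N`` is the information fraction from primary-outcome
    data alone; the early outcomes scale it up to ``tau = tau0 / V``.
    """
    var = var_beta_at(point)
    g_s = accrual_g(point.rec, point.t, point.sched.d_s)
    k = point.rec.k
    phi = point.alloc.phi
    var0 = point.sigma_s**2 / (k * phi * (1.0 - phi) * g_s)
    V = var / var0
    tau0 = float(k * g_s / point.rec.N)
    return InformationSummary(
        var_beta=float(var),
        V=float(V),
        tau0=tau0,
        tau=float(tau0 / V),
        info=float(1.0 / var),
    )


def gls_variance_oracle(
    counts0,
    counts1,
    corr: CorrelationSpec,
    sched: FollowUpSchedule,
    sigma,
) -> float:
    """Brute-force ``var(beta_s)`` from the GLS information matrix.

    Builds ``sum_i X_i' Sigma_i^{-1} X_i`` by summing over the at most ``2s``
    distinct (monotone-prefix pattern, arm) combinations, inverts, and
    returns the last diagonal entry — the variance of the occasion-``s``
    treatment effect under the cell-means parameterization (``s`` occasion
    means + ``s`` occasion-by-treatment effects).

    Entirely independent of the closed forms in this module; used as their
    verification oracle.
    """
    c0 = np.asarray(counts0, dtype=float)
    c1 = np.asarray(counts1, dtype=float)
    s = sched.s
    _check_counts(c0, c1)
    sig = np.broadcast_to(np.atleast_1d(np.asarray(sigma, dtype=float)), (s,))
    Sigma = corr_matrix(corr, sched) * np.outer(sig, sig)
    info = np.zeros((2 * s, 2 * s))
    for arm, carr in ((0, c0), (1, c1)):
        ext = np.append(carr, 0.0)
        for p in range(1, s + 1):  # prefix length
            weight = ext[p - 1] - ext[p]
            if weight <= 0:
                continue
            X = np.zeros((p, 2 * s))
            X[np.arange(p), np.arange(p)] = 1.0
            if arm == 1:
                X[np.arange(p), s + np.arange(p)] = 1.0
            Sinv = np.linalg.inv(Sigma[:p, :p])
            info += weight * (X.T @ Sinv @ X)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "information matrix singular: an occasion has no participants"
        ) from exc
    return float(cov[-1, -1])
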