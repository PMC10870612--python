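"""Group-sequential probability machinery on the canonical joint distribution.

Sequential z-statistics ``Z_1, ..., Z_K`` computed at information levels
``I_1 < ... < I_K`` are, asymptotically, jointly multivariate normal with
``E[Z_k] = delta * sqrt(I_k)`` and ``cov(Z_j, Z_k) = sqrt(I_j / I_k)`` for
``j <= k`` — the canonical joint distribution. Boundary-crossing
probabilities follow by the classical recursion over the continuation
density: the sub-density of ``Z_k`` among paths that have stayed between
the futility and efficacy bounds at every earlier analysis is propagated
forward by one-dimensional numerical integration.

The convention throughout is one-sided testing: rejection (efficacy) is an
upper-boundary exit, futility a lower-boundary exit, and at the final
analysis the two bounds coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "GsdDesign",
    "DriftSpec",
    "ExitProbabilities",
    "crossing_probabilities",
    "power",
    "solve_boundaries",
    "futility_probability_fixed_bounds",
    "sample_size_for_power",
]

_SPAN = 8.0  # continuation grids span mean +/- 8 SD
_NODES = 768  # Gauss-Legendre nodes per analysis


@dataclass(frozen=True)
class DriftSpec:
    """True treatment difference on the outcome scale.

    Drives the mean of the z-statistics: ``E[Z_k] = delta * sqrt(I_k)``.
    """

    delta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta):
            raise ValueError("delta must be finite")


@dataclass(frozen=True, eq=False)
class GsdDesign:
    """Analysis schedule with z-scale stopping boundaries.

    Parameters
    ----------
    tau : increasing information fractions, last entry 1.
    I_max : statistical information at the final analysis (1/variance units).
    lower : z-scale futility bounds ``l_1 .. l_K``.
    upper : z-scale efficacy bounds ``u_1 .. u_K``; ``+inf`` before the final
        analysis means no efficacy stopping there. At the final analysis the
        bounds must coincide so every path terminates.
    """

    tau: np.ndarray
    I_max: float
    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, tau, I_max, lower, upper) -> None:
        tau = np.asarray(tau, dtype=float)
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        K = tau.size
        if lower.shape != (K,) or upper.shape != (K,):
            raise ValueError("tau, lower and upper must have equal length")
        if np.any(np.diff(tau) <= 0) or tau[0] <= 0 or not np.isclose(tau[-1], 1.0):
            raise ValueError("tau must be strictly increasing with final value 1")
        if I_max <= 0:
            raise ValueError("I_max must be positive")
        if np.any(lower[:-1] >= upper[:-1]):
            raise ValueError("lower bound must lie below upper bound before the final analysis")
        if not np.isclose(lower[-1], upper[-1]):
            raise ValueError("final lower and upper bounds must coincide")
        for arr in (tau, lower, upper):
            arr.flags.writeable = False
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "I_max", float(I_max))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def K(self) -> int:
        return int(self.tau.size)

    @property
    def info(self) -> np.ndarray:
        """Absolute information levels ``I_k = tau_k * I_max``."""
        return self.tau * self.I_max


@dataclass(frozen=True, eq=False)
class ExitProbabilities:
    """First-exit probabilities per analysis through each boundary."""

    lower: np.ndarray
    upper: np.ndarray

    @property
    def total(self) -> float:
        return float(self.lower.sum() + self.upper.sum())


def _legendre(a: float, b: float, n: int = _NODES) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (a + b), 0.5 * (b - a) * w


def _exit_probabilities(
    info: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    delta: float,
    nodes: int = _NODES,
) -> ExitProbabilities:
    """Recursion over the continuation sub-density of ``Z_k``.

    ``Z_k | Z_{k-1} = x`` is normal with mean
    ``(x sqrt(I_{k-1}) + delta (I_k - I_{k-1})) / sqrt(I_k)`` and variance
    ``(I_k - I_{k-1}) / I_k``, by the independent-increments property of the
    score process.
    """
    K = info.size
    if np.any(np.diff(info) <= 0):
        raise ValueError("information levels must be strictly increasing")
    p_lo = np.zeros(K)
    p_up = np.zeros(K)
    theta = delta * np.sqrt(info)
    # analysis 1
    p_lo[0] = norm.cdf(lower[0] - theta[0])
    p_up[0] = norm.sf(upper[0] - theta[0]) if np.isfinite(upper[0]) else 0.0
    grid = wts = dens = None
    for k in range(K - 1):
        a = max(lower[k], theta[k] - _SPAN)
        b = min(upper[k], theta[k] + _SPAN) if np.isfinite(upper[k]) else theta[k] + _SPAN
        if b <= a:  # continuation region empty: all mass has exited
            break
        new_grid, new_wts = _legendre(a, b, nodes)
        if k == 0:
            dens = norm.pdf(new_grid - theta[0])
        else:
            dens = _propagate(grid, wts, dens, new_grid, info[k - 1], info[k], delta)
        grid, wts = new_grid, new_wts
        # exit at analysis k+1
        sd = math.sqrt((info[k + 1] - info[k]) / info[k + 1])
        cond_mean = (grid * math.sqrt(info[k]) + delta * (info[k + 1] - info[k])) / math.sqrt(
            info[k + 1]
        )
        p_lo[k + 1] = float(np.sum(wts * dens * norm.cdf((lower[k + 1] - cond_mean) / sd)))
        if np.isfinite(upper[k + 1]):
            p_up[k + 1] = float(np.sum(wts * dens * norm.sf((upper[k + 1] - cond_mean) / sd)))
    return ExitProbabilities(lower=p_lo, upper=p_up)


def _propagate(grid, wts, dens, new_grid, I_prev, I_cur, delta):
    sd = math.sqrt((I_cur - I_prev) / I_cur)
    cond_mean = (grid * math.sqrt(I_prev) + delta * (I_cur - I_prev)) / math.sqrt(I_cur)
    kern = norm.pdf((new_grid[:, None] - cond_mean[None, :]) / sd) / sd
    return kern @ (wts * dens)


def crossing_probabilities(
    design: GsdDesign, drift: DriftSpec, nodes: int = _NODES
) -> ExitProbabilities:
    """First-exit probabilities through each boundary at each analysis.

    With a terminating final analysis (``l_K = u_K``) the lower and upper
    exit probabilities sum to 1.
    """
    return _exit_probabilities(design.info, design.lower, design.upper, drift.delta, nodes)


def power(design: GsdDesign, drift: DriftSpec) -> float:
    """Probability of rejection: total upper-boundary exit probability."""
    return float(crossing_probabilities(design, drift).upper.sum())


def futility_probability_fixed_bounds(
    planned_lower,
    info_levels,
    drift: DriftSpec,
) -> np.ndarray:
    """Futility stopping probabilities with planned z-bounds held fixed.

    The planned z-scale lower bounds are applied as-is while the realized
    information levels vary (e.g. with the timing of the first interim or
    the assumed correlation): ``p_1 = Phi(l_1 - delta sqrt(I_1))`` and
    ``p_k = P(l_j < Z_j for j < k, Z_k < l_k)`` under the canonical joint
    distribution. No efficacy stopping is considered.
    """
    lower = np.asarray(planned_lower, dtype=float)
    info = np.asarray(info_levels, dtype=float)
    upper = np.full_like(lower, np.inf)
    probs = _exit_probabilities(info, lower, upper, drift.delta)
    return probs.lower


def solve_boundaries(
    tau,
    I_max: float,
    null_lower,
    null_upper,
) -> GsdDesign:
    """Boundaries from target null first-exit probabilities (error spending).

    Solves sequentially for ``l_k`` then ``u_k`` so that the first-exit
    probabilities under the null (``delta = 0``) match the supplied
    per-analysis targets; at the final analysis the two targets must be
    consistent with a common bound (their sum closes the total probability).
    A zero lower target yields an effectively unreachable bound (``-10``),
    and a zero upper target before the final analysis yields ``+inf``.
    """
    tau = np.asarray(tau, dtype=float)
    pl = np.asarray(null_lower, dtype=float)
    pu = np.asarray(null_upper, dtype=float)
    K = tau.size
    if np.any(pl < 0) or np.any(pu < 0) or pl.sum() + pu.sum() >= 1 + 1e-12:
        raise ValueError("null exit probabilities must be non-negative and total < 1")
    info = tau * I_max
    lower = np.empty(K)
    upper = np.empty(K)
    for k in range(K):
        final = k == K - 1
        if final:
            # the remaining continuation mass must split between the two exits;
            # solve for the common bound from the lower-exit target
            target = pl[k]

            def resid(b):
                lo = np.append(lower[:k], b)
                up = np.append(upper[:k], b)
                return _exit_probabilities(info[: k + 1], lo, up, 0.0).lower[k] - target

            bound = brentq(resid, -12.0, 12.0, xtol=1e-12)
            lower[k] = upper[k] = bound
            continue
        if pl[k] <= 0:
            lower[k] = -10.0
        else:
            target = pl[k]

            def resid_l(b):
                lo = np.append(lower[:k], b)
                up = np.append(upper[:k], np.inf)
                return _exit_probabilities(info[: k + 1], lo, up, 0.0).lower[k] - target

            lower[k] = brentq(resid_l, -12.0, 12.0, xtol=1e-12)
        if pu[k] <= 0:
            upper[k] = np.inf
        else:
            target = pu[k]

            def resid_u(b):
                lo = np.append(lower[:k], lower[k])
                up = np.append(upper[:k], b)
                return _exit_probabilities(info[: k + 1], lo, up, 0.0).upper[k] - target

            upper[k] = brentq(resid_u, max(lower[k] + 1e-9, -12.0), 12.0, xtol=1e-12)
    return GsdDesign(tau=tau, I_max=I_max, lower=lower, upper=upper)


def sample_size_for_power(
    design: GsdDesign,
    drift: DriftSpec,
    target: float,
    sigma_s: float,
    phi: float = 0.5,
    n_max: int = 100_000,
) -> int:
    """Smallest total sample size reaching a target power.

    Boundaries and information fractions are held fixed on the z-scale while
    the maximum information is rescaled as ``I_max(N) = N phi (1-phi) /
    sigma_s^2``; power is monotone increasing in ``N``, so bisection on the
    integers applies.
    """
    if not 0 < target < 1:
        raise ValueError("target power must lie in (0, 1)")

    def pw(n: int) -> float:
        d = GsdDesign(
            tau=design.tau,
            I_max=n * phi * (1.0 - phi) / sigma_s**2,
            lower=design.lower,
            upper=design.upper,
        )
        return power(d, drift)

    lo, hi = 1, 2
    while pw(hi) < target:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise RuntimeError(f"target power {target} unreachable below N={n_max}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if pw(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi
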