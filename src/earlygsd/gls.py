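"""Generalized least squares monitoring of monotone longitudinal trial data.

The monitoring model places separate fixed effects at each follow-up
occasion for the control-arm mean and for the treatment contrast (a
cell-means parameterization: coefficients 1..s are occasion means,
coefficients s+1..2s the occasion-specific treatment effects). With the
outcome covariance ``Sigma`` supplied, the GLS estimator

    beta_hat = (sum_i X_i' Sigma_i^{-1} X_i)^{-1} (sum_i X_i' Sigma_i^{-1} y_i)

is the maximum-likelihood estimator under multivariate normality, and its
covariance is the inverted information matrix. Because administrative
censoring produces only monotone prefixes, participants fall into at most
``2 s`` (pattern, arm) groups and all sums collapse to group-level
cross-products — the per-participant loop is never needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .correlation import CorrelationSpec, CovarianceSpec
from .schedule import FollowUpSchedule

__all__ = ["GlsFit", "gls_fit", "estimate_covariance_ml", "monitoring_statistic"]


@dataclass(frozen=True)
class GlsFit:
    """GLS coefficient estimates with their covariance.

    ``beta`` stacks the ``s`` occasion means followed by the ``s``
    occasion-by-treatment effects; the primary treatment effect is the last
    entry. ``n_by_pattern`` counts participants per (prefix length, arm).
    """

    beta: np.ndarray
    vcov: np.ndarray
    n_by_pattern: dict

    @property
    def beta_s(self) -> float:
        return float(self.beta[-1])

    @property
    def var_beta_s(self) -> float:
        return float(self.vcov[-1, -1])

    @property
    def z(self) -> float:
        return float(self.beta_s / np.sqrt(self.var_beta_s))


def _pattern_moments(data: pd.DataFrame, s: int):
    """Group participants by (arm, prefix length); return counts, sums and
    outer-product sums of their outcome vectors."""
    wide = data.pivot_table(index=["participant_id", "arm"], columns="occasion", values="y")
    wide = wide.reindex(columns=range(1, s + 1))
    Y = wide.to_numpy()
    observed = ~np.isnan(Y)
    n_obs = observed.sum(axis=1)
    max_occ = np.where(n_obs > 0, s - np.argmax(observed[:, ::-1], axis=1), 0)
    bad = np.flatnonzero(n_obs != max_occ)
    if bad.size:
        pid = wide.index[bad[0]][0]
        occs = list(np.flatnonzero(observed[bad[0]]) + 1)
        raise ValueError(f"participant {pid} has non-monotone missingness: occasions {occs}")
    arms = wide.index.get_level_values("arm").to_numpy()
    groups = {}
    for arm in (0, 1):
        for p in range(1, s + 1):
            mask = (arms == arm) & (n_obs == p)
            cnt = int(mask.sum())
            if cnt == 0:
                continue
            block = Y[mask][:, :p]
            groups[(arm, p)] = (cnt, block.sum(axis=0), block.T @ block)
    return groups


def gls_fit(
    data: pd.DataFrame,
    sched: FollowUpSchedule,
    corr: CorrelationSpec,
    cov: CovarianceSpec,
) -> GlsFit:
    """Known-covariance GLS fit of the occasion-specific treatment effects.

    ``data`` is long-format with columns ``participant_id, arm, occasion,
    y`` and monotone (prefix) missingness. Occasions with no observations in
    one of the arms make the corresponding coefficients unidentifiable and
    raise, naming the offending occasions.
    """
    s = sched.s
    Sigma = cov.covariance(corr, sched)
    groups = _pattern_moments(data, s)
    info = np.zeros((2 * s, 2 * s))
    score = np.zeros(2 * s)
    n_by_pattern = {}
    for (arm, p), (cnt, ssum, _) in groups.items():
        n_by_pattern[(p, arm)] = cnt
        Sinv = np.linalg.inv(Sigma[:p, :p])
        X = np.zeros((p, 2 * s))
        X[np.arange(p), np.arange(p)] = 1.0
        if arm == 1:
            X[np.arange(p), s + np.arange(p)] = 1.0
        XtS = X.T @ Sinv
        info += cnt * (XtS @ X)
        score += XtS @ ssum
    # identifiability: each occasion needs data in both arms
    max_p = {0: 0, 1: 0}
    for arm, p in groups:
        max_p[arm] = max(max_p[arm], p)
    deficient = [r for r in range(1, s + 1) if r > min(max_p.values())]
    if deficient:
        raise ValueError(
            f"occasions {deficient} lack observations in one arm; "
            "their coefficients are not identifiable"
        )
    vcov = np.linalg.inv(info)
    beta = vcov @ score
    return GlsFit(beta=beta, vcov=vcov, n_by_pattern=n_by_pattern)


def monitoring_statistic(fit: GlsFit) -> tuple[float, float]:
    """Monitoring pair ``(z, information)`` from a fit.

    ``z = beta_s / sd(beta_s)`` is compared against a design's z-scale
    boundaries; ``information = 1 / var(beta_s)`` locates the analysis on
    the information scale.
    """
    return fit.z, 1.0 / fit.var_beta_s


def _profile_loglik(
    param: float,
    sigma: np.ndarray,
    kind: str,
    groups: dict,
    sched: FollowUpSchedule,
) -> float:
    """Multivariate-normal log-likelihood with the mean profiled out by GLS."""
    s = sched.s
    corr = CorrelationSpec(kind, param)
    Sigma = CovarianceSpec(sigma).covariance(corr, sched)
    info = np.zeros((2 * s, 2 * s))
    score = np.zeros(2 * s)
    for (arm, p), (cnt, ssum, _) in groups.items():
        Sinv = np.linalg.inv(Sigma[:p, :p])
        X = np.zeros((p, 2 * s))
        X[np.arange(p), np.arange(p)] = 1.0
        if arm == 1:
            X[np.arange(p), s + np.arange(p)] = 1.0
        XtS = X.T @ Sinv
        info += cnt * (XtS @ X)
        score += XtS @ ssum
    # drop unidentifiable columns (occasions absent from the data)
    keep = np.where(np.diag(info) > 0)[0]
    beta = np.zeros(2 * s)
    beta[keep] = np.linalg.solve(info[np.ix_(keep, keep)], score[keep])
    ll = 0.0
    for (arm, p), (cnt, ssum, souter) in groups.items():
        Sp = Sigma[:p, :p]
        Sinv = np.linalg.inv(Sp)
        sign, logdet = np.linalg.slogdet(Sp)
        mu = beta[:p].copy()
        if arm == 1:
            mu += beta[s : s + p]
        # sum_i (y_i - mu)' Sinv (y_i - mu) from group moments
        quad = (
            np.sum(Sinv * souter)
            - 2.0 * mu @ Sinv @ ssum
            + cnt * mu @ Sinv @ mu
        )
        ll += -0.5 * (cnt * logdet + quad)
    return ll


def estimate_covariance_ml(
    data: pd.DataFrame,
    sched: FollowUpSchedule,
    kind: str,
) -> tuple[float, np.ndarray, float]:
    """ML estimation of the correlation parameter and per-occasion SDs.

    Maximizes the profile likelihood (mean structure profiled out by GLS)
    over the single correlation parameter and ``sigma_1..sigma_s``, with the
    parameter constrained to [0, 1). Returns ``(param_hat, sigma_hat,
    loglik)``; a boundary solution raises no error but is detectable from
    the returned value.
    """
    s = sched.s
    groups = _pattern_moments(data, s)
    # moment starting values
    sd0 = np.ones(s)
    for r in range(1, s + 1):
        vals = data.loc[data["occasion"] == r, "y"]
        if len(vals) > 1:
            sd0[r - 1] = max(vals.std(ddof=1), 1e-3)

    def negll(x):
        param = x[0]
        sigma = np.exp(x[1:])
        return -_profile_loglik(param, sigma, kind, groups, sched)

    x0 = np.concatenate([[0.3], np.log(sd0)])
    bounds = [(0.0, 0.999)] + [(-10.0, 10.0)] * s
    res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
    if not res.success:
        raise RuntimeError(f"covariance ML failed to converge: {res.message}")
    return float(res.x[0]), np.exp(res.x[1:]), float(-res.fun)
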