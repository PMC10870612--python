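"""Config-driven planning workflows and reference-table generation.

Higher-level orchestration over the recruitment, correlation, variance and
group-sequential modules: the variance-reduction planning grids, a complete
worked replan of a three-analysis shoulder-surgery trial (188 participants,
outcomes at 3/6/12 months, 24-month recruitment), and the futility
stopping-probability grid for a harmful true effect under planned
boundaries held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import CorrelationSpec
from .gsd import DriftSpec, GsdDesign, futility_probability_fixed_bounds, power
from .recruitment import RecruitmentSpec, counts_at, time_at_tau0
from .schedule import AllocationSpec, FollowUpSchedule, equal_spacing
from .variance import (
    DesignPoint,
    information_fraction,
    uniform_D,
    v_exp_max,
    v_exp_min,
    v_factor,
    v_uniform_extrema,
)

__all__ = [
    "ReplanResult",
    "replicate_planning_tables",
    "replan_start_reacts",
    "fig2_grid",
    "v_distribution",
    "START_REACTS",
]

# Design constants of the worked exemplar trial: two-arm, 1:1, outcomes at
# 3/6/12 months (3-month base units), 24-month recruitment, 90% power for a
# 6-point difference with SD 12, compound-symmetry correlation 0.5, interims
# when 25% and 35% of participants have primary-outcome data.
START_REACTS = {
    "N": 188,
    "T_R": 8.0,
    "d": (1.0, 2.0, 4.0),
    "phi": 0.5,
    "sigma_s": 12.0,
    "alpha": 0.5,
    "delta": 6.0,
    "tau0_targets": (0.25, 0.35),
    "bounds": {
        "fixed": {"lower": (-0.706, 0.581, 1.907), "upper": (np.inf, 3.090, 1.907)},
        "decreasing": {"lower": (-0.706, 0.581, 1.910), "upper": (np.inf, 3.090, 1.910)},
    },
}

_TAU0_LEVELS = {"early": 0.15, "mid": 0.30, "late": 0.45}


def replicate_planning_tables(
    alpha_or_gamma: float = 0.5,
    kind: str = "uniform",
    s_values=(2, 3, 4, 5, 6),
    T_R_multiple: float = 4.0,
) -> pd.DataFrame:
    """Planning grid of the variance-reduction factor and its extrema.

    For each number of occasions ``s``, recruitment model and interim timing
    (``tau0`` = 0.15/0.30/0.45, dubbed early/mid/late), computes the count
    ratio ``n_s1``, the equal-spacing V, and the min/max over intermediate
    spacings, with ``d_1 = 1``, ``d_s = 2`` and ``T_R = T_R_multiple * d_s``.
    For the exponential model the parameter is calibrated as
    ``gamma = alpha^{1/(d_s - d_1)}`` so the maxima of the two models agree
    (here ``d_s - d_1 = 1`` so gamma = alpha numerically).
    """
    if kind not in ("uniform", "exponential"):
        raise ValueError("kind must be 'uniform' or 'exponential'")
    d_1, d_s = 1.0, 2.0
    T_R = T_R_multiple * d_s
    param = alpha_or_gamma if kind == "uniform" else alpha_or_gamma ** (1.0 / (d_s - d_1))
    rows = []
    for model in ("fixed", "increasing", "decreasing"):
        rec = RecruitmentSpec(model=model, N=100.0, T_R=T_R)
        for s in s_values:
            sched = equal_spacing(s, d_1, d_s)
            for label, tau0 in _TAU0_LEVELS.items():
                t = time_at_tau0(rec, sched, tau0)
                point = DesignPoint(
                    t=t, sched=sched, rec=rec, corr=CorrelationSpec(kind, param)
                )
                g = counts_at(rec, sched, t)
                n_s1 = float(g[-1] / g[0])
                v_tilde = v_factor(point) if s > 2 else np.nan
                if kind == "uniform":
                    vmin, vmax = v_uniform_extrema(rec, t, d_1, d_s, s, param)
                else:
                    vmax = v_exp_max(rec, t, d_1, d_s, s, param)
                    vmin = (
                        v_exp_min(rec, t, d_1, d_s, s, param)[0] if s >= 3 else vmax
                    )
                row = {
                    "model": model,
                    "s": s,
                    "interim": label,
                    "tau0": tau0,
                    "t": t,
                    "n_s1": n_s1,
                    "V_equal": v_tilde,
                    "V_min": vmin,
                    "V_max": vmax,
                }
                if kind == "uniform":
                    row["D"] = uniform_D(s, param)
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReplanResult:
    """Interim schedule, information accrual and power for one recruitment model."""

    model: str
    report: pd.DataFrame
    design: GsdDesign
    power: float


def replan_start_reacts(model: str = "fixed") -> ReplanResult:
    """Analytic replan of the exemplar trial under a recruitment model.

    Derives the interim calendar times from the planned fractions of
    participants with primary-outcome data (25% and 35%), the expected
    per-occasion counts, the variance-reduction factor, information and
    information fractions at each interim, and the power of the resulting
    three-analysis design under the planning treatment difference.
    """
    P = START_REACTS
    if model not in P["bounds"]:
        raise ValueError(f"no reference boundaries for recruitment model {model!r}")
    sched = FollowUpSchedule(P["d"])
    rec = RecruitmentSpec(model=model, N=P["N"], T_R=P["T_R"])
    alloc = AllocationSpec(P["phi"])
    corr = CorrelationSpec("uniform", P["alpha"])
    I_max = P["N"] * P["phi"] * (1 - P["phi"]) / P["sigma_s"] ** 2
    rows = []
    taus = []
    for w, tau0 in enumerate(P["tau0_targets"], start=1):
        t = time_at_tau0(rec, sched, tau0)
        point = DesignPoint(
            t=t, sched=sched, rec=rec, corr=corr, alloc=alloc, sigma_s=P["sigma_s"]
        )
        summ = information_fraction(point)
        counts = counts_at(rec, sched, t)
        rows.append(
            {
                "analysis": w,
                "t": t,
                "N_1": counts[0],
                "N_2": counts[1],
                "N_3": counts[2],
                "V": summ.V,
                "tau0": summ.tau0,
                "tau": summ.tau,
                "information": summ.info,
            }
        )
        taus.append(summ.tau)
    rows.append(
        {
            "analysis": len(taus) + 1,
            "t": sched.d_s + rec.T_R,
            "N_1": P["N"],
            "N_2": P["N"],
            "N_3": P["N"],
            "V": 1.0,
            "tau0": 1.0,
            "tau": 1.0,
            "information": I_max,
        }
    )
    design = GsdDesign(
        tau=np.array(taus + [1.0]),
        I_max=I_max,
        lower=np.array(P["bounds"][model]["lower"]),
        upper=np.array(P["bounds"][model]["upper"]),
    )
    pw = power(design, DriftSpec(P["delta"]))
    return ReplanResult(
        model=model, report=pd.DataFrame(rows), design=design, power=pw
    )


def fig2_grid(
    t1_values,
    alpha_values,
    delta: float = -4.0,
    t2: float = 6.8,
) -> pd.DataFrame:
    """Futility stopping probabilities over first-interim time and correlation.

    For the exemplar trial under fixed-rate recruitment and a harmful true
    difference (default -4 points), varies the first interim time ``t1`` and
    the compound-symmetry correlation ``alpha`` while holding the planned
    z-scale lower bounds (-0.706, 0.581) and the second interim calendar
    time fixed; returns one row per grid node with ``p1`` and ``p2``.
    """
    P = START_REACTS
    sched = FollowUpSchedule(P["d"])
    rec = RecruitmentSpec(model="fixed", N=P["N"], T_R=P["T_R"])
    alloc = AllocationSpec(P["phi"])
    I_max = P["N"] * P["phi"] * (1 - P["phi"]) / P["sigma_s"] ** 2
    lower = np.array(P["bounds"]["fixed"]["lower"][:2])
    drift = DriftSpec(delta)
    rows = []
    for t1 in np.atleast_1d(t1_values):
        if not sched.d_s < t1 < t2:
            raise ValueError(f"t1={t1} must lie in (d_s, t2) = ({sched.d_s}, {t2})")
        for alpha in np.atleast_1d(alpha_values):
            taus = []
            for t in (float(t1), t2):
                if alpha == 0.0:
                    g_s = counts_at(rec, sched, t)[-1]
                    taus.append(float(g_s / P["N"]))
                else:
                    point = DesignPoint(
                        t=t,
                        sched=sched,
                        rec=rec,
                        corr=CorrelationSpec("uniform", float(alpha)),
                        alloc=alloc,
                        sigma_s=P["sigma_s"],
                    )
                    taus.append(information_fraction(point).tau)
            info = np.array(taus) * I_max
            p = futility_probability_fixed_bounds(lower, info, drift)
            rows.append(
                {"t1": float(t1), "alpha": float(alpha), "p1": p[0], "p2": p[1]}
            )
    return pd.DataFrame(rows)


def v_distribution(
    rec: RecruitmentSpec,
    t: float,
    d_1: float,
    d_s: float,
    s: int,
    corr: CorrelationSpec,
    n_sim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Empirical distribution of V over random intermediate spacings.

    Draws ``n_sim`` sorted uniform placements of ``d_2..d_{s-1}`` in
    ``(d_1, d_s)`` and evaluates the variance-reduction factor at each; all
    values fall inside the analytic min/max envelope.
    """
    if s < 3:
        raise ValueError("a V distribution needs intermediate occasions (s >= 3)")
    out = np.empty(n_sim)
    for i in range(n_sim):
        mids = np.sort(rng.uniform(d_1, d_s, size=s - 2))
        sched = FollowUpSchedule(np.concatenate(([d_1], mids, [d_s])))
        out[i] = v_factor(DesignPoint(t=t, sched=sched, rec=rec, corr=corr))
    return out
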