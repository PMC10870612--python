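"""Closed-form treatment-effect variance, V factor, extrema and information."""

import numpy as np
import pytest

from earlygsd import (
    AllocationSpec,
    CorrelationSpec,
    DesignPoint,
    FollowUpSchedule,
    RecruitmentSpec,
    counts_at,
    equal_spacing,
    gls_variance_oracle,
    information_fraction,
    time_at_tau0,
    uniform_D,
    v_exp_max,
    v_exp_min,
    v_factor,
    v_uniform_extrema,
    var_beta_at,
    var_beta_counts,
)
from earlygsd.variance import _v_exp_and_grad

from conftest import random_monotone_counts


def _point(model="fixed", tau0=0.25, alpha=0.5, kind="uniform", sigma_s=12.0, d=(1, 2, 4)):
    sched = FollowUpSchedule(d)
    rec = RecruitmentSpec(model, 188.0, 8.0)
    t = time_at_tau0(rec, sched, tau0)
    return DesignPoint(
        t=t, sched=sched, rec=rec, corr=CorrelationSpec(kind, alpha), sigma_s=sigma_s
    )


class TestVarBetaCounts:
    def test_two_occasion_closed_form(self):
        sched = FollowUpSchedule([1.0, 2.0])
        c = np.array([50.0, 25.0])
        v0 = var_beta_counts(c, c, CorrelationSpec("uniform", 0.0), sched, 1.0)
        assert v0 == pytest.approx(0.08)
        v = var_beta_counts(c, c, CorrelationSpec("uniform", 0.5), sched, 1.0)
        # (N2+N2)(1-rho^2)/N2^2 + (N1+N1) rho^2 / N1^2
        assert v == pytest.approx(50 * 0.75 / 625 + 100 * 0.25 / 2500)
        assert v == pytest.approx(0.07)

    def test_start_reacts_interim_information(self):
        counts = np.array([117.5, 94.0, 47.0]) / 2.0
        v = var_beta_counts(
            counts, counts, CorrelationSpec("uniform", 0.5), FollowUpSchedule([1, 2, 4]), 12.0
        )
        assert 1.0 / v == pytest.approx(0.101, abs=5e-4)

    @pytest.mark.parametrize("kind", ["uniform", "exponential"])
    def test_matches_gls_oracle(self, kind, rng):
        """Closed forms agree with the brute-force GLS information matrix."""
        for _ in range(100):
            s = int(rng.integers(2, 6))
            d = np.cumsum(rng.uniform(0.3, 2.0, size=s))
            sched = FollowUpSchedule(d)
            param = float(rng.uniform(0.0, 0.95))
            c0 = random_monotone_counts(rng, s)
            c1 = random_monotone_counts(rng, s)
            sigma_s = float(rng.uniform(0.5, 15.0))
            corr = CorrelationSpec(kind, param)
            closed = var_beta_counts(c0, c1, corr, sched, sigma_s)
            oracle = gls_variance_oracle(c0, c1, corr, sched, sigma_s)
            assert closed == pytest.approx(oracle, rel=1e-8)

    def test_alpha_one_limit(self):
        """As alpha -> 1 all information flows through the first occasion."""
        sched = FollowUpSchedule([1.0, 2.0, 4.0])
        c0 = np.array([80.0, 50.0, 20.0])
        c1 = np.array([70.0, 45.0, 15.0])
        v = var_beta_counts(c0, c1, CorrelationSpec("uniform", 1 - 1e-9), sched, 2.0)
        assert v == pytest.approx(4.0 * (c0[0] + c1[0]) / (c0[0] * c1[0]), rel=1e-6)

    def test_structure_errors(self):
        sched = FollowUpSchedule([1.0, 2.0])
        corr = CorrelationSpec("uniform", 0.3)
        with pytest.raises(ValueError):
            var_beta_counts([10.0, 20.0], [20.0, 10.0], corr, sched, 1.0)
        with pytest.raises(ValueError):
            var_beta_counts([10.0, 0.0], [10.0, 5.0], corr, sched, 1.0)


class TestVarBetaAt:
    def test_zero_correlation_reduces_to_primary_only(self):
        p = _point(alpha=0.0)
        k = p.rec.k
        g_s = (p.t - p.sched.d_s)
        assert var_beta_at(p) == pytest.approx(p.sigma_s**2 / (k * 0.25 * g_s))

    def test_complete_data_variance(self):
        sched = FollowUpSchedule([1, 2, 4])
        rec = RecruitmentSpec("fixed", 188.0, 8.0)
        p = DesignPoint(
            t=12.0, sched=sched, rec=rec, corr=CorrelationSpec("uniform", 0.7), sigma_s=12.0
        )
        assert var_beta_at(p) == pytest.approx(4 * 144 / 188, rel=1e-12)

    def test_interim_information(self):
        assert 1.0 / var_beta_at(_point()) == pytest.approx(0.101, abs=5e-4)

    def test_requires_primary_data(self):
        sched = FollowUpSchedule([1, 2, 4])
        rec = RecruitmentSpec("fixed", 188.0, 8.0)
        with pytest.raises(ValueError):
            DesignPoint(t=3.0, sched=sched, rec=rec, corr=CorrelationSpec("uniform", 0.5))


class TestVFactor:
    @pytest.mark.parametrize(
        "model, tau0, expected",
        [("fixed", 0.25, 0.808), ("fixed", 0.35, 0.836), ("decreasing", 0.25, 0.786), ("decreasing", 0.35, 0.820)],
    )
    def test_exemplar_values(self, model, tau0, expected):
        assert v_factor(_point(model=model, tau0=tau0)) == pytest.approx(expected, abs=5e-4)

    def test_exponential_equal_spacing(self):
        sched = equal_spacing(3)  # d = (1, 1.5, 2)
        rec = RecruitmentSpec("fixed", 100.0, 8.0)
        p = DesignPoint(
            t=3.2, sched=sched, rec=rec, corr=CorrelationSpec("exponential", 0.5)
        )
        assert v_factor(p) == pytest.approx(0.81, abs=0.005)

    @pytest.mark.parametrize("kind", ["uniform", "exponential"])
    @pytest.mark.parametrize("model", ["fixed", "increasing", "decreasing"])
    @pytest.mark.parametrize("s", [2, 3, 4, 5, 6])
    def test_monotone_in_correlation(self, kind, model, s):
        sched = equal_spacing(s)
        rec = RecruitmentSpec(model, 100.0, 8.0)
        t = time_at_tau0(rec, sched, 0.3)
        vals = [
            v_factor(DesignPoint(t=t, sched=sched, rec=rec, corr=CorrelationSpec(kind, a)))
            for a in np.linspace(0.0, 0.99, 12)
        ]
        assert np.all(np.diff(vals) <= 1e-12)
        assert vals[0] == pytest.approx(1.0)

    def test_bounds_and_bracketing_random_spacings(self, rng):
        """n_s1 <= V <= 1 and the analytic extrema bracket V for random
        intermediate spacings, both correlation models."""
        for _ in range(300):
            s = int(rng.integers(3, 7))
            mids = np.sort(rng.uniform(1.0 + 1e-3, 2.0 - 1e-3, size=s - 2))
            sched = FollowUpSchedule(np.concatenate(([1.0], mids, [2.0])))
            model = ("fixed", "increasing", "decreasing")[int(rng.integers(3))]
            rec = RecruitmentSpec(model, 100.0, 8.0)
            t = time_at_tau0(rec, sched, float(rng.uniform(0.05, 0.95)))
            param = float(rng.uniform(0.0, 0.98))
            g = counts_at(rec, sched, t)
            n_s1 = g[-1] / g[0]
            for kind in ("uniform", "exponential"):
                v = v_factor(DesignPoint(t=t, sched=sched, rec=rec, corr=CorrelationSpec(kind, param)))
                assert n_s1 - 1e-10 <= v <= 1.0 + 1e-10
                if kind == "uniform":
                    vmin, vmax = v_uniform_extrema(rec, t, 1.0, 2.0, s, param)
                else:
                    vmax = v_exp_max(rec, t, 1.0, 2.0, s, param)
                    vmin = n_s1
                assert vmin - 1e-9 <= v <= vmax + 1e-9


class TestUniformExtrema:
    def test_reference_cells(self):
        rec = RecruitmentSpec("fixed", 100.0, 8.0)
        t = time_at_tau0(rec, equal_spacing(3), 0.15)
        vmin, vmax = v_uniform_extrema(rec, t, 1.0, 2.0, 3, 0.5)
        assert vmin == pytest.approx(0.85, abs=0.005)
        assert vmax == pytest.approx(0.89, abs=0.005)

    def test_degenerate_cases(self):
        rec = RecruitmentSpec("fixed", 100.0, 8.0)
        vmin, vmax = v_uniform_extrema(rec, 3.2, 1.0, 2.0, 2, 0.5)
        assert vmin == vmax
        vmin, vmax = v_uniform_extrema(rec, 3.2, 1.0, 2.0, 4, 0.0)
        assert vmin == pytest.approx(1.0) and vmax == pytest.approx(1.0)

    def test_D_factor(self):
        assert uniform_D(2, 0.5) == pytest.approx(0.75)
        assert uniform_D(6, 0.5) == pytest.approx(0.58, abs=0.005)
        vals = [uniform_D(s, 0.5) for s in range(2, 30)]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] > 1 - 0.5  # decreasing towards the 1 - alpha limit


class TestExponentialExtrema:
    def test_max_reference(self):
        rec = RecruitmentSpec("fixed", 100.0, 8.0)
        t = time_at_tau0(rec, equal_spacing(2), 0.15)
        assert v_exp_max(rec, t, 1.0, 2.0, 2, 0.5) == pytest.approx(0.89, abs=0.005)
        assert v_exp_max(rec, t, 1.0, 2.0, 4, 0.0) == pytest.approx(1.0)

    def test_max_equals_uniform_max_under_calibration(self):
        """gamma = alpha^{1/(d_s-d_1)} aligns the two models' maxima."""
        rec = RecruitmentSpec("decreasing", 100.0, 12.0)
        d_1, d_s = 1.0, 3.0
        alpha = 0.4
        gamma = alpha ** (1.0 / (d_s - d_1))
        t = 4.0
        _, vmax_u = v_uniform_extrema(rec, t, d_1, d_s, 4, alpha)
        assert v_exp_max(rec, t, d_1, d_s, 4, gamma) == pytest.approx(vmax_u, rel=1e-12)

    def test_max_matches_grid_search(self, rng):
        rec = RecruitmentSpec("fixed", 100.0, 8.0)
        t, gamma, s = 3.2, 0.5, 4
        best = -np.inf
        for _ in range(2000):
            mids = np.sort(rng.uniform(1.0 + 1e-4, 2.0 - 1e-4, size=s - 2))
            sched = FollowUpSchedule(np.concatenate(([1.0], mids, [2.0])))
            best = max(
                best,
                v_factor(DesignPoint(t=t, sched=sched, rec=rec, corr=CorrelationSpec("exponential", gamma))),
            )
        vmax = v_exp_max(rec, t, 1.0, 2.0, s, gamma)
        assert best <= vmax + 1e-9
        assert vmax - best < 0.01  # the supremum is approached

    @pytest.mark.parametrize(
        "model, s, expected",
        [("fixed", 3, 0.80), ("decreasing", 4, 0.69)],
    )
    def test_min_reference_cells(self, model, s, expected):
        rec = RecruitmentSpec(model, 100.0, 8.0)
        t = time_at_tau0(rec, equal_spacing(s), 0.15)
        vmin, _ = v_exp_min(rec, t, 1.0, 2.0, s, 0.5)
        assert vmin == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("s", [3, 4])
    def test_min_matches_dense_grid(self, s):
        """The gradient-based minimum agrees with dense grid search."""
        rec = RecruitmentSpec("fixed", 100.0, 8.0)
        t, gamma = 3.2, 0.5
        vmin, argmin = v_exp_min(rec, t, 1.0, 2.0, s, gamma)
        grid = np.linspace(1.0 + 1e-4, 2.0 - 1e-4, 120 if s == 3 else 60)
        best = np.inf
        if s == 3:
            combos = ((m,) for m in grid)
        else:
            combos = ((m1, m2) for m1 in grid for m2 in grid if m1 < m2)
        for mids in combos:
            sched = FollowUpSchedule(np.concatenate(([1.0], mids, [2.0])))
            best = min(
                best,
                v_factor(DesignPoint(t=t, sched=sched, rec=rec, corr=CorrelationSpec("exponential", gamma))),
            )
        assert vmin == pytest.approx(best, abs=1e-4)
        assert np.all(np.diff(np.concatenate(([1.0], argmin, [2.0]))) > 0)

    def test_min_not_above_equal_spacing(self):
        rec = RecruitmentSpec("increasing", 100.0, 8.0)
        for s, gamma in [(3, 0.3), (4, 0.5), (5, 0.8)]:
            t = time_at_tau0(rec, equal_spacing(s), 0.3)
            vmin, _ = v_exp_min(rec, t, 1.0, 2.0, s, gamma)
            v_eq = v_factor(
                DesignPoint(t=t, sched=equal_spacing(s), rec=rec, corr=CorrelationSpec("exponential", gamma))
            )
            assert vmin <= v_eq + 1e-10

    @pytest.mark.parametrize("model", ["fixed", "decreasing"])
    @pytest.mark.parametrize("s", [3, 4, 6])
    @pytest.mark.parametrize("gamma", [0.2, 0.5, 0.9])
    def test_gradient_matches_finite_differences(self, model, s, gamma, rng):
        rec = RecruitmentSpec(model, 100.0, 8.0)
        t = 3.4
        for _ in range(5):
            mids = np.sort(rng.uniform(1.05, 1.95, size=s - 2))
            val, grad = _v_exp_and_grad(mids, rec, t, 1.0, 2.0, gamma)
            h = 1e-6
            for j in range(s - 2):
                up = mids.copy()
                dn = mids.copy()
                up[j] += h
                dn[j] -= h
                fd = (
                    _v_exp_and_grad(up, rec, t, 1.0, 2.0, gamma)[0]
                    - _v_exp_and_grad(dn, rec, t, 1.0, 2.0, gamma)[0]
                ) / (2 * h)
                assert grad[j] == pytest.approx(fd, abs=2e-6, rel=1e-4)


class TestInformationFraction:
    @pytest.mark.parametrize(
        "model, tau0, expected_tau",
        [("fixed", 0.25, 0.309), ("decreasing", 0.25, 0.318)],
    )
    def test_exemplar(self, model, tau0, expected_tau):
        summ = information_fraction(_point(model=model, tau0=tau0))
        assert summ.tau0 == pytest.approx(tau0, abs=1e-10)
        assert summ.tau == pytest.approx(expected_tau, abs=5e-4)
        assert summ.info == pytest.approx(1.0 / summ.var_beta)

    def test_zero_correlation(self):
        summ = information_fraction(_point(alpha=0.0))
        assert summ.V == pytest.approx(1.0)
        assert summ.tau == pytest.approx(summ.tau0)

    def test_unequal_allocation(self):
        sched = FollowUpSchedule([1, 2, 4])
        rec = RecruitmentSpec("fixed", 188.0, 8.0)
        p = DesignPoint(
            t=6.0,
            sched=sched,
            rec=rec,
            corr=CorrelationSpec("uniform", 0.5),
            alloc=AllocationSpec(0.7),
            sigma_s=12.0,
        )
        balanced = information_fraction(_point())
        skewed = information_fraction(p)
        # V and tau are allocation-invariant; absolute information is not
        assert skewed.V == pytest.approx(balanced.V)
        assert skewed.info < balanced.info


class TestGlsOracle:
    def test_complete_data(self):
        sched = FollowUpSchedule([1.0, 2.0])
        c = np.array([94.0, 94.0])
        v = gls_variance_oracle(c, c, CorrelationSpec("uniform", 0.6), sched, 12.0)
        # 94 per arm at both occasions: N = 188, var = 4 sigma^2 / N
        assert v == pytest.approx(4 * 144 / 188, rel=1e-10)

    def test_s2_closed_form(self):
        sched = FollowUpSchedule([1.0, 2.0])
        c0 = np.array([60.0, 30.0])
        c1 = np.array([50.0, 25.0])
        rho = 0.4
        want = (
            (c0[1] + c1[1]) * (1 - rho**2) / (c0[1] * c1[1])
            + (c0[0] + c1[0]) * rho**2 / (c0[0] * c1[0])
        )
        got = gls_variance_oracle(c0, c1, CorrelationSpec("uniform", rho), sched, 1.0)
        assert got == pytest.approx(want, rel=1e-10)

    def test_heterogeneous_sigma_allowed(self, rng):
        sched = FollowUpSchedule([1.0, 2.0, 3.0])
        c0 = random_monotone_counts(rng, 3)
        c1 = random_monotone_counts(rng, 3)
        v = gls_variance_oracle(
            c0, c1, CorrelationSpec("exponential", 0.5), sched, [2.0, 3.0, 4.0]
        )
        assert v > 0
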