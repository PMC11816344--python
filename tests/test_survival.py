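"""Survival primitives against closed forms, brute-force oracles and lifelines."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats

from survscreen.survival import cox_fit, km_fit, log_rank, survival_auc
from tests.conftest import surv_sim


def km_oracle(times, events):
    """Hand product-limit computation: S(t) = prod (1 - d_i/n_i)."""
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s, out = 1.0, {}
    for t in np.unique(times):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / at_risk
        out[t] = s
    return out


class TestKM:
    def test_no_censoring_closed_form(self):
        km = km_fit([1, 2], [1, 1])
        assert km.survival_at(1) == pytest.approx(0.5)
        assert km.survival_at(2) == pytest.approx(0.0)

    def test_censoring_freezes_curve(self):
        km = km_fit([1, 2], [1, 0])
        assert km.survival_at(2) == pytest.approx(0.5)

    def test_matches_hand_product_limit(self, rng):
        times = rng.integers(1, 15, 20).astype(float)
        events = rng.integers(0, 2, 20)
        km = km_fit(times, events)
        for t, s in km_oracle(times, events).items():
            assert km.survival_at(t) == pytest.approx(s, abs=1e-12)

    def test_zero_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, 50)
        km = km_fit(times, np.ones(50))
        grid = np.quantile(times, [0.1, 0.4, 0.7, 0.95])
        for t in grid:
            assert km.survival_at(t) == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_fit([], [])


def logrank_oracle(times, events, groups):
    """Direct O-E / V tabulation of the two-group log-rank statistic."""
    times, events, groups = map(np.asarray, (times, events, groups))
    O_minus_E, V = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


class TestLogRank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        res = log_rank(times, events, [0, 0, 0, 1, 1, 1])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_tabulation(self, rng):
        times = np.concatenate([rng.exponential(5, 6), rng.exponential(20, 6)])
        events = np.ones(12, dtype=int)
        groups = np.repeat([0, 1], 6)
        res = log_rank(times, events, groups)
        assert res.chi2 == pytest.approx(logrank_oracle(times, events, groups), rel=1e-6)

    def test_relabeling_invariance(self, rng):
        times, events, x = surv_sim(rng, 40, log_hr=1.0)
        a = log_rank(times, events, x)
        b = log_rank(times, events, 1 - x)
        assert a.chi2 == pytest.approx(b.chi2)

    def test_one_group_raises(self):
        with pytest.raises(ValueError):
            log_rank([1, 2], [1, 1], [0, 0])


def partial_loglik_1d(beta, times, events, x):
    """Independent O(n^2) partial log-likelihood (no ties)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_null_binary_covariate(self):
        times = np.tile([1.0, 2, 3, 4, 5, 6, 7, 8], 2)
        events = np.ones(16, dtype=int)
        x = np.repeat([0.0, 1.0], 8)
        fit = cox_fit(times, events, x)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-6)

    def test_grid_search_oracle_n5(self):
        times = np.array([2.0, 5.0, 1.0, 7.0, 4.0])
        events = np.array([1, 1, 1, 0, 1])
        x = np.array([0.5, -1.2, 2.0, 0.1, -0.3])
        fit = cox_fit(times, events, x)
        grid = np.linspace(-5, 5, 100001)
        lls = [partial_loglik_1d(b, times, events, x) for b in grid]
        assert fit.coef[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_parameter_recovery_hr3(self, rng):
        times, events, x = surv_sim(rng, 500, log_hr=np.log(3))
        fit = cox_fit(times, events, x)
        assert abs(fit.coef[0] - np.log(3)) < 3 * fit.se[0]

    def test_hr_equals_exp_coef(self, rng):
        times, events, x = surv_sim(rng, 60, log_hr=0.7)
        fit = cox_fit(times, events, x)
        assert np.allclose(fit.hr, np.exp(fit.coef))
        assert fit.n_events <= fit.n

    @pytest.mark.parametrize("round_times", [False, True])
    def test_matches_lifelines(self, rng, round_times):
        """Efron-tie fits agree with lifelines on censored data, with and without ties."""
        times, events, x = surv_sim(rng, 150, log_hr=0.8)
        z = rng.normal(size=150)
        if round_times:
            times = np.ceil(times)  # force heavy ties
        fit = cox_fit(times, events, np.column_stack([x, z]), names=["x", "z"])
        df = pd.DataFrame({"t": times, "e": events, "x": x, "z": z})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert fit.coef == pytest.approx(ref.params_.to_numpy(), abs=2e-4)
        assert fit.se == pytest.approx(ref.standard_errors_.to_numpy(), abs=2e-4)

    def test_exponential_rate_ratio_consistency(self, rng):
        times, events, x = surv_sim(rng, 2000, log_hr=np.log(2.0))
        fit = cox_fit(times, events, x)
        assert np.exp(fit.coef[0]) == pytest.approx(2.0, rel=0.10)

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 1, 0], np.ones(4))

    def test_monotone_likelihood_flagged(self):
        # the high group has zero events -> likelihood diverges
        times = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        events = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        fit = cox_fit(times, events, x)
        assert not fit.converged
        assert np.isfinite(fit.coef[0]) and abs(fit.coef[0]) <= 15.0


class TestSurvivalAUC:
    def test_perfect_marker(self):
        times = np.array([1.0, 2, 3, 10, 11, 12])
        events = np.array([1, 1, 1, 0, 0, 0])
        marker = events.astype(float)
        roc = survival_auc(times, events, marker, horizon=5)
        assert roc.auc == pytest.approx(1.0)

    def test_null_marker_near_half(self, rng):
        times, events, _ = surv_sim(rng, 800, log_hr=0.0)
        marker = rng.normal(size=800)
        roc = survival_auc(times, events, marker, horizon=np.median(times))
        assert abs(roc.auc - 0.5) < 0.08

    def test_uncensored_reduction_oracle(self, rng):
        """No censoring: equals the empirical ROC of 'event by horizon' vs marker."""
        times = rng.exponential(10, 40)
        events = np.ones(40, dtype=int)
        marker = rng.normal(size=40) + 0.1 * (times < 8)
        horizon = 8.0
        roc = survival_auc(times, events, marker, horizon)
        case = times <= horizon
        auc_oracle = stats.mannwhitneyu(marker[case], marker[~case]).statistic \
            / (case.sum() * (~case).sum())
        assert roc.auc == pytest.approx(auc_oracle, abs=1e-12)
        # sens/spec at an arbitrary threshold also reduce to plain proportions
        c = np.median(marker)
        assert roc.sens_at(c) == pytest.approx(np.mean(marker[case] > c))
        assert roc.spec_at(c) == pytest.approx(np.mean(marker[~case] <= c))

    def test_monotone_transform_invariance(self, rng):
        times, events, _ = surv_sim(rng, 100, log_hr=0.0)
        marker = rng.normal(size=100)
        h = np.median(times)
        a = survival_auc(times, events, marker, h).auc
        b = survival_auc(times, events, np.exp(2 * marker), h).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_sksurv_uno_estimator(self, rng):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        times, events, x = surv_sim(rng, 200, log_hr=1.0)
        marker = x + rng.normal(0, 0.5, 200)
        horizon = np.quantile(times, 0.5)
        y = np.array([(bool(e), t) for e, t in zip(events, times)],
                     dtype=[("event", bool), ("time", float)])
        auc_ref, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, marker, [horizon])
        mine = survival_auc(times, events, marker, horizon).auc
        assert mine == pytest.approx(float(auc_ref[0]), abs=0.02)

    def test_no_events_before_horizon_raises(self):
        with pytest.raises(ValueError):
            survival_auc([10.0, 12.0, 13.0], [1, 1, 0], [1.0, 2.0, 3.0], horizon=5)
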