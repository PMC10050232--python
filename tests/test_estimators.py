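"""Kaplan-Meier, logrank and Cox estimators against hand computations,
closed forms and independent library oracles."""

import math
import warnings

import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from pdtrial import (
    CoxPH,
    FitError,
    cox_fit,
    cox_score_test,
    km_fit,
    logrank,
    rmst,
    survival_at,
    survival_y,
)


class TestKaplanMeier:
    def test_uncensored_empirical_survival(self):
        curve = km_fit([2, 4, 6], [1, 1, 1])
        assert curve.survival_at(5) == pytest.approx(1 / 3)
        assert curve.survival_at(0) == 1.0

    def test_censored_hand_product_limit(self, toy_censored):
        curve = km_fit(*toy_censored)
        assert curve.survival_at(3) == pytest.approx(2 / 3)
        assert curve.survival_at(6) == pytest.approx(0.0)

    def test_glivenko_cantelli_against_exponential(self, rng):
        lam = math.log(2) / 9
        times = rng.exponential(1 / lam, 10_000)
        curve = km_fit(times, np.ones_like(times, dtype=int))
        grid = np.linspace(0.1, 40, 200)
        sup = np.max(np.abs(curve.survival_at(grid) - np.exp(-lam * grid)))
        assert sup < 0.02

    def test_matches_lifelines(self, rng):
        times = np.round(rng.exponential(10, 500), 1) + 0.1
        events = (rng.random(500) < 0.7).astype(int)
        curve = km_fit(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        grid = np.linspace(0.5, times.max(), 50)
        np.testing.assert_allclose(
            curve.survival_at(grid), kmf.survival_function_at_times(grid).values, atol=1e-10
        )

    def test_all_censored_flat_with_warning(self):
        with pytest.warns(UserWarning, match="all observations censored"):
            curve = km_fit([1, 2, 3], [0, 0, 0])
        assert curve.survival_at(2.5) == 1.0

    def test_beyond_support_carries_last_value_and_warns(self, toy_censored):
        curve = km_fit(*toy_censored)
        with pytest.warns(UserWarning, match="beyond the last observed time"):
            assert curve.survival_at(100.0) == 0.0


class TestRMST:
    def test_uncensored_equals_mean_truncated_time(self):
        curve = km_fit([2, 4, 6], [1, 1, 1])
        assert rmst(curve, 6) == pytest.approx(4.0)

    def test_exponential_closed_form(self, rng):
        lam = math.log(2) / 12
        times = rng.exponential(1 / lam, 200_000)
        curve = km_fit(times, np.ones_like(times, dtype=int))
        expected = (1 - math.exp(-lam * 36)) / lam  # = 15.148...
        assert expected == pytest.approx(15.148, abs=5e-3)
        assert rmst(curve, 36.0) == pytest.approx(expected, abs=0.15)

    def test_small_t_limit(self, toy_censored):
        curve = km_fit(*toy_censored)
        assert rmst(curve, 1e-9) == pytest.approx(0.0, abs=1e-8)

    def test_monotone_and_bounded(self, rng):
        times = rng.exponential(10, 300)
        events = (rng.random(300) < 0.8).astype(int)
        curve = km_fit(times, events)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = [1.0, 5.0, 10.0, 20.0, 40.0]
            vals = [rmst(curve, t) for t in grid]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(v <= t for v, t in zip(vals, grid))


class TestLogrank:
    def test_hand_computed_hypergeometric_tally(self):
        # group 0: events at 1, 2; group 1: events at 3, 4.  Hypergeometric
        # tally for group 1 at each of the four event times:
        #   t=1: n=4, n1=2, d=1, d1=0 -> O-E = -1/2, V = (2/4)(2/4)(3/3) = 1/4
        #   t=2: n=3, n1=2, d=1, d1=0 -> O-E = -2/3, V = (2/3)(1/3)(2/2) = 2/9
        #   t=3: n=2, n1=2           -> O-E = 1-1 = 0, V = 0
        #   t=4: n=1, n1=1           -> O-E = 0,       V = 0
        res = logrank([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [0, 0, 1, 1])
        o_minus_e = -0.5 - 2 / 3
        v = 1 / 4 + 2 / 9
        assert res.coefficients["o_minus_e"] == pytest.approx(o_minus_e)
        assert res.coefficients["variance"] == pytest.approx(v)
        assert res.statistic == pytest.approx(o_minus_e**2 / v)

    def test_matches_lifelines(self, rng):
        n = 300
        times = np.concatenate([rng.exponential(12, n), rng.exponential(9, n)])
        events = (rng.random(2 * n) < 0.8).astype(int)
        group = np.repeat([0, 1], n)
        res = logrank(times, events, group)
        ref = logrank_test(times[:n], times[n:], events[:n], events[n:])
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_null_calibration(self):
        """Random splits of a pooled sample reject at about the nominal rate."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 400
        for _ in range(reps):
            times = rng.exponential(10, 120)
            events = (rng.random(120) < 0.8).astype(int)
            group = rng.integers(0, 2, 120)
            if group.sum() in (0, 120):
                continue
            if logrank(times, events, group).p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=3 * math.sqrt(0.05 * 0.95 / reps))

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            logrank([1, 2, 3], [1, 1, 1], [0, 0, 0])


class TestCox:
    def test_recovers_ratio_of_medians(self):
        rng = np.random.default_rng(42)
        n = 5000
        times = np.concatenate(
            [rng.exponential(12 / math.log(2), n), rng.exponential(9 / math.log(2), n)]
        )
        events = np.ones(2 * n, dtype=int)
        x = np.repeat([0.0, 1.0], n)
        res = cox_fit(times, events, x[:, None], model=5)
        assert res.estimate == pytest.approx(12 / 9, abs=0.05)

    def test_null_hr_near_one_and_calibrated(self):
        rng = np.random.default_rng(13)
        reps, rejections, hrs = 300, 0, []
        for _ in range(reps):
            times = rng.exponential(10, 200)
            events = (rng.random(200) < 0.9).astype(int)
            x = rng.integers(0, 2, 200).astype(float)
            res = cox_fit(times, events, x[:, None], model=5)
            hrs.append(res.estimate)
            rejections += res.p_value < 0.05
        assert np.mean(np.log(hrs)) == pytest.approx(0.0, abs=0.02)
        assert rejections / reps == pytest.approx(0.05, abs=3 * math.sqrt(0.05 * 0.95 / reps))

    def test_interaction_model_null_interaction(self):
        """Equal subgroup effects leave the interaction hazard ratio at 1."""
        rng = np.random.default_rng(14)
        n = 4000
        m = rng.integers(0, 2, n).astype(float)
        x = rng.integers(0, 2, n).astype(float)
        # same HR (0.7) in both subgroups, different baselines
        rate = 0.08 * np.exp(math.log(0.7) * x + 0.3 * m)
        times = rng.exponential(1 / rate)
        events = np.ones(n, dtype=int)
        res = cox_fit(times, events, np.column_stack([x, m, x * m]), model=6)
        assert res.estimate == pytest.approx(1.0, abs=0.08)

    def test_matches_lifelines_with_ties(self, rng):
        import pandas as pd

        n = 400
        x = rng.integers(0, 2, n).astype(float)
        m = rng.integers(0, 2, n).astype(float)
        times = np.round(rng.exponential(10 * np.exp(-0.4 * x + 0.2 * m), n), 1) + 0.1
        events = (rng.random(n) < 0.8).astype(int)
        est = CoxPH().fit(np.column_stack([x, m, x * m]), (times, events))
        df = pd.DataFrame({"t": times, "e": events, "x": x, "m": m, "xm": x * m})
        ref = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(est.coef_, ref.params_.values, atol=1e-6)
        np.testing.assert_allclose(est.se_, ref.standard_errors_.values, atol=1e-6)

    def test_score_statistic_equals_logrank(self, rng):
        times = np.concatenate([rng.exponential(12, 150), rng.exponential(8, 150)])
        events = (rng.random(300) < 0.85).astype(int)
        group = np.repeat([0.0, 1.0], 150)
        assert len(np.unique(times)) == 300  # tie-free
        lr = logrank(times, events, group)
        score, _ = cox_score_test(times, events, group[:, None])
        assert score == pytest.approx(lr.statistic, abs=1e-6)

    def test_separation_raises_fit_error(self):
        # all events in one group, none in the other
        times = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        events = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        with pytest.raises(FitError):
            cox_fit(times, events, x[:, None], model=5)

    def test_row_order_invariance(self, rng):
        n = 200
        times = rng.exponential(10, n)
        events = (rng.random(n) < 0.8).astype(int)
        x = rng.integers(0, 2, n).astype(float)
        a = cox_fit(times, events, x[:, None], model=5)
        perm = rng.permutation(n)
        b = cox_fit(times[perm], events[perm], x[perm][:, None], model=5)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-10)
        lr_a = logrank(times, events, x)
        lr_b = logrank(times[perm], events[perm], x[perm])
        assert lr_a.statistic == pytest.approx(lr_b.statistic, rel=1e-10)

    def test_sklearn_param_interface(self):
        est = CoxPH(max_iter=10)
        assert est.get_params()["max_iter"] == 10
        est.set_params(tol=1e-8)
        assert est.tol == 1e-8

    def test_structured_y_convention(self, rng):
        times = rng.exponential(10, 100)
        events = (rng.random(100) < 0.8).astype(int)
        x = rng.integers(0, 2, 100).astype(float)[:, None]
        a = CoxPH().fit(x, survival_y(times, events))
        b = CoxPH().fit(x, (times, events))
        np.testing.assert_allclose(a.coef_, b.coef_)
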