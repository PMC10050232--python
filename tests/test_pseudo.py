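"""Jackknife pseudo-observations and the identity-link sandwich regression,
checked against exact uncensored identities, a brute-force leave-one-out
oracle and statsmodels' robust OLS."""

import warnings

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from pdtrial import (
    FitError,
    PseudoValueRegression,
    glm_identity,
    pseudo_observations,
)
from conftest import brute_force_pseudo, km_functional_oracle


class TestPseudoValues:
    def test_uncensored_survival_is_indicator(self, rng):
        times = rng.exponential(12, 100)
        ps = pseudo_observations(times, np.ones(100, int), "survival", 9.0)
        np.testing.assert_allclose(ps.values, (times > 9.0).astype(float), atol=1e-12)

    def test_uncensored_rmst_is_truncated_time(self, rng):
        times = rng.exponential(12, 100)
        ps = pseudo_observations(times, np.ones(100, int), "rmst", 9.0)
        np.testing.assert_allclose(ps.values, np.minimum(times, 9.0), atol=1e-12)

    @pytest.mark.parametrize("functional", ["survival", "rmst"])
    def test_censored_toy_against_brute_force(self, toy_censored, functional):
        times, events = toy_censored
        fast = pseudo_observations(times, events, functional, 5.0).values
        oracle = brute_force_pseudo(times, events, 5.0, functional)
        np.testing.assert_allclose(fast, oracle, atol=1e-12)

    @pytest.mark.parametrize("functional", ["survival", "rmst"])
    @pytest.mark.parametrize("horizon", [4.0, 15.0, 60.0])
    def test_random_censored_with_ties_against_brute_force(self, functional, horizon):
        rng = np.random.default_rng(99)
        times = np.round(rng.exponential(10, 120), 1) + 0.1  # heavy ties
        events = (rng.random(120) < 0.65).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fast = pseudo_observations(times, events, functional, horizon).values
            oracle = brute_force_pseudo(times, events, horizon, functional)
        np.testing.assert_allclose(fast, oracle, atol=1e-10)

    @settings(max_examples=40, deadline=None)
    @seed(20240917)
    @given(data=st.data())
    def test_mean_identity_property(self, data):
        """mean(pseudo-values) = n*theta_hat - (n-1)*mean(leave-one-out),
        the defining identity of the jackknife construction."""
        n = data.draw(st.integers(5, 40))
        times = np.array(data.draw(st.lists(st.floats(0.1, 50.0), min_size=n, max_size=n)))
        events = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        horizon = data.draw(st.floats(0.5, 60.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = pseudo_observations(times, events, "rmst", horizon)
            loo = np.array(
                [
                    km_functional_oracle(np.delete(times, i), np.delete(events, i), horizon, "rmst")
                    for i in range(n)
                ]
            )
        expected_mean = n * ps.theta_hat - (n - 1) * loo.mean()
        assert ps.values.mean() == pytest.approx(expected_mean, abs=1e-9)

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            pseudo_observations([5.0], [1], "survival", 3.0)

    def test_row_order_invariance(self, rng):
        times = rng.exponential(10, 150)
        events = (rng.random(150) < 0.7).astype(int)
        a = pseudo_observations(times, events, "rmst", 12.0).values
        perm = rng.permutation(150)
        b = pseudo_observations(times[perm], events[perm], "rmst", 12.0).values
        np.testing.assert_allclose(a[perm], b, atol=1e-12)


class TestIdentityLinkRegression:
    def test_uncensored_group_difference_exact(self, rng):
        """With no censoring, model (two-group indicator) recovers exactly the
        difference in group fractions surviving past t."""
        n = 200
        times = rng.exponential(10, n)
        x = rng.integers(0, 2, n).astype(float)
        ps = pseudo_observations(times, np.ones(n, int), "survival", 8.0)
        res = glm_identity(ps, np.column_stack([np.ones(n), x]), model=8)
        direct = np.mean(times[x == 1] > 8.0) - np.mean(times[x == 0] > 8.0)
        assert res.estimate == pytest.approx(direct, abs=1e-12)

    def test_censored_beta_is_difference_of_pseudo_means(self, rng):
        n = 300
        times = rng.exponential(10, n)
        events = (rng.random(n) < 0.7).astype(int)
        x = rng.integers(0, 2, n).astype(float)
        oracle = brute_force_pseudo(times, events, 12.0, "rmst")
        ps = pseudo_observations(times, events, "rmst", 12.0)
        res = glm_identity(ps, np.column_stack([np.ones(n), x]), model=10)
        assert res.estimate == pytest.approx(oracle[x == 1].mean() - oracle[x == 0].mean(), abs=1e-8)

    def test_sandwich_matches_statsmodels_hc0(self, rng):
        import statsmodels.api as sm

        n = 250
        times = rng.exponential(10, n)
        events = (rng.random(n) < 0.7).astype(int)
        x = rng.integers(0, 2, n).astype(float)
        m = rng.integers(0, 2, n).astype(float)
        ps = pseudo_observations(times, events, "survival", 9.0)
        Z = np.column_stack([np.ones(n), x, m, x * m])
        res = glm_identity(ps, Z, model=9)
        ref = sm.OLS(ps.values, Z).fit(cov_type="HC0")
        assert res.coefficients["beta_3"] == pytest.approx(ref.params[3], abs=1e-10)
        assert res.se == pytest.approx(ref.bse[3], abs=1e-10)

    def test_null_calibration(self):
        """Two arms with identical generative law: coefficient near 0 and
        rejection at about the nominal rate."""
        rng = np.random.default_rng(21)
        reps, rejections, betas = 400, 0, []
        for _ in range(reps):
            n = 200
            times = np.minimum(rng.exponential(12, n), 30.0)
            events = (times < 30.0).astype(int)
            arm = rng.integers(0, 2, n).astype(float)
            ps = pseudo_observations(times, events, "rmst", 24.0)
            res = glm_identity(ps, np.column_stack([np.ones(n), arm]), model=10)
            betas.append(res.estimate)
            rejections += res.p_value < 0.05
        assert np.mean(betas) == pytest.approx(0.0, abs=0.05)
        assert rejections / reps == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / reps))

    def test_rank_deficiency_names_columns(self, rng):
        n = 50
        times = rng.exponential(10, n)
        x = rng.integers(0, 2, n).astype(float)
        ps = pseudo_observations(times, np.ones(n, int), "survival", 5.0)
        Z = np.column_stack([np.ones(n), x, x, np.zeros(n)])  # duplicated + zero column
        with pytest.raises(FitError, match="collinear"):
            glm_identity(ps, Z, model=9)

    def test_estimator_class_interface(self, rng):
        n = 150
        times = rng.exponential(10, n)
        events = (rng.random(n) < 0.8).astype(int)
        x = rng.integers(0, 2, n).astype(float)[:, None]
        est = PseudoValueRegression(functional="rmst", horizon=12.0).fit(x, (times, events))
        assert est.coef_.shape == (2,)
        assert est.pseudo_values_.shape == (n,)
        assert est.get_params()["horizon"] == 12.0
        # per-group pseudo-values are the documented non-default option
        est2 = PseudoValueRegression(functional="rmst", horizon=12.0).fit(
            x, (times, events), groups=x.ravel()
        )
        assert np.isfinite(est2.coef_).all()
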