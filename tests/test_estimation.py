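"""Likelihood, analytic score, ML fitting and Wald intervals."""

import numpy as np
import pytest
from scipy import stats

from tiht import (
    DomainError,
    TIHTWParams,
    fit_mle,
    log_likelihood,
    score,
    tihtw_log_pdf,
    tihtw_quantile,
    wald_ci,
    weibull_mle,
)
from tests.conftest import make_sample


class TestLogLikelihood:
    def test_unit_exponential_datum(self):
        # alpha = gamma = theta = 1: density exp(-x), so l({1}) = -1
        assert log_likelihood([1.0, 1.0, 1.0], [1.0]) == pytest.approx(-1.0)

    def test_theta_one_reduces_to_weibull_loglik(self):
        x = make_sample(TIHTWParams(1.2, 0.8, 1.0), 200, seed=4)
        a, g = 1.3, 0.9
        expected = np.sum(np.log(a * g) + (a - 1) * np.log(x) - g * x**a)
        assert log_likelihood([a, g, 1.0], x) == pytest.approx(expected, rel=1e-12)

    def test_structural_form_matches_log_density_sum(self):
        rng = np.random.default_rng(5)
        x = make_sample(TIHTWParams(0.9, 1.1, 0.7), 50, seed=6)
        for _ in range(5):
            t = rng.uniform(0.4, 2.0, size=3)
            direct = np.sum(tihtw_log_pdf(x, TIHTWParams(*t)))
            assert log_likelihood(t, x) == pytest.approx(direct, abs=1e-10 * abs(direct))

    def test_domain_violation_is_minus_inf(self):
        x = np.array([0.5, 1.5])
        assert log_likelihood([1.0, 1.0, -0.5], x) == -np.inf

    def test_nonpositive_data_rejected(self):
        with pytest.raises(DomainError):
            log_likelihood([1.0, 1.0, 1.0], [1.0, 0.0])


class TestScore:
    def test_matches_finite_differences(self):
        x = make_sample(TIHTWParams(1.4, 1.0, 0.9), 30, seed=7)
        t = np.array([1.1, 0.8, 1.3])
        g = score(t, x)
        for i in range(3):
            h = 1e-6 * (1.0 + t[i])
            tp, tm = t.copy(), t.copy()
            tp[i] += h
            tm[i] -= h
            fd = (log_likelihood(tp, x) - log_likelihood(tm, x)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-5)

    def test_theta_one_component_matches_finite_difference(self):
        x = make_sample(TIHTWParams(1.0, 1.0, 1.0), 40, seed=8)
        t = np.array([1.0, 1.0, 1.0])
        g = score(t, x)
        h = 1e-6
        fd = (
            log_likelihood([1.0, 1.0, 1.0 + h], x)
            - log_likelihood([1.0, 1.0, 1.0 - h], x)
        ) / (2 * h)
        assert g[2] == pytest.approx(fd, rel=1e-5)

    def test_vanishes_at_mle(self, sample_5000):
        fit = fit_mle(sample_5000, "tihtw")
        g = score(fit.estimates, sample_5000)
        assert np.max(np.abs(g)) < 1e-4 * sample_5000.size


class TestWeibullMle:
    def test_matches_scipy(self):
        x = make_sample(TIHTWParams(1.3, 0.6, 1.0), 400, seed=9)
        a_hat, g_hat = weibull_mle(x)
        c, loc, scale = stats.weibull_min.fit(x, floc=0)
        assert a_hat == pytest.approx(c, rel=1e-4)
        assert g_hat == pytest.approx(scale**-c, rel=1e-3)


class TestFitMle:
    def test_parameter_recovery_within_three_se(self, heavy_params, sample_5000):
        fit = fit_mle(sample_5000, "tihtw")
        truth = np.array(
            [heavy_params.alpha, heavy_params.gamma, heavy_params.theta]
        )
        assert fit.converged
        assert np.all(np.abs(fit.estimates - truth) < 3.0 * fit.std_errors)

    def test_refit_is_fixed_point(self, sample_5000):
        fit = fit_mle(sample_5000, "tihtw")
        refit = fit_mle(sample_5000, "tihtw", init=fit.estimates)
        np.testing.assert_allclose(refit.estimates, fit.estimates, rtol=1e-5)

    def test_loglik_and_information_criteria_consistent(self, sample_5000):
        fit = fit_mle(sample_5000, "tihtw")
        assert fit.loglik_max == pytest.approx(
            log_likelihood(fit.estimates, sample_5000)
        )
        k, n = 3, sample_5000.size
        assert fit.aic == pytest.approx(-2 * fit.loglik_max + 2 * k)
        assert fit.bic == pytest.approx(-2 * fit.loglik_max + k * np.log(n))

    def test_nested_likelihood_ordering(self):
        x = make_sample(TIHTWParams(1.2, 0.9, 0.6), 400, seed=11)
        full = fit_mle(x, "tihtw")
        nested = fit_mle(x, "weibull")
        assert full.loglik_max >= nested.loglik_max - 1e-6

    def test_scale_equivariance(self):
        x = make_sample(TIHTWParams(1.1, 0.8, 0.7), 2000, seed=12)
        c = 3.0
        fit = fit_mle(x, "tihtw")
        fit_scaled = fit_mle(c * x, "tihtw")
        a, g, th = fit.estimates
        a2, g2, th2 = fit_scaled.estimates
        assert a2 == pytest.approx(a, rel=1e-3)
        assert th2 == pytest.approx(th, rel=2e-3)
        assert g2 == pytest.approx(g / c**a, rel=5e-3)

    def test_too_small_sample_rejected(self):
        with pytest.raises(DomainError):
            fit_mle([1.0, 2.0], "tihtw")


class TestWaldCi:
    def test_normal_quantile_multiplier(self, sample_5000):
        fit = fit_mle(sample_5000, "tihtw")
        lo, hi = wald_ci(fit, level=0.95)
        np.testing.assert_allclose(
            hi - fit.estimates, 1.959964 * fit.std_errors, rtol=1e-6
        )
        np.testing.assert_allclose(lo, fit.ci_lower, rtol=1e-12)

    def test_zero_se_degenerate_interval(self, sample_5000):
        fit = fit_mle(sample_5000, "tihtw")
        degenerate = fit.__class__(**{**fit.__dict__, "std_errors": np.zeros(3)})
        lo, hi = wald_ci(degenerate, 0.95)
        np.testing.assert_array_equal(lo, degenerate.estimates)
        np.testing.assert_array_equal(hi, degenerate.estimates)

    def test_width_shrinks_like_root_n(self):
        p = TIHTWParams(1.2, 0.9, 0.8)
        small = fit_mle(make_sample(p, 500, seed=13), "tihtw")
        big = fit_mle(make_sample(p, 2000, seed=13), "tihtw")
        ratio = (small.ci_upper - small.ci_lower) / (big.ci_upper - big.ci_lower)
        # expect about 2 = sqrt(2000/500) on average; individual parameters
        # are noisy on the correlated (gamma, theta) ridge
        assert np.all(ratio > 1.0)
        assert 1.3 < ratio.mean() < 4.0

    def test_invalid_level(self, sample_5000):
        fit = fit_mle(sample_5000, "tihtw")
        with pytest.raises(DomainError):
            wald_ci(fit, 1.0)
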