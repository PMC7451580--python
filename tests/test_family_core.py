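"""Generic TI-HT transform: reductions, stability, inversion, sampling."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from tiht import (
    DomainError,
    ParameterError,
    TIHTParams,
    TIHTWParams,
    WeibullParams,
    tiht_cdf,
    tiht_hrf,
    tiht_pdf,
    tiht_quantile,
    tiht_rng,
    tiht_sf,
    weibull_baseline,
)


def tp(alpha, gamma, theta):
    return TIHTParams(theta=theta, xi=(alpha, gamma)), weibull_baseline(
        WeibullParams(alpha, gamma)
    )


class TestReductions:
    def test_theta_one_collapses_to_baseline_exactly(self):
        params, base = tp(1.7, 0.6, 1.0)
        x = np.array([0.05, 0.3, 1.0, 2.7, 9.0])
        u = np.array([0.01, 0.25, 0.5, 0.9, 0.999])
        assert np.array_equal(tiht_cdf(x, params, base), base.cdf(x))
        assert np.array_equal(tiht_pdf(x, params, base), base.pdf(x))
        assert np.array_equal(tiht_quantile(u, params, base), base.quantile(u))
        draws = tiht_rng(100, params, base, seed=3)
        base_draws = base.quantile(np.random.default_rng(3).random(100))
        assert np.array_equal(draws, base_draws)

    def test_rayleigh_median_closed_form(self):
        params, base = tp(2.0, 1.0, 1.0)
        assert tiht_quantile(0.5, params, base) == pytest.approx(
            np.sqrt(np.log(2.0)), rel=1e-12
        )


class TestCdfPdf:
    def test_cdf_matches_cumulative_quadrature_of_pdf(self):
        params, base = tp(0.8, 1.0, 0.5)
        for x in [0.5, 1.0, 2.0, 5.0]:
            num, _ = integrate.quad(
                lambda t: tiht_pdf(t, params, base), 0.0, x, limit=300
            )
            assert tiht_cdf(x, params, base) == pytest.approx(num, abs=1e-6)

    def test_cdf_zero_at_support_lower_and_bounded(self):
        params, base = tp(1.4, 1.0, 0.9)
        assert tiht_cdf(0.0, params, base) == 0.0
        assert tiht_cdf(-3.0, params, base) == 0.0
        vals = tiht_cdf(np.logspace(-3, 2, 50), params, base)
        assert np.all((vals >= 0.0) & (vals <= 1.0))
        assert np.all(np.diff(vals) >= 0.0)

    def test_pdf_normalizes_to_one(self):
        params, base = tp(1.4, 1.0, 0.9)
        total, _ = integrate.quad(
            lambda t: tiht_pdf(t, params, base), 0.0, np.inf, limit=300
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_pdf_matches_central_difference_of_cdf(self):
        params, base = tp(0.8, 0.5, 1.0)
        x, h = 1.3, 1e-6
        fd = (tiht_cdf(x + h, params, base) - tiht_cdf(x - h, params, base)) / (2 * h)
        assert tiht_pdf(x, params, base) == pytest.approx(fd, rel=1e-5)


class TestSurvivalHazard:
    def test_sf_at_zero_is_one(self):
        params, base = tp(0.8, 1.0, 0.5)
        assert tiht_sf(0.0, params, base) == 1.0

    def test_heavy_tail_criterion_sf_beats_exponential(self):
        # For a sub-exponential baseline (alpha < 1) the survival function
        # beats every exponential: sf(x) * exp(p x) -> infinity.  (With
        # alpha = 1 the tail is exponential with rate theta*gamma and the
        # product diverges only for p above that rate.)
        params, base = tp(0.8, 1.0, 0.9)
        p = 0.45
        x = np.linspace(20.0, 300.0, 30)
        prod = tiht_sf(x, params, base) * np.exp(p * x)
        assert np.all(np.diff(prod) > 0.0)
        assert prod[-1] > 1e6 * prod[0]

    def test_exponential_rate_tail_needs_p_above_theta_gamma(self):
        # alpha = 1 boundary case: divergence iff p > theta * gamma.
        params, base = tp(1.0, 1.0, 0.9)
        x = np.linspace(30.0, 300.0, 20)
        above = tiht_sf(x, params, base) * np.exp(1.1 * 0.9 * x)
        below = tiht_sf(x, params, base) * np.exp(0.5 * 0.9 * x)
        assert np.all(np.diff(above) > 0.0)
        assert np.all(np.diff(below) < 0.0)

    def test_hrf_is_pdf_over_sf(self):
        params, base = tp(1.2, 0.7, 0.6)
        x = np.random.default_rng(0).uniform(0.05, 8.0, size=25)
        expected = tiht_pdf(x, params, base) / tiht_sf(x, params, base)
        assert np.allclose(tiht_hrf(x, params, base), expected, rtol=1e-12)

    def test_hrf_overflow_guidance(self):
        params, base = tp(2.0, 1.0, 1.5)
        with pytest.raises(FloatingPointError, match="underflow"):
            tiht_hrf(1e6, params, base)

    def test_weibull_tail_asymptote(self):
        # sf(x) / exp(-theta gamma x^alpha) -> theta^(-theta)
        alpha, gamma, theta = 1.3, 0.8, 0.7
        params, base = tp(alpha, gamma, theta)
        x = np.logspace(0.0, 1.2, 40)
        ratio = tiht_sf(x, params, base) / np.exp(-theta * gamma * x**alpha)
        assert ratio[-1] == pytest.approx(theta ** (-theta), rel=0.01)


class TestQuantile:
    def test_u_zero_maps_to_support_lower(self):
        params, base = tp(0.9, 1.0, 0.7)
        assert tiht_quantile(0.0, params, base) == 0.0

    def test_round_trip_dense_grid(self):
        params, base = tp(1.2, 0.7, 0.55)
        u = np.concatenate(
            [np.linspace(1e-10, 0.99, 300), 1.0 - np.logspace(-12, -3, 60)]
        )
        x = tiht_quantile(u, params, base)
        assert np.max(np.abs(tiht_cdf(x, params, base) - u)) < 1e-9

    def test_matches_bisection_root(self):
        params, base = tp(1.2, 0.7, 0.9)
        u = 0.95
        root = optimize.brentq(
            lambda x: tiht_cdf(x, params, base) - u, 1e-9, 1e4, xtol=1e-12
        )
        assert tiht_quantile(u, params, base) == pytest.approx(root, abs=1e-8)

    @pytest.mark.parametrize("theta,heavier", [(0.5, True), (1.8, False)])
    def test_stochastic_ordering_against_weibull(self, theta, heavier):
        alpha, gamma = 1.1, 0.9
        params, base = tp(alpha, gamma, theta)
        wparams, _ = tp(alpha, gamma, 1.0)
        u = np.linspace(0.7, 0.9999, 50)
        q_tiht = tiht_quantile(u, params, base)
        q_weib = tiht_quantile(u, wparams, base)
        if heavier:
            assert np.all(q_tiht > q_weib)
        else:
            assert np.all(q_tiht < q_weib)

    def test_rejects_levels_outside_unit_interval(self):
        params, base = tp(1.0, 1.0, 0.5)
        for bad in (-0.1, 1.0, 1.5, np.nan):
            with pytest.raises(DomainError):
                tiht_quantile(bad, params, base)


class TestRng:
    def test_deterministic_and_positive(self):
        params, base = tp(0.8, 1.0, 0.5)
        a = tiht_rng(500, params, base, seed=42)
        b = tiht_rng(500, params, base, seed=42)
        assert np.array_equal(a, b)
        assert np.all(a > 0.0)

    def test_ks_agreement_with_cdf(self):
        alpha, gamma, theta = 0.8, 0.5, 1.0
        params, base = tp(alpha, gamma, theta)
        n = 100_000
        draws = tiht_rng(n, params, base, seed=7)
        ks = stats.kstest(draws, lambda x: tiht_cdf(x, params, base)).statistic
        assert ks < 1.95 / np.sqrt(n)

    def test_invalid_sample_size(self):
        params, base = tp(1.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            tiht_rng(0, params, base, seed=1)


def test_theta_must_be_positive():
    with pytest.raises(ParameterError):
        TIHTParams(theta=0.0)
    with pytest.raises(ParameterError):
        TIHTParams(theta=-1.5)


def test_nonfinite_x_rejected():
    params, base = tp(1.0, 1.0, 0.5)
    with pytest.raises(DomainError):
        tiht_cdf(np.inf, params, base)
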