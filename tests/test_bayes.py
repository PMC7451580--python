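"""Posterior evaluation, MCMC sampling, convergence diagnostics and DIC."""

import numpy as np
import pytest
from scipy import special

from tiht import (
    PriorSpec,
    TIHTWParams,
    gelman_rubin,
    log_posterior,
    mcmc_sample,
)
from tiht.bayes import McmcResult, dic, dic_preference
from tiht.estimation import log_likelihood
from tests.conftest import make_sample


class TestLogPosterior:
    def test_componentwise_decomposition(self):
        x = make_sample(TIHTWParams(1.2, 0.9, 0.8), 80, seed=41)
        priors = PriorSpec(shapes=(2.0, 1.5, 1.0), rates=(1.0, 2.0, 0.5))
        t1 = np.array([1.1, 0.8, 0.9])
        t2 = np.array([1.4, 1.1, 0.6])

        def parts(t):
            ll = log_likelihood(t, x)
            prior = sum(
                a * np.log(b) - special.gammaln(a) + (a - 1) * np.log(v) - b * v
                for a, b, v in zip(priors.shapes, priors.rates, t)
            )
            return ll + prior

        diff = log_posterior(t1, x, priors) - log_posterior(t2, x, priors)
        assert diff == pytest.approx(parts(t1) - parts(t2), rel=1e-12)

    def test_flat_prior_limit_constant_offset(self):
        x = make_sample(TIHTWParams(1.2, 0.9, 0.8), 50, seed=43)
        priors = PriorSpec.diffuse(3, a=1.0, b=1e-8)
        offsets = [
            log_posterior([1.0, 1.0, t], x, priors) - log_likelihood([1.0, 1.0, t], x)
            for t in (0.5, 1.0, 2.0)
        ]
        assert np.ptp(offsets) < 1e-6

    def test_nonpositive_theta_is_minus_inf(self):
        x = np.array([1.0, 2.0, 0.5, 1.5])
        priors = PriorSpec.diffuse(3)
        assert log_posterior([1.0, 1.0, -1.0], x, priors) == -np.inf


class TestGelmanRubin:
    def test_identical_chains(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=(1, 200, 2))
        chains = np.repeat(chain, 2, axis=0)
        rhat = gelman_rubin(chains)
        np.testing.assert_allclose(rhat, np.sqrt(199.0 / 200.0), rtol=1e-12)

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = 0.0 + 0.01 * rng.normal(size=(200, 1))
        b = 5.0 + 0.01 * rng.normal(size=(200, 1))
        rhat = gelman_rubin(np.stack([a, b]))
        assert rhat[0] > 10.0

    def test_requires_multiple_chains(self):
        from tiht import DomainError

        with pytest.raises(DomainError):
            gelman_rubin(np.zeros((1, 100, 2)))


@pytest.fixture(scope="module")
def result():
    x = make_sample(TIHTWParams(1.4, 1.0, 0.9), 800, seed=47)
    return mcmc_sample(
        x, family="tihtw", n_chains=2, n_iter=4000, n_burnin=1500, seed=7
    ), x


class TestMcmc:

    def test_seed_determinism(self):
        x = make_sample(TIHTWParams(1.4, 1.0, 0.9), 200, seed=53)
        a = mcmc_sample(x, n_chains=2, n_iter=800, n_burnin=300, seed=3)
        b = mcmc_sample(x, n_chains=2, n_iter=800, n_burnin=300, seed=3)
        np.testing.assert_array_equal(a.chains, b.chains)
        assert a.dic == b.dic

    def test_chains_positive_and_mixed(self, result):
        res, _ = result
        assert np.all(res.chains > 0.0)
        assert np.all(res.rhat < 1.1)
        assert np.all((res.acceptance_rate > 0.1) & (res.acceptance_rate < 0.6))

    def test_summaries_bracket_median(self, result):
        res, _ = result
        assert np.all(res.credible_lower <= res.posterior_median)
        assert np.all(res.posterior_median <= res.credible_upper)

    def test_thinning_bookkeeping(self):
        x = make_sample(TIHTWParams(1.4, 1.0, 0.9), 150, seed=59)
        res = mcmc_sample(x, n_chains=2, n_iter=1000, n_burnin=400, thin=10, seed=5)
        assert res.chains.shape[1] == int(np.ceil((1000 - 400) / 10))

    def test_dic_recomputation_matches(self, result):
        res, x = result
        d, p = dic(res, x)
        assert d == pytest.approx(res.dic)
        assert p == pytest.approx(res.p_d)

    def test_conjugate_cross_check(self):
        # Pin the Weibull shape at 1 with a near-degenerate prior; the rate
        # posterior is then conjugate: gamma | x ~ Gamma(a0 + n, b0 + sum x).
        rng = np.random.default_rng(61)
        x = rng.exponential(scale=1.0 / 1.3, size=400)
        a0, b0 = 2.0, 1.0
        priors = PriorSpec(shapes=(1e8, a0), rates=(1e8, b0))
        res = mcmc_sample(
            x, priors=priors, family="weibull", n_chains=2,
            n_iter=8000, n_burnin=2000, seed=11,
        )
        draws = res.chains.reshape(-1, 2)[:, 1]
        a_post, b_post = a0 + x.size, b0 + x.sum()
        exact_mean = a_post / b_post
        exact_sd = np.sqrt(a_post) / b_post
        mc_se = draws.std() / np.sqrt(200.0)  # generous ESS allowance
        assert abs(draws.mean() - exact_mean) < 3.0 * mc_se
        assert abs(draws.std() - exact_sd) < 0.2 * exact_sd


class TestDic:
    def test_degenerate_chain(self):
        x = np.array([0.5, 1.0, 2.0])
        t0 = np.array([1.0, 1.0, 1.0])
        ll0 = log_likelihood(t0, x)
        res = McmcResult(
            family="tihtw",
            param_names=("alpha", "gamma", "theta"),
            chains=np.tile(t0, (2, 50, 1)),
            chain_loglik=np.full((2, 50), ll0),
            n_chains=2,
            n_iter=100,
            n_burnin=50,
            thin=1,
            seed=0,
            posterior_median=t0,
            posterior_mean=t0,
            posterior_sd=np.zeros(3),
            credible_lower=t0,
            credible_upper=t0,
            rhat=np.ones(3),
            acceptance_rate=np.array([0.3, 0.3]),
            dic=0.0,
            p_d=0.0,
        )
        d, p = dic(res, x)
        assert p == pytest.approx(0.0, abs=1e-10)
        assert d == pytest.approx(-2.0 * ll0)

    def test_preference_labels(self):
        labels = dic_preference({"a": 100.0, "b": 107.0, "c": 120.0})
        assert labels["a"] == "comparable support"
        assert labels["b"] == "considerably less support"
        assert labels["c"] == "strongly disfavored"
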