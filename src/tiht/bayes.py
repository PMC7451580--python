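"""Bayesian fitting of TI-HT-Weibull (and nested Weibull) by MCMC.

Independent gamma priors on each (positive) parameter, default
Gamma(shape=0.01, rate=0.01) -- a diffuse choice that lets the data
dominate.  Posterior sampling is adaptive random-walk Metropolis on
log-parameters: a multivariate normal proposal whose covariance starts
from the inverse observed information at the MLE (scaled by 2.38^2/d) and
whose global scale is tuned by Robbins-Monro toward 35% acceptance during
burn-in only, so the post-burn-in kernel is a fixed, valid Metropolis
kernel.

Convergence is monitored by the Gelman-Rubin potential scale reduction
factor; model adequacy by the deviance information criterion
DIC = D_bar + p_D with p_D = D_bar - D(theta_bar).  The plug-in theta_bar
is the posterior mean taken on the sampler's working (log) scale and
mapped back: the DIC plug-in is parameterization-dependent, and on the
original scale the arithmetic mean of draws from this model's curved
(gamma, theta) posterior ridge falls off the ridge, corrupting p_D.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import special

from .distributions import get_family
from .estimation import _observed_information, fit_mle, log_likelihood
from .family_core import DomainError

__all__ = [
    "PriorSpec",
    "McmcResult",
    "log_posterior",
    "mcmc_sample",
    "gelman_rubin",
    "dic",
    "dic_preference",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gamma(a, b) priors (shape a, rate b) per parameter."""

    shapes: Tuple[float, ...]
    rates: Tuple[float, ...]

    def __post_init__(self):
        if len(self.shapes) != len(self.rates):
            raise ValueError("shapes and rates must have equal length")
        if any(a <= 0 for a in self.shapes) or any(b <= 0 for b in self.rates):
            raise ValueError("gamma prior hyperparameters must be positive")

    @classmethod
    def diffuse(cls, k: int, a: float = 0.01, b: float = 0.01) -> "PriorSpec":
        return cls(shapes=(a,) * k, rates=(b,) * k)

    def log_density(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= 0.0):
            return -np.inf
        a = np.asarray(self.shapes)
        b = np.asarray(self.rates)
        return float(
            np.sum(a * np.log(b) - special.gammaln(a) + (a - 1.0) * np.log(theta) - b * theta)
        )


def log_posterior(theta, data, priors: PriorSpec, family: str = "tihtw") -> float:
    """Unnormalized log posterior: log-likelihood plus gamma log-priors."""
    t = np.asarray(theta, dtype=float).ravel()
    lp = priors.log_density(t)
    if not np.isfinite(lp):
        return -np.inf
    return log_likelihood(t, data, family) + lp


@dataclass(frozen=True)
class McmcResult:
    family: str
    param_names: Tuple[str, ...]
    chains: np.ndarray  # (n_chains, n_kept, k), post burn-in, thinned
    chain_loglik: np.ndarray  # (n_chains, n_kept)
    n_chains: int
    n_iter: int
    n_burnin: int
    thin: int
    seed: int
    posterior_median: np.ndarray
    posterior_mean: np.ndarray
    posterior_sd: np.ndarray
    credible_lower: np.ndarray
    credible_upper: np.ndarray
    rhat: np.ndarray
    acceptance_rate: np.ndarray
    dic: float
    p_d: float
    warnings_: Tuple[str, ...] = ()

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "posterior_median": self.posterior_median,
                "posterior_sd": self.posterior_sd,
                "ci_lower": self.credible_lower,
                "ci_upper": self.credible_upper,
                "rhat": self.rhat,
            }
        )


def gelman_rubin(chains) -> np.ndarray:
    """Potential scale reduction factor per parameter.

    ``chains`` has shape (m, n, k) (chains, iterations, parameters).
    R = sqrt( (W (n-1)/n + B/n) / W ) with W the mean within-chain
    variance and B = n * var(chain means).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    m, n, k = arr.shape
    if m < 2 or n < 10:
        raise DomainError("need at least 2 chains of length >= 10")
    w = np.mean(np.var(arr, axis=1, ddof=1), axis=0)
    b = n * np.var(np.mean(arr, axis=1), axis=0, ddof=1)
    if np.any(w == 0.0):
        raise ArithmeticError("zero within-chain variance; R undefined")
    return np.sqrt((w * (n - 1.0) / n + b / n) / w)


def _proposal_covariance(
    t_hat: np.ndarray, x: np.ndarray, family: str, priors: "PriorSpec"
) -> np.ndarray:
    """Log-scale covariance from the observed posterior information.

    Likelihood curvature (finite differences of the analytic/numeric score)
    plus the analytic gamma-prior curvature (a-1)/theta^2 per parameter, so
    strongly informative priors tighten the proposal in their direction.
    """
    k = t_hat.size
    try:
        info = _observed_information(t_hat, x, family)
        info = info + np.diag(
            (np.asarray(priors.shapes) - 1.0) / t_hat**2
        )
        cov = np.linalg.inv(info)
        # delta method to the log scale: J = diag(1/theta)
        j = np.diag(1.0 / t_hat)
        cov_log = j @ cov @ j
        np.linalg.cholesky(cov_log)  # check PD
        return cov_log
    except np.linalg.LinAlgError:
        return np.eye(k) * 0.01


def mcmc_sample(
    data,
    priors: Optional[PriorSpec] = None,
    family: str = "tihtw",
    n_chains: int = 2,
    n_iter: int = 6000,
    n_burnin: int = 2000,
    thin: int = 1,
    seed: int = 0,
) -> McmcResult:
    """Adaptive random-walk Metropolis sampler for the posterior.

    Chains start at the MLE perturbed by overdispersed jitter on the log
    scale.  Retained draws are the post-burn-in iterations thinned by
    ``thin`` (``ceil((n_iter - n_burnin)/thin)`` per chain).  Summaries:
    posterior median/sd and equal-tailed 95% credible intervals, per-chain
    acceptance rates, Gelman-Rubin R per parameter, DIC and p_D.
    """
    if n_iter <= n_burnin:
        raise DomainError("n_iter must exceed n_burnin")
    if n_chains < 2:
        raise DomainError("need at least 2 chains for the Gelman-Rubin diagnostic")
    x = np.asarray(data, dtype=float).ravel()
    fam = get_family(family)
    k = fam.n_params
    if priors is None:
        priors = PriorSpec.diffuse(k)
    if len(priors.shapes) != k:
        raise ValueError(f"priors must cover {k} parameters for {fam.name}")

    fit = fit_mle(x, fam.name)
    t_hat = np.where(np.isfinite(fit.estimates), fit.estimates, 1.0)
    cov_log = _proposal_covariance(t_hat, x, fam.name, priors)
    chol = np.linalg.cholesky(cov_log * (2.38**2 / k))

    n_kept = math.ceil((n_iter - n_burnin) / thin)
    chains = np.empty((n_chains, n_kept, k))
    chain_ll = np.empty((n_chains, n_kept))
    acc_rates = np.empty(n_chains)
    target_acc = 0.35

    def logpost_and_ll(t: np.ndarray) -> Tuple[float, float]:
        lp = priors.log_density(t)
        if not np.isfinite(lp):
            return -np.inf, -np.inf
        ll = log_likelihood(t, x, fam.name)
        return ll + lp, ll

    for c in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(c,)))
        z = np.log(t_hat) + 0.5 * (rng.standard_normal(k) @ chol.T)
        lp, ll = logpost_and_ll(np.exp(z))
        if not np.isfinite(lp):
            z = np.log(t_hat)
            lp, ll = logpost_and_ll(np.exp(z))
        log_scale = 0.0
        n_acc = 0
        kept = 0
        for it in range(n_iter):
            step = np.exp(log_scale) * (chol @ rng.standard_normal(k))
            z_prop = z + step
            t_prop = np.exp(z_prop)
            lp_prop, ll_prop = logpost_and_ll(t_prop)
            # Jacobian of the log-parameter map: + sum(z) on each side
            log_ratio = (lp_prop + np.sum(z_prop)) - (lp + np.sum(z))
            if np.log(rng.random()) < log_ratio:
                z, lp, ll = z_prop, lp_prop, ll_prop
                accepted = 1
            else:
                accepted = 0
            if it < n_burnin:
                # Robbins-Monro scale adaptation, burn-in only
                log_scale += (accepted - target_acc) / (1.0 + 0.1 * it) ** 0.6
            else:
                n_acc += accepted
                if (it - n_burnin) % thin == 0:
                    chains[c, kept] = np.exp(z)
                    chain_ll[c, kept] = ll
                    kept += 1
        acc_rates[c] = n_acc / (n_iter - n_burnin)

    pooled = chains.reshape(-1, k)
    med = np.median(pooled, axis=0)
    mean = np.mean(pooled, axis=0)
    sd = np.std(pooled, axis=0, ddof=1)
    lo = np.quantile(pooled, 0.025, axis=0)
    hi = np.quantile(pooled, 0.975, axis=0)
    try:
        rhat = gelman_rubin(chains)
    except ArithmeticError:
        rhat = np.full(k, np.nan)

    d_bar = float(np.mean(-2.0 * chain_ll))
    plug_in = np.exp(np.mean(np.log(pooled), axis=0))
    d_at_mean = -2.0 * log_likelihood(plug_in, x, fam.name)
    p_d = d_bar - d_at_mean
    dic_value = d_bar + p_d

    notes = []
    if np.any((acc_rates < 0.05) | (acc_rates > 0.8)):
        notes.append(f"acceptance rate outside [0.05, 0.8]: {acc_rates}")
    if p_d < 0:
        notes.append("negative p_D: posterior may be multimodal or mean atypical")

    return McmcResult(
        family=fam.name,
        param_names=fam.param_names,
        chains=chains,
        chain_loglik=chain_ll,
        n_chains=n_chains,
        n_iter=n_iter,
        n_burnin=n_burnin,
        thin=thin,
        seed=int(seed),
        posterior_median=med,
        posterior_mean=mean,
        posterior_sd=sd,
        credible_lower=lo,
        credible_upper=hi,
        rhat=np.asarray(rhat),
        acceptance_rate=acc_rates,
        dic=float(dic_value),
        p_d=float(p_d),
        warnings_=tuple(notes),
    )


def dic(result: McmcResult, data, family: Optional[str] = None) -> Tuple[float, float]:
    """(DIC, p_D) recomputed from the retained draws.

    D_bar is the posterior mean deviance; p_D = D_bar - D(theta_bar) with
    theta_bar the log-scale posterior mean mapped back (see module note).
    A negative p_D is returned as-is with a warning (the standard DIC
    pathology under multimodality or an atypical plug-in).
    """
    fam = family or result.family
    x = np.asarray(data, dtype=float).ravel()
    d_bar = float(np.mean(-2.0 * result.chain_loglik))
    draws = result.chains.reshape(-1, len(result.param_names))
    theta_bar = np.exp(np.mean(np.log(draws), axis=0))
    p_d = d_bar - (-2.0 * log_likelihood(theta_bar, x, fam))
    if p_d < 0:
        warnings.warn("negative p_D (multimodality warning)", RuntimeWarning, stacklevel=2)
    return float(d_bar + p_d), float(p_d)


def dic_preference(dic_values: Dict[str, float]) -> Dict[str, str]:
    """Rule-of-thumb support labels relative to the minimum-DIC model.

    Differences > 10: essentially no support for the larger-DIC model;
    5-10: considerably less support; < 5: no meaningful preference.
    """
    if not dic_values:
        return {}
    d_min = min(dic_values.values())
    labels = {}
    for name, d in dic_values.items():
        delta = d - d_min
        if delta > 10:
            labels[name] = "strongly disfavored"
        elif delta >= 5:
            labels[name] = "considerably less support"
        else:
            labels[name] = "comparable support"
    return labels
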