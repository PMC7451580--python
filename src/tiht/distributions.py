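"""Concrete families: TI-HT-Weibull closed forms, named reductions, competitors.

The Weibull baseline uses the *rate* parameterization

    F(x) = 1 - exp(-gamma * x**alpha),

i.e. ``gamma`` multiplies ``x**alpha`` directly (not the ``(x/scale)**alpha``
scale form).  All fitted values reported by this package are in that rate
form; :func:`weibull_rate_to_scale` / :func:`weibull_scale_to_rate` convert.

The TI-HT-Weibull (TI-HTW) three-parameter law

    G(x; alpha, gamma, theta)
        = 1 - [ exp(-gamma x**alpha) / (1 - (1-theta)(1 - exp(-gamma x**alpha))) ]**theta

is provided both through the generic transform (:mod:`tiht.family_core`)
and as direct closed-form evaluators here; the two agree to a few ulp.

Competitor families used in model comparison -- exponentiated Weibull (EW),
Lomax and Burr XII -- are exposed through a registry keyed by lowercase
identifiers: ``tihtw``, ``tihte``, ``tihtr``, ``weibull``, ``ew``,
``lomax``, ``burr12``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Tuple

import numpy as np

from .family_core import (
    BaselineDistribution,
    DomainError,
    ParameterError,
    TIHTParams,
    tiht_cdf,
    tiht_log_pdf,
    tiht_pdf,
    tiht_quantile,
    tiht_sf,
)

__all__ = [
    "WeibullParams",
    "TIHTWParams",
    "weibull_baseline",
    "weibull_rate_to_scale",
    "weibull_scale_to_rate",
    "tihtw_cdf",
    "tihtw_pdf",
    "tihtw_log_pdf",
    "tihtw_sf",
    "tihtw_quantile",
    "reduce_special_case",
    "Family",
    "FAMILIES",
    "get_family",
    "competitor_logpdf",
    "competitor_cdf",
    "competitor_quantile",
]


def _require_positive(**kwargs):
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0.0:
            raise ParameterError(f"{name} must be a finite positive real, got {value!r}")


@dataclass(frozen=True)
class WeibullParams:
    """Rate-form Weibull: shape ``alpha > 0``, rate-type scale ``gamma > 0``."""

    alpha: float
    gamma: float

    def __post_init__(self):
        _require_positive(alpha=self.alpha, gamma=self.gamma)


@dataclass(frozen=True)
class TIHTWParams:
    """TI-HT-Weibull parameters (alpha, gamma, theta), all strictly positive."""

    alpha: float
    gamma: float
    theta: float

    def __post_init__(self):
        _require_positive(alpha=self.alpha, gamma=self.gamma, theta=self.theta)

    @property
    def weibull(self) -> WeibullParams:
        return WeibullParams(self.alpha, self.gamma)

    @property
    def tiht(self) -> TIHTParams:
        return TIHTParams(theta=self.theta, xi=(self.alpha, self.gamma))


def weibull_rate_to_scale(p: WeibullParams) -> Tuple[float, float]:
    """Return (shape, scale) with ``F = 1 - exp(-(x/scale)**shape)``."""
    return p.alpha, p.gamma ** (-1.0 / p.alpha)


def weibull_scale_to_rate(shape: float, scale: float) -> WeibullParams:
    """Convert the scale parameterization to the rate form used here."""
    _require_positive(shape=shape, scale=scale)
    return WeibullParams(alpha=shape, gamma=scale ** (-shape))


def weibull_baseline(p: WeibullParams) -> BaselineDistribution:
    """Weibull baseline with exact survival/log-survival callables."""
    a, g = p.alpha, p.gamma

    def cdf(x):
        x = np.asarray(x, dtype=float)
        return -np.expm1(-g * np.power(np.maximum(x, 0.0), a))

    def sf(x):
        x = np.asarray(x, dtype=float)
        return np.exp(-g * np.power(np.maximum(x, 0.0), a))

    def log_sf(x):
        x = np.asarray(x, dtype=float)
        return -g * np.power(np.maximum(x, 0.0), a)

    def log_pdf(x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.log(a * g) + (a - 1.0) * np.log(x) - g * np.power(x, a)
        return np.where(x > 0.0, lp, -np.inf)

    def pdf(x):
        return np.exp(log_pdf(x))

    def quantile(u):
        u = np.asarray(u, dtype=float)
        with np.errstate(divide="ignore"):
            return np.power(-np.log1p(-u) / g, 1.0 / a)

    def isf(s):
        s = np.asarray(s, dtype=float)
        with np.errstate(divide="ignore"):
            return np.power(-np.log(s) / g, 1.0 / a)

    return BaselineDistribution(
        name="weibull",
        xi=(a, g),
        cdf=cdf,
        pdf=pdf,
        log_pdf=log_pdf,
        quantile=quantile,
        sf=sf,
        log_sf=log_sf,
        isf=isf,
        support_lower=0.0,
    )


# ---------------------------------------------------------------------------
# TI-HTW closed forms
# ---------------------------------------------------------------------------

def tihtw_cdf(x, p: TIHTWParams):
    return tiht_cdf(x, p.tiht, weibull_baseline(p.weibull))


def tihtw_sf(x, p: TIHTWParams):
    return tiht_sf(x, p.tiht, weibull_baseline(p.weibull))


def tihtw_log_pdf(x, p: TIHTWParams):
    """Direct closed form of the TI-HTW log-density.

    log g = log(alpha theta^2 gamma) + (alpha-1) log x - theta gamma x^alpha
            - (theta+1) log(theta + (1-theta) exp(-gamma x^alpha)).
    """
    a, g, th = p.alpha, p.gamma, p.theta
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        xa = np.power(np.where(arr > 0, arr, 1.0), a)
        s = np.exp(-g * xa)
        lp = (
            np.log(a * th * th * g)
            + (a - 1.0) * np.log(np.where(arr > 0, arr, 1.0))
            - th * g * xa
            - (th + 1.0) * np.log(th + (1.0 - th) * s)
        )
    out = np.where(arr > 0.0, lp, -np.inf)
    return float(out[()]) if scalar else out


def tihtw_pdf(x, p: TIHTWParams):
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    out = np.exp(tihtw_log_pdf(arr, p))
    return float(np.asarray(out)[()]) if scalar else np.asarray(out)


def tihtw_quantile(u, p: TIHTWParams):
    return tiht_quantile(u, p.tiht, weibull_baseline(p.weibull))


def reduce_special_case(p: TIHTWParams) -> Tuple[str, Tuple[float, ...]]:
    """Identify which named sub-model a TI-HTW parameter point reduces to.

    Returns ``(label, params)``:

    - theta=1              -> ("weibull", (alpha, gamma))
    - theta=gamma=1        -> ("weibull_one_param", (alpha,))
    - theta=alpha=1        -> ("exponential", (gamma,))
    - theta=1, alpha=2     -> ("rayleigh", (gamma,))
    - alpha=1              -> ("tihte", (theta, gamma))
    - alpha=2              -> ("tihtr", (theta, gamma))
    - otherwise            -> ("tihtw", (alpha, gamma, theta))
    """
    a, g, th = p.alpha, p.gamma, p.theta
    if th == 1.0:
        if a == 1.0:
            return "exponential", (g,)
        if a == 2.0:
            return "rayleigh", (g,)
        if g == 1.0:
            return "weibull_one_param", (a,)
        return "weibull", (a, g)
    if a == 1.0:
        return "tihte", (th, g)
    if a == 2.0:
        return "tihtr", (th, g)
    return "tihtw", (a, g, th)


# ---------------------------------------------------------------------------
# Family registry (used by estimation, gof, mc_study, cli)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Family:
    """A parametric lifetime family exposed to the fitting machinery.

    All callables take ``(x_or_u, params_vector)`` with parameters in the
    order of ``param_names`` (all strictly positive; optimizers work on
    logs).
    """

    name: str
    param_names: Tuple[str, ...]
    log_pdf: Callable
    cdf: Callable
    quantile: Callable

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _tihtw_vec(params):
    return TIHTWParams(alpha=params[0], gamma=params[1], theta=params[2])


def _family_tihtw() -> Family:
    return Family(
        name="tihtw",
        param_names=("alpha", "gamma", "theta"),
        log_pdf=lambda x, t: tihtw_log_pdf(x, _tihtw_vec(t)),
        cdf=lambda x, t: tihtw_cdf(x, _tihtw_vec(t)),
        quantile=lambda u, t: tihtw_quantile(u, _tihtw_vec(t)),
    )


def _family_tiht_fixed_alpha(name: str, alpha: float) -> Family:
    def vec(t):
        return TIHTWParams(alpha=alpha, gamma=t[1], theta=t[0])

    return Family(
        name=name,
        param_names=("theta", "gamma"),
        log_pdf=lambda x, t: tihtw_log_pdf(x, vec(t)),
        cdf=lambda x, t: tihtw_cdf(x, vec(t)),
        quantile=lambda u, t: tihtw_quantile(u, vec(t)),
    )


def _family_weibull() -> Family:
    def log_pdf(x, t):
        return weibull_baseline(WeibullParams(*t)).log_pdf(x)

    def cdf(x, t):
        return weibull_baseline(WeibullParams(*t)).cdf(x)

    def quantile(u, t):
        return weibull_baseline(WeibullParams(*t)).quantile(np.asarray(u, dtype=float))

    return Family("weibull", ("alpha", "gamma"), log_pdf, cdf, quantile)


def _family_ew() -> Family:
    # Exponentiated Weibull: cdf = (1 - exp(-gamma x^alpha))^theta_e
    def log_pdf(x, t):
        a, te, g = t
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            xa = np.power(np.where(x > 0, x, 1.0), a)
            log_w = np.log(a * g * te) + (a - 1.0) * np.log(np.where(x > 0, x, 1.0)) - g * xa
            lp = log_w + (te - 1.0) * np.log(-np.expm1(-g * xa))
        return np.where(x > 0.0, lp, -np.inf)

    def cdf(x, t):
        a, te, g = t
        x = np.asarray(x, dtype=float)
        return np.power(-np.expm1(-g * np.power(np.maximum(x, 0.0), a)), te)

    def quantile(u, t):
        a, te, g = t
        u = np.asarray(u, dtype=float)
        return np.power(-np.log1p(-np.power(u, 1.0 / te)) / g, 1.0 / a)

    return Family("ew", ("alpha", "theta_e", "gamma"), log_pdf, cdf, quantile)


def _family_lomax() -> Family:
    # Lomax: cdf = 1 - (1 + x/lam)^(-a)
    def log_pdf(x, t):
        a, lam = t
        x = np.asarray(x, dtype=float)
        lp = np.log(a / lam) - (a + 1.0) * np.log1p(np.maximum(x, 0.0) / lam)
        return np.where(x >= 0.0, lp, -np.inf)

    def cdf(x, t):
        a, lam = t
        x = np.asarray(x, dtype=float)
        return -np.expm1(-a * np.log1p(np.maximum(x, 0.0) / lam))

    def quantile(u, t):
        a, lam = t
        u = np.asarray(u, dtype=float)
        return lam * np.expm1(-np.log1p(-u) / a)

    return Family("lomax", ("alpha", "lam"), log_pdf, cdf, quantile)


def _family_burr12() -> Family:
    # Burr XII (two-parameter): cdf = 1 - (1 + x^c)^(-k)
    def log_pdf(x, t):
        c, k = t
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = (
                np.log(c * k)
                + (c - 1.0) * np.log(np.where(x > 0, x, 1.0))
                - (k + 1.0) * np.log1p(np.power(np.where(x > 0, x, 1.0), c))
            )
        return np.where(x > 0.0, lp, -np.inf)

    def cdf(x, t):
        c, k = t
        x = np.asarray(x, dtype=float)
        return -np.expm1(-k * np.log1p(np.power(np.maximum(x, 0.0), c)))

    def quantile(u, t):
        c, k = t
        u = np.asarray(u, dtype=float)
        return np.power(np.expm1(-np.log1p(-u) / k), 1.0 / c)

    return Family("burr12", ("c", "k"), log_pdf, cdf, quantile)


FAMILIES: Dict[str, Family] = {
    "tihtw": _family_tihtw(),
    "tihte": _family_tiht_fixed_alpha("tihte", 1.0),
    "tihtr": _family_tiht_fixed_alpha("tihtr", 2.0),
    "weibull": _family_weibull(),
    "ew": _family_ew(),
    "lomax": _family_lomax(),
    "burr12": _family_burr12(),
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; available: {sorted(FAMILIES)}"
        ) from None


def _validate_competitor(family: str, params) -> Tuple[Family, np.ndarray]:
    fam = get_family(family)
    t = np.asarray(params, dtype=float)
    if t.shape != (fam.n_params,):
        raise ParameterError(
            f"{fam.name} expects {fam.n_params} parameters {fam.param_names}, got {t.shape}"
        )
    if not np.all(np.isfinite(t)) or np.any(t <= 0.0):
        raise ParameterError(f"{fam.name} parameters must be finite and positive: {t}")
    return fam, t


def competitor_logpdf(x, family: str, params):
    """Log-density of a registered family at parameter vector ``params``."""
    fam, t = _validate_competitor(family, params)
    return fam.log_pdf(np.asarray(x, dtype=float), t)


def competitor_cdf(x, family: str, params):
    fam, t = _validate_competitor(family, params)
    return fam.cdf(np.asarray(x, dtype=float), t)


def competitor_quantile(u, family: str, params):
    fam, t = _validate_competitor(family, params)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u >= 1.0):
        raise DomainError("quantile levels must lie in [0, 1)")
    return fam.quantile(u, t)
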