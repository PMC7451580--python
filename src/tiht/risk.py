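"""Actuarial tail measures for the TI-HT-Weibull model: VaR and TVaR.

VaR_q is the q-quantile of the loss law, in closed form

    VaR_q = ( -(1/gamma) log(1 - ((1-q)^{1/theta} - 1)
                               / ((1-theta)(1-q)^{1/theta} - 1)) )^{1/alpha}.

TVaR_q = E[X | X > VaR_q] is canonically computed by adaptive quadrature
after the substitution u = G(x), which turns the semi-infinite tail
integral into ``integral_q^1 Q(u) du / (1 - q)`` and so avoids truncating
an infinite domain.

A series form with upper-incomplete-gamma terms is provided as a
cross-check on theta in (0, 2): expanding the transform denominator in
powers of ``(1-theta) F`` and the resulting ``F^i`` binomially gives

    TVaR_q = theta^2/(1-q) gamma^{-1/alpha}
             sum_i binom(i+theta, theta) (1-theta)^i
             sum_{k=0}^{i} binom(i, k) (-1)^k (theta+k)^{-1-1/alpha}
             Gamma(1 + 1/alpha, gamma (theta+k) VaR_q^alpha),

where Gamma(.,.) is the upper incomplete gamma function.  The
``(1-F)^{theta-1}`` kernel (the generalized binomial j-series) is kept in
exact exponential form ``exp(-(theta-1) gamma x^alpha)`` before
integrating, which keeps the series convergent for non-integer theta.
"""

from __future__ import annotations

import warnings
from typing import Literal, NamedTuple

import numpy as np
from scipy import integrate, special

from .distributions import TIHTWParams, tihtw_quantile
from .family_core import DomainError
from .moments import _SERIES_IMAX, _SERIES_LOOKBACK, _SERIES_RTOL

__all__ = ["var_q", "tvar_q", "RiskMeasure", "risk_measures"]


class RiskMeasure(NamedTuple):
    q: float
    var_q: float
    tvar_q: float
    method: str


def var_q(p: TIHTWParams, q) -> float:
    """Closed-form value at risk (the q-quantile).

    Direct evaluation of the quantile display; agrees with the generic
    inversion :func:`tiht.distributions.tihtw_quantile` to ~1e-10.
    """
    arr = np.asarray(q, dtype=float)
    scalar = arr.ndim == 0
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DomainError(
            "VaR level must lie strictly in (0, 1); the limits are 0 and infinity"
        )
    a, g, th = p.alpha, p.gamma, p.theta
    s = np.power(1.0 - arr, 1.0 / th)
    if abs(th - 1.0) < 1e-12:
        inner = arr
    else:
        inner = (s - 1.0) / ((1.0 - th) * s - 1.0)
    out = np.power(-np.log1p(-inner) / g, 1.0 / a)
    return float(out[()]) if scalar else out


def _tvar_quadrature(p: TIHTWParams, q: float) -> float:
    value, err = integrate.quad(
        lambda u: float(tihtw_quantile(u, p)),
        q,
        1.0,
        epsabs=1e-10,
        epsrel=1e-10,
        limit=400,
    )
    if not np.isfinite(value):
        raise ArithmeticError("tail quadrature diverged; TVaR undefined")
    return value / (1.0 - q)


def _tvar_series(p: TIHTWParams, q: float, i_max: int = _SERIES_IMAX) -> float:
    a, g, th = p.alpha, p.gamma, p.theta
    if not (0.0 < th < 2.0):
        raise DomainError(
            f"series TVaR requires theta in (0, 2); got {th}. Use method='quadrature'."
        )
    v = var_q(p, q) if q > 0.0 else 0.0
    va = g * v**a
    inv_a = 1.0 / a
    gam_full = special.gamma(1.0 + inv_a)

    def tail_term(c: float) -> float:
        # (theta+k)^(-1-1/alpha) Gamma(1+1/alpha, gamma(theta+k) VaR^alpha)
        return c ** (-1.0 - inv_a) * gam_full * float(special.gammaincc(1.0 + inv_a, c * va))

    total = 0.0
    recent = []
    i = 0
    while i <= i_max:
        log_bin = (
            special.gammaln(i + th + 1.0)
            - special.gammaln(th + 1.0)
            - special.gammaln(i + 1.0)
        )
        w = np.exp(log_bin) * (1.0 - th) ** i
        inner = 0.0
        for k in range(i + 1):
            inner += (-1.0) ** k * special.binom(i, k) * tail_term(th + k)
        term = w * inner
        total += term
        recent.append(abs(term))
        if len(recent) > _SERIES_LOOKBACK:
            recent.pop(0)
        if i >= _SERIES_LOOKBACK and sum(recent) < _SERIES_RTOL * max(abs(total), 1e-300):
            break
        i += 1
    return th * th / (1.0 - q) * g ** (-inv_a) * total


def tvar_q(
    p: TIHTWParams,
    q: float,
    method: Literal["quadrature", "series"] = "quadrature",
) -> float:
    """Tail value at risk E[X | X > VaR_q].

    ``method='quadrature'`` (canonical) integrates the quantile over
    (q, 1); ``method='series'`` evaluates the incomplete-gamma series
    (theta in (0, 2) only), agreeing to ~1e-4 relative.
    At q = 0 the TVaR is the distribution mean.
    """
    q = float(q)
    if not (0.0 <= q < 1.0):
        raise DomainError(f"TVaR level must lie in [0, 1), got {q}")
    if method == "quadrature":
        return _tvar_quadrature(p, q)
    if method == "series":
        return _tvar_series(p, q)
    raise ValueError(f"unknown method {method!r}")


def risk_measures(p: TIHTWParams, q, method: str = "quadrature"):
    """Convenience: list of :class:`RiskMeasure` rows over a level grid."""
    levels = np.atleast_1d(np.asarray(q, dtype=float))
    return [
        RiskMeasure(q=float(ql), var_q=var_q(p, ql), tvar_q=tvar_q(p, ql, method), method=method)
        for ql in levels
    ]
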