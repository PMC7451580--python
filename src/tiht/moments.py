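"""Moments, descriptive measures and mgf of TI-HT distributions.

Adaptive quadrature is the canonical method throughout: the r-th raw
moment is the integral of ``Q(u)**r`` over the unit interval after the
exact substitution ``u = G(x)`` (equivalently, quadrature of ``x**r g(x)``
over the support, but free of infinite-domain truncation).

A series expansion of the TI-HT-Weibull moment is provided as an
independent cross-check.  It expands the transform denominator as

    [1 - (1-theta) F]^{-(theta+1)} = sum_i binom(i+theta, theta) (1-theta)^i F^i,

valid for ``|1-theta| < 1`` i.e. ``theta in (0, 2)``, giving

    mu'_r = theta^2 sum_i binom(i+theta, theta) (1-theta)^i lambda_{r,i},
    lambda_{r,i} = integral_0^1 Q_W(u)^r u^i (1-u)^{theta-1} du,

where ``Q_W`` is the baseline Weibull quantile.  The ``(1-u)^{theta-1}``
kernel is the exact sum of the generalized binomial series
``sum_j binom(theta-1, j) (-u)^j`` (a finite sum when theta is a positive
integer); resumming it under the integral keeps the cross-check convergent
over the whole theta in (0, 2) domain, where the raw alternating j-tail
decays only like ``j**-theta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import integrate, special

from .distributions import TIHTWParams, weibull_baseline
from .family_core import BaselineDistribution, DomainError, TIHTParams, tiht_quantile

__all__ = [
    "raw_moment_numeric",
    "raw_moment_series",
    "SeriesMoment",
    "descriptive_measures",
    "DescriptiveMeasures",
    "mgf",
]

# truncation rule for the i-series: stop once the last _SERIES_LOOKBACK terms
# together contribute < _SERIES_RTOL relative, hard cap _SERIES_IMAX
_SERIES_RTOL = 1e-12
_SERIES_LOOKBACK = 10
_SERIES_IMAX = 500


def raw_moment_numeric(
    r: int,
    params: TIHTParams,
    base: BaselineDistribution,
    tol: float = 1e-10,
) -> float:
    """r-th raw moment by adaptive quadrature (the canonical method).

    Integrates ``Q(u)**r`` over (0, 1) with ``Q`` the TI-HT quantile; this
    is exactly ``integral x**r g(x) dx`` after ``u = G(x)``.

    Raises
    ------
    DomainError
        If ``r`` is negative.
    ArithmeticError
        If the quadrature does not converge (non-integrable tail).
    """
    if not isinstance(r, (int, np.integer)) or r < 0:
        raise DomainError(f"moment order must be a nonnegative integer, got {r!r}")
    if r == 0:
        return 1.0

    def integrand(u):
        return float(tiht_quantile(u, params, base)) ** r

    with warnings.catch_warnings():
        warnings.simplefilter("error", integrate.IntegrationWarning)
        try:
            value, err = integrate.quad(integrand, 0.0, 1.0, epsabs=tol, epsrel=tol, limit=400)
        except integrate.IntegrationWarning as exc:
            raise ArithmeticError(
                f"moment quadrature did not converge for r={r}: {exc}"
            ) from exc
    if not np.isfinite(value) or err > max(1e-6, 1e-6 * abs(value)):
        raise ArithmeticError(
            f"moment quadrature unreliable for r={r}: value={value}, err={err}"
        )
    return float(value)


class SeriesMoment(NamedTuple):
    """Partial sum of the series moment with a truncation-error estimate."""

    value: float
    error: float
    terms: int


def _log_binom_theta(i: np.ndarray, theta: float) -> np.ndarray:
    """log binom(i + theta, theta) for integer i >= 0 and real theta > 0."""
    return (
        special.gammaln(i + theta + 1.0)
        - special.gammaln(theta + 1.0)
        - special.gammaln(i + 1.0)
    )


def raw_moment_series(
    r: int,
    params: TIHTWParams,
    i_max: int = _SERIES_IMAX,
) -> SeriesMoment:
    """Series cross-check of the TI-HT-Weibull r-th raw moment.

    Valid on the expansion domain ``theta in (0, 2)``; outside it the
    geometric expansion of the transform denominator diverges and callers
    are directed to :func:`raw_moment_numeric`.
    """
    if not isinstance(r, (int, np.integer)) or r < 0:
        raise DomainError(f"moment order must be a nonnegative integer, got {r!r}")
    theta = params.theta
    if not (0.0 < theta < 2.0):
        raise DomainError(
            f"series expansion requires theta in (0, 2); got theta={theta}. "
            "Use raw_moment_numeric instead."
        )
    qw = weibull_baseline(params.weibull).quantile

    # QAWS evaluates the integrand at u = 1 exactly, where the Weibull
    # quantile is infinite; clamping one ulp inside changes the integral
    # far below the series tolerance.
    u_hi = 1.0 - 1e-16

    def lam(i: int) -> float:
        # integral_0^1 Q_W(u)^r u^i (1-u)^(theta-1) du ; the algebraic
        # endpoint weight is handed to QUADPACK exactly.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            value, _ = integrate.quad(
                lambda u: float(qw(min(u, u_hi))) ** r * u**i,
                0.0,
                1.0,
                weight="alg",
                wvar=(0.0, theta - 1.0),
                epsabs=1e-12,
                epsrel=1e-12,
                limit=200,
            )
        return value

    total = 0.0
    recent = []
    i = 0
    while i <= i_max:
        log_c = _log_binom_theta(np.asarray(float(i)), theta) + (
            i * np.log(abs(1.0 - theta)) if theta != 1.0 and i > 0 else 0.0
        )
        sign = 1.0 if theta <= 1.0 or i % 2 == 0 else -1.0
        if theta == 1.0 and i > 0:
            term = 0.0
        else:
            term = sign * np.exp(float(log_c)) * lam(i)
        total += term
        recent.append(abs(term))
        if len(recent) > _SERIES_LOOKBACK:
            recent.pop(0)
        if (
            i >= _SERIES_LOOKBACK
            and sum(recent) < _SERIES_RTOL * max(abs(total), 1e-300)
        ):
            break
        i += 1
    value = theta * theta * total
    err = theta * theta * sum(recent)
    return SeriesMoment(value=float(value), error=float(err), terms=i + 1)


@dataclass(frozen=True)
class DescriptiveMeasures:
    mean: float
    variance: float
    skewness: float
    kurtosis: float


def descriptive_measures(
    params: TIHTParams, base: BaselineDistribution
) -> DescriptiveMeasures:
    """Mean, variance, moment skewness and kurtosis from raw moments 1-4.

    Skewness is ``mu3 / mu2**1.5`` and kurtosis ``mu4 / mu2**2`` on central
    moments.  A non-convergent fourth moment yields NaN fields rather than
    an exception (the measures are then undefined).
    """
    try:
        m = [raw_moment_numeric(r, params, base) for r in (1, 2, 3, 4)]
    except ArithmeticError:
        nan = float("nan")
        return DescriptiveMeasures(nan, nan, nan, nan)
    mean = m[0]
    var = m[1] - mean**2
    mu3 = m[2] - 3.0 * mean * m[1] + 2.0 * mean**3
    mu4 = m[3] - 4.0 * mean * m[2] + 6.0 * mean**2 * m[1] - 3.0 * mean**4
    return DescriptiveMeasures(
        mean=mean,
        variance=var,
        skewness=mu3 / var**1.5,
        kurtosis=mu4 / var**2,
    )


def mgf(
    t: float,
    params: TIHTParams,
    base: BaselineDistribution,
    r_max: int = 0,
) -> float:
    """Moment generating function E[exp(tX)] by quadrature of exp(t Q(u)).

    For a Weibull baseline with shape ``alpha < 1`` the right tail decays
    slower than every exponential (the family's heavy-tail criterion), so
    the mgf diverges for any ``t > 0``: NaN is returned as the
    undefined-result signal.  ``r_max > 0`` instead evaluates the truncated
    moment series ``sum_r t^r mu'_r / r!`` (an estimate, not canonical).
    """
    t = float(t)
    if t == 0.0:
        return 1.0
    if t > 0.0 and base.name == "weibull":
        alpha, gamma = base.xi
        # sf ~ theta^-theta exp(-theta gamma x^alpha): finite only if the
        # exponential tilt is beaten by the Weibull tail.
        if alpha < 1.0 or (alpha == 1.0 and t >= params.theta * gamma):
            warnings.warn(
                "mgf diverges for this tail/t combination; returning NaN",
                RuntimeWarning,
                stacklevel=2,
            )
            return float("nan")
    if r_max > 0:
        return float(
            sum(
                t**r / special.factorial(r) * raw_moment_numeric(r, params, base)
                for r in range(r_max + 1)
            )
        )

    def integrand(u):
        return np.exp(t * float(tiht_quantile(u, params, base)))

    with warnings.catch_warnings():
        warnings.simplefilter("error", integrate.IntegrationWarning)
        try:
            value, _ = integrate.quad(
                integrand, 0.0, 1.0, epsabs=1e-10, epsrel=1e-10, limit=400
            )
        except integrate.IntegrationWarning:
            warnings.warn(
                "mgf quadrature did not converge; returning NaN",
                RuntimeWarning,
                stacklevel=2,
            )
            return float("nan")
    return float(value)
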