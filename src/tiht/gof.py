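"""Goodness-of-fit and model-discrimination statistics.

Information criteria: ``AIC = -2 l_hat + 2k``, ``BIC = -2 l_hat + k log n``.

EDF statistics on the probability-integral transform u_i = cdf(x_(i)):

    CM = 1/(12n) + sum_i (u_i - (2i-1)/(2n))^2
    AD = -n - (1/n) sum_i (2i-1) [log u_i + log(1 - u_{n+1-i})]
    KS = max( max_i (i/n - u_i), max_i (u_i - (i-1)/n) )

with the KS p-value from the asymptotic Kolmogorov distribution.

.. warning::
   The KS p-value is NOT adjusted for estimated parameters (no
   Lilliefors-type correction); with fitted models it is liberal.  This
   matches the convention of the comparison tables this module mirrors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .distributions import get_family
from .estimation import FitResult, fit_mle
from .family_core import DomainError

__all__ = ["GofRow", "discrimination_measures", "edf_statistics", "compare_models"]


class EdfStatistics(NamedTuple):
    cm: float
    ad: float
    ks: float
    ks_pvalue: float


@dataclass(frozen=True)
class GofRow:
    family: str
    k_params: int
    aic: float
    bic: float
    cm: float
    ad: float
    ks: float
    ks_pvalue: float
    converged: bool
    fit: Optional[FitResult] = None


def discrimination_measures(fit: FitResult):
    """(AIC, BIC) of a converged fit."""
    k, n = fit.k_params, fit.n_obs
    aic = -2.0 * fit.loglik_max + 2.0 * k
    bic = -2.0 * fit.loglik_max + k * np.log(n)
    return float(aic), float(bic)


def edf_statistics(data, fitted_cdf) -> EdfStatistics:
    """Cramer-von Mises, Anderson-Darling and Kolmogorov-Smirnov statistics.

    ``fitted_cdf`` is a callable evaluating the fitted cdf elementwise.
    Transformed values that land exactly on 0 or 1 are nudged to the
    nearest representable interior value (with a warning) so the AD log
    terms stay finite.
    """
    x = np.sort(np.asarray(data, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise DomainError("need at least 2 observations for EDF statistics")
    u = np.asarray(fitted_cdf(x), dtype=float)
    if np.any(np.diff(u) < -1e-12):
        raise DomainError("fitted cdf must be nondecreasing over the data range")
    tiny = np.finfo(float).tiny
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn(
            "probability-integral transforms hit 0 or 1; perturbing to the "
            "nearest interior value",
            RuntimeWarning,
            stacklevel=2,
        )
        u = np.clip(u, tiny, 1.0 - np.finfo(float).epsneg)
    i = np.arange(1, n + 1, dtype=float)
    cm = 1.0 / (12.0 * n) + float(np.sum((u - (2.0 * i - 1.0) / (2.0 * n)) ** 2))
    ad = -n - float(np.mean((2.0 * i - 1.0) * (np.log(u) + np.log1p(-u[::-1]))))
    ks = float(max(np.max(i / n - u), np.max(u - (i - 1.0) / n)))
    ks_p = float(special.kolmogorov(np.sqrt(n) * ks))
    return EdfStatistics(cm=cm, ad=ad, ks=ks, ks_pvalue=ks_p)


def compare_models(
    data,
    families: Sequence[str],
    inits: Optional[dict] = None,
) -> List[GofRow]:
    """Fit each family by ML and rank by AIC (ties: BIC, then name).

    Families that fail to fit are kept as rows with NaN measures and
    ``converged=False`` (sorted last), never dropped silently; non-finite
    EDF statistics propagate as NaN.
    """
    if len(families) < 2:
        raise DomainError("need at least two families to compare")
    x = np.asarray(data, dtype=float).ravel()
    rows: List[GofRow] = []
    for name in families:
        fam = get_family(name)
        init = (inits or {}).get(fam.name)
        try:
            fit = fit_mle(x, fam.name, init=init)
        except Exception:
            rows.append(
                GofRow(fam.name, fam.n_params, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False)
            )
            continue
        aic, bic = discrimination_measures(fit)
        try:
            st = edf_statistics(x, lambda xv: fam.cdf(xv, fit.estimates))
            cm, ad, ks, ksp = st
        except (DomainError, FloatingPointError):
            cm = ad = ks = ksp = np.nan
        rows.append(
            GofRow(fam.name, fam.n_params, aic, bic, cm, ad, ks, ksp, fit.converged, fit)
        )

    def key(row: GofRow):
        aic = row.aic if np.isfinite(row.aic) else np.inf
        bic = row.bic if np.isfinite(row.bic) else np.inf
        return (aic, bic, row.family)

    return sorted(rows, key=key)


def comparison_table(rows: Sequence[GofRow]) -> pd.DataFrame:
    """Ranked comparison as a DataFrame (Dist, AIC, BIC, CM, AD, KS, p-value)."""
    return pd.DataFrame(
        [
            {
                "Dist": r.family,
                "AIC": r.aic,
                "BIC": r.bic,
                "CM": r.cm,
                "AD": r.ad,
                "KS": r.ks,
                "p-value": r.ks_pvalue,
            }
            for r in rows
        ]
    )
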