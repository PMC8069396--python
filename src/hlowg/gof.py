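"""Goodness-of-fit battery: information criteria, EDF statistics, TTT transform.

The Kolmogorov-Smirnov p-value uses the asymptotic Kolmogorov distribution
with the fitted parameters treated as known; when parameters are estimated
from the same data this p-value is optimistic, which the report notes but
does not correct (the comparison tables this module mirrors do the same).
The Anderson-Darling and Cramer-von Mises statistics are the plain A^2 and
W^2 forms without small-sample modification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np
from scipy.special import kolmogorov

from .family import HlowParams, cdf

__all__ = [
    "GofReport",
    "information_criteria",
    "ks_test",
    "ad_cvm",
    "ttt_transform",
    "gof_report",
]


@dataclass
class GofReport:
    """Model-comparison report (column order of the usual comparison tables)."""

    neg_logL: float
    AkIC: float
    CAkIC: float
    BsIC: float
    HQIC: float
    AD: Optional[float] = None
    CvM: Optional[float] = None
    KS: Optional[float] = None
    ks_pvalue: Optional[float] = None
    df: int = 0
    n: int = 0
    note: str = (
        "KS p-value from the asymptotic Kolmogorov distribution with "
        "parameters treated as known (optimistic under estimation)"
    )

    def to_dict(self) -> dict:
        return asdict(self)


def information_criteria(neg_logL: float, df: int, n: int) -> GofReport:
    """AkIC / CAkIC / BsIC / HQIC from a maximized log-likelihood.

    AkIC = 2 nll + 2 df;  CAkIC = AkIC + 2 df (df+1)/(n-df-1);
    BsIC = 2 nll + df log n;  HQIC = 2 nll + 2 df log(log n).
    """
    df, n = int(df), int(n)
    if n <= df + 1:
        raise ValueError("corrected AIC undefined: need n > df + 1")
    akic = 2.0 * neg_logL + 2.0 * df
    return GofReport(
        neg_logL=float(neg_logL),
        AkIC=akic,
        CAkIC=akic + 2.0 * df * (df + 1.0) / (n - df - 1.0),
        BsIC=2.0 * neg_logL + df * np.log(n),
        HQIC=2.0 * neg_logL + 2.0 * df * np.log(np.log(n)),
        df=df,
        n=n,
    )


def _fitted_probs(p: HlowParams, x) -> np.ndarray:
    x = np.sort(np.asarray(x, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("sample is empty")
    return cdf(p, x)


def ks_test(p: HlowParams, x) -> Tuple[float, float]:
    """Kolmogorov-Smirnov distance of the sample to the fitted CDF, with the
    asymptotic p-value at sqrt(n) * D."""
    z = _fitted_probs(p, x)
    n = z.size
    j = np.arange(1, n + 1, dtype=float)
    d = max(np.max(j / n - z), np.max(z - (j - 1.0) / n))
    return float(d), float(kolmogorov(np.sqrt(n) * d))


def ad_cvm(p: HlowParams, x) -> Tuple[float, float]:
    """Anderson-Darling A^2 and Cramer-von Mises W^2 statistics."""
    z = _fitted_probs(p, x)
    n = z.size
    if np.any((z <= 0.0) | (z >= 1.0)):
        warnings.warn("fitted probabilities at 0 or 1 clipped to [1e-12, 1-1e-12]")
        z = np.clip(z, 1e-12, 1.0 - 1e-12)
    j = np.arange(1, n + 1, dtype=float)
    ad = -n - np.sum((2.0 * j - 1.0) * (np.log(z) + np.log1p(-z[::-1]))) / n
    cvm = 1.0 / (12.0 * n) + np.sum((z - (2.0 * j - 1.0) / (2.0 * n)) ** 2)
    return float(ad), float(cvm)


def ttt_transform(x) -> np.ndarray:
    """Scaled total-time-on-test transform.

    Returns an (n, 2) array of points (i/n, T_i) with
    T_i = [sum_{j<=i} x_(j) + (n-i) x_(i)] / sum_j x_j; a concave curve above
    the diagonal diagnoses an increasing failure rate.
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if np.any(x < 0) or x.sum() == 0:
        raise ValueError("observations must be nonnegative with positive total")
    csum = np.cumsum(x)
    i = np.arange(1, n + 1)
    T = (csum + (n - i) * x) / csum[-1]
    return np.column_stack([i / n, T])


def gof_report(p: HlowParams, x, neg_logL: float, df: int) -> GofReport:
    """Full battery for a fitted sub-model on a sample."""
    x = np.asarray(x, dtype=float).ravel()
    rep = information_criteria(neg_logL, df, x.size)
    rep.AD, rep.CvM = ad_cvm(p, x)
    rep.KS, rep.ks_pvalue = ks_test(p, x)
    return rep
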