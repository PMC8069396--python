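"""Positive-support baseline distributions for the Type I HLOW-G family.

A baseline is an absolutely continuous distribution G on (0, infinity).  The
family layers an odd-Weibull and a half-logistic transform on top of the odds
ratio t(x) = G(x)/(1-G(x)), so every baseline here exposes, besides the usual
cdf/pdf/ppf, numerically safe ``logcdf`` and ``logsf`` (the odds ratio is formed
as exp(logcdf - logsf), which stays accurate when G is close to 0 or 1).

Six baselines are provided: exponential, Rayleigh, Lindley, Weibull, Frechet
and Lomax.  Parameter vectors follow the conventions

======================  ======================================  ==========
name                    G(x; phi)                               phi
======================  ======================================  ==========
exponential             1 - exp(-a x)                           (a,)
rayleigh                1 - exp(-a^2 x^2)                       (a,)
lindley                 1 - (1 + a x/(a+1)) exp(-a x)           (a,)
weibull                 1 - exp(-(x/b)^a)      a shape, b scale (a, b)
frechet                 exp(-(a/x)^b)          a scale, b shape (a, b)
lomax                   1 - (1 + x/b)^(-a)                      (a, b)
======================  ======================================  ==========
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.special import lambertw

__all__ = [
    "BaselineSpec",
    "make_baseline",
    "baseline_odds",
    "log_odds",
    "BASELINE_NAMES",
    "UnsupportedBaselineError",
]


class UnsupportedBaselineError(ValueError):
    """Raised when a baseline name is not one of the six supported models."""


_ARITY = {
    "exponential": 1,
    "rayleigh": 1,
    "lindley": 1,
    "weibull": 2,
    "frechet": 2,
    "lomax": 2,
}

BASELINE_NAMES = tuple(sorted(_ARITY))

_PARAM_NAMES = {
    "exponential": ("a",),
    "rayleigh": ("a",),
    "lindley": ("a",),
    "weibull": ("a", "b"),
    "frechet": ("a", "b"),
    "lomax": ("a", "b"),
}


@dataclass(frozen=True)
class BaselineSpec:
    """A concrete baseline distribution with a fixed parameter vector.

    Attributes
    ----------
    name : str
        One of the six supported baseline identifiers.
    phi : tuple of float
        Positive parameter vector, ordered as in the module table.
    param_names : tuple of str
        Labels for the components of ``phi``.
    """

    name: str
    phi: Tuple[float, ...]
    param_names: Tuple[str, ...]
    _logcdf: Callable = field(repr=False)
    _logsf: Callable = field(repr=False)
    _logpdf: Callable = field(repr=False)
    _ppf: Callable = field(repr=False)
    _isf: Callable = field(repr=False)
    # analytic (dG/dphi_k, dlog g/dphi_k) callables, or None -> numeric fallback
    _dG_dphi: Optional[Callable] = field(default=None, repr=False)
    _dlogg_dphi: Optional[Callable] = field(default=None, repr=False)

    # -- distribution functions -------------------------------------------
    def logcdf(self, x):
        x = _check_x(x, allow_zero=True)
        return self._logcdf(x)

    def logsf(self, x):
        x = _check_x(x, allow_zero=True)
        return self._logsf(x)

    def cdf(self, x):
        return np.exp(self.logcdf(x))

    def sf(self, x):
        return np.exp(self.logsf(x))

    def logpdf(self, x):
        x = _check_x(x)
        return self._logpdf(x)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1)):
            raise ValueError("ppf argument must lie in [0, 1]")
        return self._ppf(u)

    def isf(self, q):
        """Inverse survival function; stable where sf is small."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("isf argument must lie in [0, 1]")
        return self._isf(q)

    # -- parameter derivatives (used by the analytic score) ----------------
    def dG_dphi(self, x, k: int):
        """d G(x; phi) / d phi_k, analytic where available else central diff."""
        x = np.asarray(x, dtype=float)
        if self._dG_dphi is not None:
            return self._dG_dphi(x, k)
        return _numdiff_param(lambda p: make_baseline(self.name, p).cdf(x),
                              self.phi, k)

    def dlogg_dphi(self, x, k: int):
        x = np.asarray(x, dtype=float)
        if self._dlogg_dphi is not None:
            return self._dlogg_dphi(x, k)
        return _numdiff_param(lambda p: make_baseline(self.name, p).logpdf(x),
                              self.phi, k)


def _check_x(x, allow_zero: bool = False):
    x = np.asarray(x, dtype=float)
    if allow_zero:
        if np.any(x < 0):
            raise ValueError("x must be nonnegative")
    elif np.any(x <= 0):
        raise ValueError("x must be strictly positive")
    return x


def _numdiff_param(f, phi, k, rel_h=1e-6):
    h = rel_h * max(abs(phi[k]), 1.0)
    up = list(phi)
    dn = list(phi)
    up[k] += h
    dn[k] -= h
    return (f(tuple(up)) - f(tuple(dn))) / (2 * h)


# ---------------------------------------------------------------------------
# constructors per baseline; each returns the five core callables
# ---------------------------------------------------------------------------

def _exponential(a):
    def logsf(x):
        return -a * x

    def logcdf(x):
        with np.errstate(divide="ignore"):
            return np.log(-np.expm1(-a * x))

    def logpdf(x):
        return np.log(a) - a * x

    def ppf(u):
        return -np.log1p(-u) / a

    def isf(q):
        with np.errstate(divide="ignore"):
            return -np.log(q) / a

    def dG(x, k):
        return x * np.exp(-a * x)

    def dlogg(x, k):
        return 1.0 / a - x

    return logcdf, logsf, logpdf, ppf, isf, dG, dlogg


def _rayleigh(a):
    def logsf(x):
        return -(a * x) ** 2

    def logcdf(x):
        with np.errstate(divide="ignore"):
            return np.log(-np.expm1(-(a * x) ** 2))

    def logpdf(x):
        return np.log(2 * a * a) + np.log(x) - (a * x) ** 2

    def ppf(u):
        return np.sqrt(-np.log1p(-u)) / a

    def isf(q):
        with np.errstate(divide="ignore"):
            return np.sqrt(-np.log(q)) / a

    def dG(x, k):
        return 2 * a * x * x * np.exp(-(a * x) ** 2)

    def dlogg(x, k):
        return 2.0 / a - 2 * a * x * x

    return logcdf, logsf, logpdf, ppf, isf, dG, dlogg


def _lindley(a):
    # G(x) = 1 - (1 + a x/(a+1)) e^{-a x}; density a^2/(a+1) (1+x) e^{-a x}
    def logsf(x):
        return np.log1p(a * x / (a + 1.0)) - a * x

    def logcdf(x):
        with np.errstate(divide="ignore"):
            return np.log(-np.expm1(logsf(x)))

    def logpdf(x):
        return 2 * np.log(a) - np.log(a + 1.0) + np.log1p(x) - a * x

    def ppf(u):
        u = np.asarray(u, dtype=float)
        # invert (1 + a x/(a+1)) e^{-a x} = 1-u via the secondary Lambert branch
        arg = (1.0 + a) * (u - 1.0) * np.exp(-(1.0 + a))
        w = np.real(lambertw(arg, k=-1))
        x = -1.0 - 1.0 / a - w / a
        return np.where(u == 0.0, 0.0, x)

    def isf(q):
        return ppf(1.0 - np.asarray(q, dtype=float))

    def dG(x, k):
        # dG/da = e^{-ax} [x (1 + a x/(a+1)) - x/(a+1)^2]
        e = np.exp(-a * x)
        return e * (x * (1.0 + a * x / (a + 1.0)) - x / (a + 1.0) ** 2)

    def dlogg(x, k):
        return 2.0 / a - 1.0 / (a + 1.0) - x

    return logcdf, logsf, logpdf, ppf, isf, dG, dlogg


def _weibull(a, b):
    def logsf(x):
        return -((x / b) ** a)

    def logcdf(x):
        with np.errstate(divide="ignore"):
            return np.log(-np.expm1(logsf(x)))

    def logpdf(x):
        z = x / b
        return np.log(a / b) + (a - 1) * np.log(z) - z ** a

    def ppf(u):
        return b * (-np.log1p(-u)) ** (1.0 / a)

    def isf(q):
        with np.errstate(divide="ignore"):
            return b * (-np.log(q)) ** (1.0 / a)

    return logcdf, logsf, logpdf, ppf, isf, None, None


def _frechet(a, b):
    # G(x) = exp(-(a/x)^b): a is the scale, b the shape
    def logcdf(x):
        with np.errstate(divide="ignore"):
            return -((a / x) ** b)

    def logsf(x):
        with np.errstate(divide="ignore"):
            return np.log(-np.expm1(-((a / x) ** b)))

    def logpdf(x):
        z = a / x
        return np.log(b / a) + (b + 1) * np.log(z) - z ** b

    def ppf(u):
        with np.errstate(divide="ignore"):
            return a * (-np.log(u)) ** (-1.0 / b)

    def isf(q):
        return a * (-np.log1p(-q)) ** (-1.0 / b)

    def dG(x, k):
        z = (a / x) ** b
        G = np.exp(-z)
        if k == 0:  # scale a
            return -G * z * b / a
        return -G * z * np.log(a / x)  # shape b

    def dlogg(x, k):
        z = a / x
        if k == 0:
            return b / a - (b / a) * z ** b
        return 1.0 / b + np.log(z) * (1.0 - z ** b)

    return logcdf, logsf, logpdf, ppf, isf, dG, dlogg


def _lomax(a, b):
    def logsf(x):
        return -a * np.log1p(x / b)

    def logcdf(x):
        with np.errstate(divide="ignore"):
            return np.log(-np.expm1(logsf(x)))

    def logpdf(x):
        return np.log(a / b) - (a + 1) * np.log1p(x / b)

    def ppf(u):
        return b * np.expm1(-np.log1p(-u) / a)

    def isf(q):
        with np.errstate(divide="ignore"):
            return b * np.expm1(-np.log(q) / a)

    return logcdf, logsf, logpdf, ppf, isf, None, None


_FACTORIES = {
    "exponential": _exponential,
    "rayleigh": _rayleigh,
    "lindley": _lindley,
    "weibull": _weibull,
    "frechet": _frechet,
    "lomax": _lomax,
}


def make_baseline(name: str, phi: Sequence[float]) -> BaselineSpec:
    """Construct a :class:`BaselineSpec` from a name and parameter vector.

    Parameters
    ----------
    name : str
        One of ``exponential, rayleigh, lindley, weibull, frechet, lomax``.
    phi : sequence of float
        Positive parameters; length 1 for the one-parameter baselines,
        length 2 otherwise (order as in the module table).

    Raises
    ------
    UnsupportedBaselineError
        For an unknown name.
    ValueError
        For a parameter vector of wrong length or with non-positive entries.
    """
    name = str(name).lower()
    if name not in _FACTORIES:
        raise UnsupportedBaselineError(
            f"unknown baseline {name!r}; choose from {', '.join(BASELINE_NAMES)}"
        )
    phi = tuple(float(v) for v in np.atleast_1d(phi))
    if len(phi) != _ARITY[name]:
        raise ValueError(
            f"baseline {name!r} takes {_ARITY[name]} parameter(s), got {len(phi)}"
        )
    if any(not np.isfinite(v) or v <= 0 for v in phi):
        raise ValueError(f"baseline parameters must be positive, got {phi}")
    logcdf, logsf, logpdf, ppf, isf, dG, dlogg = _FACTORIES[name](*phi)
    return BaselineSpec(
        name=name,
        phi=phi,
        param_names=_PARAM_NAMES[name],
        _logcdf=logcdf,
        _logsf=logsf,
        _logpdf=logpdf,
        _ppf=ppf,
        _isf=isf,
        _dG_dphi=dG,
        _dlogg_dphi=dlogg,
    )


def log_odds(b: BaselineSpec, x):
    """log of the odds ratio G(x)/(1-G(x)), formed from log G and log(1-G)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    with np.errstate(divide="ignore"):
        return b.logcdf(x) - b.logsf(x)


def baseline_odds(b: BaselineSpec, x):
    """Odds ratio G(x)/(1-G(x)); nondecreasing in x, 0 at the origin."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be strictly positive")
    return np.exp(log_odds(b, x))
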