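"""Response functions F for thresholds models.

The thresholds model P(Y > y) = F(alpha * (theta - delta(y))) is driven by a
strictly increasing distribution function F.  Everything the likelihood,
information and moment formulas need from F is collected in a single
:class:`ResponseFunction` object: the cdf, the density f and its first two
derivatives, the quantile function, and the moment constants (c, d).

The constants c and d describe the implied response distribution under a
*linear* difficulty delta(y) = delta0 + delta*y: the response then satisfies
E(Y) = gamma*theta - gamma0 with gamma = 1/delta, gamma0 = (delta0 + d/alpha)/delta
and var(Y) = c * gamma^2 / alpha^2.  With theta = 0, alpha = delta = 1 and
delta0 = 0 one has P(Y > y) = F(-y), i.e. Y is distributed as -V with V ~ F,
so d equals the mean of F and c its variance.  They are computed here by
numeric integration, which keeps the definition verifiable by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate
from scipy import stats

__all__ = ["ResponseFunction", "make_response_function", "moment_constants"]

_SUPPORTED = ("normal", "logistic")


@dataclass(frozen=True)
class ResponseFunction:
    """A strictly increasing distribution function F with derivatives.

    Attributes
    ----------
    name : str
        Label, ``"normal"`` or ``"logistic"``.
    cdf, density, quantile : callable
        F, f = F' and the quantile function F^{-1}.
    density_d1, density_d2 : callable
        First and second derivatives of the density, f' and f''.
    logpdf : callable
        log f, used for numerically stable continuous likelihoods.
    symmetric : bool
        Whether f(-x) = f(x); both shipped functions are symmetric.
    c_const, d_const : float
        Moment constants of the implied linear-difficulty response
        distribution (variance and mean of F respectively).
    """

    name: str
    cdf: Callable[[np.ndarray], np.ndarray]
    sf: Callable[[np.ndarray], np.ndarray]
    density: Callable[[np.ndarray], np.ndarray]
    density_d1: Callable[[np.ndarray], np.ndarray]
    density_d2: Callable[[np.ndarray], np.ndarray]
    quantile: Callable[[np.ndarray], np.ndarray]
    logpdf: Callable[[np.ndarray], np.ndarray]
    dlogpdf: Callable[[np.ndarray], np.ndarray]
    symmetric: bool
    c_const: float = field(default=np.nan)
    d_const: float = field(default=np.nan)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ResponseFunction({self.name!r})"


def moment_constants(F: "ResponseFunction" | None = None,
                     density: Callable | None = None) -> tuple[float, float]:
    """Return the constants (c, d) of the linear-difficulty moment formulas.

    d is the mean of F and c its variance, obtained by adaptive quadrature
    of the density over a wide interval.  For a symmetric F, d = 0 (up to
    quadrature error, which is forced to exactly 0 when ``F.symmetric``).
    """
    if density is None:
        density = F.density
    lo, hi = -60.0, 60.0
    mass, _ = integrate.quad(density, lo, hi, limit=200)
    if not np.isfinite(mass) or abs(mass - 1.0) > 1e-6:
        raise ValueError(f"density does not integrate to 1 (got {mass!r})")
    d, _ = integrate.quad(lambda x: x * density(x), lo, hi, limit=200)
    m2, _ = integrate.quad(lambda x: x * x * density(x), lo, hi, limit=200)
    c = m2 - d * d
    if F is not None and F.symmetric:
        d = 0.0
    if c <= 0:
        raise ValueError("response function has non-positive variance")
    return c, d


def _normal() -> ResponseFunction:
    phi = stats.norm.pdf
    rf = ResponseFunction(
        name="normal",
        cdf=stats.norm.cdf,
        sf=stats.norm.sf,
        density=phi,
        # phi'(x) = -x phi(x); phi''(x) = (x^2 - 1) phi(x)
        density_d1=lambda x: -np.asarray(x) * phi(x),
        density_d2=lambda x: (np.square(x) - 1.0) * phi(x),
        quantile=stats.norm.ppf,
        logpdf=stats.norm.logpdf,
        dlogpdf=lambda x: -np.asarray(x, dtype=float),
        symmetric=True,
    )
    return rf


def _logistic() -> ResponseFunction:
    F = stats.logistic.cdf
    f = stats.logistic.pdf

    def d1(x):
        # f' = f (1 - 2F)
        return f(x) * (1.0 - 2.0 * F(x))

    def d2(x):
        # f'' = f [(1 - 2F)^2 - 2f]
        Fx = F(x)
        fx = f(x)
        return fx * ((1.0 - 2.0 * Fx) ** 2 - 2.0 * fx)

    return ResponseFunction(
        name="logistic",
        cdf=F,
        sf=stats.logistic.sf,
        density=f,
        density_d1=d1,
        density_d2=d2,
        quantile=stats.logistic.ppf,
        logpdf=stats.logistic.logpdf,
        dlogpdf=lambda x: 1.0 - 2.0 * F(x),  # (log f)' = 1 - 2F
        symmetric=True,
    )


_BUILDERS = {"normal": _normal, "logistic": _logistic}


def make_response_function(name: str) -> ResponseFunction:
    """Build a fully populated :class:`ResponseFunction` from its label.

    Raises
    ------
    ValueError
        If the label is not one of ``normal`` or ``logistic``.
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown response function {name!r}; supported: {', '.join(_SUPPORTED)}"
        ) from None
    rf = builder()
    c, d = moment_constants(rf)
    object.__setattr__(rf, "c_const", float(c))
    object.__setattr__(rf, "d_const", float(d))
    return rf
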