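"""Item difficulty functions delta_i(y).

Every item in a thresholds model carries a non-decreasing difficulty function
defined on the item's response support.  The difficulty function encodes how
hard it is to exceed each response level and, together with the response
function F, fully determines the response distribution.

Families
--------
Parametric families have the form delta(y) = delta0 + slope * g(y) with

====================  ==========================  =======================
family                g(y)                        natural support
====================  ==========================  =======================
``linear``            y                           real line
``log``               log(y)                      positive reals
``log1p``             log(1 + y)                  counts / finite ordinal
``adapted_logit``     log((1 + y) / (k - y))      finite ordinal {0..k}
``inverse_cdf``       a * F^{-1}(y)               open unit interval
====================  ==========================  =======================

Beyond these, ``bspline`` difficulties expand delta in a monotone cubic
B-spline basis (non-decreasing coefficients), and ``free_ordinal`` leaves the
k threshold values of a finite ordinal item completely free (the graded
response model parameterization).  Binary items only ever use the single
value delta(0), so they store no slope.

Conventions for discrete supports: delta(-1) = -inf (exceeding -1 is
certain) and delta at the top of a finite support is +inf (exceeding the top
category is impossible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import brentq

__all__ = [
    "SupportSpec",
    "DifficultyFunction",
    "ParametricDifficulty",
    "BinaryDifficulty",
    "FreeOrdinalDifficulty",
    "BSplineDifficulty",
    "make_bspline_difficulty",
    "make_parametric_difficulty",
    "PARAMETRIC_FAMILIES",
]

PARAMETRIC_FAMILIES = ("linear", "log", "log1p", "adapted_logit", "inverse_cdf")

_CONTINUOUS_KINDS = ("real", "positive", "unit_interval")
_DISCRETE_KINDS = ("binary", "ordinal", "count")


@dataclass(frozen=True)
class SupportSpec:
    """Response support of an item.

    ``kind`` is one of ``real``, ``positive``, ``unit_interval`` (continuous)
    or ``binary``, ``ordinal``, ``count`` (discrete).  For ordinal items the
    responses live in {0, ..., k} (k + 1 categories, k >= 1 after the binary
    case is split off; the model requires k >= 2 for a genuinely ordinal
    item).  ``bounds`` holds the original (a, b) interval of unit-interval
    data before the affine map onto (0, 1).
    """

    kind: str
    k: Optional[int] = None
    bounds: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.kind not in _CONTINUOUS_KINDS + _DISCRETE_KINDS:
            raise ValueError(f"unknown support kind {self.kind!r}")
        if self.kind == "ordinal":
            if self.k is None or self.k < 2:
                raise ValueError("ordinal support needs k >= 2 (responses 0..k)")
        if self.kind == "unit_interval" and self.bounds is not None:
            a, b = self.bounds
            if not a < b:
                raise ValueError("unit_interval bounds must satisfy a < b")

    @property
    def continuous(self) -> bool:
        return self.kind in _CONTINUOUS_KINDS

    @property
    def discrete(self) -> bool:
        return not self.continuous

    @property
    def top(self) -> Optional[int]:
        """Top category of a finite discrete support, else None."""
        if self.kind == "binary":
            return 1
        if self.kind == "ordinal":
            return self.k
        return None

    def contains(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.kind == "real":
            return np.isfinite(y)
        if self.kind == "positive":
            return np.isfinite(y) & (y > 0)
        if self.kind == "unit_interval":
            return np.isfinite(y) & (y > 0) & (y < 1)
        is_int = np.isfinite(y) & (np.mod(y, 1) == 0)
        if self.kind == "binary":
            return is_int & (y >= 0) & (y <= 1)
        if self.kind == "ordinal":
            return is_int & (y >= 0) & (y <= self.k)
        return is_int & (y >= 0)  # count

    def values(self) -> np.ndarray:
        """All support points of a finite discrete support."""
        if self.top is None:
            raise ValueError(f"support {self.kind!r} is not finite")
        return np.arange(self.top + 1)


class DifficultyFunction:
    """Common interface of all difficulty families.

    Subclasses implement ``evaluate`` (vectorized), ``derivative`` and
    ``inverse`` where meaningful, plus the design-matrix hooks
    ``design_matrix``/``design_matrix_deriv`` and parameter plumbing
    (``params`` / ``with_params``) used by the estimation machinery.
    """

    family: str
    support: SupportSpec

    # -- evaluation -------------------------------------------------------
    def evaluate(self, y):
        raise NotImplementedError

    def __call__(self, y):
        return self.evaluate(y)

    def derivative(self, y):
        raise NotImplementedError(
            f"family {self.family!r} has no derivative (discrete-only)"
        )

    def inverse(self, v):
        raise NotImplementedError(
            f"family {self.family!r} is not invertible (discrete-only)"
        )

    # -- estimation plumbing ---------------------------------------------
    @property
    def params(self) -> np.ndarray:
        raise NotImplementedError

    def with_params(self, params: Sequence[float]) -> "DifficultyFunction":
        raise NotImplementedError

    def design_matrix(self, y) -> np.ndarray:
        """Phi(y): rows of basis values so that delta(y) = Phi(y) @ params."""
        raise NotImplementedError

    def design_matrix_deriv(self, y) -> np.ndarray:
        """Phi'(y): derivative of the basis, continuous families only."""
        raise NotImplementedError

    # -- helpers ----------------------------------------------------------
    def _check_domain(self, y, allow_sentinels: bool = True):
        """Validate y; with sentinels, -1 and the finite top are allowed."""
        y = np.asarray(y, dtype=float)
        ok = self.support.contains(y)
        if allow_sentinels and self.support.discrete:
            ok = ok | (y == -1)
            if self.support.top is not None:
                ok = ok | (y == self.support.top)
        if not np.all(ok):
            bad = np.asarray(y)[~ok]
            raise ValueError(
                f"value(s) {bad[:5]} outside support {self.support.kind!r}"
            )
        return y


def _as_scalar_or_array(out, y_in):
    if np.isscalar(y_in) or (isinstance(y_in, np.ndarray) and y_in.ndim == 0):
        return float(out.reshape(-1)[0])
    return out


class ParametricDifficulty(DifficultyFunction):
    """delta(y) = intercept + slope * g(y) for a fixed transform g."""

    def __init__(self, family: str, intercept: float, slope: float,
                 support: SupportSpec, transform_const: float = 1.0,
                 quantile: Callable | None = None,
                 cdf: Callable | None = None):
        if family not in PARAMETRIC_FAMILIES:
            raise ValueError(f"unknown parametric family {family!r}")
        if slope <= 0:
            raise ValueError("difficulty slope must be positive")
        if family == "adapted_logit" and support.top is None:
            raise ValueError("adapted_logit needs a finite ordinal support")
        if family == "inverse_cdf" and (quantile is None or cdf is None):
            raise ValueError("inverse_cdf needs the response quantile and cdf")
        if family == "log" and support.discrete:
            raise ValueError("log family excludes 0; use log1p for counts")
        self.family = family
        self.intercept = float(intercept)
        self.slope = float(slope)
        self.support = support
        self.transform_const = float(transform_const)
        self._quantile = quantile
        self._cdf = cdf

    # transform g and its pieces ------------------------------------------
    def _g(self, y):
        y = np.asarray(y, dtype=float)
        if self.family == "linear":
            return y
        if self.family == "log":
            return np.log(y)
        if self.family == "log1p":
            return np.log1p(y)
        if self.family == "adapted_logit":
            k = self.support.top
            with np.errstate(divide="ignore"):
                return np.log1p(y) - np.log(k - y)
        # inverse_cdf
        return self.transform_const * self._quantile(y)

    def _g_deriv(self, y):
        y = np.asarray(y, dtype=float)
        if self.family == "linear":
            return np.ones_like(y)
        if self.family == "log":
            return 1.0 / y
        if self.family == "log1p":
            return 1.0 / (1.0 + y)
        if self.family == "adapted_logit":
            k = self.support.top
            return 1.0 / (1.0 + y) + 1.0 / (k - y)
        # inverse_cdf: d/dy a F^{-1}(y) = a / f(F^{-1}(y))
        return self.transform_const / self._density(self._quantile(y))

    def _g_inverse(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "linear":
            return t
        if self.family == "log":
            return np.exp(t)
        if self.family == "log1p":
            return np.expm1(t)
        if self.family == "adapted_logit":
            k = self.support.top
            et = np.exp(t)
            return (k * et - 1.0) / (1.0 + et)
        return self._cdf(t / self.transform_const)

    # interface ------------------------------------------------------------
    def evaluate(self, y):
        y_in = y
        y = self._check_domain(y)
        out = np.full(y.shape, np.nan)
        if self.support.discrete:
            lo = y == -1
            top = (y == self.support.top) if self.support.top is not None \
                else np.zeros(y.shape, bool)
        else:
            lo = top = np.zeros(y.shape, bool)
        mid = ~(lo | top)
        out[lo] = -np.inf
        out[top] = np.inf
        if np.any(mid):
            out[mid] = self.intercept + self.slope * self._g(y[mid])
        return _as_scalar_or_array(out, y_in)

    def derivative(self, y):
        if self.support.discrete:
            raise NotImplementedError("derivative undefined on a discrete support")
        y_in = y
        y = self._check_domain(y, allow_sentinels=False)
        out = self.slope * self._g_deriv(y)
        return _as_scalar_or_array(np.asarray(out, dtype=float), y_in)

    _density = None  # set when family == inverse_cdf via factory

    def inverse(self, v):
        v_in = v
        v = np.asarray(v, dtype=float)
        t = (v - self.intercept) / self.slope
        out = self._g_inverse(t)
        inside = self.support.contains(out)
        if self.support.continuous and not np.all(inside):
            raise ValueError("value outside the range of the difficulty function")
        return _as_scalar_or_array(np.asarray(out, dtype=float), v_in)

    # estimation plumbing ---------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        return np.array([self.intercept, self.slope])

    def with_params(self, params):
        d0, sl = params
        new = ParametricDifficulty.__new__(ParametricDifficulty)
        new.__dict__.update(self.__dict__)
        new.intercept = float(d0)
        new.slope = float(sl)
        return new

    def design_matrix(self, y):
        y = np.atleast_1d(np.asarray(y, dtype=float))
        return np.column_stack([np.ones_like(y), self._g(y)])

    def design_matrix_deriv(self, y):
        y = np.atleast_1d(np.asarray(y, dtype=float))
        return np.column_stack([np.zeros_like(y), self._g_deriv(y)])


class BinaryDifficulty(DifficultyFunction):
    """Binary items: only delta(0) matters, no slope is stored."""

    family = "binary"

    def __init__(self, delta0: float):
        self.delta0 = float(delta0)
        self.support = SupportSpec("binary")

    def evaluate(self, y):
        y_in = y
        y = self._check_domain(y)
        out = np.where(y == -1, -np.inf, np.where(y == 1, np.inf, self.delta0))
        return _as_scalar_or_array(np.asarray(out, dtype=float), y_in)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.delta0])

    def with_params(self, params):
        return BinaryDifficulty(params[0])

    def design_matrix(self, y):
        y = np.atleast_1d(np.asarray(y, dtype=float))
        return np.ones((y.size, 1))


class FreeOrdinalDifficulty(DifficultyFunction):
    """Free threshold values delta(0) < ... < delta(k-1) on {0, ..., k}.

    This is the graded response model parameterization: with
    delta_r = delta(r - 1), P(Y >= r) = F(alpha (theta - delta_r)).
    """

    family = "free_ordinal"

    def __init__(self, values: Sequence[float]):
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("free_ordinal needs at least two threshold values")
        if np.any(np.diff(values) <= 0):
            raise ValueError("free_ordinal values must be strictly increasing")
        self.values = values
        self.support = SupportSpec("ordinal", k=values.size)

    def evaluate(self, y):
        y_in = y
        y = self._check_domain(y)
        out = np.full(y.shape, np.nan)
        k = self.support.top
        lo = y == -1
        top = y == k
        mid = ~(lo | top)
        out[lo] = -np.inf
        out[top] = np.inf
        if np.any(mid):
            out[mid] = self.values[y[mid].astype(int)]
        return _as_scalar_or_array(out, y_in)

    @property
    def params(self) -> np.ndarray:
        return self.values.copy()

    def with_params(self, params):
        return FreeOrdinalDifficulty(params)

    def design_matrix(self, y):
        y = np.atleast_1d(np.asarray(y, dtype=float)).astype(int)
        out = np.zeros((y.size, self.values.size))
        out[np.arange(y.size), y] = 1.0
        return out


class BSplineDifficulty(DifficultyFunction):
    """Monotone difficulty expanded in a cubic B-spline basis.

    Non-decreasing coefficients guarantee a non-decreasing function (the
    B-spline variation-diminishing property).  On discrete supports the
    basis is evaluated only at the support points; the -1 / top-category
    conventions apply as for every discrete difficulty.
    """

    family = "bspline"

    def __init__(self, coefs: Sequence[float], knots: np.ndarray,
                 support: SupportSpec, degree: int = 3):
        coefs = np.asarray(coefs, dtype=float)
        if np.any(np.diff(coefs) < -1e-12):
            raise ValueError("bspline coefficients must be non-decreasing")
        if knots.size != coefs.size + degree + 1:
            raise ValueError("knot vector inconsistent with coefficient count")
        self.coefs = coefs
        self.knots = np.asarray(knots, dtype=float)
        self.degree = degree
        self.support = support
        self._bs = BSpline(self.knots, coefs, degree, extrapolate=False)
        self._bs_d = self._bs.derivative()

    @property
    def range(self) -> tuple[float, float]:
        p = self.degree
        return float(self.knots[p]), float(self.knots[-p - 1])

    def evaluate(self, y):
        y_in = y
        y = self._check_domain(y)
        out = np.full(y.shape, np.nan)
        if self.support.discrete:
            lo = y == -1
            top = (y == self.support.top) if self.support.top is not None else np.zeros(y.shape, bool)
            mid = ~(lo | top)
            out[lo] = -np.inf
            out[top] = np.inf
        else:
            mid = np.ones(y.shape, bool)
        if np.any(mid):
            vals = self._bs(np.clip(y[mid], *self.range))
            out[mid] = vals
        if np.any(np.isnan(out)):
            raise ValueError("response outside the spline knot range")
        return _as_scalar_or_array(out, y_in)

    def derivative(self, y):
        if self.support.discrete:
            raise NotImplementedError("derivative undefined on a discrete support")
        y_in = y
        y = self._check_domain(y, allow_sentinels=False)
        out = self._bs_d(y)
        return _as_scalar_or_array(np.asarray(out, dtype=float), y_in)

    def inverse(self, v):
        v_in = v
        v = np.atleast_1d(np.asarray(v, dtype=float))
        lo, hi = self.range
        flo, fhi = self._bs(lo), self._bs(hi)
        out = np.empty_like(v)
        for i, vi in enumerate(v):
            if not (flo <= vi <= fhi):
                raise ValueError(f"value {vi} outside the difficulty range "
                                 f"[{flo}, {fhi}]")
            out[i] = brentq(lambda t: self._bs(t) - vi, lo, hi, xtol=1e-12)
        return _as_scalar_or_array(out, v_in)

    @property
    def params(self) -> np.ndarray:
        return self.coefs.copy()

    def with_params(self, params):
        return BSplineDifficulty(params, self.knots, self.support, self.degree)

    def design_matrix(self, y):
        y = np.atleast_1d(np.asarray(y, dtype=float))
        return BSpline.design_matrix(
            np.clip(y, *self.range), self.knots, self.degree
        ).toarray()

    def design_matrix_deriv(self, y):
        y = np.atleast_1d(np.asarray(y, dtype=float))
        n = self.coefs.size
        out = np.empty((y.size, n))
        eye = np.eye(n)
        for j in range(n):
            bj = BSpline(self.knots, eye[j], self.degree, extrapolate=False)
            out[:, j] = bj.derivative()(np.clip(y, *self.range))
        return out


def make_bspline_difficulty(support: SupportSpec, n_basis: int,
                            coefs: Sequence[float],
                            data_range: tuple[float, float] | None = None,
                            degree: int = 3) -> BSplineDifficulty:
    """Build a monotone cubic B-spline difficulty.

    Knots are equally spaced over ``data_range``; when absent the range
    defaults to the full finite support ({0, ..., k-1} for ordinal items).
    ``coefs`` must be non-decreasing and of length ``n_basis``.
    """
    coefs = np.asarray(coefs, dtype=float)
    if coefs.size != n_basis:
        raise ValueError("coefs length must equal n_basis")
    if np.any(np.diff(coefs) < -1e-12):
        raise ValueError("bspline coefficients must be non-decreasing")
    if data_range is None:
        if support.kind == "ordinal":
            data_range = (0.0, float(support.k - 1))
        elif support.kind == "unit_interval":
            data_range = (1e-6, 1.0 - 1e-6)
        else:
            raise ValueError("data_range required for this support")
    lo, hi = map(float, data_range)
    if not lo < hi:
        raise ValueError("empty data range for spline knots")
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError(f"n_basis must be at least degree + 1 = {degree + 1}")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    return BSplineDifficulty(coefs, knots, support, degree)


def make_parametric_difficulty(family: str, intercept: float, slope: float,
                               support: SupportSpec, transform_const: float = 1.0,
                               response_function=None) -> ParametricDifficulty:
    """Factory wiring the response function into ``inverse_cdf`` difficulties."""
    quantile = cdf = None
    if family == "inverse_cdf":
        if response_function is None:
            raise ValueError("inverse_cdf difficulty needs a response function")
        quantile, cdf = response_function.quantile, response_function.cdf
    d = ParametricDifficulty(family, intercept, slope, support,
                             transform_const=transform_const,
                             quantile=quantile, cdf=cdf)
    if family == "inverse_cdf":
        d._density = response_function.density
    return d
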