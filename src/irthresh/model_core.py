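"""The thresholds model P(Y > y) = F(alpha_i (theta - delta_i(y))).

An :class:`ItemSpec` bundles an item's support, difficulty function and
discrimination parameter alpha_i; a :class:`ThresholdsModel` holds the item
list, the shared response function F and the latent scale sigma_theta
(person parameters are modeled as N(0, sigma_theta^2)).

The probabilistic quantities exposed here cover all item formats with one
formula each:

* ``prob_exceed`` — the exceedance probability F(alpha (theta - delta(y))),
  which read as a function of y is the person threshold (PT) function and
  read as a function of theta is the item characteristic (IC) function;
* ``cdf`` — 1 - prob_exceed;
* ``density_continuous`` — f(alpha (theta - delta(y))) alpha delta'(y);
* ``pmf_discrete`` — telescoping differences of exceedance probabilities;
* ``linear_moments`` — the closed-form mean/variance available under a
  linear difficulty;
* ``categorize`` — the discretized item implied by cut points, which is
  again a thresholds (graded response) item: categorization stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .difficulty_functions import (
    BinaryDifficulty,
    DifficultyFunction,
    FreeOrdinalDifficulty,
    SupportSpec,
)
from .response_functions import ResponseFunction, make_response_function

__all__ = [
    "ItemSpec",
    "ThresholdsModel",
    "prob_exceed",
    "ic_function",
    "cdf",
    "density_continuous",
    "log_density_continuous",
    "pmf_discrete",
    "linear_moments",
    "categorize",
]


@dataclass(frozen=True)
class ItemSpec:
    """One item: identifier, support, difficulty function, discrimination."""

    item_id: str
    difficulty: DifficultyFunction
    discrimination: float = 1.0

    def __post_init__(self):
        if self.discrimination <= 0:
            raise ValueError("discrimination must be positive")

    @property
    def support(self) -> SupportSpec:
        return self.difficulty.support

    @property
    def continuous(self) -> bool:
        return self.support.continuous


@dataclass(frozen=True)
class ThresholdsModel:
    """A full test: items, the shared response function, latent scale."""

    items: tuple[ItemSpec, ...]
    response_function: ResponseFunction
    sigma_theta: float = 1.0

    def __post_init__(self):
        if len(self.items) == 0:
            raise ValueError("a thresholds model needs at least one item")
        if self.sigma_theta <= 0:
            raise ValueError("sigma_theta must be positive")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids")
        object.__setattr__(self, "items", tuple(self.items))

    @classmethod
    def from_items(cls, items: Sequence[ItemSpec], response: str | ResponseFunction = "normal",
                   sigma_theta: float = 1.0) -> "ThresholdsModel":
        if isinstance(response, str):
            response = make_response_function(response)
        return cls(tuple(items), response, sigma_theta)

    def item(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"unknown item {item_id!r}")

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]


# ---------------------------------------------------------------------------
# probabilistic quantities


def prob_exceed(m: ThresholdsModel, item: str, theta, y):
    """P(Y > y | theta) = F(alpha (theta - delta(y))).

    Equals 1 at the sentinel y = -1 of discrete items (delta(-1) = -inf) and
    0 at the top of a finite support.
    """
    it = m.item(item)
    delta = it.difficulty.evaluate(y)
    eta = it.discrimination * (np.asarray(theta, dtype=float) - delta)
    return m.response_function.cdf(eta)


def ic_function(m: ThresholdsModel, item: str, y, thetas):
    """Item characteristic function: prob_exceed across a theta grid."""
    thetas = np.asarray(thetas, dtype=float)
    return prob_exceed(m, item, thetas, y)


def cdf(m: ThresholdsModel, item: str, theta, y):
    """Distribution function P(Y <= y | theta) = 1 - prob_exceed."""
    return 1.0 - prob_exceed(m, item, theta, y)


def density_continuous(m: ThresholdsModel, item: str, theta, y):
    """Density of a continuous item: f(alpha(theta - delta(y))) alpha delta'(y)."""
    it = m.item(item)
    if not it.continuous:
        raise TypeError(f"item {item!r} is discrete; use pmf_discrete")
    a = it.discrimination
    eta = a * (np.asarray(theta, dtype=float) - it.difficulty.evaluate(y))
    return m.response_function.density(eta) * a * it.difficulty.derivative(y)


def log_density_continuous(m: ThresholdsModel, item: str, theta, y):
    """log of :func:`density_continuous`, stable in the tails."""
    it = m.item(item)
    if not it.continuous:
        raise TypeError(f"item {item!r} is discrete; use pmf_discrete")
    a = it.discrimination
    eta = a * (np.asarray(theta, dtype=float) - it.difficulty.evaluate(y))
    return (m.response_function.logpdf(eta) + np.log(a)
            + np.log(it.difficulty.derivative(y)))


def pmf_discrete(m: ThresholdsModel, item: str, theta, r):
    """P(Y = r | theta) = F(alpha(theta - delta(r-1))) - F(alpha(theta - delta(r))).

    The sentinel conventions delta(-1) = -inf and delta(top) = +inf make the
    formula cover r = 0 and the top category of a finite support.
    """
    it = m.item(item)
    if it.continuous:
        raise TypeError(f"item {item!r} is continuous; use density_continuous")
    r = np.asarray(r)
    if not np.all(it.support.contains(r)):
        raise ValueError(f"response {r} outside support of item {item!r}")
    upper = prob_exceed(m, item, theta, np.asarray(r, dtype=float) - 1)
    lower = prob_exceed(m, item, theta, r)
    return upper - lower


def pmf_vector(m: ThresholdsModel, item: str, theta) -> np.ndarray:
    """Probabilities of all categories of a finite discrete item at theta."""
    it = m.item(item)
    support = it.support.values()
    return np.array([pmf_discrete(m, item, theta, r) for r in support])


def linear_moments(m: ThresholdsModel, item: str, theta):
    """Mean and variance of a continuous linear-difficulty item.

    mean = gamma theta - gamma0 and var = c gamma^2 / alpha^2 with
    gamma = 1/slope, gamma0 = (intercept + d/alpha)/slope, and (c, d) the
    moment constants of the response function.
    """
    it = m.item(item)
    d = it.difficulty
    if not (it.continuous and getattr(d, "family", None) == "linear"):
        raise TypeError("linear_moments needs a continuous linear-difficulty item")
    c_const = m.response_function.c_const
    d_const = m.response_function.d_const
    a = it.discrimination
    gamma = 1.0 / d.slope
    gamma0 = (d.intercept + d_const / a) / d.slope
    mean = gamma * np.asarray(theta, dtype=float) - gamma0
    var = c_const * gamma ** 2 / a ** 2
    return mean, var


def categorize(m: ThresholdsModel, item: str, taus: Sequence[float]) -> ItemSpec:
    """Discretize a continuous item at cut points taus.

    Returns an ordinal item with free thresholds delta(tau_r) and the same
    discrimination.  Its pmf equals the probability that the continuous
    response falls in (tau_r, tau_{r+1}] — thresholds models are stable
    under categorization, and the categorized item is a graded response
    item with delta_r = delta(tau_r).
    """
    it = m.item(item)
    if not it.continuous:
        raise TypeError("categorize needs a continuous item")
    taus = np.asarray(taus, dtype=float)
    if taus.ndim != 1 or taus.size < 1:
        raise ValueError("need at least one cut point")
    if np.any(np.diff(taus) <= 0):
        raise ValueError("cut points must be strictly increasing")
    values = np.atleast_1d(it.difficulty.evaluate(taus))
    if values.size == 1:
        new_diff: DifficultyFunction = BinaryDifficulty(values[0])
    else:
        new_diff = FreeOrdinalDifficulty(values)
    return ItemSpec(item_id=f"{it.item_id}_cat", difficulty=new_diff,
                    discrimination=it.discrimination)
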