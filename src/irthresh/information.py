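"""Item (Fisher) information.

For a discrete item with category probabilities pi_r(theta),

    I(theta) = sum_r (pi_r'(theta)^2 - pi_r(theta) pi_r''(theta)) / pi_r(theta),

and for a finite support {0, ..., k} the algebraically equivalent form
without second derivatives,

    I(theta) = sum_{r=1}^k pi_r'^2 / pi_r + (sum_{r=1}^k pi_r')^2 / pi_0.

The derivatives pi', pi'' are exact: with eta_r = alpha (theta - delta(r)),
pi_r = F(eta_{r-1}) - F(eta_r), so pi_r' = alpha (f(eta_{r-1}) - f(eta_r))
and pi_r'' = alpha^2 (f'(eta_{r-1}) - f'(eta_r)).

For a continuous item only the observed information has a closed form,

    I_obs(theta, y) = alpha^2 ((f'(eta)/f(eta))^2 - f''(eta)/f(eta)),
    eta = alpha (theta - delta(y));

for a normal F this is alpha^2 for every (theta, y), so expected and
observed information coincide.  The expected information is obtained by
numeric integration over the implied response distribution, which after
the substitution v = alpha (theta - delta(y)) (v ~ F) no longer involves
theta or the difficulty at all.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from .model_core import ThresholdsModel

__all__ = [
    "item_information_discrete",
    "observed_information_continuous",
    "expected_information_continuous",
    "total_information",
]

_COUNT_TAIL = 1e-12


def _category_terms(m: ThresholdsModel, item: str, theta: float):
    """Yield (pi_r, pi_r', pi_r'') over the (possibly truncated) support."""
    it = m.item(item)
    F = m.response_function
    a = it.discrimination
    d = it.difficulty

    def eta(r):
        return a * (theta - d.evaluate(float(r)))

    top = it.support.top
    r = 0
    cum = 0.0
    while True:
        e_up = eta(r - 1)  # +inf at r = 0
        e_lo = eta(r)      # -inf at the top category
        fu = 0.0 if not np.isfinite(e_up) else float(F.density(e_up))
        fl = 0.0 if not np.isfinite(e_lo) else float(F.density(e_lo))
        du = 0.0 if not np.isfinite(e_up) else float(F.density_d1(e_up))
        dl = 0.0 if not np.isfinite(e_lo) else float(F.density_d1(e_lo))
        # F(e_up) - F(e_lo); in the upper tail the survival-function form
        # sf(e_lo) - sf(e_up) keeps precision where 1 - cdf underflows
        if min(e_up, e_lo) > 0:
            pi = (0.0 if not np.isfinite(e_lo) else float(F.sf(e_lo))) \
                - (0.0 if not np.isfinite(e_up) else float(F.sf(e_up)))
        else:
            Fu = 1.0 if not np.isfinite(e_up) else float(F.cdf(e_up))
            Fl = 0.0 if not np.isfinite(e_lo) else float(F.cdf(e_lo))
            pi = Fu - Fl
        pi1 = a * (fu - fl)
        pi2 = a * a * (du - dl)
        yield r, pi, pi1, pi2
        cum += pi
        if top is not None and r >= top:
            break
        if top is None and cum >= 1.0 - _COUNT_TAIL and r > 0:
            break
        r += 1


def item_information_discrete(m: ThresholdsModel, item: str, theta: float,
                              form: str = "general") -> float:
    """Fisher information of a discrete item at theta.

    ``form="general"`` uses the second-derivative formula over all
    categories (count supports truncated at cumulative mass 1 - 1e-12);
    ``form="finite"`` uses the first-derivative-only identity available for
    finite supports.  The two agree to numerical precision.
    """
    it = m.item(item)
    if it.continuous:
        raise TypeError("item_information_discrete needs a discrete item")
    terms = list(_category_terms(m, item, theta))
    for r, pi, _, _ in terms:
        if pi <= 0.0:
            raise FloatingPointError(
                f"category {r} of item {item!r} has zero probability at "
                f"theta={theta}")
    if form == "general":
        return float(sum((pi1 ** 2 - pi * pi2) / pi
                         for _, pi, pi1, pi2 in terms))
    if form == "finite":
        if it.support.top is None:
            raise ValueError("finite-category form needs a finite support")
        pi0 = terms[0][1]
        s = sum(pi1 ** 2 / pi for _, pi, pi1, _ in terms[1:])
        s1 = sum(pi1 for _, _, pi1, _ in terms[1:])
        return float(s + s1 ** 2 / pi0)
    raise ValueError(f"unknown form {form!r}")


def observed_information_continuous(m: ThresholdsModel, item: str,
                                    theta: float, y: float) -> float:
    """Observed information of a continuous item at (theta, y)."""
    it = m.item(item)
    if not it.continuous:
        raise TypeError("needs a continuous item")
    F = m.response_function
    a = it.discrimination
    eta = a * (theta - it.difficulty.evaluate(y))
    f = float(F.density(eta))
    return a * a * ((float(F.density_d1(eta)) / f) ** 2
                    - float(F.density_d2(eta)) / f)


def expected_information_continuous(m: ThresholdsModel, item: str,
                                    theta: float) -> float:
    """Expected information: E_Y[I_obs], integrated over the implied
    response distribution.  Independent of theta for location families."""
    it = m.item(item)
    if not it.continuous:
        raise TypeError("needs a continuous item")
    F = m.response_function
    a = it.discrimination

    def integrand(v):
        f = np.maximum(F.density(v), 1e-300)
        return a * a * ((F.density_d1(v) / f) ** 2 - F.density_d2(v) / f) * f

    # integrate between extreme quantiles: the omitted tail mass carries
    # O(eta^2 f) weight and is far below the quadrature tolerance
    lo, hi = float(F.quantile(1e-13)), float(F.quantile(1.0 - 1e-13))
    val, _ = integrate.quad(integrand, lo, hi, limit=200)
    if not np.isfinite(val):
        raise FloatingPointError("expected information integral diverged")
    return float(val)


def total_information(m: ThresholdsModel, theta: float) -> float:
    """Total information: the sum of item informations at theta."""
    total = 0.0
    for it in m.items:
        if it.continuous:
            total += expected_information_continuous(m, it.item_id, theta)
        else:
            total += item_information_discrete(m, it.item_id, theta)
    return total
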