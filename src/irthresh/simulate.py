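"""Seeded response generation from thresholds models.

Continuous responses use the inverse construction implied by the model:
with V ~ F, the draw Y = delta^{-1}(theta - V/alpha) has exceedance
probability F(alpha (theta - delta(y))) for every y.  Discrete responses
are drawn by cdf inversion; count items walk the support until the
cumulative mass exceeds the uniform draw (truncated at mass 1 - 1e-12,
with the remainder assigned to the next category).

``generate_dataset`` produces wide persons x items data from any model,
and the ``preset_*`` builders emulate the study designs the package is
validated on:

* person-recovery: 10 continuous linear-difficulty items with intercepts
  -2.25 + (i-1) * 0.5 and slopes (1,1,1,1,2,2,2,2,3,3), theta ~ N(0, 1);
* count: 5 count items with log(1+y) difficulties and varying slopes,
  200 persons, sigma_theta = 1;
* cognition-like: 194 x 6 seven-category ratings (children's
  self-regulation), linear difficulties;
* fears-like: 200 x 5 seven-category Likert ratings (political fears),
  logarithmic difficulties;
* fluency-like: 202 x 4 verbal-fluency counts, logarithmic difficulties.

Ordinal presets emit categories 0..6; rating data observed on 1..7 labels
is shifted to start at 0 by the reading layer (``first_category``), with
the log difficulty log(1 + y') on the shifted scale equal to log(y) on the
original one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .difficulty_functions import SupportSpec, make_parametric_difficulty
from .model_core import ItemSpec, ThresholdsModel
from .response_functions import make_response_function

__all__ = [
    "SimulationConfig",
    "sample_continuous",
    "sample_discrete",
    "generate_dataset",
    "preset_person_recovery",
    "preset_count",
    "preset_cognition_like",
    "preset_fears_like",
    "preset_fluency_like",
    "collapse_categories",
]

_COUNT_TAIL = 1e-12


@dataclass(frozen=True)
class SimulationConfig:
    """Fully determined simulation: model, size, seed, optional fixed theta."""

    model: ThresholdsModel
    n_persons: int
    seed: int
    theta: Optional[np.ndarray] = None


def sample_continuous(item: ItemSpec, F, theta, rng) -> np.ndarray:
    """Draw continuous responses via Y = delta^{-1}(theta - V/alpha), V ~ F."""
    if not item.continuous:
        raise TypeError("sample_continuous needs a continuous item")
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    v = F.quantile(rng.uniform(size=theta.shape))
    return np.asarray(item.difficulty.inverse(theta - v / item.discrimination))


def sample_discrete(item: ItemSpec, F, theta, rng) -> np.ndarray:
    """Draw discrete responses by cdf inversion."""
    if item.continuous:
        raise TypeError("sample_discrete needs a discrete item")
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    n = theta.size
    u = rng.uniform(size=n)
    a = item.discrimination
    d = item.difficulty
    top = item.support.top
    if top is not None:
        # cdf at r is 1 - F(alpha (theta - delta(r)))
        rs = np.arange(top)  # categories 0..top-1; top catches the rest
        exceed = F.cdf(a * (theta[:, None] - d.evaluate(rs.astype(float))[None, :]))
        cum = 1.0 - exceed  # (n, top), cdf at r
        return (u[:, None] > cum).sum(axis=1)
    # count support: walk categories until enough mass is accumulated
    out = np.full(n, -1, dtype=int)
    cum = np.zeros(n)
    r = 0
    alive = np.ones(n, dtype=bool)
    while np.any(alive):
        cum[alive] = 1.0 - F.cdf(a * (theta[alive] - d.evaluate(float(r))))
        hit = alive & (u <= cum)
        out[hit] = r
        alive &= ~hit
        # stopping rule: assign the remaining tail mass to the next category
        done = alive & (cum >= 1.0 - _COUNT_TAIL)
        out[done] = r + 1
        alive &= ~done
        r += 1
    return out


def generate_dataset(cfg: SimulationConfig):
    """Simulate a persons x items response matrix.

    Returns ``(data, theta, params)``: a wide DataFrame (columns = item
    ids), the generating abilities, and a dict of true item parameters for
    recovery checks.
    """
    m = cfg.model
    rng = np.random.default_rng(cfg.seed)
    if cfg.theta is not None:
        theta = np.asarray(cfg.theta, dtype=float)
        if theta.size != cfg.n_persons:
            raise ValueError("fixed theta length does not match n_persons")
    else:
        theta = rng.normal(0.0, m.sigma_theta, size=cfg.n_persons)
    cols = {}
    for it in m.items:
        if it.continuous:
            cols[it.item_id] = sample_continuous(it, m.response_function, theta, rng)
        else:
            cols[it.item_id] = sample_discrete(it, m.response_function, theta, rng)
    data = pd.DataFrame(cols)
    params = {
        it.item_id: dict(params=it.difficulty.params.tolist(),
                         family=it.difficulty.family,
                         alpha=it.discrimination)
        for it in m.items
    }
    params["sigma_theta"] = m.sigma_theta
    return data, theta, params


# ---------------------------------------------------------------------------
# presets


def _parametric_items(family, intercepts, slopes, alphas, support, F=None,
                      prefix="item"):
    items = []
    for i, (d0, sl, al) in enumerate(zip(intercepts, slopes, alphas), start=1):
        diff = make_parametric_difficulty(family, d0, sl, support,
                                          response_function=F)
        items.append(ItemSpec(f"{prefix}{i}", diff, al))
    return items


def preset_person_recovery(sigma_theta: float = 1.0) -> ThresholdsModel:
    """10 continuous linear items for person-parameter recovery.

    Intercepts -2.25 + (i-1) * 0.5 (= -2.25, -1.75, ..., 2.25); slopes 1 for
    items 1-4, 2 for items 5-8, 3 for items 9-10; alpha = 1; normal F.
    """
    intercepts = [-2.25 + (i - 1) * 0.5 for i in range(1, 11)]
    slopes = [1, 1, 1, 1, 2, 2, 2, 2, 3, 3]
    support = SupportSpec("real")
    items = _parametric_items("linear", intercepts, slopes, [1.0] * 10, support)
    return ThresholdsModel.from_items(items, "normal", sigma_theta)


def preset_count(varying_alpha: bool = False,
                 sigma_theta: float = 1.0) -> ThresholdsModel:
    """5 count items with log(1+y) difficulties and varying slopes.

    Intercepts/slopes put typical counts in the 5..20 range (verbal-fluency
    scale).  With ``varying_alpha`` the discriminations differ too, the
    last one pinned at 1.
    """
    intercepts = [-2.0, -2.5, -3.0, -3.5, -2.8]
    slopes = [1.0, 1.2, 1.4, 1.3, 0.9]
    alphas = [1.25, 0.8, 1.1, 0.9, 1.0] if varying_alpha else [1.0] * 5
    support = SupportSpec("count")
    items = _parametric_items("log1p", intercepts, slopes, alphas, support)
    return ThresholdsModel.from_items(items, "normal", sigma_theta)


# Ordinal presets: the generating parameters live on the original 1..7
# response scale; shifting labels to 0..6 turns delta0 + delta * y into
# (delta0 + delta) + delta * y'.

_COGNITION_INTERCEPTS = [-6.302662, -3.646508, -2.635715, -3.149895,
                         -5.747873, -3.367810]
_COGNITION_SLOPES = [1.1934046, 1.5804284, 0.8577245, 1.0391432,
                     1.0304311, 1.5432459]


def preset_cognition_like(sigma_theta: float = 1.5) -> ThresholdsModel:
    """194 x 6 ratings with linear difficulties (six-item rating scale).

    Emulates a self-regulation rating scale with seven ordered categories;
    responses are emitted as 0..6 (original labels 1..7 shifted to start at
    0).  The generating intercepts are stated on the original 1..7 scale
    and absorbed into the shift: delta0 + delta * y = (delta0 + delta) +
    delta * y' with y' = y - 1.
    """
    support = SupportSpec("ordinal", k=6)
    items = []
    for i, (d0, sl) in enumerate(zip(_COGNITION_INTERCEPTS, _COGNITION_SLOPES),
                                 start=1):
        diff = make_parametric_difficulty("linear", d0 + sl, sl, support)
        items.append(ItemSpec(f"item{i}", diff, 1.0))
    return ThresholdsModel.from_items(items, "normal", sigma_theta)


_FEARS_INTERCEPTS = [-4.840, -6.661, -7.569, -4.571, -5.716]
_FEARS_SLOPES = [3.056, 3.807, 4.093, 3.040, 3.400]


def preset_fears_like(sigma_theta: float = 1.0) -> ThresholdsModel:
    """200 x 5 seven-category Likert ratings with log(1+y) difficulties.

    Generating parameters are stated for log(y) on the original 1..7
    labels, which is identical to log(1+y') on the shifted 0..6 scale.
    """
    support = SupportSpec("ordinal", k=6)
    items = _parametric_items("log1p", _FEARS_INTERCEPTS, _FEARS_SLOPES,
                              [1.0] * 5, support)
    return ThresholdsModel.from_items(items, "normal", sigma_theta)


def preset_fluency_like(sigma_theta: float = 1.09) -> ThresholdsModel:
    """202 x 4 verbal-fluency counts with log(1+y) difficulties."""
    intercepts = [-3.3, -2.6, -2.9, -3.1]
    slopes = [1.05, 0.95, 1.0, 1.0]
    support = SupportSpec("count")
    items = _parametric_items("log1p", intercepts, slopes, [1.0] * 4, support)
    return ThresholdsModel.from_items(items, "normal", sigma_theta)


_PRESETS = {
    "person_recovery": (preset_person_recovery, 100),
    "count": (preset_count, 200),
    "cognition_like": (preset_cognition_like, 194),
    "fears_like": (preset_fears_like, 200),
    "fluency_like": (preset_fluency_like, 202),
}


def preset(name: str, seed: int, n_persons: Optional[int] = None,
           **kwargs):
    """Generate data from a named preset; returns (data, theta, params)."""
    try:
        builder, default_n = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; "
                         f"available: {sorted(_PRESETS)}") from None
    model = builder(**kwargs)
    cfg = SimulationConfig(model=model, n_persons=n_persons or default_n,
                           seed=seed)
    return generate_dataset(cfg)


def collapse_categories(column: pd.Series, thresholds: Sequence[float]) -> pd.Series:
    """Recode a response column into len(thresholds)+1 ordered categories.

    Category r means the original response fell in (t_r, t_{r+1}]; used to
    build mixed-format variants of the ordinal presets (e.g. collapsing a
    1..7 item to three categories at thresholds 4 and 6).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return pd.Series(np.searchsorted(thresholds, column.to_numpy(),
                                     side="left"),
                     index=column.index, name=column.name)
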