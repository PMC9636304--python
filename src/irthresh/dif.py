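"""Differential item functioning (DIF) for thresholds models.

DIF is modeled by item-specific covariate effects: the person term theta_p
is replaced by theta_p + x_p' gamma_i inside F(alpha_i(.)), so a nonzero
gamma_i means the item behaves differently for equally able persons with
different covariate values.  A binary covariate recovers the classical
focal/reference-group setting.  The hypothesis gamma_i = 0 is tested by a
likelihood-ratio test, item at a time, with Benjamini-Hochberg adjustment
across items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import FitResult, fit_mml, lrt
from .model_core import ItemSpec

__all__ = ["DIFConfig", "fit_dif", "test_dif_item", "dif_scan"]


@dataclass(frozen=True)
class DIFConfig:
    """Covariate design for DIF analysis.

    ``covariates`` is a persons x q matrix aligned with the response rows;
    ``items_under_test`` names the items whose person term carries a free
    gamma_i (all other items keep gamma = 0).
    """

    covariates: np.ndarray
    items_under_test: tuple[str, ...]

    def __post_init__(self):
        X = np.asarray(self.covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "items_under_test",
                           tuple(self.items_under_test))


def fit_dif(data, items: Sequence[ItemSpec], dif: DIFConfig,
            **fit_kwargs) -> FitResult:
    """Fit the thresholds model with item-specific covariate effects."""
    return fit_mml(data, items,
                   dif_covariates=dif.covariates,
                   dif_items=list(dif.items_under_test),
                   **fit_kwargs)


def test_dif_item(data, items: Sequence[ItemSpec], dif: DIFConfig,
                  item: str, baseline: Optional[FitResult] = None,
                  **fit_kwargs) -> tuple[float, int, float]:
    """LRT of H0: gamma_item = 0.  Returns (statistic, df, p-value)."""
    if baseline is None:
        baseline = fit_mml(data, items, **fit_kwargs)
    one = DIFConfig(dif.covariates, (item,))
    full = fit_dif(data, items, one, **fit_kwargs)
    stat, df = lrt(full, baseline)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def dif_scan(data, items: Sequence[ItemSpec], dif: DIFConfig,
             alpha_level: float = 0.05, **fit_kwargs) -> pd.DataFrame:
    """Test every item under test one at a time.

    Returns a table with the LRT statistic, df, raw and Benjamini-Hochberg
    adjusted p-values, and a flag at the requested level.
    """
    baseline = fit_mml(data, items, **fit_kwargs)
    rows = []
    for item in dif.items_under_test:
        stat, df, p = test_dif_item(data, items, dif, item,
                                    baseline=baseline, **fit_kwargs)
        rows.append(dict(item=item, statistic=stat, df=df, p_value=p))
    out = pd.DataFrame(rows)
    out["p_adjusted"] = _benjamini_hochberg(out["p_value"].to_numpy())
    out["flagged"] = out["p_adjusted"] < alpha_level
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
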