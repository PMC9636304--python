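"""Reading and writing: responses, item configurations, fit reports.

The primary on-disk formats are a wide CSV for responses (header row of
item ids, one row per person, empty cells for missing) and a JSON or YAML
item configuration describing, per item, the support kind, the difficulty
family and the estimation constraints.  Fit results round-trip through a
JSON report with stable key order.

Item configuration schema::

    response: normal | logistic          (default normal)
    free_discrimination: bool            (default false; first alpha fixed at 1)
    common_slope: bool                   (default false)
    items:
      - id: item1
        support: real | positive | unit_interval | binary | ordinal | count
        k: 6                             (ordinal: responses use k+1 categories)
        bounds: [a, b]                   (unit_interval only)
        family: linear | log | log1p | adapted_logit | inverse_cdf |
                bspline | free_ordinal  (defaults per support, see below)
        n_basis: 6                       (bspline only)
        first_category: 1                (ordinal/binary label offset, default 0)

Family defaults by support: real -> linear, positive -> log,
unit_interval -> inverse_cdf, count -> log1p, ordinal -> log1p; binary
items take no family (only delta(0) is identified, so any g would be
absorbed into the intercept — a configured slope or family is ignored with
a warning).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .difficulty_functions import (
    BinaryDifficulty,
    FreeOrdinalDifficulty,
    SupportSpec,
    make_bspline_difficulty,
    make_parametric_difficulty,
)
from .estimation import FitResult
from .model_core import ItemSpec
from .response_functions import make_response_function

__all__ = [
    "ItemConfig",
    "ItemConfigFile",
    "read_responses",
    "write_responses",
    "long_to_wide",
    "read_item_config",
    "build_items",
    "prepare_responses",
    "write_fit_report",
    "read_fit_report",
]

_DEFAULT_FAMILY = {
    "real": "linear",
    "positive": "log",
    "unit_interval": "inverse_cdf",
    "count": "log1p",
    "ordinal": "log1p",
}

_LEGAL = {
    "real": {"linear", "bspline"},
    "positive": {"log", "bspline"},
    "unit_interval": {"inverse_cdf", "bspline"},
    "binary": set(),
    "ordinal": {"linear", "log1p", "adapted_logit", "free_ordinal", "bspline"},
    "count": {"log1p"},
}


@dataclass(frozen=True)
class ItemConfig:
    id: str
    support: str
    k: Optional[int] = None
    bounds: Optional[tuple[float, float]] = None
    family: Optional[str] = None
    n_basis: int = 6
    first_category: int = 0
    transform_const: float = 1.0
    squeeze: bool = False


@dataclass(frozen=True)
class ItemConfigFile:
    items: tuple[ItemConfig, ...]
    response: str = "normal"
    free_discrimination: bool = False
    common_slope: bool = False


# ---------------------------------------------------------------------------
# responses


def read_responses(path) -> pd.DataFrame:
    """Read a wide response CSV (header of item ids, one row per person)."""
    df = pd.read_csv(path, header=0, skipinitialspace=True)
    # pandas mangles duplicate headers to name.1; detect from the raw header
    with open(path) as fh:
        raw = [c.strip() for c in fh.readline().rstrip("\n").split(",")]
    seen, dup = set(), []
    for c in raw:
        if c in seen:
            dup.append(c)
        seen.add(c)
    if dup:
        raise ValueError(f"duplicated item ids in header: {dup}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ValueError(
                f"non-numeric cell in column {col!r} near line {line}") from exc
    return df


def write_responses(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def long_to_wide(df: pd.DataFrame, person_col="person", item_col="item",
                 value_col="response") -> pd.DataFrame:
    """Convert long-format (person, item, response) records to wide."""
    return df.pivot(index=person_col, columns=item_col, values=value_col)


# ---------------------------------------------------------------------------
# item configuration


def read_item_config(path) -> ItemConfigFile:
    """Parse a JSON or YAML item configuration file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        raw = yaml.safe_load(text)
    else:
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "items" not in raw:
        raise ValueError("item config must be a mapping with an 'items' list")
    items = []
    for entry in raw["items"]:
        items.append(_parse_item(entry))
    ids = [it.id for it in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate item ids in config")
    return ItemConfigFile(
        items=tuple(items),
        response=raw.get("response", "normal"),
        free_discrimination=bool(raw.get("free_discrimination", False)),
        common_slope=bool(raw.get("common_slope", False)),
    )


def _parse_item(entry: dict) -> ItemConfig:
    if "id" not in entry or "support" not in entry:
        raise ValueError(f"item entry needs 'id' and 'support': {entry!r}")
    support = entry["support"]
    if support not in _LEGAL:
        raise ValueError(f"unknown support {support!r} for item {entry['id']!r}")
    family = entry.get("family")
    if support == "binary":
        if family is not None or "slope" in entry:
            warnings.warn(
                f"item {entry['id']!r} is binary: only delta(0) is "
                "identified, the configured family/slope is ignored")
        family = None
    else:
        if family is None:
            family = _DEFAULT_FAMILY[support]
        if family not in _LEGAL[support]:
            raise ValueError(
                f"family {family!r} not available for support {support!r} "
                f"(item {entry['id']!r}); legal: {sorted(_LEGAL[support])}")
    bounds = entry.get("bounds")
    return ItemConfig(
        id=str(entry["id"]),
        support=support,
        k=entry.get("k"),
        bounds=tuple(bounds) if bounds is not None else None,
        family=family,
        n_basis=int(entry.get("n_basis", 6)),
        first_category=int(entry.get("first_category", 0)),
        transform_const=float(entry.get("transform_const", 1.0)),
        squeeze=bool(entry.get("squeeze", False)),
    )


def prepare_responses(df: pd.DataFrame, cfg: ItemConfigFile) -> pd.DataFrame:
    """Shift ordinal/binary labels to start at 0 and map unit-interval data.

    Ordinal data observed on labels first_category..first_category+k are
    shifted down by ``first_category``; unit-interval data are affinely
    mapped from their (a, b) bounds onto (0, 1).  Exact-boundary values are
    rejected unless the item sets ``squeeze: true``, in which case the
    standard compression (y (n - 1) + 1/2) / n is applied.
    """
    out = df.copy()
    for ic in cfg.items:
        if ic.id not in out.columns:
            raise ValueError(f"item {ic.id!r} missing from responses")
        col = out[ic.id].astype(float)
        if ic.support in ("ordinal", "binary") and ic.first_category:
            col = col - ic.first_category
        if ic.support == "unit_interval" and ic.bounds is not None:
            a, b = ic.bounds
            col = (col - a) / (b - a)
        if ic.support == "unit_interval":
            at_edge = col.notna() & ((col <= 0) | (col >= 1))
            if at_edge.any():
                if not ic.squeeze:
                    raise ValueError(
                        f"item {ic.id!r}: responses on the interval boundary "
                        "(difficulty diverges there); rescale or set "
                        "'squeeze: true'")
                n = int(col.notna().sum())
                col = (col * (n - 1) + 0.5) / n
        out[ic.id] = col
    return out


def build_items(cfg: ItemConfigFile, data: Optional[pd.DataFrame] = None
                ) -> list[ItemSpec]:
    """Template ItemSpecs (neutral starting parameters) from a config.

    ``data`` (already passed through :func:`prepare_responses`) supplies
    observed ranges where a family needs them (spline knots over the
    response range).
    """
    F = make_response_function(cfg.response)
    items = []
    for ic in cfg.items:
        if ic.support == "binary":
            items.append(ItemSpec(ic.id, BinaryDifficulty(0.0)))
            continue
        if ic.support == "ordinal":
            support = SupportSpec("ordinal", k=ic.k)
            if ic.k is None:
                raise ValueError(f"ordinal item {ic.id!r} needs k")
        elif ic.support == "unit_interval":
            support = SupportSpec("unit_interval", bounds=ic.bounds)
        else:
            support = SupportSpec(ic.support)
        if ic.family == "free_ordinal":
            vals = np.linspace(-1.0, 1.0, ic.k)
            items.append(ItemSpec(ic.id, FreeOrdinalDifficulty(vals)))
        elif ic.family == "bspline":
            rng = None
            if support.continuous:
                if data is None or ic.id not in data:
                    raise ValueError(
                        f"bspline item {ic.id!r} needs data to place knots")
                y = data[ic.id].dropna().to_numpy()
                eps = 1e-6 * (y.max() - y.min() + 1.0)
                rng = (float(y.min()) - eps, float(y.max()) + eps)
            diff = make_bspline_difficulty(support, ic.n_basis,
                                           np.linspace(-1, 1, ic.n_basis),
                                           data_range=rng)
            items.append(ItemSpec(ic.id, diff))
        else:
            diff = make_parametric_difficulty(
                ic.family, 0.0, 1.0, support,
                transform_const=ic.transform_const, response_function=F)
            items.append(ItemSpec(ic.id, diff))
    return items


# ---------------------------------------------------------------------------
# fit reports


def write_fit_report(fit: FitResult, path, seed: Optional[int] = None) -> None:
    """Serialize a fit to JSON (stable key order, diffable)."""
    report = {
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "sigma_theta": fit.sigma_theta_hat,
        "estimates": fit.item_estimates.to_dict(orient="records"),
        "gamma": ({k: list(map(float, v)) for k, v in fit.gamma.items()}
                  if fit.gamma else None),
        "convergence": {
            "converged": bool(fit.converged),
            "n_iter": int(fit.n_iter),
            "gradient_norm": (None if not np.isfinite(fit.gradient_norm)
                              else float(fit.gradient_norm)),
        },
        "options": fit.options,
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def read_fit_report(path) -> dict:
    """Read back a fit report; estimates return as a DataFrame."""
    with open(path) as fh:
        report = json.load(fh)
    report["estimates"] = pd.DataFrame(report["estimates"])
    return report


def model_from_report(report: dict, cfg: ItemConfigFile,
                      data: Optional[pd.DataFrame] = None):
    """Rebuild the fitted ThresholdsModel from a report + item config.

    The config supplies supports/families (as at fit time), the report the
    estimated parameter values; ``data`` is needed only for continuous
    spline items (knot placement follows the observed range).
    """
    from .model_core import ItemSpec as _ItemSpec, ThresholdsModel

    est = report["estimates"].set_index("parameter")["estimate"]
    templates = build_items(cfg, data=data)
    shared_slope = est.get("slope")
    items = []
    for it in templates:
        d = it.difficulty
        n = d.params.size
        if isinstance(d, BinaryDifficulty):
            pars = [est[f"{it.item_id}:delta0"]]
        elif f"{it.item_id}:delta0" in est.index:
            pars = [est[f"{it.item_id}:delta0"], shared_slope]
        elif f"{it.item_id}:delta[0]" in est.index:
            pars = [est[f"{it.item_id}:delta[0]"], est[f"{it.item_id}:delta[1]"]]
        else:
            pars = [est[f"{it.item_id}:coefs[{l}]"] for l in range(n)]
        alpha = float(est.get(f"{it.item_id}:alpha", 1.0))
        items.append(_ItemSpec(it.item_id, d.with_params(pars), alpha))
    return ThresholdsModel.from_items(items, cfg.response,
                                      float(report["sigma_theta"]))
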