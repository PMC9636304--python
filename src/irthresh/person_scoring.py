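"""Posterior person-parameter estimation.

Given (fitted) item parameters, the posterior of theta for a response
vector y is proportional to prod_i f_i(y_i | theta) times the N(0,
sigma_theta^2) prior, with the continuous density or the discrete pmf per
item — mixed formats go through exactly the same machinery.  EAP is the
posterior mean computed on the Gauss-Hermite grid, MAP the posterior mode
from a 1-D maximization, and the posterior standard deviation comes from
the second posterior moment.  Missing responses simply drop out of the
product; a person with no observed responses gets the prior back (flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .estimation import gauss_hermite
from .model_core import ThresholdsModel, log_density_continuous, pmf_discrete

__all__ = ["PersonScore", "posterior_density", "score_person", "score_persons"]


@dataclass(frozen=True)
class PersonScore:
    theta_eap: float
    theta_map: float
    posterior_sd: float
    prior_only: bool = False


def _log_joint(m: ThresholdsModel, responses: dict, thetas: np.ndarray) -> np.ndarray:
    """log prod_i f_i(y_i | theta) + log prior over a theta grid."""
    thetas = np.asarray(thetas, dtype=float)
    out = stats.norm.logpdf(thetas, scale=m.sigma_theta)
    for item_id, y in responses.items():
        if y is None or (np.isscalar(y) and not np.isfinite(y)):
            continue
        it = m.item(item_id)
        if it.continuous:
            out = out + log_density_continuous(m, item_id, thetas, y)
        else:
            p = pmf_discrete(m, item_id, thetas, int(y))
            out = out + np.log(np.maximum(p, 1e-300))
    return out


def posterior_density(m: ThresholdsModel, responses: dict, theta) -> np.ndarray:
    """Posterior density of theta given the responses, GH-normalized."""
    quad = gauss_hermite(61)
    nodes = quad.theta_nodes(m.sigma_theta)
    # marginal: int prod f_i * prior = (1/sqrt(pi)) sum w_q prod f_i(theta_q)
    log_l = _log_joint(m, responses, nodes) - stats.norm.logpdf(
        nodes, scale=m.sigma_theta)
    log_c = logsumexp(quad.log_weights + log_l)
    return np.exp(_log_joint(m, responses, np.asarray(theta, dtype=float)) - log_c)


def score_person(m: ThresholdsModel, responses: dict,
                 n_nodes: int = 61) -> PersonScore:
    """EAP/MAP ability estimate with posterior standard deviation."""
    observed = {k: v for k, v in responses.items()
                if v is not None and np.isfinite(v)}
    prior_only = len(observed) == 0
    quad = gauss_hermite(n_nodes)
    nodes = quad.theta_nodes(m.sigma_theta)
    log_l = _log_joint(m, observed, nodes) - stats.norm.logpdf(
        nodes, scale=m.sigma_theta)
    logw = quad.log_weights + log_l
    w = np.exp(logw - logsumexp(logw))
    eap = float(np.sum(w * nodes))
    second = float(np.sum(w * nodes ** 2))
    psd = float(np.sqrt(max(second - eap ** 2, 0.0)))

    span = 8.0 * m.sigma_theta
    res = optimize.minimize_scalar(
        lambda t: -_log_joint(m, observed, np.array([t]))[0],
        bounds=(-span, span), method="bounded",
        options=dict(xatol=1e-8))
    return PersonScore(theta_eap=eap, theta_map=float(res.x),
                       posterior_sd=psd, prior_only=prior_only)


def score_persons(m: ThresholdsModel, data, n_nodes: int = 61) -> pd.DataFrame:
    """Score every row of a wide response DataFrame/array."""
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, dtype=float), columns=m.item_ids)
    rows = []
    for _, row in data.iterrows():
        responses = {c: (row[c] if np.isfinite(row[c]) else None)
                     for c in m.item_ids}
        s = score_person(m, responses, n_nodes=n_nodes)
        rows.append(dict(theta_eap=s.theta_eap, theta_map=s.theta_map,
                         posterior_sd=s.posterior_sd,
                         prior_only=s.prior_only))
    return pd.DataFrame(rows, index=data.index)
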