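"""Marginal maximum likelihood estimation for thresholds models.

Item parameters and the latent scale sigma_theta are estimated by maximizing
the marginal log-likelihood

    l = sum_p log  integral  prod_i f_pi(y_pi | theta)  N(0, sigma_theta^2)(theta) dtheta,

where f_pi is the continuous density or the discrete probability mass
function of item i, so mixed-format tests are handled natively.  The
integral is approximated by Gauss-Hermite quadrature with nodes standardized
to the current sigma_theta (theta_q = sqrt(2) * sigma * x_q for physicists'
nodes x_q), and the score function is computed analytically through the
posterior-weight (Fisher) identity

    d l / d pi = sum_p E[ d log f_pi(y_pi | theta) / d pi | y_p ],

the expectation running over the discrete posterior defined by the
quadrature grid.  Optimization is quasi-Newton (BFGS) on an unconstrained
reparameterization: log slopes, log discriminations, log sigma, and
log-increments for ordered threshold/spline coefficients.

Identifiability: when discriminations vary, the first item's alpha is fixed
at 1 and sigma_theta is free; with all alphas fixed at 1, sigma_theta is
free.  Standard errors come from the inverse observed information in the
natural (untransformed) parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .difficulty_functions import (
    BinaryDifficulty,
    BSplineDifficulty,
    FreeOrdinalDifficulty,
    ParametricDifficulty,
)
from .model_core import ItemSpec, ThresholdsModel
from .response_functions import ResponseFunction, make_response_function

__all__ = [
    "QuadratureRule",
    "PenaltyConfig",
    "FitResult",
    "MarginalProblem",
    "gauss_hermite",
    "marginal_loglik",
    "score",
    "fit_mml",
    "penalized_loglik",
    "lrt",
    "aic",
]

_TINY = 1e-300


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Hermite rule in physicists' form: int e^{-x^2} h(x) dx."""

    nodes: np.ndarray
    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    def theta_nodes(self, sigma: float) -> np.ndarray:
        """Latent nodes for an N(0, sigma^2) integral."""
        return np.sqrt(2.0) * sigma * self.nodes

    @property
    def log_weights(self) -> np.ndarray:
        return np.log(self.weights) - 0.5 * np.log(np.pi)


def gauss_hermite(n_nodes: int = 61) -> QuadratureRule:
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return QuadratureRule(nodes=x, weights=w)


@dataclass(frozen=True)
class PenaltyConfig:
    """Shape penalty coupling spline difficulty functions across items.

    P_lambda = lambda * sum_{i>=2} sum_{l>=2}
        [(d_{i,l} - d_{i,l-1}) - (d_{i-1,l} - d_{i-1,l-1})]^2

    Large lambda forces the increments of adjacent spline coefficients to
    agree across items, i.e. shifted (shape-identical) difficulty
    functions; lambda = 0 recovers the plain log-likelihood.
    """

    lam: float = 0.0

    @property
    def active(self) -> bool:
        return self.lam > 0


@dataclass
class FitResult:
    """Outcome of a marginal maximum likelihood fit."""

    model: ThresholdsModel
    loglik: float
    n_params: int
    sigma_theta_hat: float
    item_estimates: pd.DataFrame
    cov: Optional[np.ndarray] = None
    se: Optional[dict] = None
    param_names: Optional[list] = None
    converged: bool = False
    n_iter: int = 0
    gradient_norm: float = np.nan
    gamma: Optional[dict] = None
    options: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


# ---------------------------------------------------------------------------
# parameter blocks and transforms


def _increments_forward(u: np.ndarray) -> np.ndarray:
    v = np.empty_like(u)
    v[0] = u[0]
    if u.size > 1:
        v[1:] = u[0] + np.cumsum(np.exp(u[1:]))
    return v


def _increments_backward(v: np.ndarray) -> np.ndarray:
    u = np.empty_like(v)
    u[0] = v[0]
    if v.size > 1:
        d = np.diff(v)
        u[1:] = np.log(np.maximum(d, 1e-8))
    return u


def _increments_chain(u: np.ndarray, g_nat: np.ndarray) -> np.ndarray:
    # v_r = u_0 + sum_{j<=r} exp(u_j)  =>  dv_r/du_0 = 1, dv_r/du_j = exp(u_j) 1{j<=r}
    g = np.empty_like(g_nat)
    g[0] = g_nat.sum()
    if g_nat.size > 1:
        tail = np.cumsum(g_nat[::-1])[::-1]
        g[1:] = np.exp(u[1:]) * tail[1:]
    return g


class _Block:
    """One contiguous block of the unconstrained parameter vector."""

    def __init__(self, name: str, kind: str, size: int, item: Optional[int] = None):
        self.name = name
        self.kind = kind  # 'id' | 'd0_logslope' | 'increments' | 'log'
        self.size = size
        self.item = item
        self.offset = -1  # filled by layout

    def forward(self, u: np.ndarray) -> np.ndarray:
        if self.kind == "id":
            return u
        if self.kind == "log":
            return np.exp(u)
        if self.kind == "d0_logslope":
            return np.array([u[0], np.exp(u[1])])
        return _increments_forward(u)

    def backward(self, v: np.ndarray) -> np.ndarray:
        if self.kind == "id":
            return np.asarray(v, dtype=float)
        if self.kind == "log":
            return np.log(v)
        if self.kind == "d0_logslope":
            return np.array([v[0], np.log(v[1])])
        return _increments_backward(np.asarray(v, dtype=float))

    def chain(self, u: np.ndarray, g_nat: np.ndarray) -> np.ndarray:
        if self.kind == "id":
            return g_nat
        if self.kind == "log":
            return g_nat * np.exp(u)
        if self.kind == "d0_logslope":
            return np.array([g_nat[0], g_nat[1] * np.exp(u[1])])
        return _increments_chain(u, g_nat)


# ---------------------------------------------------------------------------
# the marginal likelihood problem


class MarginalProblem:
    """Marginal log-likelihood, score and observed information.

    Parameters
    ----------
    items : sequence of ItemSpec
        Templates carrying supports, difficulty families and starting
        values.
    data : DataFrame or ndarray
        Wide persons x items responses; NaN marks missing entries.
    response : str or ResponseFunction
    free_discrimination : bool
        If true, alphas of items 2..I are free (first fixed at 1).
    common_slope : bool
        Share the difficulty slope across all parametric items (requires a
        common family).
    penalty : PenaltyConfig, optional
        Spline shape penalty; requires all items to share a common B-spline
        basis.
    dif_covariates, dif_items : DIF design (persons x q matrix and the item
        ids whose person term becomes theta + x' gamma_i).
    """

    def __init__(self, items: Sequence[ItemSpec], data,
                 response: str | ResponseFunction = "normal",
                 free_discrimination: bool = False,
                 common_slope: bool = False,
                 penalty: Optional[PenaltyConfig] = None,
                 n_nodes: int = 61,
                 dif_covariates=None,
                 dif_items: Optional[Sequence[str]] = None):
        self.items = list(items)
        self.F = (make_response_function(response)
                  if isinstance(response, str) else response)
        self.free_discrimination = bool(free_discrimination)
        self.common_slope = bool(common_slope)
        self.penalty = penalty if (penalty and penalty.active) else None
        self.quad = gauss_hermite(n_nodes)

        self.Y, self.mask = self._coerce_data(data)
        self.P, self.I = self.Y.shape
        if self.I != len(self.items):
            raise ValueError("data columns do not match item list")
        self._validate_supports()

        # DIF design
        if dif_covariates is not None:
            X = np.asarray(dif_covariates, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if X.shape[0] != self.P:
                raise ValueError("covariate rows do not align with response rows")
            if np.any(np.std(X, axis=0) < 1e-12):
                raise ValueError("constant covariate column: confounded with "
                                 "the item intercept, remove it")
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError("collinear covariate columns")
            self.X = X
            ids = self.item_ids()
            self.dif_idx = [ids.index(i) for i in (dif_items or [])]
        else:
            self.X = None
            self.dif_idx = []

        if self.common_slope:
            fams = {it.difficulty.family for it in self.items
                    if isinstance(it.difficulty, ParametricDifficulty)}
            if len(fams) != 1:
                raise ValueError("common_slope needs all items parametric "
                                 "with one shared family")
        if self.penalty is not None:
            if not all(isinstance(it.difficulty, BSplineDifficulty)
                       for it in self.items):
                raise ValueError("the shape penalty requires B-spline "
                                 "difficulties for all items")
            knots = [it.difficulty.knots for it in self.items]
            if not all(np.allclose(knots[0], k) for k in knots):
                raise ValueError("the shape penalty requires a common "
                                 "B-spline basis across items")

        self._build_blocks()
        self._precompute_designs()

    # -- setup -------------------------------------------------------------
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @staticmethod
    def _coerce_data(data):
        if isinstance(data, pd.DataFrame):
            arr = data.to_numpy(dtype=float)
        else:
            arr = np.asarray(data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("responses must be a persons x items matrix")
        mask = np.isfinite(arr)
        return arr, mask

    def _validate_supports(self):
        for j, it in enumerate(self.items):
            y = self.Y[self.mask[:, j], j]
            ok = it.support.contains(y)
            if not np.all(ok):
                p = np.nonzero(self.mask[:, j])[0][~ok][0]
                raise ValueError(
                    f"response {self.Y[p, j]!r} of person {p} outside the "
                    f"support of item {it.item_id!r}")

    def _build_blocks(self):
        blocks: list[_Block] = []
        for j, it in enumerate(self.items):
            d = it.difficulty
            if isinstance(d, BinaryDifficulty):
                blocks.append(_Block(f"{it.item_id}:delta0", "id", 1, j))
            elif isinstance(d, ParametricDifficulty):
                if self.common_slope:
                    blocks.append(_Block(f"{it.item_id}:delta0", "id", 1, j))
                else:
                    blocks.append(_Block(f"{it.item_id}:delta", "d0_logslope", 2, j))
            elif isinstance(d, (FreeOrdinalDifficulty, BSplineDifficulty)):
                blocks.append(_Block(f"{it.item_id}:coefs", "increments",
                                     d.params.size, j))
            else:  # pragma: no cover - defensive
                raise TypeError(f"unsupported difficulty {type(d).__name__}")
        if self.common_slope:
            blocks.append(_Block("slope", "log", 1, None))
        if self.free_discrimination:
            for j in range(1, self.I):
                blocks.append(_Block(f"{self.items[j].item_id}:alpha", "log", 1, j))
        blocks.append(_Block("sigma_theta", "log", 1, None))
        if self.X is not None:
            for j in self.dif_idx:
                blocks.append(_Block(f"{self.items[j].item_id}:gamma", "id",
                                     self.X.shape[1], j))
        off = 0
        for b in blocks:
            b.offset = off
            off += b.size
        self.blocks = blocks
        self.n_free = off

    def _precompute_designs(self):
        """Design matrices Phi at the observed responses, per item."""
        self._design = []
        for j, it in enumerate(self.items):
            d = it.difficulty
            y = self.Y[:, j]
            obs = self.mask[:, j]
            ysafe = np.where(obs, y, _safe_value(it))
            if it.continuous:
                Phi = d.design_matrix(ysafe)
                Phid = d.design_matrix_deriv(ysafe)
                self._design.append(dict(kind="cont", Phi=Phi, Phid=Phid))
            else:
                top = it.support.top
                m0 = obs & (ysafe > 0)           # has a finite lower threshold
                mt = obs & ((top is None) | (ysafe < (top if top is not None else np.inf)))
                Phim1 = d.design_matrix(np.where(m0, ysafe - 1, 0))
                Phim1[~m0] = 0.0
                Phiy = d.design_matrix(np.where(mt, ysafe, 0))
                Phiy[~mt] = 0.0
                self._design.append(dict(kind="disc", Phim1=Phim1, Phiy=Phiy,
                                         m0=m0, mt=mt))

    # -- parameter plumbing -------------------------------------------------
    def natural_from_items(self, items: Sequence[ItemSpec], sigma: float,
                           gamma: Optional[dict] = None) -> np.ndarray:
        """Collect the natural parameter vector from ItemSpecs + sigma."""
        v = np.zeros(self.n_free)
        for b in self.blocks:
            if b.kind == "id" and b.name.endswith(":gamma"):
                g = (gamma or {}).get(self.items[b.item].item_id,
                                      np.zeros(b.size))
                v[b.offset:b.offset + b.size] = g
            elif b.name == "slope":
                slopes = [it.difficulty.slope for it in items
                          if isinstance(it.difficulty, ParametricDifficulty)]
                v[b.offset] = slopes[0]
            elif b.name == "sigma_theta":
                v[b.offset] = sigma
            elif b.name.endswith(":alpha"):
                v[b.offset] = items[b.item].discrimination
            elif b.name.endswith(":delta0"):
                d = items[b.item].difficulty
                v[b.offset] = d.params[0]
            else:
                v[b.offset:b.offset + b.size] = items[b.item].difficulty.params
        return v

    def unconstrained_from_natural(self, v: np.ndarray) -> np.ndarray:
        x = np.zeros_like(v)
        for b in self.blocks:
            sl = slice(b.offset, b.offset + b.size)
            x[sl] = b.backward(v[sl])
        return x

    def natural_from_unconstrained(self, x: np.ndarray) -> np.ndarray:
        v = np.zeros_like(x)
        for b in self.blocks:
            sl = slice(b.offset, b.offset + b.size)
            v[sl] = b.forward(x[sl])
        return v

    def param_names(self) -> list[str]:
        names = []
        for b in self.blocks:
            if b.size == 1:
                names.append(b.name)
            else:
                names.extend(f"{b.name}[{l}]" for l in range(b.size))
        return names

    def _structure(self, v: np.ndarray):
        """Split a natural vector into per-item params, alphas, sigma, gammas."""
        diff_params = [None] * self.I
        alphas = np.ones(self.I)
        sigma = 1.0
        gammas = {}
        shared_slope = None
        for b in self.blocks:
            seg = v[b.offset:b.offset + b.size]
            if b.name == "slope":
                shared_slope = seg[0]
            elif b.name == "sigma_theta":
                sigma = seg[0]
            elif b.name.endswith(":alpha"):
                alphas[b.item] = seg[0]
            elif b.name.endswith(":gamma"):
                gammas[b.item] = seg.copy()
            elif b.name.endswith(":delta0"):
                diff_params[b.item] = seg.copy()
            else:
                diff_params[b.item] = seg.copy()
        if shared_slope is not None:
            for j in range(self.I):
                if (isinstance(self.items[j].difficulty, ParametricDifficulty)
                        and diff_params[j].size == 1):
                    diff_params[j] = np.array([diff_params[j][0], shared_slope])
        return diff_params, alphas, sigma, gammas

    def model_at(self, v: np.ndarray) -> tuple[ThresholdsModel, dict]:
        """Materialize a ThresholdsModel from a natural parameter vector."""
        diff_params, alphas, sigma, gammas = self._structure(v)
        new_items = []
        for j, it in enumerate(self.items):
            d = it.difficulty.with_params(diff_params[j])
            new_items.append(ItemSpec(it.item_id, d, alphas[j]))
        model = ThresholdsModel(tuple(new_items), self.F, sigma)
        g = {self.items[j].item_id: gammas[j] for j in gammas}
        return model, g

    # -- core evaluation ----------------------------------------------------
    def _eval_natural(self, v: np.ndarray, want_grad: bool = True):
        diff_params, alphas, sigma, gammas = self._structure(v)
        F, quad = self.F, self.quad
        TH = quad.theta_nodes(sigma)                       # (Q,)
        Q = TH.size
        logw = quad.log_weights

        A = np.zeros((self.P, Q))
        per_item = []
        for j, it in enumerate(self.items):
            pars = diff_params[j]
            a = alphas[j]
            dsg = self._design[j]
            obs = self.mask[:, j]
            off = None
            if j in gammas:
                off = self.X @ gammas[j]
            t = TH[None, :] if off is None else off[:, None] + TH[None, :]

            if dsg["kind"] == "cont":
                dy = dsg["Phi"] @ pars                     # (P,)
                dd = dsg["Phid"] @ pars
                eta = a * (t - dy[:, None])
                logf = F.logpdf(eta) + np.log(a) + np.log(dd)[:, None]
                rec = dict(kind="cont")
                if want_grad:
                    r1 = F.dlogpdf(eta)
                    rec.update(r1=r1, eta_arg=t - dy[:, None], dd=dd, a=a)
            else:
                m0, mt = dsg["m0"], dsg["mt"]
                dm1 = np.where(m0, dsg["Phim1"] @ pars, -np.inf)
                dyv = np.where(mt, dsg["Phiy"] @ pars, np.inf)
                # eta at the two thresholds; masked infinities handled apart
                tm1 = np.where(m0, dm1, 0.0)
                tyv = np.where(mt, dyv, 0.0)
                eta_u = a * (t - tm1[:, None])
                eta_l = a * (t - tyv[:, None])
                Fu = np.where(m0[:, None], F.cdf(eta_u), 1.0)
                Fl = np.where(mt[:, None], F.cdf(eta_l), 0.0)
                f = np.maximum(Fu - Fl, _TINY)
                logf = np.log(f)
                rec = dict(kind="disc")
                if want_grad:
                    phu = np.where(m0[:, None], F.density(eta_u), 0.0)
                    phl = np.where(mt[:, None], F.density(eta_l), 0.0)
                    rec.update(f=f, phu=phu, phl=phl, a=a,
                               arg_u=np.where(m0[:, None], t - tm1[:, None], 0.0),
                               arg_l=np.where(mt[:, None], t - tyv[:, None], 0.0))
            logf = np.where(obs[:, None], logf, 0.0)
            A += logf
            per_item.append(rec)

        A += logw[None, :]
        c = logsumexp(A, axis=1)                           # (P,)
        ll = float(c.sum())
        pen = 0.0
        if self.penalty is not None:
            pen, pen_grads = self._penalty_value_grads(diff_params)
            ll -= pen
        if not want_grad:
            return ll

        R = np.exp(A - c[:, None])                         # posterior weights
        gnat = np.zeros(self.n_free)
        sum_dtheta = np.zeros((self.P, Q))

        for j, it in enumerate(self.items):
            dsg = self._design[j]
            rec = per_item[j]
            obs = self.mask[:, j][:, None]
            a = rec["a"]
            if rec["kind"] == "cont":
                r1 = rec["r1"]
                dd = rec["dd"]
                W = np.where(obs, R, 0.0)
                # difficulty params: -a r1 Phi_j + Phid_j / dd
                t1 = (W * (-a * r1)).sum(axis=1)           # (P,)
                gd = dsg["Phi"].T @ t1 + dsg["Phid"].T @ ((W.sum(axis=1)) / dd)
                ga = (W * (r1 * rec["eta_arg"] + 1.0 / a)).sum()
                dth = np.where(obs, a * r1, 0.0)
            else:
                f, phu, phl = rec["f"], rec["phu"], rec["phl"]
                W = np.where(obs, R, 0.0)
                # d logf / d delta_param = (-a phu Phim1 + a phl Phiy)/f
                gu = (W * (-a * phu / f)).sum(axis=1)
                gl = (W * (a * phl / f)).sum(axis=1)
                gd = dsg["Phim1"].T @ gu + dsg["Phiy"].T @ gl
                ga = (W * ((rec["arg_u"] * phu - rec["arg_l"] * phl) / f)).sum()
                dth = np.where(obs, a * (phu - phl) / f, 0.0)
            sum_dtheta += dth
            # scatter into natural gradient
            for b in self.blocks:
                if b.item != j:
                    continue
                if b.name.endswith(":alpha"):
                    gnat[b.offset] += ga
                elif b.name.endswith(":gamma"):
                    per_p = (R * dth).sum(axis=1)          # (P,)
                    gnat[b.offset:b.offset + b.size] += self.X.T @ per_p
                elif b.name.endswith(":delta0"):
                    gnat[b.offset] += gd[0]
                else:
                    gnat[b.offset:b.offset + b.size] += gd
            if self.common_slope and not isinstance(it.difficulty, BinaryDifficulty):
                sb = next(b for b in self.blocks if b.name == "slope")
                gnat[sb.offset] += gd[1]

        # sigma via theta_q = sqrt(2) sigma x_q
        dtheta_dsigma = np.sqrt(2.0) * self.quad.nodes     # (Q,)
        sb = next(b for b in self.blocks if b.name == "sigma_theta")
        gnat[sb.offset] = float((R * sum_dtheta * dtheta_dsigma[None, :]).sum())

        if self.penalty is not None:
            for j in range(self.I):
                for b in self.blocks:
                    if b.item == j and b.kind == "increments":
                        gnat[b.offset:b.offset + b.size] -= pen_grads[j]
        return ll, gnat

    def _penalty_value_grads(self, diff_params):
        lam = self.penalty.lam
        C = np.vstack(diff_params)                         # (I, M+1)
        D = np.diff(C, axis=1)                             # increments (I, M)
        E = np.diff(D, axis=0)                             # (I-1, M)
        # only l >= 2 (skip the first increment) enters the penalty
        E2 = E[:, 1:]
        val = lam * float((E2 ** 2).sum())
        gD = np.zeros_like(D)
        gD[1:, 1:] += 2.0 * lam * E2
        gD[:-1, 1:] -= 2.0 * lam * E2
        gC = np.zeros_like(C)
        gC[:, 1:] += gD
        gC[:, :-1] -= gD
        return val, list(gC)

    # -- public surface ------------------------------------------------------
    def loglik(self, x: np.ndarray) -> float:
        """Marginal (penalized) log-likelihood at unconstrained x."""
        return self._eval_natural(self.natural_from_unconstrained(x),
                                  want_grad=False)

    def loglik_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        v = self.natural_from_unconstrained(x)
        ll, gnat = self._eval_natural(v, want_grad=True)
        g = np.zeros_like(gnat)
        for b in self.blocks:
            sl = slice(b.offset, b.offset + b.size)
            g[sl] = b.chain(x[sl], gnat[sl])
        return ll, g

    def loglik_natural(self, v: np.ndarray) -> float:
        return self._eval_natural(v, want_grad=False)

    def grad_natural(self, v: np.ndarray) -> np.ndarray:
        return self._eval_natural(v, want_grad=True)[1]

    def observed_information(self, v: np.ndarray) -> np.ndarray:
        """-Hessian of the log-likelihood at natural parameters v.

        Central finite differences of the analytic score; the score itself
        is exact, so the Hessian is accurate to O(h^2)."""
        n = v.size
        H = np.zeros((n, n))
        for i in range(n):
            h = 1e-5 * max(1.0, abs(v[i]))
            vp, vm = v.copy(), v.copy()
            vp[i] += h
            vm[i] -= h
            H[:, i] = (self.grad_natural(vp) - self.grad_natural(vm)) / (2 * h)
        H = 0.5 * (H + H.T)
        return -H

    def n_model_params(self) -> int:
        """Free parameter count entering AIC (gammas included when present)."""
        return self.n_free

    def default_start(self) -> np.ndarray:
        """Starting values: intercepts from response means through g,
        slopes/alphas/sigma at 1, spline coefs from standardized responses."""
        items = []
        for j, it in enumerate(self.items):
            y = self.Y[self.mask[:, j], j]
            d = it.difficulty
            if isinstance(d, BinaryDifficulty):
                p = np.clip(y.mean() if y.size else 0.5, 0.05, 0.95)
                items.append(ItemSpec(it.item_id, d.with_params(
                    [-float(self.F.quantile(p))]), 1.0))
            elif isinstance(d, ParametricDifficulty):
                m = float(np.mean(y)) if y.size else 1.0
                m = _clip_to_interior(m, it)
                g = float(d._g(m))
                items.append(ItemSpec(it.item_id, d.with_params([-g, 1.0]), 1.0))
            elif isinstance(d, FreeOrdinalDifficulty):
                k = d.support.top
                v = []
                for r in range(1, k + 1):
                    p = np.clip(np.mean(y >= r) if y.size else 0.5, 0.02, 0.98)
                    v.append(-float(self.F.quantile(p)))
                v = np.maximum.accumulate(v) + 1e-3 * np.arange(k)
                items.append(ItemSpec(it.item_id, d.with_params(v), 1.0))
            else:  # BSpline
                mu = float(np.mean(y)) if y.size else 0.0
                sd = float(np.std(y)) if y.size > 1 else 1.0
                sd = max(sd, 1e-2)
                t, p = d.knots, d.degree
                greville = np.array([t[l + 1:l + p + 1].mean()
                                     for l in range(d.params.size)])
                coefs = (greville - mu) / sd
                coefs = np.maximum.accumulate(coefs)
                coefs += 1e-3 * np.arange(coefs.size)
                items.append(ItemSpec(it.item_id, d.with_params(coefs), 1.0))
        v0 = self.natural_from_items(items, 1.0)
        return self.unconstrained_from_natural(v0)


def _safe_value(it: ItemSpec):
    """An in-support placeholder for missing entries (masked out later)."""
    s = it.support
    if s.kind == "real":
        return 0.0
    if s.kind == "positive":
        return 1.0
    if s.kind == "unit_interval":
        return 0.5
    return 0.0


def _clip_to_interior(m: float, it: ItemSpec) -> float:
    s = it.support
    if s.kind == "positive":
        return max(m, 1e-3)
    if s.kind == "unit_interval":
        return min(max(m, 1e-3), 1 - 1e-3)
    if s.kind == "ordinal":
        return min(max(m, 0.2), s.k - 0.2)
    if s.kind == "count":
        return max(m, 0.2)
    return m


# ---------------------------------------------------------------------------
# module-level operations


def marginal_loglik(m: ThresholdsModel, data, n_nodes: int = 61,
                    gamma: Optional[dict] = None, dif_covariates=None) -> float:
    """GH-approximated marginal log-likelihood of a fixed model."""
    prob = MarginalProblem(m.items, data, response=m.response_function,
                           n_nodes=n_nodes, dif_covariates=dif_covariates,
                           dif_items=list(gamma) if gamma else None)
    v = prob.natural_from_items(m.items, m.sigma_theta, gamma=gamma)
    return prob.loglik_natural(v)


def score(m: ThresholdsModel, data, n_nodes: int = 61,
          free_discrimination: bool = False,
          common_slope: bool = False) -> np.ndarray:
    """Analytic score in the unconstrained parameterization at the model's
    current parameter values."""
    prob = MarginalProblem(m.items, data, response=m.response_function,
                           n_nodes=n_nodes,
                           free_discrimination=free_discrimination,
                           common_slope=common_slope)
    v = prob.natural_from_items(m.items, m.sigma_theta)
    x = prob.unconstrained_from_natural(v)
    return prob.loglik_grad(x)[1]


def fit_mml(data, items: Sequence[ItemSpec],
            response: str | ResponseFunction = "normal",
            free_discrimination: bool = False,
            common_slope: bool = False,
            penalty: Optional[PenaltyConfig] = None,
            n_nodes: int = 61,
            dif_covariates=None,
            dif_items: Optional[Sequence[str]] = None,
            start: Optional[np.ndarray] = None,
            compute_cov: bool = True,
            gtol: float = 1e-5,
            max_iter: int = 500,
            verbose: bool = False) -> FitResult:
    """Fit a thresholds model by marginal maximum likelihood.

    ``items`` are templates: their supports and difficulty families define
    the model, their parameter values are ignored unless ``start`` is given.
    Returns a :class:`FitResult`; non-convergence is reported through
    ``converged=False`` with diagnostics, not raised.
    """
    prob = MarginalProblem(items, data, response=response,
                           free_discrimination=free_discrimination,
                           common_slope=common_slope, penalty=penalty,
                           n_nodes=n_nodes, dif_covariates=dif_covariates,
                           dif_items=dif_items)
    x0 = prob.default_start() if start is None else np.asarray(start, float)

    trace = []

    def neg(x):
        ll, g = prob.loglik_grad(x)
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(g)
        return -ll, -g

    def cb(xk):
        if verbose:
            ll = prob.loglik(xk)
            trace.append(ll)
            print(f"iter {len(trace):3d}  loglik {ll:.6f}")

    res = optimize.minimize(neg, x0, jac=True, method="BFGS",
                            callback=cb if verbose else None,
                            options=dict(gtol=gtol, maxiter=max_iter))
    x_hat = res.x
    v_hat = prob.natural_from_unconstrained(x_hat)
    model, gamma = prob.model_at(v_hat)
    ll_pen = prob.loglik(x_hat)
    # report the *unpenalized* marginal loglik; with no penalty they coincide
    ll = ll_pen if prob.penalty is None else _unpenalized(prob, v_hat)

    names = prob.param_names()
    cov = se = None
    if compute_cov:
        try:
            H = prob.observed_information(v_hat)
            cov = np.linalg.inv(H)
            se = dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))
        except np.linalg.LinAlgError:
            cov = se = None

    est = _estimates_table(prob, model, names, v_hat, se)
    grad_norm = float(np.max(np.abs(res.jac)))
    return FitResult(
        model=model,
        loglik=float(ll),
        n_params=prob.n_model_params(),
        sigma_theta_hat=float(model.sigma_theta),
        item_estimates=est,
        cov=cov,
        se=se,
        param_names=names,
        converged=bool(res.success) or grad_norm < 1e-3,
        n_iter=int(res.nit),
        gradient_norm=grad_norm,
        gamma=gamma or None,
        options=dict(response=prob.F.name, n_nodes=n_nodes,
                     free_discrimination=free_discrimination,
                     common_slope=common_slope,
                     penalty_lambda=(penalty.lam if penalty else 0.0)),
    )


def _unpenalized(prob: MarginalProblem, v: np.ndarray) -> float:
    saved = prob.penalty
    prob.penalty = None
    try:
        return prob.loglik_natural(v)
    finally:
        prob.penalty = saved


def _estimates_table(prob, model, names, v, se) -> pd.DataFrame:
    rows = []
    for b in prob.blocks:
        seg = v[b.offset:b.offset + b.size]
        for l in range(b.size):
            nm = b.name if b.size == 1 else f"{b.name}[{l}]"
            rows.append(dict(
                parameter=nm,
                item=(prob.items[b.item].item_id if b.item is not None else ""),
                estimate=seg[l],
                se=(se.get(nm, np.nan) if se else np.nan),
            ))
    return pd.DataFrame(rows)


def penalized_loglik(m: ThresholdsModel, data, pen: PenaltyConfig,
                     n_nodes: int = 61) -> float:
    """Marginal log-likelihood minus the spline shape penalty."""
    prob = MarginalProblem(m.items, data, response=m.response_function,
                           penalty=pen if pen.active else None,
                           n_nodes=n_nodes)
    v = prob.natural_from_items(m.items, m.sigma_theta)
    return prob.loglik_natural(v)


def lrt(full: FitResult, reduced: FitResult) -> tuple[float, int]:
    """Likelihood ratio statistic 2(l_full - l_reduced) and df."""
    df = full.n_params - reduced.n_params
    stat = 2.0 * (full.loglik - reduced.loglik)
    if df < 0:
        raise ValueError("the reduced model has more parameters than the full")
    if stat < -1e-6 * max(1.0, abs(full.loglik)):
        raise ValueError(
            f"full-model loglik below reduced-model loglik (stat={stat:.4g}); "
            "models not nested or optimization did not converge")
    return max(stat, 0.0), df


def aic(fit: FitResult) -> float:
    return fit.aic
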