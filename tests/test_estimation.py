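"""Marginal likelihood, analytic score, fitting, penalties, model tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from irthresh import (
    FitResult,
    ItemSpec,
    MarginalProblem,
    PenaltyConfig,
    SimulationConfig,
    ThresholdsModel,
    aic,
    fit_mml,
    gauss_hermite,
    generate_dataset,
    lrt,
    marginal_loglik,
    penalized_loglik,
)
from irthresh.difficulty_functions import (
    BinaryDifficulty,
    FreeOrdinalDifficulty,
    SupportSpec,
    make_bspline_difficulty,
    make_parametric_difficulty,
)
from irthresh.model_core import density_continuous, pmf_discrete


def mixed_items():
    return [
        ItemSpec("cont", make_parametric_difficulty(
            "linear", -0.5, 1.2, SupportSpec("real"))),
        ItemSpec("bin", BinaryDifficulty(0.3)),
        ItemSpec("ord", FreeOrdinalDifficulty([-1.0, 0.2, 1.1])),
        ItemSpec("cnt", make_parametric_difficulty(
            "log1p", -1.5, 1.1, SupportSpec("count"))),
    ]


@pytest.fixture(scope="module")
def mixed_data():
    items = mixed_items()
    m = ThresholdsModel.from_items(items, "normal", 1.3)
    data, theta, _ = generate_dataset(SimulationConfig(m, 30, seed=7))
    data.iloc[0, 0] = np.nan
    return items, m, data


def trapezoid_loglik(model, data):
    """Independent marginal-likelihood oracle on a fine theta grid."""
    sig = model.sigma_theta
    grid = np.linspace(-9 * sig, 9 * sig, 4001)
    prior = stats.norm.pdf(grid, scale=sig)
    total = 0.0
    for _, row in data.iterrows():
        like = np.ones_like(grid)
        for it in model.items:
            y = row[it.item_id]
            if not np.isfinite(y):
                continue
            if it.continuous:
                like = like * density_continuous(model, it.item_id, grid, y)
            else:
                like = like * pmf_discrete(model, it.item_id, grid, int(y))
        total += np.log(np.trapezoid(like * prior, grid))
    return total


class TestMarginalLoglik:
    def test_matches_trapezoid_oracle(self, mixed_data):
        _, m, data = mixed_data
        gh = marginal_loglik(m, data, n_nodes=61)
        tz = trapezoid_loglik(m, data)
        assert abs(gh - tz) < 1e-6

    def test_degenerate_sigma_single_binary(self):
        items = [ItemSpec("b", BinaryDifficulty(0.0))]
        m = ThresholdsModel.from_items(items, "normal", 1e-8)
        data = pd.DataFrame({"b": [1.0]})
        assert marginal_loglik(m, data) == pytest.approx(np.log(0.5), abs=1e-8)

    def test_invariant_to_item_order(self, mixed_data):
        items, m, data = mixed_data
        perm = [2, 0, 3, 1]
        m2 = ThresholdsModel.from_items([m.items[i] for i in perm],
                                        "normal", m.sigma_theta)
        data2 = data[[m.items[i].item_id for i in perm]]
        assert marginal_loglik(m, data) == pytest.approx(
            marginal_loglik(m2, data2), abs=1e-10)

    def test_gh_node_convergence(self, mixed_data):
        items, m, data = mixed_data
        # bounded-support items: 41 nodes already converged
        sub = [it for it in m.items if it.item_id != "cnt"]
        msub = ThresholdsModel.from_items(sub, "normal", m.sigma_theta)
        dsub = data[[it.item_id for it in sub]]
        assert abs(marginal_loglik(msub, dsub, n_nodes=41)
                   - marginal_loglik(msub, dsub, n_nodes=81)) < 1e-6
        # the count item's wide response range needs the default 61 nodes
        assert abs(marginal_loglik(m, data, n_nodes=61)
                   - marginal_loglik(m, data, n_nodes=101)) < 1e-6

    def test_support_violation_reported(self, mixed_data):
        items, _, data = mixed_data
        bad = data.copy()
        bad.iloc[3, 1] = 2.0  # binary item with an illegal response
        with pytest.raises(ValueError, match="person 3"):
            MarginalProblem(items, bad, response="normal")


class TestScore:
    @pytest.mark.parametrize("opts", [
        dict(),
        dict(free_discrimination=True),
        dict(common_slope=False, response="logistic"),
    ])
    def test_matches_finite_differences(self, mixed_data, opts):
        items, _, data = mixed_data
        kwargs = dict(response="normal")
        kwargs.update(opts)
        prob = MarginalProblem(items, data, **kwargs)
        x0 = prob.default_start() + 0.05
        _, g = prob.loglik_grad(x0)
        for i in range(x0.size):
            h = 1e-6
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            fd = (prob.loglik(xp) - prob.loglik(xm)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_all_missing_item_has_zero_gradient(self):
        items = [ItemSpec("a", BinaryDifficulty(0.0)),
                 ItemSpec("b", BinaryDifficulty(0.0))]
        data = pd.DataFrame({"a": [0.0, 1.0, 1.0], "b": [np.nan] * 3})
        prob = MarginalProblem(items, data, response="normal")
        _, g = prob.loglik_grad(prob.default_start())
        names = prob.param_names()
        assert g[names.index("b:delta0")] == 0.0

    def test_small_gradient_at_truth_for_large_n(self):
        norms = []
        for seed in range(5):
            items = [ItemSpec(f"i{j}", BinaryDifficulty(-0.5 + 0.5 * j))
                     for j in range(4)]
            m = ThresholdsModel.from_items(items, "normal", 1.0)
            data, _, _ = generate_dataset(SimulationConfig(m, 2000, seed=seed))
            prob = MarginalProblem(items, data, response="normal")
            v = prob.natural_from_items(items, 1.0)
            g = prob.grad_natural(v)
            norms.append(np.max(np.abs(g)) / 2000)
        # score at the truth is O_p(sqrt(n)); per-person it vanishes
        assert np.median(norms) < 0.1


class TestFitMml:
    def test_count_recovery_fixed_alpha(self):
        from irthresh.simulate import preset_count
        m = preset_count()
        truth = {it.item_id: it.difficulty.params for it in m.items}
        data, _, _ = generate_dataset(SimulationConfig(m, 200, seed=12))
        fit = fit_mml(data, m.items, response="normal")
        assert fit.converged
        est = fit.item_estimates.set_index("parameter")["estimate"]
        ses = fit.item_estimates.set_index("parameter")["se"]
        within = 0
        total = 0
        for iid, pars in truth.items():
            for l, name in enumerate([f"{iid}:delta[0]", f"{iid}:delta[1]"]):
                total += 1
                within += abs(est[name] - pars[l]) <= 3 * ses[name]
        assert within >= total - 1

    def test_refit_from_optimum_is_fixed_point(self):
        items = [ItemSpec(f"i{j}", BinaryDifficulty(-0.4 + 0.4 * j))
                 for j in range(3)]
        m = ThresholdsModel.from_items(items, "normal", 1.0)
        data, _, _ = generate_dataset(SimulationConfig(m, 150, seed=3))
        fit1 = fit_mml(data, items, response="normal", compute_cov=False)
        prob = MarginalProblem(fit1.model.items, data, response="normal")
        v = prob.natural_from_items(fit1.model.items, fit1.sigma_theta_hat)
        fit2 = fit_mml(data, items, response="normal", compute_cov=False,
                       start=prob.unconstrained_from_natural(v))
        assert abs(fit2.loglik - fit1.loglik) < 1e-6

    def test_monotone_objective_trace(self):
        # BFGS with line search: the penalized loglik never decreases
        items = [ItemSpec(f"i{j}", BinaryDifficulty(0.0)) for j in range(3)]
        m = ThresholdsModel.from_items(items, "normal", 1.0)
        data, _, _ = generate_dataset(SimulationConfig(m, 120, seed=5))
        prob = MarginalProblem(items, data, response="normal")
        from scipy import optimize
        trace = []

        def neg(x):
            ll, g = prob.loglik_grad(x)
            return -ll, -g

        optimize.minimize(neg, prob.default_start(), jac=True, method="BFGS",
                          callback=lambda xk: trace.append(prob.loglik(xk)))
        assert np.all(np.diff(trace) > -1e-9)

    def test_varying_alpha_separates_parameters(self):
        from irthresh.simulate import preset_count
        rs, ri, rsl = [], [], []
        for seed in (21, 22, 23):
            m = preset_count(varying_alpha=True)
            data, _, _ = generate_dataset(SimulationConfig(m, 400, seed=seed))
            fit = fit_mml(data, m.items, response="normal",
                          free_discrimination=True, compute_cov=False)
            true_alpha = [it.discrimination for it in m.items][1:]
            est = fit.item_estimates.set_index("parameter")["estimate"]
            got_alpha = [est[f"{it.item_id}:alpha"] for it in m.items[1:]]
            ri.append(np.corrcoef(
                [it.difficulty.intercept for it in m.items],
                [est[f"{it.item_id}:delta[0]"] for it in m.items])[0, 1])
            rsl.append(np.corrcoef(
                [it.difficulty.slope for it in m.items],
                [est[f"{it.item_id}:delta[1]"] for it in m.items])[0, 1])
            rs.append(np.corrcoef(true_alpha, got_alpha)[0, 1])
        assert np.median(ri) > 0.7
        assert np.median(rsl) > 0.7
        assert np.median(rs) > 0.7

    def test_se_within_factor_two_of_empirical_sd(self):
        # observed-information SEs vs spread of estimates across seeds
        from irthresh.simulate import preset_count
        m = preset_count()
        ests, ses = [], []
        for seed in range(50):
            data, _, _ = generate_dataset(SimulationConfig(m, 200, seed=seed))
            fit = fit_mml(data, m.items, response="normal",
                          compute_cov=(seed == 0))
            tab = fit.item_estimates.set_index("parameter")
            ests.append(tab["estimate"]["item1:delta[0]"])
            if seed == 0:
                ses.append(tab["se"]["item1:delta[0]"])
        emp = np.std(ests)
        assert ses[0] / emp < 2 and emp / ses[0] < 2


@pytest.fixture(scope="module")
def spline_setup():
    sup = SupportSpec("ordinal", k=6)
    base = np.array([-2.0, -1.2, -0.5, 0.1, 0.9, 1.8])
    items = [ItemSpec(f"s{j}", make_bspline_difficulty(sup, 6, base + 0.3 * j))
             for j in range(3)]
    m = ThresholdsModel.from_items(items, "normal", 1.0)
    data, _, _ = generate_dataset(SimulationConfig(m, 120, seed=11))
    return items, m, data


class TestPenalty:
    def test_lambda_zero_equals_plain_loglik(self, spline_setup):
        items, m, data = spline_setup
        plain = marginal_loglik(m, data)
        pen = penalized_loglik(m, data, PenaltyConfig(0.0))
        assert pen == pytest.approx(plain, abs=1e-12)

    def test_identical_coefs_zero_penalty(self, spline_setup):
        items, m, data = spline_setup
        same = [ItemSpec(it.item_id, m.items[0].difficulty, 1.0)
                for it in m.items]
        ms = ThresholdsModel.from_items(same, "normal", 1.0)
        assert penalized_loglik(ms, data, PenaltyConfig(1e4)) == pytest.approx(
            marginal_loglik(ms, data), abs=1e-9)

    def test_large_lambda_gives_shifted_shapes(self, spline_setup):
        items, _, data = spline_setup
        fit = fit_mml(data, items, response="normal",
                      penalty=PenaltyConfig(1e6), compute_cov=False)
        incs = np.array([np.diff(it.difficulty.params)
                         for it in fit.model.items])
        # increments beyond the first agree across items
        assert np.ptp(incs[:, 1:], axis=0).max() < 1e-2

    def test_mixed_bases_rejected(self, spline_setup):
        items, _, data = spline_setup
        other = list(items)
        other[0] = ItemSpec("s0", make_parametric_difficulty(
            "log1p", 0.0, 1.0, SupportSpec("ordinal", k=6)))
        with pytest.raises(ValueError):
            MarginalProblem(other, data, response="normal",
                            penalty=PenaltyConfig(1.0))


class TestModelComparison:
    def test_identical_models_stat_zero(self, mixed_data):
        items, m, data = mixed_data
        fit = fit_mml(data, items, response="normal", compute_cov=False)
        stat, df = lrt(fit, fit)
        assert stat == 0.0 and df == 0

    def test_aic_bookkeeping(self):
        dummy = ThresholdsModel.from_items([ItemSpec("b", BinaryDifficulty(0))])
        f = FitResult(model=dummy, loglik=-1445.832, n_params=13,
                      sigma_theta_hat=1.0, item_estimates=pd.DataFrame())
        assert aic(f) == pytest.approx(2917.664)
        f0 = FitResult(model=dummy, loglik=0.0, n_params=0,
                       sigma_theta_hat=1.0, item_estimates=pd.DataFrame())
        assert aic(f0) == 0.0
        f1 = FitResult(model=dummy, loglik=-1445.832, n_params=14,
                       sigma_theta_hat=1.0, item_estimates=pd.DataFrame())
        assert aic(f1) == pytest.approx(2919.664)

    def test_n_params_bookkeeping(self, mixed_data):
        items, _, data = mixed_data
        # binary 1 + parametric 2 + free_ordinal 3 + count 2 + sigma = 9
        prob = MarginalProblem(items, data, response="normal")
        assert prob.n_model_params() == 9
        # free discrimination adds I - 1 = 3 (first alpha fixed)
        prob2 = MarginalProblem(items, data, response="normal",
                                free_discrimination=True)
        assert prob2.n_model_params() == 12

    def test_common_slope_counts_one_slope(self):
        items = [ItemSpec(f"i{j}", make_parametric_difficulty(
            "linear", 0.0, 1.0, SupportSpec("real"))) for j in range(6)]
        m = ThresholdsModel.from_items(items, "normal")
        data, _, _ = generate_dataset(SimulationConfig(m, 20, seed=0))
        common = MarginalProblem(items, data, common_slope=True)
        varying = MarginalProblem(items, data, common_slope=False)
        # 6 intercepts + 1 slope + sigma vs 6 intercepts + 6 slopes + sigma
        assert common.n_model_params() == 8
        assert varying.n_model_params() == 13

    def test_lrt_null_distribution(self):
        # data from a common-slope model: the common-vs-varying LRT is
        # asymptotically chi^2 with I - 1 df
        stats_ = []
        items = [ItemSpec(f"i{j}", make_parametric_difficulty(
            "linear", -0.5 + 0.5 * j, 1.3, SupportSpec("real")))
            for j in range(3)]
        m = ThresholdsModel.from_items(items, "normal", 1.0)
        for seed in range(200):
            data, _, _ = generate_dataset(SimulationConfig(m, 80, seed=seed))
            red = fit_mml(data, items, common_slope=True, compute_cov=False)
            full = fit_mml(data, items, common_slope=False, compute_cov=False)
            stat, df = lrt(full, red)
            stats_.append(stat)
        assert df == 2
        mean = np.mean(stats_)
        se = np.sqrt(2 * df / len(stats_))
        assert abs(mean - df) < 3 * se
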