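"""Model-level quantities: PT/IC functions, densities, pmfs, moments,
closed-form reductions, categorization stability."""

import numpy as np
import pytest
from scipy import integrate, stats

from irthresh import (
    ItemSpec,
    ThresholdsModel,
    categorize,
    cdf,
    density_continuous,
    ic_function,
    linear_moments,
    pmf_discrete,
    prob_exceed,
)
from irthresh.difficulty_functions import (
    BinaryDifficulty,
    FreeOrdinalDifficulty,
    SupportSpec,
    make_parametric_difficulty,
)
from irthresh.model_core import pmf_vector

REAL = SupportSpec("real")
POS = SupportSpec("positive")


def linear_item(item_id="x", d0=0.0, slope=1.0, alpha=1.0):
    return ItemSpec(item_id, make_parametric_difficulty("linear", d0, slope, REAL), alpha)


@pytest.fixture()
def simple_model():
    return ThresholdsModel.from_items([linear_item()], "normal")


class TestProbExceed:
    def test_symmetry_at_zero(self, simple_model):
        assert prob_exceed(simple_model, "x", 0.0, 0.0) == pytest.approx(0.5)

    def test_normal_cdf_value(self, simple_model):
        assert prob_exceed(simple_model, "x", 2.0, 0.0) == pytest.approx(
            stats.norm.cdf(2.0), abs=1e-12)

    def test_sentinel_minus_one_is_one(self):
        m = ThresholdsModel.from_items([ItemSpec("b", BinaryDifficulty(0.3))])
        assert prob_exceed(m, "b", -1.2, -1) == pytest.approx(1.0)

    def test_monotone_in_theta_and_y(self, simple_model):
        thetas = np.linspace(-4, 4, 50)
        assert np.all(np.diff(prob_exceed(simple_model, "x", thetas, 0.7)) > 0)
        ys = np.linspace(-4, 4, 50)
        assert np.all(np.diff(prob_exceed(simple_model, "x", 0.7, ys)) < 0)

    def test_unknown_item(self, simple_model):
        with pytest.raises(KeyError):
            prob_exceed(simple_model, "nope", 0.0, 0.0)


class TestICFunction:
    def test_limits_and_fixed_point(self, simple_model):
        grid = np.array([-30.0, 1.0, 30.0])
        vals = ic_function(simple_model, "x", 1.0, grid)
        assert vals[0] == pytest.approx(0.0, abs=1e-12)
        assert vals[1] == pytest.approx(0.5)
        assert vals[2] == pytest.approx(1.0, abs=1e-12)

    def test_no_crossing_under_common_alpha(self):
        items = [linear_item("a", d0=-1.0, slope=0.7),
                 linear_item("b", d0=1.5, slope=2.0)]
        m = ThresholdsModel.from_items(items, "normal")
        grid = np.linspace(-5, 5, 201)
        ya = ic_function(m, "a", 1.0, grid)
        yb = ic_function(m, "b", 1.0, grid)
        diff = ya - yb
        # same sign everywhere: the curves never cross
        assert np.all(diff > 0) or np.all(diff < 0)


class TestCdfAndDensity:
    def test_cdf_complements_prob_exceed(self, simple_model):
        for th, y in [(0.0, 0.3), (1.2, -2.0), (-0.7, 1.9)]:
            assert cdf(simple_model, "x", th, y) + \
                prob_exceed(simple_model, "x", th, y) == pytest.approx(1.0)

    def test_normal_linear_density_is_normal(self):
        # implied distribution: Y ~ N((theta - d0)/slope, 1/(alpha*slope))
        d0, slope, alpha, theta = 1.0, 2.0, 1.5, 0.8
        m = ThresholdsModel.from_items(
            [linear_item("x", d0, slope, alpha)], "normal")
        y = np.linspace(-2, 2, 41)
        want = stats.norm.pdf(y, loc=(theta - d0) / slope,
                              scale=1 / (alpha * slope))
        got = density_continuous(m, "x", theta, y)
        assert np.allclose(got, want, atol=1e-12)

    def test_normal_log_density_is_lognormal(self):
        d0, slope, alpha, theta = 0.3, 1.4, 1.2, 0.5
        item = ItemSpec("p", make_parametric_difficulty("log", d0, slope, POS), alpha)
        m = ThresholdsModel.from_items([item], "normal")
        y = np.linspace(0.05, 6, 60)
        mu = (theta - d0) / slope
        sig = 1 / (alpha * slope)
        want = np.exp(-(np.log(y) - mu) ** 2 / (2 * sig**2)) / (
            y * np.sqrt(2 * np.pi) * sig)
        got = density_continuous(m, "p", theta, y)
        assert np.allclose(got, want, atol=1e-12)

    def test_density_integrates_to_one(self):
        item = ItemSpec("p", make_parametric_difficulty("log", 0.0, 1.0, POS), 1.3)
        m = ThresholdsModel.from_items([item], "logistic")
        val, _ = integrate.quad(
            lambda y: density_continuous(m, "p", 0.4, y), 1e-12, np.inf,
            limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_density_at_zero_values(self, simple_model):
        assert density_continuous(simple_model, "x", 0.0, 0.0) == \
            pytest.approx(0.3989422804, abs=1e-7)


class TestPmf:
    def test_binary_reduction(self):
        # P(Y=1) = F(alpha(theta - delta0)): the two-parameter binary model
        m = ThresholdsModel.from_items(
            [ItemSpec("b", BinaryDifficulty(0.4), 1.9)], "logistic")
        for th in (-1.0, 0.0, 2.0):
            want = stats.logistic.cdf(1.9 * (th - 0.4))
            assert pmf_discrete(m, "b", th, 1) == pytest.approx(want, abs=1e-15)
            assert pmf_discrete(m, "b", th, 0) == pytest.approx(1 - want, abs=1e-15)

    def test_graded_response_reduction(self):
        # free-ordinal exceedances equal F(alpha(theta - delta_r)) exactly
        vals = np.array([-1.2, 0.1, 1.4])
        m = ThresholdsModel.from_items(
            [ItemSpec("o", FreeOrdinalDifficulty(vals), 1.3)], "normal")
        th = 0.6
        for r in range(1, 4):
            want = stats.norm.cdf(1.3 * (th - vals[r - 1]))
            got = sum(pmf_discrete(m, "o", th, s) for s in range(r, 4))
            assert got == pytest.approx(want, abs=1e-12)

    def test_ordinal_logistic_example(self):
        m = ThresholdsModel.from_items(
            [ItemSpec("o", FreeOrdinalDifficulty([-1.0, 1.0]))], "logistic")
        probs = [pmf_discrete(m, "o", 0.0, r) for r in range(3)]
        assert probs == pytest.approx([0.26894, 0.46212, 0.26894], abs=1e-5)

    def test_pmf_sums_to_one(self):
        m = ThresholdsModel.from_items(
            [ItemSpec("o", FreeOrdinalDifficulty([-2.0, -0.5, 0.3, 2.0]), 0.8)],
            "logistic")
        assert pmf_vector(m, "o", 0.7).sum() == pytest.approx(1.0, abs=1e-12)
        cnt = ItemSpec("c", make_parametric_difficulty(
            "log1p", -1.0, 1.1, SupportSpec("count")))
        mc = ThresholdsModel.from_items([cnt], "normal")
        total = pmf_discrete(mc, "c", 0.5, np.arange(5000)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_out_of_support_raises(self):
        m = ThresholdsModel.from_items(
            [ItemSpec("o", FreeOrdinalDifficulty([-1.0, 1.0]))])
        with pytest.raises(ValueError):
            pmf_discrete(m, "o", 0.0, 5)


class TestLinearMoments:
    def test_closed_form_example(self):
        m = ThresholdsModel.from_items([linear_item("x", 2.0, 3.0)], "normal")
        mean, var = linear_moments(m, "x", 0.5)
        assert mean == pytest.approx(-0.5)
        assert var == pytest.approx(1 / 9)

    def test_unit_slope_mean_is_theta_minus_intercept(self):
        m = ThresholdsModel.from_items([linear_item("x", 0.7, 1.0)], "logistic")
        mean, _ = linear_moments(m, "x", 1.3)
        assert mean == pytest.approx(1.3 - 0.7)

    def test_alpha_scaling_of_variance(self):
        m1 = ThresholdsModel.from_items([linear_item("x", 0.0, 1.0, 1.0)])
        m2 = ThresholdsModel.from_items([linear_item("x", 0.0, 1.0, 2.0)])
        _, v1 = linear_moments(m1, "x", 0.0)
        _, v2 = linear_moments(m2, "x", 0.0)
        assert v2 == pytest.approx(v1 / 4)

    def test_monte_carlo_agreement(self, rng):
        from irthresh.simulate import sample_continuous
        d0, slope, alpha, theta = -0.5, 1.6, 1.2, 0.9
        item = linear_item("x", d0, slope, alpha)
        m = ThresholdsModel.from_items([item], "logistic")
        n = 10**6
        draws = sample_continuous(item, m.response_function,
                                  np.full(n, theta), rng)
        mean, var = linear_moments(m, "x", theta)
        se_mean = np.sqrt(var / n)
        assert abs(draws.mean() - mean) < 4 * se_mean
        # variance of the sample variance ~ (mu4 - var^2)/n; generous 4-SE band
        mu4 = np.mean((draws - draws.mean()) ** 4)
        se_var = np.sqrt((mu4 - var**2) / n)
        assert abs(draws.var() - var) < 4 * se_var

    def test_nonlinear_rejected(self):
        item = ItemSpec("p", make_parametric_difficulty("log", 0.0, 1.0, POS))
        m = ThresholdsModel.from_items([item])
        with pytest.raises(TypeError):
            linear_moments(m, "p", 0.0)


class TestCategorize:
    def test_pmf_matches_cdf_differences(self):
        m = ThresholdsModel.from_items([linear_item("x", 0.3, 1.4, 1.2)], "normal")
        taus = np.array([-1.0, 0.2, 1.1])
        cat = categorize(m, "x", taus)
        mc = ThresholdsModel.from_items([cat], "normal")
        th = 0.7
        edges = np.concatenate([[-np.inf], taus, [np.inf]])
        for r in range(4):
            want = (cdf(m, "x", th, edges[r + 1]) if np.isfinite(edges[r + 1])
                    else 1.0)
            want -= cdf(m, "x", th, edges[r]) if np.isfinite(edges[r]) else 0.0
            assert pmf_discrete(mc, cat.item_id, th, r) == pytest.approx(
                want, abs=1e-12)

    def test_single_threshold_gives_binary(self):
        m = ThresholdsModel.from_items([linear_item("x", 0.0, 1.0)], "normal")
        theta_star = 0.8
        tau = m.item("x").difficulty.inverse(theta_star)
        cat = categorize(m, "x", [tau])
        mc = ThresholdsModel.from_items([cat], "normal")
        for th in (-1.0, 0.0, 2.0):
            assert pmf_discrete(mc, cat.item_id, th, 1) == pytest.approx(
                stats.norm.cdf(th - theta_star), abs=1e-12)

    def test_thresholds_are_difficulty_values(self):
        # the categorized item is a graded response item with
        # delta_r = delta(tau_r)
        m = ThresholdsModel.from_items([linear_item("x", 0.5, 2.0)], "normal")
        taus = np.array([-0.3, 0.4, 0.9])
        cat = categorize(m, "x", taus)
        assert isinstance(cat.difficulty, FreeOrdinalDifficulty)
        assert np.allclose(cat.difficulty.values,
                           0.5 + 2.0 * taus, atol=1e-14)

    def test_unsorted_taus_rejected(self):
        m = ThresholdsModel.from_items([linear_item()], "normal")
        with pytest.raises(ValueError):
            categorize(m, "x", [1.0, 0.5])
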