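import numpy as np
import pytest
from scipy import stats

from deltadisc import (
    ExactDesign,
    FitFailure,
    MCConfig,
    default_fit_bounds,
    fit_nls,
    hit_rate_study,
    lr_decide,
    make_example1_problem,
    perturb_params,
    simulate_lognormal_rescaled,
    simulate_normal,
)
from deltadisc.models import (
    COMPETITIVE_INHIBITION,
    ENZYME_NOMINAL0,
    EXPONENTIAL_1D,
    LINEAR_1D,
)
from deltadisc.models import DiscriminationProblem, FlexibleNominalSet


class TestPerturbParams:
    def test_c_zero_returns_nominal_exactly(self, enzyme_coarse):
        rng = np.random.default_rng(0)
        out = perturb_params(enzyme_coarse.nominal0, 0.0, rng)
        assert np.array_equal(out, enzyme_coarse.nominal0.nominal)

    def test_c_one_stays_within_one_standard_error(self, enzyme_coarse):
        rng = np.random.default_rng(1)
        draws = np.array([perturb_params(enzyme_coarse.nominal0, 1.0, rng)
                          for _ in range(500)])
        assert draws[:, 0].min() >= 7.298 - 0.114
        assert draws[:, 0].max() <= 7.298 + 0.114

    def test_empirical_mean_matches_nominal(self, enzyme_coarse):
        rng = np.random.default_rng(2)
        n = 20_000
        draws = np.array([perturb_params(enzyme_coarse.nominal0, 2.0, rng)
                          for _ in range(n)])
        # SD of a uniform on +-2 half-widths is 2*hw/sqrt(3).
        se = 2 * enzyme_coarse.nominal0.half_width / np.sqrt(3) / np.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - enzyme_coarse.nominal0.nominal)
                      < 3 * se)

    def test_negative_c_rejected(self, enzyme_coarse):
        with pytest.raises(ValueError):
            perturb_params(enzyme_coarse.nominal0, -1.0, np.random.default_rng(0))


DESIGN6 = ExactDesign.from_points([[30.0, 0.0], [30.0, 40.0], [15.0, 20.0],
                                   [3.0, 0.0], [30.0, 10.0], [10.0, 5.0]])


class TestSimulateNormal:
    def test_sigma_zero_gives_exact_means(self):
        rng = np.random.default_rng(0)
        sim = simulate_normal(DESIGN6, COMPETITIVE_INHIBITION, ENZYME_NOMINAL0,
                              0.0, rng)
        np.testing.assert_array_equal(
            sim.y, COMPETITIVE_INHIBITION.eta(ENZYME_NOMINAL0, DESIGN6.as_array()))

    def test_fixed_seed_is_reproducible(self):
        a = simulate_normal(DESIGN6, COMPETITIVE_INHIBITION, ENZYME_NOMINAL0,
                            0.3, np.random.default_rng(42))
        b = simulate_normal(DESIGN6, COMPETITIVE_INHIBITION, ENZYME_NOMINAL0,
                            0.3, np.random.default_rng(42))
        np.testing.assert_array_equal(a.y, b.y)

    def test_error_standard_deviation(self):
        rng = np.random.default_rng(3)
        sigma = 0.37
        mu = COMPETITIVE_INHIBITION.eta(ENZYME_NOMINAL0, DESIGN6.as_array())
        errs = np.concatenate([
            simulate_normal(DESIGN6, COMPETITIVE_INHIBITION, ENZYME_NOMINAL0,
                            sigma, rng).y - mu
            for _ in range(4000)])
        assert errs.std() == pytest.approx(sigma, rel=0.02)


class TestSimulateLognormalRescaled:
    def test_mean_exact_and_sd_matched(self):
        rng = np.random.default_rng(4)
        sigma = 5 * 0.1526
        mu = COMPETITIVE_INHIBITION.eta(ENZYME_NOMINAL0, DESIGN6.as_array())
        ys = np.array([
            simulate_lognormal_rescaled(DESIGN6, COMPETITIVE_INHIBITION,
                                        ENZYME_NOMINAL0, sigma, rng).y
            for _ in range(20_000)])
        # Per-point mean within 3 MC standard errors of the model mean.
        se = ys.std(axis=0, ddof=1) / np.sqrt(ys.shape[0])
        assert np.all(np.abs(ys.mean(axis=0) - mu) < 3 * se)
        # Per-point SD matches the target within 2%.
        np.testing.assert_allclose(ys.std(axis=0, ddof=1),
                                   sigma * np.ones_like(mu), rtol=0.02)

    def test_observations_positive_and_right_skewed(self):
        rng = np.random.default_rng(5)
        ys = np.array([
            simulate_lognormal_rescaled(DESIGN6, COMPETITIVE_INHIBITION,
                                        ENZYME_NOMINAL0, 5 * 0.1526, rng).y
            for _ in range(5000)])
        assert np.all(ys > 0)
        assert np.all(stats.skew(ys, axis=0) > 0)

    def test_vanishing_sigma_recovers_means(self):
        rng = np.random.default_rng(6)
        mu = COMPETITIVE_INHIBITION.eta(ENZYME_NOMINAL0, DESIGN6.as_array())
        sim = simulate_lognormal_rescaled(DESIGN6, COMPETITIVE_INHIBITION,
                                          ENZYME_NOMINAL0, 1e-9, rng)
        np.testing.assert_allclose(sim.y, mu, rtol=1e-6)

    def test_nonpositive_mean_rejected(self):
        d = ExactDesign.from_points([[0.0, 0.0]])  # mean is exactly 0 here
        with pytest.raises(ValueError, match="nonpositive mean"):
            simulate_lognormal_rescaled(d, COMPETITIVE_INHIBITION, ENZYME_NOMINAL0,
                                        0.3, np.random.default_rng(0))


class TestFitNLS:
    def test_linear_model_closed_form(self):
        # On the two-point design (-1, 1) the least-squares slope of theta*x
        # is (y2 - y1)/2.
        d = ExactDesign.from_points([-1.0, 1.0])
        bounds = (np.array([-50.0]), np.array([50.0]))
        for y in ([0.3, 1.9], [-1.0, 2.0], [2.0, -0.4]):
            theta, rss = fit_nls(LINEAR_1D, d, y, [np.array([0.0])], bounds)
            assert theta[0] == pytest.approx((y[1] - y[0]) / 2, abs=1e-9)

    def test_exponential_exact_interpolation(self):
        d = ExactDesign.from_points([-1.0, 1.0])
        y = [np.exp(-1), np.e]
        theta, rss = fit_nls(EXPONENTIAL_1D, d, y, [np.array([0.5])],
                             (np.array([-10.0]), np.array([10.0])))
        assert theta[0] == pytest.approx(1.0, abs=1e-8)
        assert rss == pytest.approx(0.0, abs=1e-14)

    def test_exponential_estimate_matches_quartic_root(self):
        # The stationarity condition for fitting exp(theta x) to (y1, y2) at
        # x = (-1, 1) reduces to the polynomial g^4 - g^3 y2 + g y1 - 1 = 0
        # with theta = log g.
        d = ExactDesign.from_points([-1.0, 1.0])
        y1, y2 = 0.5, 2.0
        roots = np.roots([1.0, -y2, 0.0, y1, -1.0])
        real = roots[np.abs(roots.imag) < 1e-10].real
        candidates = np.log(real[real > 0])

        def rss_of(th):
            return (np.exp(-th) - y1) ** 2 + (np.exp(th) - y2) ** 2

        oracle = min(candidates, key=rss_of)
        theta, _ = fit_nls(EXPONENTIAL_1D, d, [y1, y2], [np.array([0.0])],
                           (np.array([-10.0]), np.array([10.0])))
        assert theta[0] == pytest.approx(oracle, abs=1e-7)

    def test_noiseless_enzyme_recovery(self, enzyme_coarse):
        y = COMPETITIVE_INHIBITION.eta(ENZYME_NOMINAL0, DESIGN6.as_array())
        bounds = default_fit_bounds(COMPETITIVE_INHIBITION, enzyme_coarse.nominal0)
        start = ENZYME_NOMINAL0 + np.array([0.4, -0.5, 0.3])
        theta, rss = fit_nls(COMPETITIVE_INHIBITION, DESIGN6, y, [start], bounds)
        np.testing.assert_allclose(theta, ENZYME_NOMINAL0, atol=1e-6)
        assert rss < 1e-12

    def test_all_starts_failing_raises(self):
        d = ExactDesign.from_points([-1.0, 1.0])
        with pytest.raises(FitFailure):
            fit_nls(EXPONENTIAL_1D, d, [np.nan, np.nan], [np.array([0.0])],
                    (np.array([-10.0]), np.array([10.0])))


class TestLRDecide:
    def test_smaller_rss_wins_and_ties_go_to_model0(self):
        assert lr_decide(0.0, 0.5) == 0
        assert lr_decide(0.5, 0.0) == 1
        assert lr_decide(0.3, 0.3) == 0

    def test_argument_swap_is_complementary_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.uniform(0, 1, 2)
            if a != b:
                assert lr_decide(a, b) == 1 - lr_decide(b, a)


@pytest.fixture(scope="module")
def toy_problem():
    return make_example1_problem(1.0, 2.0, 0.25)


@pytest.fixture(scope="module")
def toy_design():
    return ExactDesign.from_points([1.0, 1.5, 2.0, 2.0])


class TestHitRateStudy:
    def test_fixed_seed_is_bit_reproducible(self, toy_problem, toy_design):
        cfg = MCConfig(n_reps=100, c=0.0, sigma=0.5, seed=11, n_starts=2)
        a = hit_rate_study(toy_problem, {"d": toy_design}, cfg)
        b = hit_rate_study(toy_problem, {"d": toy_design}, cfg)
        assert a.table.equals(b.table)

    def test_near_noiseless_data_always_classified_correctly(self, toy_problem,
                                                             toy_design):
        cfg = MCConfig(n_reps=50, c=0.0, sigma=0.001, seed=3, n_starts=2)
        tab = hit_rate_study(toy_problem, {"d": toy_design}, cfg).table
        assert np.all(tab["hit_rate"] == 100.0)
        assert np.all(tab["n_failed"] == 0)

    def test_relabeling_models_preserves_hit_rates(self, toy_problem, toy_design):
        """Swapping the roles of the two models swaps the table rows but leaves
        every hit rate unchanged, because simulation streams are keyed by the
        data-generating model."""
        swapped = DiscriminationProblem(
            toy_problem.model1, toy_problem.model0,
            toy_problem.nominal1, toy_problem.nominal0,
            toy_problem.design_space)
        cfg = MCConfig(n_reps=60, c=0.5, sigma=0.4, seed=21, n_starts=3)
        tab = hit_rate_study(toy_problem, {"d": toy_design}, cfg).table
        tab_sw = hit_rate_study(swapped, {"d": toy_design}, cfg).table
        by_model = tab.set_index("true_model")["hit_rate"]
        by_model_sw = tab_sw.set_index("true_model")["hit_rate"]
        for name in by_model.index:
            assert by_model[name] == by_model_sw[name]

    def test_hit_rate_degrades_with_noise(self, toy_problem, toy_design):
        rates = []
        for sigma in (0.05, 0.4, 1.2):
            cfg = MCConfig(n_reps=400, c=0.0, sigma=sigma, seed=5, n_starts=2)
            tab = hit_rate_study(toy_problem, {"d": toy_design}, cfg).table
            rates.append(tab["hit_rate"].mean())
        # Monotone nonincreasing within 2 MC standard errors of slack.
        slack = 2 * 100 * np.sqrt(0.25 / 400)
        assert rates[1] <= rates[0] + slack
        assert rates[2] <= rates[1] + slack

    def test_parameter_recovery_at_vanishing_noise(self, enzyme_coarse):
        rng = np.random.default_rng(9)
        bounds = default_fit_bounds(COMPETITIVE_INHIBITION, enzyme_coarse.nominal0)
        for error_model in ("normal", "lognormal_rescaled"):
            # x1 = 3 rows keep all means positive for the log-normal generator.
            d = ExactDesign.from_points([[3.0, 0.0], [15.0, 8.0], [30.0, 16.0],
                                         [30.0, 40.0], [24.0, 24.0], [9.0, 32.0]])
            if error_model == "normal":
                sim = simulate_normal(d, COMPETITIVE_INHIBITION, ENZYME_NOMINAL0,
                                      1e-6, rng)
            else:
                sim = simulate_lognormal_rescaled(d, COMPETITIVE_INHIBITION,
                                                  ENZYME_NOMINAL0, 1e-6, rng)
            theta, _ = fit_nls(COMPETITIVE_INHIBITION, d, sim.y,
                               [ENZYME_NOMINAL0 + 0.3], bounds)
            np.testing.assert_allclose(theta, ENZYME_NOMINAL0, atol=1e-4)

    def test_table_schema_and_mc_se(self, toy_problem, toy_design):
        cfg = MCConfig(n_reps=80, c=0.0, sigma=0.3, seed=1, n_starts=2)
        out = hit_rate_study(toy_problem, {"d": toy_design}, cfg)
        tab = out.table
        assert set(tab.columns) >= {"design", "true_model", "c", "sigma",
                                    "error_model", "N", "hit_rate", "mc_se",
                                    "n_failed"}
        assert np.all((tab["hit_rate"] >= 0) & (tab["hit_rate"] <= 100))
        p = tab["hit_rate"] / 100
        np.testing.assert_allclose(tab["mc_se"], 100 * np.sqrt(p * (1 - p) / 80))
        assert out.metadata["seed"] == 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCConfig(n_reps=0)
        with pytest.raises(ValueError):
            MCConfig(sigma=0.0)
        with pytest.raises(ValueError):
            MCConfig(error_model="cauchy")
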