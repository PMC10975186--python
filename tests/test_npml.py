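"""Population-level machinery: likelihoods, EM weights, adaptive grid,
information criteria and fit diagnostics."""

import math

import numpy as np
import pytest

from quasipk import (
    DiscreteMixture,
    ErrorModel,
    ErrorPolynomial,
    NPMLConfig,
    SubjectData,
    adaptive_grid_fit,
    aic_bic,
    likelihood_matrix,
    obs_pred_regression,
    optimize_weights,
    fit_metrics,
)
from quasipk.npml import (
    DEFAULT_RANGES,
    DegenerateLikelihoodError,
    ScaledLikelihood,
    _loglik_of_weights,
    ranges_to_array,
)
from tests.conftest import make_noise_free_subject

RANGES_1C = ranges_to_array(DEFAULT_RANGES["1c"], "1c")


def simplex_grid_loglik(L: np.ndarray, n_grid: int = 2001) -> float:
    """Brute-force NPML oracle: exhaustive search of mixture weights on the
    simplex (2 or 3 columns)."""
    n, m = L.shape
    best = -np.inf
    ws = np.linspace(0.0, 1.0, n_grid)
    if m == 2:
        for w0 in ws:
            mix = L @ np.array([w0, 1.0 - w0])
            if np.all(mix > 0):
                best = max(best, float(np.sum(np.log(mix))))
    elif m == 3:
        for w0 in np.linspace(0.0, 1.0, 201):
            for w1 in np.linspace(0.0, 1.0 - w0, 201):
                mix = L @ np.array([w0, w1, 1.0 - w0 - w1])
                if np.all(mix > 0):
                    best = max(best, float(np.sum(np.log(mix))))
    else:
        raise ValueError("oracle supports 2 or 3 columns")
    return best


class TestLikelihoodMatrix:
    def test_zero_residuals_constant_sd(self, constant_error, noise_free_subject):
        subj = noise_free_subject([0.4, 40.0], "1c")
        mix = DiscreteMixture(np.array([[0.4, 40.0]]), np.array([1.0]), RANGES_1C, "1c")
        L = likelihood_matrix([subj], mix, constant_error)
        # perfect fit with sigma = 1: log L = -sum_k log(sqrt(2 pi))
        expected = -subj.n_dp * math.log(math.sqrt(2 * math.pi))
        assert L.loglik()[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_identical_points_identical_columns(self, constant_error, noise_free_subject):
        subj = noise_free_subject([0.3, 50.0], "1c")
        mix = DiscreteMixture(
            np.array([[0.4, 40.0], [0.4, 40.0]]),
            np.array([0.5, 0.5]),
            RANGES_1C,
            "1c",
        )
        L = likelihood_matrix([subj], mix, constant_error)
        np.testing.assert_array_equal(L.values[:, 0], L.values[:, 1])

    def test_single_observation_normal_density(self, constant_error):
        # obs 12, pred 10, SD 2: density exp(-0.5) / (2 sqrt(2 pi))
        subj = make_noise_free_subject([0.4, 40.0], "1c")
        err = ErrorModel(polynomial=ErrorPolynomial((2.0, 0.0, 0.0, 0.0), degree=1))
        one_obs = SubjectData("X", subj.regimen, subj.times[:1], np.array([12.0]))
        thetas = np.array([[0.4, 40.0]])
        from quasipk.npml import _likelihood_from_thetas
        from quasipk.pk_models import predict_theta_matrix

        pred = predict_theta_matrix("1c", thetas, one_obs.regimen, one_obs.times)[0, 0]
        shifted = SubjectData(
            "X", subj.regimen, subj.times[:1], np.array([pred + 2.0])
        )  # one SD away
        L = _likelihood_from_thetas([shifted], thetas, "1c", err)
        dens = float(np.exp(L.loglik()[0, 0]))
        assert dens == pytest.approx(math.exp(-0.5) / (2 * math.sqrt(2 * math.pi)), rel=1e-9)
        assert dens == pytest.approx(0.120985, abs=5e-7)


class TestOptimizeWeights:
    def test_single_column_gets_weight_one(self):
        w, ll = optimize_weights(np.array([[0.3], [0.8]]))
        assert w == pytest.approx([1.0])

    def test_two_subject_symmetric_problem(self):
        w, ll = optimize_weights(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert w == pytest.approx([0.5, 0.5], abs=1e-6)
        assert ll == pytest.approx(simplex_grid_loglik(np.eye(2)), abs=1e-4)

    def test_duplicated_column_mass_is_preserved(self):
        L = np.array([[0.9, 0.1, 0.1], [0.2, 0.7, 0.7]])
        w_dup, ll_dup = optimize_weights(L)
        w_single, ll_single = optimize_weights(L[:, :2])
        assert ll_dup == pytest.approx(ll_single, abs=1e-6)
        assert w_dup[1] + w_dup[2] == pytest.approx(w_single[1], abs=1e-4)

    def test_matches_simplex_grid_search_on_random_toys(self):
        rng = np.random.default_rng(11)
        for m in (2, 3):
            L = rng.uniform(0.05, 1.0, size=(4, m))
            w, ll = optimize_weights(L)
            assert ll == pytest.approx(simplex_grid_loglik(L), abs=2e-3)

    def test_monotone_loglik_trace_and_beats_uniform(self):
        rng = np.random.default_rng(3)
        L = rng.uniform(0.01, 1.0, size=(6, 10))
        w, ll, trace = optimize_weights(L, return_trace=True)
        assert np.all(np.diff(trace) >= -1e-10)
        uniform_ll = float(np.sum(np.log(L @ np.full(10, 0.1))))
        assert ll >= uniform_ll - 1e-12

    def test_all_zero_row_rejected(self):
        with pytest.raises(DegenerateLikelihoodError):
            optimize_weights(np.array([[1.0, 0.5], [0.0, 0.0]]))


class TestAdaptiveGrid:
    def test_infinite_tolerance_stops_after_one_cycle(self, noise_free_subject):
        subj = noise_free_subject([0.4, 40.0], "1c")
        cfg = NPMLConfig(n_initial=64, tol=np.inf, seed=5)
        mix, report = adaptive_grid_fit([subj], "1c", config=cfg)
        # one weight pass on the initial grid, no refinement
        from quasipk.npml import _likelihood_from_thetas, _sobol_grid

        grid = _sobol_grid(RANGES_1C, 64, 5)
        L = _likelihood_from_thetas([subj], grid, "1c", ErrorModel())
        _, ll0 = optimize_weights(L)
        assert -2.0 * ll0 == pytest.approx(report.neg2LL, abs=0.02)

    def test_deterministic_given_seed(self):
        from quasipk import generate_cohort

        cohort = generate_cohort(n_subjects=4, seed=9)
        cfg = NPMLConfig(n_initial=40, max_cycles=4, seed=2)
        mix1, rep1 = adaptive_grid_fit(cohort.subjects, "1c", config=cfg)
        mix2, rep2 = adaptive_grid_fit(cohort.subjects, "1c", config=cfg)
        np.testing.assert_array_equal(mix1.thetas, mix2.thetas)
        np.testing.assert_array_equal(mix1.probabilities, mix2.probabilities)
        assert rep1.neg2LL == rep2.neg2LL

    def test_two_point_mixture_recovered(self, noise_free_subject):
        subs = [
            noise_free_subject([0.2, 20.0], "1c", "A1"),
            noise_free_subject([0.2, 20.0], "1c", "A2"),
            noise_free_subject([0.6, 80.0], "1c", "B1"),
            noise_free_subject([0.6, 80.0], "1c", "B2"),
        ]
        mix, _ = adaptive_grid_fit(
            [s for s in subs], "1c", config=NPMLConfig(n_initial=64, tol=1e-4, seed=7)
        )
        for truth in (np.array([0.2, 20.0]), np.array([0.6, 80.0])):
            d = np.max(np.abs(mix.thetas - truth) / truth, axis=1)
            assert mix.probabilities[d < 0.02].sum() == pytest.approx(0.5, abs=0.02)

    def test_mixture_invariants_hold(self, noise_free_subject):
        subj = noise_free_subject([0.5, 60.0], "1c")
        mix, report = adaptive_grid_fit(
            [subj], "1c", config=NPMLConfig(n_initial=32, max_cycles=6, seed=1)
        )
        assert mix.probabilities.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(mix.thetas >= mix.ranges[:, 0] - 1e-9)
        assert np.all(mix.thetas <= mix.ranges[:, 1] + 1e-9)
        assert report.n_support == mix.n_points >= 1


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "neg2ll, P, aic_expected, bic_expected",
        [
            (478.8, 3, 485.2, 491.6),
            (423.5, 5, 434.4, 444.8),
            (474.4, 4, 483.0, 491.5),
            (422.4, 6, 435.7, 448.1),
        ],
    )
    def test_small_sample_correction_reproduces_study_table(
        self, neg2ll, P, aic_expected, bic_expected
    ):
        aic, bic = aic_bic(neg2ll, P, 72)
        assert aic == pytest.approx(aic_expected, abs=0.1)
        assert bic == pytest.approx(bic_expected, abs=0.1)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError, match="small-sample"):
            aic_bic(100.0, 5, 6)


class TestRegressionAndMetrics:
    def test_identity_prediction(self):
        r = obs_pred_regression([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert (r.slope, r.intercept, r.r_squared) == pytest.approx((1.0, 0.0, 1.0))

    def test_predicted_double_of_observed(self):
        obs = np.array([1.0, 2.0, 3.0])
        r = obs_pred_regression(obs, 2.0 * obs)
        assert r.slope == pytest.approx(0.5)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_ols(self):
        obs, pred = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 5.0])
        # closed-form OLS of obs on pred
        b = np.cov(pred, obs, ddof=1)[0, 1] / np.var(pred, ddof=1)
        a = obs.mean() - b * pred.mean()
        r2 = np.corrcoef(pred, obs)[0, 1] ** 2
        r = obs_pred_regression(obs, pred)
        assert (r.slope, r.intercept, r.r_squared) == pytest.approx((b, a, r2))

    def test_zero_variance_predictions_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            obs_pred_regression([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])

    def test_perfect_fit_zero_bias_and_imprecision(self, noise_free_subject):
        subj = noise_free_subject([0.4, 40.0], "1c")
        mix = DiscreteMixture(
            np.array([[0.4, 40.0], [0.41, 41.0]]),
            np.array([1.0, 0.0]),
            RANGES_1C,
            "1c",
        )
        report = fit_metrics([subj], mix)
        assert report.bias == pytest.approx(0.0, abs=1e-9)
        assert report.imprecision == pytest.approx(0.0, abs=1e-9)
        assert set(report.shrinkage) == {"K", "V"}
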