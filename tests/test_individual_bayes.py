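"""MAP Bayesian reweighting of discrete priors by individual data."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from quasipk import (
    DiscreteMixture,
    ErrorModel,
    ErrorPolynomial,
    SubjectData,
    compare_estimates,
    generate_quasi_model,
    mse,
    posterior,
)
from quasipk.npml import DEFAULT_RANGES, ranges_to_array
from quasipk.pk_models import predict_theta_matrix
from tests.conftest import make_noise_free_subject

RANGES_1C = ranges_to_array(DEFAULT_RANGES["1c"], "1c")


def brute_force_posterior(prior: DiscreteMixture, subject: SubjectData, err: ErrorModel):
    """Independent posterior oracle: normal pdfs multiplied per observation,
    weighted by the prior, normalized."""
    weights = []
    for theta, w in zip(prior.thetas, prior.probabilities):
        pred = predict_theta_matrix(
            prior.model_type, theta[None, :], subject.regimen, subject.times,
            crcl=subject.crcl,
        )[0]
        sd = np.sqrt(np.asarray(err.variance(pred)))
        lik = float(np.prod(norm.pdf(subject.observations, loc=pred, scale=sd)))
        weights.append(w * lik)
    weights = np.array(weights)
    return weights / weights.sum()


class TestPosterior:
    def test_single_point_prior(self, constant_error, noise_free_subject):
        subj = noise_free_subject([0.4, 40.0], "1c")
        prior = DiscreteMixture(np.array([[0.3, 30.0]]), np.array([1.0]), RANGES_1C, "1c")
        post = posterior(prior, subj, constant_error)
        assert post.posterior_weights == pytest.approx([1.0])
        assert post.map_point == pytest.approx([0.3, 30.0])

    def test_proportional_to_prior_times_likelihood(self, constant_error):
        rng = np.random.default_rng(17)
        for trial in range(4):
            m = rng.integers(2, 6)
            thetas = np.column_stack(
                [rng.uniform(0.1, 0.75, m), rng.uniform(10, 100, m)]
            )
            w = rng.dirichlet(np.ones(m))
            prior = DiscreteMixture(thetas, w, RANGES_1C, "1c")
            truth = thetas[0] * [1.02, 0.98]
            subj = make_noise_free_subject(truth, "1c", f"T{trial}")
            post = posterior(prior, subj, constant_error)
            oracle = brute_force_posterior(prior, subj, constant_error)
            np.testing.assert_allclose(post.posterior_weights, oracle, rtol=1e-8, atol=1e-12)

    def test_mass_concentrates_on_generating_point(self, noise_free_subject):
        subj = noise_free_subject([0.4, 40.0], "1c")
        thetas = np.array([[0.4, 40.0], [0.5, 50.0], [0.3, 70.0]])
        prior = DiscreteMixture(thetas, np.full(3, 1 / 3), RANGES_1C, "1c")
        tight = ErrorModel(polynomial=ErrorPolynomial((1e-3, 0.0, 0.0, 0.0), degree=1))
        post = posterior(prior, subj, tight)
        assert post.posterior_weights[0] == pytest.approx(1.0, abs=1e-12)
        assert post.mse == pytest.approx(0.0, abs=1e-12)

    def test_posterior_curve_mse_bounded_by_worst_point(self, constant_error):
        rng = np.random.default_rng(23)
        thetas = np.column_stack([rng.uniform(0.1, 0.75, 5), rng.uniform(10, 100, 5)])
        prior = DiscreteMixture(thetas, rng.dirichlet(np.ones(5)), RANGES_1C, "1c")
        subj = make_noise_free_subject([0.35, 45.0], "1c")
        post = posterior(prior, subj, constant_error)
        worst = max(
            mse(
                subj.observations,
                predict_theta_matrix("1c", th[None, :], subj.regimen, subj.times)[0],
            )
            for th in thetas
        )
        assert post.mse <= worst + 1e-12

    def test_more_observations_sharpen_posterior_on_average(self, constant_error):
        def entropy(w):
            w = w[w > 0]
            return float(-(w * np.log(w)).sum())

        rng = np.random.default_rng(31)
        prior = generate_quasi_model(model_type="1c", n_points=50, seed=2)
        ent_short, ent_full = [], []
        for rep in range(12):
            theta = prior.thetas[rng.integers(50)]
            full = make_noise_free_subject(theta, "1c", f"R{rep}")
            obs = full.observations + rng.normal(0, 1.0, full.n_dp)
            sub_full = SubjectData(full.id, full.regimen, full.times, obs)
            sub_short = SubjectData(full.id, full.regimen, full.times[:3], obs[:3])
            ent_short.append(entropy(posterior(prior, sub_short, constant_error).posterior_weights))
            ent_full.append(entropy(posterior(prior, sub_full, constant_error).posterior_weights))
        assert np.mean(ent_full) <= np.mean(ent_short)


class TestMse:
    def test_perfect_predictions(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        # residuals (1, 2): (1 + 4) / 2
        assert mse([1.0, 2.0], [2.0, 4.0]) == pytest.approx(2.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mse([1.0, 2.0], [1.0])

    def test_study_design_has_six_points_per_subject(self, noise_free_subject):
        subj = noise_free_subject([0.4, 40.0], "1c")
        assert subj.n_dp == 6


class TestComparison:
    def _post(self, theta, subject, err):
        prior = DiscreteMixture(np.array([theta]), np.array([1.0]), RANGES_1C, "1c")
        return posterior(prior, subject, err)

    def test_self_comparison_all_ones(self, constant_error, noise_free_subject):
        subj = noise_free_subject([0.4, 40.0], "1c")
        a = self._post([0.3, 30.0], subj, constant_error)
        rep = compare_estimates(a, a)
        assert rep.mse_ratio == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in rep.parameter_ratios.values())

    def test_mse_ratio_below_one_means_numerator_better(self):
        import dataclasses

        subj = make_noise_free_subject([0.4, 40.0], "1c")
        err = ErrorModel(polynomial=ErrorPolynomial((1.0, 0.0, 0.0, 0.0), degree=1))
        a = self._post([0.4, 40.0], subj, err)
        b = self._post([0.3, 30.0], subj, err)
        a = dataclasses.replace(a, mse=1.0)
        b = dataclasses.replace(b, mse=2.0)
        assert compare_estimates(a, b).mse_ratio == pytest.approx(0.5)

    def test_parameter_ratio_arithmetic(self, constant_error, noise_free_subject):
        subj = noise_free_subject([0.4, 40.0], "1c")
        a = self._post([0.4, 40.0], subj, constant_error)
        b = self._post([0.5, 50.0], subj, constant_error)
        rep = compare_estimates(a, b)
        assert rep.parameter_ratios["K"] == pytest.approx(0.8)
        assert rep.parameter_ratios["V"] == pytest.approx(0.8)

    def test_kcp_kpc_ratio_for_two_compartment(self, constant_error):
        ranges = ranges_to_array(DEFAULT_RANGES["2c"], "2c")
        subj = make_noise_free_subject([0.5, 1.0, 0.5, 20.0], "2c")
        pa = posterior(
            DiscreteMixture(np.array([[0.5, 1.0, 0.5, 20.0]]), np.array([1.0]), ranges, "2c"),
            subj, constant_error,
        )
        pb = posterior(
            DiscreteMixture(np.array([[0.5, 1.0, 1.0, 20.0]]), np.array([1.0]), ranges, "2c"),
            subj, constant_error,
        )
        rep = compare_estimates(pa, pb)
        assert rep.kcp_kpc_ratio_ratio == pytest.approx(2.0)

    def test_zero_denominator_flagged_not_fatal(self, constant_error, noise_free_subject):
        import dataclasses

        subj = noise_free_subject([0.4, 40.0], "1c")
        a = self._post([0.4, 40.0], subj, constant_error)
        b = dataclasses.replace(self._post([0.3, 30.0], subj, constant_error), mse=0.0)
        with pytest.warns(UserWarning, match="undefined"):
            rep = compare_estimates(a, b)
        assert math.isnan(rep.mse_ratio)
        assert "mse" in rep.undefined

    def test_different_subjects_rejected(self, constant_error):
        sa = make_noise_free_subject([0.4, 40.0], "1c", "A")
        sb = make_noise_free_subject([0.4, 40.0], "1c", "B")
        a = self._post([0.4, 40.0], sa, constant_error)
        b = self._post([0.4, 40.0], sb, constant_error)
        with pytest.raises(ValueError, match="same subject"):
            compare_estimates(a, b)
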