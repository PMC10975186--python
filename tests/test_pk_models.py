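"""Closed-form infusion kinetics: exact values, ODE agreement, structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quasipk import Params1C, Params2C, Regimen, effective_K, predict_1c, predict_2c
from quasipk.pk_models import (
    DoseEvent,
    InvalidParameterError,
    predict_theta_matrix,
)

SINGLE_DOSE = Regimen.from_events([DoseEvent(0.0, 3.0, 4000.0)])


class TestOneCompartment:
    def test_zero_before_first_dose(self):
        reg = Regimen.from_events([DoseEvent(2.0, 3.0, 4000.0)])
        assert predict_1c(Params1C(0.5, 20.0), reg, [0.0, 1.0, 1.999]) == pytest.approx(
            [0.0, 0.0, 0.0]
        )

    def test_end_of_infusion_closed_form(self):
        # (4000/3)/(K V) (1 - e^{-K*3}) at K=0.5, V=20
        expected = (4000.0 / 3.0) / (0.5 * 20.0) * -np.expm1(-1.5)
        c = predict_1c(Params1C(0.5, 20.0), SINGLE_DOSE, [3.0])
        assert c[0] == pytest.approx(expected, rel=1e-12)
        assert c[0] == pytest.approx(103.58, abs=0.005)

    @given(factor=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_dose(self, factor):
        reg = Regimen.repeated(4000.0, 6.0, 3.0, 3)
        t = [1.0, 3.0, 7.5, 14.0]
        base = predict_1c(Params1C(0.3, 30.0), reg, t)
        scaled = predict_1c(Params1C(0.3, 30.0), reg.scaled(factor), t)
        assert scaled == pytest.approx(base * factor, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="times"):
            predict_1c(Params1C(0.5, 20.0), SINGLE_DOSE, [-1.0])

    def test_invalid_parameters_rejected(self):
        for bad in [dict(K=0.0, V=20.0), dict(K=np.nan, V=20.0), dict(K=0.5, V=-1.0)]:
            with pytest.raises(InvalidParameterError):
                Params1C(**bad)


class TestTwoCompartment:
    def test_zero_before_first_dose(self):
        reg = Regimen.from_events([DoseEvent(5.0, 3.0, 4000.0)])
        c = predict_2c(Params2C(0.8, 1.0, 0.5, 12.0), reg, [0.0, 4.9])
        assert c == pytest.approx([0.0, 0.0])

    def test_reduces_to_one_compartment_when_kcp_zero(self, regimen, sampling_times):
        t = np.concatenate([[1.0, 3.0, 10.0], sampling_times])
        c2 = predict_2c(Params2C(0.5, 0.0, 0.0, 20.0), regimen, t)
        c1 = predict_1c(Params1C(0.5, 20.0), regimen, t)
        np.testing.assert_allclose(c2, c1, rtol=1e-9)

    def test_matches_ode_oracle_on_study_regimen(self, regimen, sampling_times, ode_oracle):
        p = Params2C(K=0.8, KCP=1.0, KPC=0.5, Vc=12.0)
        closed = predict_2c(p, regimen, sampling_times)
        numeric = ode_oracle(p, regimen, sampling_times)
        np.testing.assert_allclose(closed, numeric, rtol=1e-6)

    def test_repeated_eigenvalue_limit_continuous(self):
        # K = KPC and KCP -> 0+ drives the eigenvalue gap through zero;
        # the limiting form must join the generic branch smoothly.
        t = [1.0, 3.0, 5.0]
        base = predict_2c(Params2C(0.5, 1e-9, 0.5, 20.0), SINGLE_DOSE, t)
        near = predict_2c(Params2C(0.5, 1e-7, 0.5, 20.0), SINGLE_DOSE, t)
        np.testing.assert_allclose(base, near, rtol=1e-5)

    def test_kpc_required_with_kcp(self):
        with pytest.raises(InvalidParameterError, match="KPC"):
            Params2C(0.5, 1.0, 0.0, 20.0)


class TestStructuralProperties:
    def test_superposition_over_events(self):
        e1, e2 = DoseEvent(0.0, 3.0, 4000.0), DoseEvent(2.0, 3.0, 2000.0)  # overlapping
        t = [0.5, 2.5, 4.0, 9.0]
        p1, p2 = Params1C(0.4, 25.0), Params2C(0.6, 0.8, 0.4, 15.0)
        for predict, p in [(predict_1c, p1), (predict_2c, p2)]:
            both = predict(p, Regimen.from_events([e1, e2]), t)
            sum_of_parts = predict(p, Regimen.from_events([e1]), t) + predict(
                p, Regimen.from_events([e2]), t
            )
            np.testing.assert_allclose(both, sum_of_parts, rtol=1e-12)

    def test_monotone_washout(self, regimen):
        t = np.linspace(regimen.last_end + 0.01, regimen.last_end + 12.0, 200)
        c1 = predict_1c(Params1C(0.3, 30.0), regimen, t)
        c2 = predict_2c(Params2C(0.9, 2.0, 0.7, 10.0), regimen, t)
        assert np.all(np.diff(c1) < 0)
        assert np.all(np.diff(c2) < 0)

    def test_random_draws_match_ode(self, regimen, sampling_times, ode_oracle):
        rng = np.random.default_rng(42)
        for _ in range(10):
            p1 = Params1C(rng.uniform(0.1, 0.75), rng.uniform(10, 100))
            np.testing.assert_allclose(
                predict_1c(p1, regimen, sampling_times),
                ode_oracle(p1, regimen, sampling_times),
                rtol=1e-6,
            )
            p2 = Params2C(
                rng.uniform(0.1, 1.7),
                rng.uniform(0.05, 5.0),
                rng.uniform(0.05, 5.0),
                rng.uniform(5, 35),
            )
            np.testing.assert_allclose(
                predict_2c(p2, regimen, sampling_times),
                ode_oracle(p2, regimen, sampling_times),
                rtol=1e-6,
            )


class TestEffectiveK:
    @pytest.mark.parametrize(
        "ki, ks, crcl, expected",
        [(0.05, 0.0, 80.0, 0.05), (0.02, 0.004, 100.0, 0.42), (0.07, 0.003, 0.0, 0.07)],
    )
    def test_linear_covariate_rule(self, ki, ks, crcl, expected):
        assert effective_K(ki, ks, crcl) == pytest.approx(expected)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            effective_K(0.0, 0.001, 0.0)

    def test_covariate_model_matrix_uses_crcl(self, regimen, sampling_times):
        theta = np.array([[0.02, 0.004, 30.0]])  # KI, KS, V
        via_cov = predict_theta_matrix("1c_crcl", theta, regimen, sampling_times, crcl=100.0)
        direct = predict_theta_matrix(
            "1c", np.array([[0.42, 30.0]]), regimen, sampling_times
        )
        np.testing.assert_allclose(via_cov, direct, rtol=1e-12)

    def test_higher_clearance_lower_concentrations(self, regimen, sampling_times):
        theta = np.array([[0.02, 0.004, 30.0]])
        lo = predict_theta_matrix("1c_crcl", theta, regimen, sampling_times, crcl=50.0)
        hi = predict_theta_matrix("1c_crcl", theta, regimen, sampling_times, crcl=150.0)
        assert np.all(hi < lo)
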