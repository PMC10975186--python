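"""Shared fixtures: the study design, error models, and an ODE oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from quasipk import (
    ErrorModel,
    ErrorPolynomial,
    NoiseSettings,
    Params1C,
    Params2C,
    Regimen,
    SubjectData,
    study_regimen,
    study_sampling_times,
)
from quasipk.pk_models import DoseEvent, predict_theta_matrix


@pytest.fixture(scope="session")
def regimen():
    """The study regimen: five 4 g / 3 h infusions given q6h."""
    return study_regimen()


@pytest.fixture(scope="session")
def sampling_times():
    return study_sampling_times()


@pytest.fixture(scope="session")
def constant_error():
    """Concentration-independent SD of 1 mg/L: keeps likelihood arithmetic
    transparent in unit tests."""
    return ErrorModel(polynomial=ErrorPolynomial((1.0, 0.0, 0.0, 0.0), degree=1))


def ode_concentration(params, regimen: Regimen, times) -> np.ndarray:
    """Adaptive ODE integration of the compartment equations, segment by
    segment across infusion on/off edges — the independent numerical oracle
    for the closed-form predictions."""
    times = np.asarray(times, dtype=float)
    two_cmt = isinstance(params, Params2C)

    def rate_at(t: float) -> float:
        return sum(e.rate for e in regimen.events if e.start_time <= t < e.end_time)

    if two_cmt:
        K, KCP, KPC, V = params.K, params.KCP, params.KPC, params.Vc

        def rhs(t, y):
            return [
                rate_at(t) - (K + KCP) * y[0] + KPC * y[1],
                KCP * y[0] - KPC * y[1],
            ]

        y = [0.0, 0.0]
    else:
        K, V = params.K, params.V

        def rhs(t, y):
            return [rate_at(t) - K * y[0]]

        y = [0.0]

    edges = sorted(
        {e.start_time for e in regimen.events}
        | {e.end_time for e in regimen.events}
        | set(times.tolist())
        | {0.0, float(times.max())}
    )
    edges = [e for e in edges if e <= times.max() + 1e-12]
    out = {}
    t_prev = edges[0]
    if t_prev in times:
        out[t_prev] = y[0] / V
    for t_next in edges[1:]:
        sol = solve_ivp(
            rhs, (t_prev, t_next), y, rtol=1e-10, atol=1e-12, dense_output=False
        )
        y = [float(v) for v in sol.y[:, -1]]
        if np.any(np.isclose(times, t_next)):
            out[t_next] = y[0] / V
        t_prev = t_next
    return np.array([out[min(out, key=lambda k: abs(k - t))] for t in times])


@pytest.fixture(scope="session")
def ode_oracle():
    return ode_concentration


def make_noise_free_subject(
    theta, model_type: str, subject_id: str = "S01", crcl: float | None = None
) -> SubjectData:
    """A subject whose observations are exactly one parameter vector's
    predicted study-design curve."""
    reg = study_regimen()
    times = study_sampling_times()
    theta = np.asarray(theta, dtype=float)
    pred = predict_theta_matrix(model_type, theta[None, :], reg, times, crcl=crcl)[0]
    cov = {} if crcl is None else {"CRCL": crcl}
    return SubjectData(
        id=subject_id, regimen=reg, times=times, observations=pred, covariates=cov
    )


@pytest.fixture(scope="session")
def noise_free_subject():
    return make_noise_free_subject
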