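"""Closed-form compartmental models for intravenous infusion regimens.

All quantities use the conventions of clinical beta-lactam TDM work:
concentrations in mg/L, times in hours, volumes in litres, first-order
rate constants in 1/h.  Doses are zero-order (constant-rate) infusions
characterised by a start time, a duration and a total amount in mg.

Multi-dose regimens are handled by full-history superposition: the models
are linear, so the concentration under a regimen is the sum of the
single-infusion responses of its dose events.  No steady-state shortcut
is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DoseEvent",
    "Regimen",
    "Params1C",
    "Params2C",
    "CovariateParams1C",
    "CovariateParams2C",
    "InvalidParameterError",
    "predict_1c",
    "predict_2c",
    "effective_K",
    "MODEL_PARAM_NAMES",
    "model_dimension",
    "predict_theta_matrix",
]

# Relative eigenvalue-gap threshold below which the two-compartment
# bi-exponential collapses onto its repeated-root limiting form.
_EIGEN_GAP_RTOL = 1e-10


class InvalidParameterError(ValueError):
    """A pharmacokinetic parameter violates its positivity/finiteness contract."""


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order IV infusion: ``amount`` mg delivered over ``duration`` h
    starting at ``start_time`` h."""

    start_time: float
    duration: float
    amount: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.start_time) and self.start_time >= 0):
            raise InvalidParameterError(f"start_time must be finite and >= 0, got {self.start_time}")
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise InvalidParameterError(f"duration must be finite and > 0, got {self.duration}")
        if not (math.isfinite(self.amount) and self.amount >= 0):
            raise InvalidParameterError(f"amount must be finite and >= 0, got {self.amount}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of dose events.  Events may overlap; the linear
    models superpose them."""

    events: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        starts = [e.start_time for e in self.events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("dose events must be sorted by start_time")

    @classmethod
    def from_events(cls, events: Iterable[DoseEvent]) -> "Regimen":
        return cls(tuple(sorted(events, key=lambda e: e.start_time)))

    @classmethod
    def repeated(
        cls,
        amount: float,
        interval: float,
        duration: float,
        n_doses: int,
        first_start: float = 0.0,
    ) -> "Regimen":
        """Build ``n_doses`` identical infusions given every ``interval`` h."""
        return cls(
            tuple(
                DoseEvent(first_start + i * interval, duration, amount)
                for i in range(n_doses)
            )
        )

    @property
    def last_end(self) -> float:
        return max(e.end_time for e in self.events) if self.events else 0.0

    def scaled(self, factor: float) -> "Regimen":
        """Regimen with every dose amount multiplied by ``factor``."""
        return Regimen(
            tuple(DoseEvent(e.start_time, e.duration, e.amount * factor) for e in self.events)
        )


def _check_positive(**values: float) -> None:
    for name, v in values.items():
        if not (math.isfinite(v) and v > 0):
            raise InvalidParameterError(f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class Params1C:
    """One-compartment parameters: elimination rate constant K (1/h) and
    apparent volume of distribution V (L)."""

    K: float
    V: float

    def __post_init__(self) -> None:
        _check_positive(K=self.K, V=self.V)


@dataclass(frozen=True)
class Params2C:
    """Two-compartment micro-constant parameters.

    K is elimination from the central compartment, KCP/KPC the
    central->peripheral and peripheral->central transfer rate constants
    (1/h), Vc the central-compartment volume (L).
    """

    K: float
    KCP: float
    KPC: float
    Vc: float

    def __post_init__(self) -> None:
        _check_positive(K=self.K, Vc=self.Vc)
        if not (math.isfinite(self.KCP) and self.KCP >= 0):
            raise InvalidParameterError(f"KCP must be finite and >= 0, got {self.KCP}")
        if self.KCP > 0 and not (math.isfinite(self.KPC) and self.KPC > 0):
            raise InvalidParameterError("KPC must be > 0 whenever KCP > 0")


@dataclass(frozen=True)
class CovariateParams1C:
    """One-compartment parameters with renally driven elimination:
    K = KI + KS * CRCL."""

    KI: float
    KS: float
    V: float

    def __post_init__(self) -> None:
        if self.KI < 0 or self.KS < 0:
            raise InvalidParameterError("KI and KS must be >= 0")
        _check_positive(V=self.V)

    def resolve(self, crcl: float) -> Params1C:
        return Params1C(effective_K(self.KI, self.KS, crcl), self.V)


@dataclass(frozen=True)
class CovariateParams2C:
    """Two-compartment parameters with K = KI + KS * CRCL."""

    KI: float
    KS: float
    KCP: float
    KPC: float
    Vc: float

    def __post_init__(self) -> None:
        if self.KI < 0 or self.KS < 0:
            raise InvalidParameterError("KI and KS must be >= 0")
        _check_positive(Vc=self.Vc)

    def resolve(self, crcl: float) -> Params2C:
        return Params2C(effective_K(self.KI, self.KS, crcl), self.KCP, self.KPC, self.Vc)


def effective_K(KI: float, KS: float, crcl: float) -> float:
    """Total elimination rate constant K = KI + KS * CRCL (1/h).

    KI is the non-renal component, KS the renal component per unit of
    creatinine clearance.  CRCL is in mL/min by default (the package-wide
    convention; see the covariates module).
    """
    if crcl < 0:
        raise ValueError(f"creatinine clearance must be >= 0, got {crcl}")
    k = KI + KS * crcl
    if not (math.isfinite(k) and k > 0):
        raise InvalidParameterError(f"KI + KS*CRCL must be finite and > 0, got {k}")
    return k


def _validate_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        t = t.ravel()
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and >= 0")
    return t


# ---------------------------------------------------------------------------
# Vectorised cores.  Parameter arrays broadcast against a trailing time axis,
# so a (m, 1) parameter column against (n,) times yields an (m, n) matrix.
# ---------------------------------------------------------------------------


def _step_response_1c(K: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Integral of e^{-K tau} from 0 to t, clipped at t <= 0 (returns 0)."""
    tc = np.maximum(t, 0.0)
    return -np.expm1(-K * tc) / K


def _conc_1c(K: np.ndarray, V: np.ndarray, regimen: Regimen, t: np.ndarray) -> np.ndarray:
    c = np.zeros(np.broadcast_shapes(np.shape(K), np.shape(V), np.shape(t)))
    for ev in regimen.events:
        te = t - ev.start_time
        c = c + (ev.rate / V) * (
            _step_response_1c(K, te) - _step_response_1c(K, te - ev.duration)
        )
    return c


def _eigen_2c(K: np.ndarray, KCP: np.ndarray, KPC: np.ndarray):
    """Hybrid rate constants (alpha, beta) of the two-compartment system:
    roots of lambda^2 - (K+KCP+KPC) lambda + K*KPC = 0, alpha >= beta > 0."""
    s = K + KCP + KPC
    disc = s * s - 4.0 * K * KPC
    root = np.sqrt(np.maximum(disc, 0.0))
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    return alpha, beta


def _step_response_2c(
    KPC: np.ndarray, alpha: np.ndarray, beta: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Unit-rate infusion step response of the central amount (per unit Vc),
    i.e. the convolution of the bi-exponential impulse response with a unit
    step switched on at t = 0; 0 for t <= 0."""
    tc = np.maximum(t, 0.0)
    gap = alpha - beta
    degenerate = gap <= _EIGEN_GAP_RTOL * np.maximum(alpha, 1e-300)

    with np.errstate(divide="ignore", invalid="ignore"):
        A = (KPC - alpha) / (beta - alpha)
        B = (KPC - beta) / (alpha - beta)
        regular = -A * np.expm1(-alpha * tc) / alpha - B * np.expm1(-beta * tc) / beta

    # Repeated-root limit alpha == beta == lam (l'Hopital on the gap):
    # impulse response e^{-lam t} (1 + (KPC - lam) t); integrate in closed form.
    lam = 0.5 * (alpha + beta)
    e = np.exp(-lam * tc)
    limiting = -np.expm1(-lam * tc) / lam + (KPC - lam) * (1.0 - e * (1.0 + lam * tc)) / (
        lam * lam
    )
    return np.where(degenerate, limiting, regular)


def _conc_2c(
    K: np.ndarray,
    KCP: np.ndarray,
    KPC: np.ndarray,
    Vc: np.ndarray,
    regimen: Regimen,
    t: np.ndarray,
) -> np.ndarray:
    # KCP == 0 never populates the peripheral compartment; KPC is then inert
    # and may sit at 0, which the eigen decomposition cannot represent.
    # Substituting any positive KPC with KCP = 0 gives the identical
    # mono-exponential kinetics, so normalise that corner to the 1-cmt core.
    K = np.asarray(K, dtype=float)
    KCP = np.asarray(KCP, dtype=float)
    KPC = np.asarray(KPC, dtype=float)
    KPC_safe = np.where(KCP == 0.0, np.maximum(KPC, 1.0), KPC)
    alpha, beta = _eigen_2c(K, KCP, KPC_safe)
    c = np.zeros(
        np.broadcast_shapes(np.shape(K), np.shape(KCP), np.shape(KPC), np.shape(Vc), np.shape(t))
    )
    for ev in regimen.events:
        te = t - ev.start_time
        c = c + (ev.rate / Vc) * (
            _step_response_2c(KPC_safe, alpha, beta, te)
            - _step_response_2c(KPC_safe, alpha, beta, te - ev.duration)
        )
    if np.any(KCP == 0.0):
        one_c = _conc_1c(K, np.asarray(Vc, dtype=float), regimen, t)
        c = np.where(KCP == 0.0, one_c, c)
    return c


def predict_1c(params: Params1C, regimen: Regimen, times: Sequence[float]) -> np.ndarray:
    """Central concentration (mg/L) of the one-compartment infusion model.

    Solves dA/dt = input(t) - K*A, c = A/V, exactly, superposed over all
    dose events of the regimen.
    """
    t = _validate_times(times)
    return _conc_1c(np.float64(params.K), np.float64(params.V), regimen, t)


def predict_2c(params: Params2C, regimen: Regimen, times: Sequence[float]) -> np.ndarray:
    """Central concentration (mg/L) of the two-compartment infusion model,
    from the bi-exponential solution in the hybrid constants (alpha, beta)."""
    t = _validate_times(times)
    return _conc_2c(
        np.float64(params.K),
        np.float64(params.KCP),
        np.float64(params.KPC),
        np.float64(params.Vc),
        regimen,
        t,
    )


# ---------------------------------------------------------------------------
# Model-type registry used by the population machinery.  Support-point
# parameter vectors are ordered exactly as listed here.
# ---------------------------------------------------------------------------

MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "1c": ("K", "V"),
    "2c": ("K", "KCP", "KPC", "Vc"),
    "1c_crcl": ("KI", "KS", "V"),
    "2c_crcl": ("KI", "KS", "KCP", "KPC", "Vc"),
}


def model_dimension(model_type: str) -> int:
    try:
        return len(MODEL_PARAM_NAMES[model_type])
    except KeyError:
        raise ValueError(
            f"unknown model type {model_type!r}; expected one of {sorted(MODEL_PARAM_NAMES)}"
        ) from None


def predict_theta_matrix(
    model_type: str,
    thetas: np.ndarray,
    regimen: Regimen,
    times: Sequence[float],
    crcl: float | None = None,
) -> np.ndarray:
    """Concentration matrix for many support points at once.

    ``thetas`` is (m, p) with columns ordered per ``MODEL_PARAM_NAMES``;
    the result is (m, n_times).  Covariate model types require ``crcl``
    (mL/min) to resolve K = KI + KS*CRCL.
    """
    t = _validate_times(times)
    th = np.atleast_2d(np.asarray(thetas, dtype=float))
    if th.shape[1] != model_dimension(model_type):
        raise ValueError(
            f"theta matrix has {th.shape[1]} columns, model {model_type!r} "
            f"needs {model_dimension(model_type)}"
        )
    if model_type.endswith("_crcl"):
        if crcl is None:
            raise ValueError(f"model {model_type!r} requires a CRCL covariate value")
        if crcl < 0:
            raise ValueError("CRCL must be >= 0")

    if model_type == "1c":
        K, V = th[:, 0:1], th[:, 1:2]
        return _conc_1c(K, V, regimen, t)
    if model_type == "2c":
        K, KCP, KPC, Vc = (th[:, i : i + 1] for i in range(4))
        return _conc_2c(K, KCP, KPC, Vc, regimen, t)
    if model_type == "1c_crcl":
        K = th[:, 0:1] + th[:, 1:2] * crcl
        return _conc_1c(K, th[:, 2:3], regimen, t)
    # 2c_crcl
    K = th[:, 0:1] + th[:, 1:2] * crcl
    KCP, KPC, Vc = th[:, 2:3], th[:, 3:4], th[:, 4:5]
    return _conc_2c(K, KCP, KPC, Vc, regimen, t)
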