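"""Assay error polynomial and observation-variance composition.

The fixed-effect (observation) error model maps a concentration to the
standard deviation of its measurement:

    SD(c) = c0 + c1*c + c2*c^2 + c3*c^3     (mg/L)

fitted by unweighted least squares on (nominal concentration, replicate SD)
pairs from a spiking experiment, one polynomial per degree 1..3, the best
degree selected by r^2.

``PIPERACILLIN_CUBIC`` is the package's default error model for
piperacillin HPLC-UV work.  Total observation variance optionally folds in
proportional terms for dosing error, model misspecification and sample
timing error (each expressed as a fraction of the predicted concentration,
added in quadrature) and a multiplicative inflation factor gamma.  The
quadrature composition is this package's convention for giving those three
scalar settings a precise meaning; with all three at zero and gamma = 1 the
variance is exactly SD(c)^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ErrorPolynomial",
    "NoiseSettings",
    "ErrorModel",
    "InvalidErrorModelError",
    "UnderdeterminedFitError",
    "fit_error_polynomial",
    "sd_at",
    "observation_variance",
    "PIPERACILLIN_CUBIC",
    "DEFAULT_NOISE",
]

logger = logging.getLogger(__name__)


class InvalidErrorModelError(ValueError):
    """The polynomial produced a nonpositive SD — it is being used outside
    its calibrated range or is malformed."""


class UnderdeterminedFitError(ValueError):
    """Fewer distinct concentration levels than polynomial coefficients."""


@dataclass(frozen=True)
class ErrorPolynomial:
    """SD(c) = c0 + c1 c + c2 c^2 + c3 c^3, coefficients in ascending order.

    ``calibration_range`` is the concentration span (mg/L) the polynomial
    was fitted over; evaluation outside it is allowed but logged.
    """

    coefficients: tuple[float, float, float, float]
    degree: int
    r_squared: float | None = None
    calibration_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError(f"degree must be 1, 2 or 3, got {self.degree}")
        if len(self.coefficients) != 4:
            raise ValueError("coefficients must be the 4-tuple (c0, c1, c2, c3)")
        if any(c != 0.0 for c in self.coefficients[self.degree + 1 :]):
            raise ValueError("coefficients above the declared degree must be 0")

    def __call__(self, c):
        return sd_at(self, c)


@dataclass(frozen=True)
class NoiseSettings:
    """Proportional error fractions for dose amount, structural-model and
    sample-timing uncertainty (each dimensionless, >= 0)."""

    dosing_error: float = 0.0
    model_misspecification: float = 0.0
    timing_error: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dosing_error", "model_misspecification", "timing_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Third-degree assay error polynomial of the piperacillin HPLC-UV assay,
#: fitted on 20 spiking levels plus blanks (r^2 = 0.9564).
PIPERACILLIN_CUBIC = ErrorPolynomial(
    coefficients=(0.255056, 0.049873, -0.000361, 0.000001),
    degree=3,
    r_squared=0.9564,
    calibration_range=(0.0, 200.0),
)

#: Default proportional-error settings for individual Bayesian runs.
DEFAULT_NOISE = NoiseSettings(0.01, 0.01, 0.01)


def sd_at(poly: ErrorPolynomial, c) -> np.ndarray | float:
    """Assay SD (mg/L) at concentration ``c`` (mg/L, scalar or array)."""
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentration must be >= 0")
    if poly.calibration_range is not None:
        lo, hi = poly.calibration_range
        if np.any(arr < lo) or np.any(arr > hi):
            logger.info(
                "evaluating error polynomial outside its calibrated range %s", poly.calibration_range
            )
    c0, c1, c2, c3 = poly.coefficients
    sd = c0 + arr * (c1 + arr * (c2 + arr * c3))
    if np.any(sd <= 0):
        raise InvalidErrorModelError(
            f"error polynomial gave nonpositive SD at c={arr[sd <= 0] if arr.ndim else arr}"
        )
    return sd if arr.ndim else float(sd)


def observation_variance(
    poly: ErrorPolynomial,
    predicted_c,
    noise: NoiseSettings | None = None,
    gamma: float = 1.0,
) -> np.ndarray | float:
    """Total observation variance ((mg/L)^2) at a predicted concentration.

    gamma^2 * [SD(c)^2 + (dosing*c)^2 + (misspec*c)^2 + (timing*c)^2].
    """
    if gamma < 1.0:
        raise ValueError("gamma must be >= 1")
    arr = np.asarray(predicted_c, dtype=float)
    var = np.square(np.asarray(sd_at(poly, arr)))
    if noise is not None:
        prop2 = (
            noise.dosing_error**2 + noise.model_misspecification**2 + noise.timing_error**2
        )
        var = var + prop2 * np.square(arr)
    var = gamma**2 * var
    return var if arr.ndim else float(var)


@dataclass(frozen=True)
class ErrorModel:
    """Bundle of polynomial + proportional noise + gamma, the complete
    observation-error specification a fit consumes."""

    polynomial: ErrorPolynomial = PIPERACILLIN_CUBIC
    noise: NoiseSettings = field(default_factory=NoiseSettings)
    gamma: float = 1.0

    def sd(self, c):
        return np.sqrt(self.variance(c))

    def variance(self, predicted_c):
        return observation_variance(self.polynomial, predicted_c, self.noise, self.gamma)


@dataclass(frozen=True)
class PolynomialFitResult:
    fits: tuple[ErrorPolynomial, ...]
    selected: ErrorPolynomial


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn(
            "all SD values identical: r^2 is undefined, reported as 0", stacklevel=3
        )
        return 0.0
    return 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot


def fit_error_polynomial(
    levels, max_degree: int = 3
) -> PolynomialFitResult:
    """Fit SD-vs-concentration polynomials of degree 1..max_degree.

    ``levels`` is a sequence of (nominal concentration, replicate SD) pairs.
    Each degree is fitted by unweighted ordinary least squares; the fit with
    the highest r^2 is flagged as selected (ties favour the lower degree).
    """
    data = np.asarray(list(levels), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("levels must be (concentration, SD) pairs")
    conc, sd = data[:, 0], data[:, 1]
    if np.any(sd < 0):
        raise ValueError("SD values must be >= 0")
    if not 1 <= max_degree <= 3:
        raise ValueError("max_degree must be 1, 2 or 3")
    n_levels = len(np.unique(conc))
    if n_levels < max_degree + 2:
        raise UnderdeterminedFitError(
            f"{n_levels} distinct concentration levels cannot support a "
            f"degree-{max_degree} fit (need >= {max_degree + 2})"
        )
    crange = (float(conc.min()), float(conc.max()))
    fits = []
    for degree in range(1, max_degree + 1):
        coef = np.polynomial.polynomial.polyfit(conc, sd, degree)
        padded = tuple(float(c) for c in coef) + (0.0,) * (4 - degree - 1)
        fitted = np.polynomial.polynomial.polyval(conc, coef)
        fits.append(
            ErrorPolynomial(
                coefficients=padded,
                degree=degree,
                r_squared=_r_squared(sd, fitted),
                calibration_range=crange,
            )
        )
    selected = max(fits, key=lambda f: (f.r_squared, -f.degree))
    return PolynomialFitResult(fits=tuple(fits), selected=selected)
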