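"""Creatinine clearance for unstable renal function (Jelliffe's method).

Critically ill patients rarely have a steady-state serum creatinine, so
clearance is estimated from a creatinine mass balance over the interval
between two serum measurements:

    0.4 * BW * (c2 - c1) / T  =  P_adj - ((c1 + c2) / 2) * CCR * 1440

Solving for CCR gives the clearance in hundreds of mL per minute.  BW is
body weight in kg, c1/c2 serum creatinine in mg/dL, P_adj the adjusted
daily creatinine production in mg/day.  The factor 1440 (minutes per day)
fixes the equation's time base to days, so the sampling interval T is in
days here; a convenience converter from hours is provided.

Downstream covariate models consume CRCL in mL/min (``to_ml_min=True``,
the default of :func:`jelliffe_crcl`'s second return value); the
hundreds-of-mL/min scale remains available for interoperability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RenalInput",
    "ProductionConstants",
    "JELLIFFE_PRODUCTION",
    "jelliffe_crcl",
    "adjusted_production",
    "hours_to_days",
]

MINUTES_PER_DAY = 1440.0


class NonphysicalResultError(ValueError):
    """The balance equation yielded a negative clearance — inputs are
    mutually inconsistent (e.g. creatinine rising faster than production
    allows)."""


@dataclass(frozen=True)
class RenalInput:
    """Inputs to the unstable-renal-function clearance estimate."""

    body_weight: float  # kg
    c1: float  # first serum creatinine, mg/dL
    c2: float  # second serum creatinine, mg/dL
    interval_T: float  # time between the two samples, days
    p_adj: float  # adjusted creatinine production, mg/day

    def __post_init__(self) -> None:
        for name in ("body_weight", "c1", "c2", "interval_T", "p_adj"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")


def hours_to_days(hours: float) -> float:
    return hours / 24.0


def jelliffe_crcl(inp: RenalInput, to_ml_min: bool = True) -> float:
    """Creatinine clearance from the unstable-renal-function balance.

    Returns mL/min when ``to_ml_min`` (default), else hundreds of mL/min
    (the equation's native scale).
    """
    accumulation = 0.4 * inp.body_weight * (inp.c2 - inp.c1) / inp.interval_T
    mean_scr = 0.5 * (inp.c1 + inp.c2)
    ccr = (inp.p_adj - accumulation) / (MINUTES_PER_DAY * mean_scr)
    if ccr < 0:
        raise NonphysicalResultError(
            f"negative clearance ({ccr:.4g} hundreds of mL/min): creatinine "
            "accumulation exceeds the assumed production"
        )
    return ccr * 100.0 if to_ml_min else ccr


@dataclass(frozen=True)
class ProductionConstants:
    """Per-kg daily creatinine production, linear in age:
    production/BW = intercept - slope * age (mg/kg/day)."""

    intercept: float
    slope: float


#: Literature constants for daily creatinine production by sex, with the
#: concentration-dependent correction factor (1.035 - 0.0337 * mean SCr)
#: applied when a mean serum creatinine is supplied.  Overridable per call.
JELLIFFE_PRODUCTION: dict[str, ProductionConstants] = {
    "M": ProductionConstants(intercept=29.305, slope=0.203),
    "F": ProductionConstants(intercept=25.3, slope=0.175),
}

_CORRECTION_INTERCEPT = 1.035
_CORRECTION_SLOPE = 0.0337


def adjusted_production(
    age: float,
    body_weight: float,
    sex: str,
    mean_scr: float | None = None,
    constants: dict[str, ProductionConstants] | None = None,
) -> float:
    """Adjusted daily creatinine production P_adj in mg/day.

    Linear-in-age per-kg production scaled by body weight; when ``mean_scr``
    (mg/dL) is given, the production is reduced by the standard correction
    for the diminished production seen at elevated creatinine, floored at
    5% of the uncorrected value to keep P_adj positive.
    """
    if age <= 0 or body_weight <= 0:
        raise ValueError("age and body_weight must be > 0")
    table = constants if constants is not None else JELLIFFE_PRODUCTION
    key = sex.upper()[:1]
    if key not in table:
        raise ValueError(f"sex must be one of {sorted(table)}, got {sex!r}")
    k = table[key]
    per_kg = k.intercept - k.slope * age
    if per_kg <= 0:
        raise ValueError(f"production constants give nonpositive per-kg rate at age {age}")
    p = body_weight * per_kg
    if mean_scr is not None:
        correction = max(_CORRECTION_INTERCEPT - _CORRECTION_SLOPE * mean_scr, 0.05)
        p *= correction
    return p
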