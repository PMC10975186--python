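"""Dose-arithmetic helpers: mass/molar conversions and co-formulation ratios.

Piperacillin/tazobactam is dosed as a fixed 8:1 mass combination; the
molar ratio of the components is a useful cross-check against the slope of
the tazobactam-vs-piperacillin concentration relationship.
"""

from __future__ import annotations

__all__ = [
    "mg_to_mmol",
    "molar_ratio",
    "PIPERACILLIN_MW",
    "TAZOBACTAM_MW",
    "STUDY_DAILY_DOSE_MMOL",
]

#: Molecular weights, g/mol (free acids).
PIPERACILLIN_MW = 517.55
TAZOBACTAM_MW = 300.29

#: Daily doses of the study regimen in mmol: 16 g piperacillin + 2 g
#: tazobactam.
STUDY_DAILY_DOSE_MMOL = {"piperacillin": 30.98, "tazobactam": 6.66}


def mg_to_mmol(mg: float, molecular_weight: float) -> float:
    """Convert a mass dose (mg) to mmol given the molecular weight (g/mol)."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be > 0")
    return mg / molecular_weight


def molar_ratio(mmol_numerator: float, mmol_denominator: float) -> float:
    """Molar ratio of two doses given in mmol."""
    if mmol_denominator == 0:
        raise ZeroDivisionError("denominator dose must be nonzero")
    return mmol_numerator / mmol_denominator
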