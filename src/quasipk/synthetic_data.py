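"""Synthetic cohorts emulating the piperacillin TDM study design.

The emulated design: 4 g piperacillin every 6 h as 3-h IV infusions, with
six samples drawn 0.25, 0.5, 1, 1.5, 2 and 2.5 h after the end of one
infusion preceded by a configurable dosing history (default four earlier
doses, about a day of therapy).  True parameters are drawn uniformly
within the study's posterior ranges, noise-free curves come from the
closed-form models, and observational noise is Gaussian with the assay
error polynomial's SD at the predicted concentration.  Negative noisy
draws are truncated at zero and counted in the cohort metadata — the
measurand is strictly nonnegative.

Ground truth is always carried beside the data so estimation can be
scored, never hidden state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assay_error import ErrorPolynomial, PIPERACILLIN_CUBIC, sd_at
from .npml import DEFAULT_RANGES, SubjectData, ranges_to_array
from .pk_models import MODEL_PARAM_NAMES, Regimen, predict_theta_matrix

__all__ = [
    "SyntheticCohort",
    "STUDY_SAMPLING_OFFSETS",
    "study_regimen",
    "study_sampling_times",
    "generate_cohort",
    "generate_covariate_cohort",
]

#: Post-infusion sampling offsets (h) of the study design.
STUDY_SAMPLING_OFFSETS = (0.25, 0.5, 1.0, 1.5, 2.0, 2.5)

STUDY_DOSE_MG = 4000.0
STUDY_INTERVAL_H = 6.0
STUDY_INFUSION_H = 3.0

#: Doses administered before the sampled infusion (roughly 24 h of q6h
#: therapy, sampling on the day after treatment start).
DEFAULT_N_PREDOSE = 4


def study_regimen(n_predose: int = DEFAULT_N_PREDOSE) -> Regimen:
    """The study's q6h 3-h-infusion regimen: ``n_predose`` doses followed by
    the sampled infusion."""
    return Regimen.repeated(
        amount=STUDY_DOSE_MG,
        interval=STUDY_INTERVAL_H,
        duration=STUDY_INFUSION_H,
        n_doses=n_predose + 1,
    )


def study_sampling_times(
    n_predose: int = DEFAULT_N_PREDOSE,
    offsets: Sequence[float] = STUDY_SAMPLING_OFFSETS,
) -> np.ndarray:
    """Absolute sampling times (h from first dose) for the study design."""
    infusion_end = n_predose * STUDY_INTERVAL_H + STUDY_INFUSION_H
    return infusion_end + np.asarray(offsets, dtype=float)


@dataclass(frozen=True)
class SyntheticCohort:
    """Subjects with known ground truth and full generator provenance."""

    subjects: tuple[SubjectData, ...]
    truth: np.ndarray  # (n_subjects, p) true parameter vectors
    model_type: str
    ranges: np.ndarray
    seed: int
    n_truncated: int  # negative noise draws clamped to 0
    generator_config: dict = field(default_factory=dict)

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAM_NAMES[self.model_type]

    @property
    def n_observations(self) -> int:
        return sum(s.n_dp for s in self.subjects)

    def truth_manifest(self) -> dict:
        return {
            "model_type": self.model_type,
            "param_names": list(self.param_names),
            "seed": self.seed,
            "n_truncated": self.n_truncated,
            "truth": {
                s.id: dict(zip(self.param_names, map(float, th)))
                for s, th in zip(self.subjects, self.truth)
            },
            "generator_config": self.generator_config,
        }

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_manifest(), fh, indent=2)


def _make_observations(
    preds: np.ndarray,
    error: ErrorPolynomial | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    if error is None:
        return preds.copy(), 0
    sd = np.asarray(sd_at(error, np.maximum(preds, 0.0)))
    obs = preds + rng.normal(0.0, 1.0, size=preds.shape) * sd
    n_trunc = int(np.sum(obs < 0))
    return np.maximum(obs, 0.0), n_trunc


def generate_cohort(
    n_subjects: int = 12,
    model_type: str = "1c",
    ranges: Mapping[str, tuple[float, float]] | np.ndarray | None = None,
    regimen: Regimen | None = None,
    sampling_times: Sequence[float] | None = None,
    error: ErrorPolynomial | None = PIPERACILLIN_CUBIC,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate a study-like cohort with known ground truth.

    ``error=None`` switches observation noise off, making observations equal
    the model predictions exactly.  Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rg = ranges if isinstance(ranges, np.ndarray) else ranges_to_array(
        ranges if ranges is not None else DEFAULT_RANGES[model_type], model_type
    )
    reg = regimen if regimen is not None else study_regimen()
    times = (
        np.asarray(sampling_times, dtype=float)
        if sampling_times is not None
        else study_sampling_times()
    )
    rng = np.random.default_rng(seed)
    truth = np.column_stack([rng.uniform(lo, hi, size=n_subjects) for lo, hi in rg])

    subjects, n_trunc = [], 0
    for i in range(n_subjects):
        pred = predict_theta_matrix(model_type, truth[i : i + 1], reg, times)[0]
        obs, trunc = _make_observations(pred, error, rng)
        n_trunc += trunc
        subjects.append(
            SubjectData(id=f"S{i + 1:02d}", regimen=reg, times=times, observations=obs)
        )
    return SyntheticCohort(
        subjects=tuple(subjects),
        truth=truth,
        model_type=model_type,
        ranges=rg,
        seed=seed,
        n_truncated=n_trunc,
        generator_config={
            "n_subjects": n_subjects,
            "sampling_times": [float(t) for t in times],
            "noise": error is not None,
        },
    )


def generate_covariate_cohort(
    n_subjects: int = 12,
    model_type: str = "1c_crcl",
    ranges: Mapping[str, tuple[float, float]] | np.ndarray | None = None,
    crcl_range: tuple[float, float] = (30.0, 150.0),
    regimen: Regimen | None = None,
    sampling_times: Sequence[float] | None = None,
    error: ErrorPolynomial | None = PIPERACILLIN_CUBIC,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate a cohort whose elimination is driven by creatinine clearance.

    Each subject receives a CRCL (mL/min) drawn uniformly in ``crcl_range``;
    the effective elimination rate is K = KI + KS * CRCL.  Truth stores the
    (KI, KS, ...) vectors; CRCL sits in each subject's covariates.
    """
    if not model_type.endswith("_crcl"):
        raise ValueError("generate_covariate_cohort needs a covariate model type")
    if crcl_range[0] < 0 or crcl_range[0] >= crcl_range[1]:
        raise ValueError("crcl_range must be 0 <= low < high")
    rg = ranges if isinstance(ranges, np.ndarray) else ranges_to_array(
        ranges if ranges is not None else DEFAULT_RANGES[model_type], model_type
    )
    reg = regimen if regimen is not None else study_regimen()
    times = (
        np.asarray(sampling_times, dtype=float)
        if sampling_times is not None
        else study_sampling_times()
    )
    rng = np.random.default_rng(seed)
    truth = np.column_stack([rng.uniform(lo, hi, size=n_subjects) for lo, hi in rg])
    crcls = rng.uniform(*crcl_range, size=n_subjects)

    subjects, n_trunc = [], 0
    for i in range(n_subjects):
        pred = predict_theta_matrix(
            model_type, truth[i : i + 1], reg, times, crcl=float(crcls[i])
        )[0]
        obs, trunc = _make_observations(pred, error, rng)
        n_trunc += trunc
        subjects.append(
            SubjectData(
                id=f"S{i + 1:02d}",
                regimen=reg,
                times=times,
                observations=obs,
                covariates={"CRCL": float(crcls[i])},
            )
        )
    return SyntheticCohort(
        subjects=tuple(subjects),
        truth=truth,
        model_type=model_type,
        ranges=rg,
        seed=seed,
        n_truncated=n_trunc,
        generator_config={
            "n_subjects": n_subjects,
            "sampling_times": [float(t) for t in times],
            "crcl_range": list(crcl_range),
            "noise": error is not None,
        },
    )
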