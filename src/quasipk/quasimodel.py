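"""Fully artificial quasi-models: uniform random discrete priors.

A quasi-model is a discrete mixing distribution whose support points are
drawn uniformly at random within stated parameter ranges and all carry the
same probability.  It encodes no population data beyond the ranges
themselves, yet reweighted by a single subject's concentrations it can
individualize pharmacokinetic estimates the way a data-derived population
prior does.  A batch of such models is generated, each is fitted to the
subject by nonparametric MAP Bayesian analysis, and the model with the
smallest mean squared prediction error is selected.

Draws use one uniform stream per model, consumed parameter by parameter:
all n values of the first parameter are drawn, then all n of the second,
and point j is assembled from the j-th draw of each parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .assay_error import ErrorModel
from .individual_bayes import IndividualPosterior, posterior
from .npml import (
    DEFAULT_RANGES,
    DegenerateLikelihoodError,
    DiscreteMixture,
    SubjectData,
    ranges_to_array,
)

__all__ = [
    "QuasiModelBatch",
    "generate_quasi_model",
    "generate_batch",
    "select_best",
    "DEFAULT_N_POINTS",
    "DEFAULT_N_MODELS",
]

logger = logging.getLogger(__name__)

#: Support points per quasi-model.  A default, not a cap: the study value
#: reflects an external software limit, and larger grids are admissible.
DEFAULT_N_POINTS = 399

#: Quasi-models per batch.
DEFAULT_N_MODELS = 30

_SEED_MOD = 2**31


@dataclass(frozen=True)
class QuasiModelBatch:
    """A reproducible set of artificial priors sharing one parameter box."""

    models: tuple[DiscreteMixture, ...]
    seeds: tuple[int, ...]
    n_points: int
    ranges: np.ndarray
    model_type: str

    def __post_init__(self) -> None:
        if len(self.models) != len(self.seeds):
            raise ValueError("one seed per model required")
        for m in self.models:
            if m.n_points != self.n_points:
                raise ValueError("every model must have exactly n_points support points")

    @property
    def n_models(self) -> int:
        return len(self.models)


def _resolve_ranges(ranges, model_type: str) -> np.ndarray:
    if ranges is None:
        ranges = DEFAULT_RANGES[model_type]
    if isinstance(ranges, np.ndarray):
        return ranges
    return ranges_to_array(ranges, model_type)


def generate_quasi_model(
    ranges: Mapping[str, tuple[float, float]] | np.ndarray | None = None,
    model_type: str = "1c",
    n_points: int = DEFAULT_N_POINTS,
    seed: int = 0,
) -> DiscreteMixture:
    """One artificial prior: ``n_points`` uniform support points with equal
    probability 1/n_points, drawn inside ``ranges`` (study posterior ranges
    by default)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rg = _resolve_ranges(ranges, model_type)
    rng = np.random.default_rng(seed)
    cols = [rng.uniform(lo, hi, size=n_points) for lo, hi in rg]
    thetas = np.column_stack(cols)
    probs = np.full(n_points, 1.0 / n_points)
    return DiscreteMixture(thetas, probs, rg, model_type)


def generate_batch(
    ranges: Mapping[str, tuple[float, float]] | np.ndarray | None = None,
    model_type: str = "1c",
    n_models: int = DEFAULT_N_MODELS,
    n_points: int = DEFAULT_N_POINTS,
    master_seed: int = 0,
) -> QuasiModelBatch:
    """A batch of quasi-models with per-model seeds derived reproducibly
    (and kept below 2^31) from ``master_seed``."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rg = _resolve_ranges(ranges, model_type)
    state = np.random.SeedSequence(master_seed).generate_state(2 * n_models)
    seeds: list[int] = []
    for s in state:
        s = int(s) % _SEED_MOD
        if s not in seeds:
            seeds.append(s)
        if len(seeds) == n_models:
            break
    if len(seeds) < n_models:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not derive distinct per-model seeds")
    models = tuple(
        generate_quasi_model(rg, model_type, n_points=n_points, seed=s) for s in seeds
    )
    return QuasiModelBatch(
        models=models,
        seeds=tuple(seeds),
        n_points=n_points,
        ranges=rg,
        model_type=model_type,
    )


def select_best(
    batch: QuasiModelBatch,
    subject: SubjectData,
    error: ErrorModel | None = None,
) -> tuple[int, IndividualPosterior, np.ndarray]:
    """Fit every quasi-model of the batch to the subject and pick the one
    with the smallest MSE (ties resolved to the lowest model index).

    Returns (best index, best posterior, per-model MSE table); a model whose
    posterior degenerates is excluded with NaN in the table.
    """
    err = error or ErrorModel()
    mses = np.full(batch.n_models, np.nan)
    posteriors: list[IndividualPosterior | None] = []
    for idx, model in enumerate(batch.models):
        try:
            post = posterior(model, subject, err)
        except DegenerateLikelihoodError:
            logger.warning(
                "quasi-model %d degenerate for subject %s; excluded", idx, subject.id
            )
            posteriors.append(None)
            continue
        posteriors.append(post)
        mses[idx] = post.mse
    if np.all(np.isnan(mses)):
        raise DegenerateLikelihoodError(
            f"every quasi-model degenerate for subject {subject.id}"
        )
    best = int(np.nanargmin(mses))
    return best, posteriors[best], mses
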