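"""Nonparametric maximum-likelihood population estimation on a discrete grid.

The population model is a discrete mixing distribution: a set of support
points (parameter vectors with probabilities) over the admissible parameter
box.  Estimation alternates two steps, in the spirit of adaptive-grid
nonparametric algorithms:

1. *weights*: given a fixed grid, find the mixture weights maximising the
   exact population log-likelihood sum_i log sum_j w_j L_ij.  The
   multiplicative EM update w_j <- w_j * mean_i(L_ij / sum_k w_k L_ik)
   is used; it is monotone in the log-likelihood and converges to the
   grid-restricted NPML solution.
2. *grid refinement*: low-weight points are dropped, near-duplicates merged,
   and each survivor is perturbed coordinate-wise by a shrinking step to
   propose new candidate points, clipped to the parameter box.

Cycles repeat until the log-likelihood gain falls below a tolerance.  The
optimum of the weight step — not the interior-point algorithm the original
adaptive-grid software uses — is the contract.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.stats import qmc

from .assay_error import ErrorModel
from .pk_models import MODEL_PARAM_NAMES, Regimen, model_dimension, predict_theta_matrix

__all__ = [
    "SupportPoint",
    "DiscreteMixture",
    "SubjectData",
    "FitReport",
    "NPMLConfig",
    "DegenerateLikelihoodError",
    "DEFAULT_RANGES",
    "likelihood_matrix",
    "optimize_weights",
    "adaptive_grid_fit",
    "fit_metrics",
    "obs_pred_regression",
    "aic_bic",
]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)

#: Posterior parameter ranges of the piperacillin study models, the default
#: parameter boxes for population fits and quasi-model generation.
#: Units: rate constants 1/h (KS per mL/min of CRCL), volumes L.
DEFAULT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "1c": {"K": (0.10, 0.75), "V": (10.0, 100.0)},
    "2c": {
        "K": (0.10, 1.70),
        "KCP": (0.05, 5.00),
        "KPC": (0.05, 5.00),
        "Vc": (5.0, 35.0),
    },
    "1c_crcl": {"KI": (0.005, 0.100), "KS": (0.001, 0.006), "V": (15.0, 80.0)},
    "2c_crcl": {
        "KI": (0.00, 0.35),
        "KS": (0.0005, 0.0250),
        "KCP": (0.2, 6.0),
        "KPC": (0.2, 6.0),
        "Vc": (5.0, 25.0),
    },
}


class DegenerateLikelihoodError(RuntimeError):
    """A subject's observations have zero likelihood under every support point."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SupportPoint:
    """One atom of the discrete population distribution."""

    theta: tuple[float, ...]
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0 + 1e-12:
            raise ValueError(f"probability must be in [0, 1], got {self.probability}")


def ranges_to_array(
    ranges: Mapping[str, tuple[float, float]], model_type: str
) -> np.ndarray:
    """(p, 2) low/high array in the model's canonical parameter order."""
    names = MODEL_PARAM_NAMES[model_type]
    missing = set(names) - set(ranges)
    if missing:
        raise ValueError(f"ranges missing parameters {sorted(missing)} for {model_type!r}")
    arr = np.array([ranges[n] for n in names], dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("each parameter range must be finite with low < high")
    return arr


@dataclass(frozen=True)
class DiscreteMixture:
    """Discrete population distribution over support points.

    ``thetas`` is (n_points, p) with columns ordered per
    ``MODEL_PARAM_NAMES[model_type]``; ``probabilities`` sums to 1.
    ``ranges`` is the (p, 2) admissible box.
    """

    thetas: np.ndarray
    probabilities: np.ndarray
    ranges: np.ndarray
    model_type: str

    def __post_init__(self) -> None:
        th = np.atleast_2d(np.asarray(self.thetas, dtype=float))
        pr = np.asarray(self.probabilities, dtype=float)
        rg = np.asarray(self.ranges, dtype=float)
        object.__setattr__(self, "thetas", th)
        object.__setattr__(self, "probabilities", pr)
        object.__setattr__(self, "ranges", rg)
        p = model_dimension(self.model_type)
        if th.shape[1] != p:
            raise ValueError(f"thetas must have {p} columns for {self.model_type!r}")
        if pr.shape != (th.shape[0],):
            raise ValueError("probabilities must match the number of support points")
        if np.any(pr < -1e-15):
            raise ValueError("probabilities must be >= 0")
        if abs(pr.sum() - 1.0) > 1e-10:
            raise ValueError(f"probabilities must sum to 1 (got {pr.sum():.12g})")
        if rg.shape != (p, 2):
            raise ValueError(f"ranges must be ({p}, 2)")
        tol = 1e-9 * (rg[:, 1] - rg[:, 0])
        if np.any(th < rg[:, 0] - tol) or np.any(th > rg[:, 1] + tol):
            raise ValueError("support points must lie within the parameter ranges")

    @property
    def n_points(self) -> int:
        return self.thetas.shape[0]

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAM_NAMES[self.model_type]

    @property
    def points(self) -> tuple[SupportPoint, ...]:
        return tuple(
            SupportPoint(tuple(t), float(w))
            for t, w in zip(self.thetas, self.probabilities)
        )

    def mean(self) -> np.ndarray:
        """Probability-weighted mean parameter vector."""
        return self.probabilities @ self.thetas

    def variance(self) -> np.ndarray:
        """Per-parameter variance under the mixing distribution."""
        m = self.mean()
        return self.probabilities @ (self.thetas - m) ** 2

    def with_probabilities(self, probabilities: np.ndarray) -> "DiscreteMixture":
        return DiscreteMixture(self.thetas, probabilities, self.ranges, self.model_type)


@dataclass(frozen=True)
class SubjectData:
    """One subject's dosing history, timed observations and covariates."""

    id: str
    regimen: Regimen
    times: np.ndarray
    observations: np.ndarray
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        obs = np.asarray(self.observations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "observations", obs)
        if t.size < 1:
            raise ValueError(f"subject {self.id}: needs >= 1 observation")
        if obs.shape != t.shape:
            raise ValueError(f"subject {self.id}: observations must match times")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"subject {self.id}: times must be strictly increasing")
        if not np.all(np.isfinite(obs)):
            raise ValueError(f"subject {self.id}: observations must be finite")

    @property
    def n_dp(self) -> int:
        return int(self.times.size)

    @property
    def crcl(self) -> float | None:
        v = self.covariates.get("CRCL")
        return None if v is None else float(v)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class FitReport:
    """Population-fit diagnostics."""

    neg2LL: float
    AIC: float
    BIC: float
    bias: float
    imprecision: float
    shrinkage: dict[str, float]  # percent, per parameter
    n_support: int
    n_observations: int
    n_parameters: int  # random-effect parameters + 1 error parameter
    regression_population: RegressionResult
    regression_posterior: RegressionResult

    def to_dict(self) -> dict:
        return {
            "neg2LL": self.neg2LL,
            "AIC": self.AIC,
            "BIC": self.BIC,
            "bias": self.bias,
            "imprecision": self.imprecision,
            "shrinkage_percent": dict(self.shrinkage),
            "n_support": self.n_support,
            "n_observations": self.n_observations,
            "n_parameters": self.n_parameters,
            "regression_population": vars(self.regression_population).copy(),
            "regression_posterior": vars(self.regression_posterior).copy(),
        }


@dataclass(frozen=True)
class NPMLConfig:
    """Tuning of the adaptive-grid fit.

    n_initial seeds the grid from a scrambled Sobol sequence over the box;
    each refinement perturbs survivors by a fraction of the range that
    starts at 0.2 and shrinks by ``refinement_shrink`` per cycle; cycles
    stop when the log-likelihood gain drops below ``tol``.
    """

    n_initial: int = 100
    refinement_shrink: float = 0.5
    tol: float = 0.01
    max_cycles: int = 50
    seed: int = 0
    em_tol: float = 1e-8
    em_max_iter: int = 5000
    drop_weight_frac: float = 1e-8
    merge_rtol: float = 1e-4
    # Columns whose per-subject log-likelihoods differ by less than this are
    # statistically indistinguishable; their weight is pooled onto one
    # representative (mimicking the sparse vertex solutions of exact NPML
    # solvers and keeping refinement grids modest).
    ll_merge_tol: float = 0.02
    # Points whose first-order (KKT) multiplier mean_i(L_ij / mix_i) falls
    # below 1 - kkt_drop_tol carry no appreciable weight at the current
    # optimum; they are pruned even before their EM weight has decayed.
    kkt_drop_tol: float = 0.01
    # Refinement stops once the step has shrunk below this fraction of each
    # parameter range (and the log-likelihood gain is below tol).
    delta_min_frac: float = 1e-4
    # Only the highest-weighted points spawn refinement proposals; keeps the
    # per-cycle grid bounded for the 4-5 parameter models.
    max_refine_points: int = 30


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


class ScaledLikelihood(NamedTuple):
    """Per-subject-scaled likelihood matrix.

    ``values[i, j] = exp(loglik[i, j] - log_scale[i])`` where ``log_scale``
    is each row's maximum log-likelihood, keeping the matrix free of
    underflow; the true log-likelihood of any weighting w is
    ``log(values @ w) + log_scale`` row-wise.
    """

    values: np.ndarray
    log_scale: np.ndarray

    def loglik(self) -> np.ndarray:
        # floor protects fully underflowed entries; they stay ~-690 + scale
        return np.log(np.maximum(self.values, 1e-300)) + self.log_scale[:, None]


def predictions_for_subject(
    mixture_or_thetas, model_type: str, subject: SubjectData
) -> np.ndarray:
    """(n_points, n_dp) predicted concentrations for every support point."""
    thetas = getattr(mixture_or_thetas, "thetas", mixture_or_thetas)
    return predict_theta_matrix(
        model_type, thetas, subject.regimen, subject.times, crcl=subject.crcl
    )


def _subject_loglik(
    subject: SubjectData, preds: np.ndarray, error: ErrorModel
) -> np.ndarray:
    """Log p(subject's observations | theta_j) for every row of ``preds``."""
    var = np.asarray(error.variance(np.maximum(preds, 0.0)), dtype=float)
    resid2 = (subject.observations[None, :] - preds) ** 2
    return -0.5 * np.sum(_LOG_2PI + np.log(var) + resid2 / var, axis=1)


def likelihood_matrix(
    subjects: Sequence[SubjectData],
    mixture: DiscreteMixture,
    error: ErrorModel,
) -> ScaledLikelihood:
    """Row-scaled matrix of p(subject i | support point j).

    Densities are independent normals around each point's predicted curve
    with the observation-variance model's SD, multiplied over a subject's
    samples; computed in log space and rescaled per subject.
    """
    return _likelihood_from_thetas(subjects, mixture.thetas, mixture.model_type, error)


def _likelihood_from_thetas(
    subjects: Sequence[SubjectData],
    thetas: np.ndarray,
    model_type: str,
    error: ErrorModel,
) -> ScaledLikelihood:
    rows = []
    for s in subjects:
        preds = predict_theta_matrix(model_type, thetas, s.regimen, s.times, crcl=s.crcl)
        rows.append(_subject_loglik(s, preds, error))
    logl = np.vstack(rows)
    log_scale = logl.max(axis=1)
    bad = ~np.isfinite(log_scale)
    if np.any(bad):
        names = [subjects[i].id for i in np.nonzero(bad)[0]]
        raise DegenerateLikelihoodError(
            f"subjects {names} have zero likelihood under every support point"
        )
    return ScaledLikelihood(np.exp(logl - log_scale[:, None]), log_scale)


# ---------------------------------------------------------------------------
# Weight optimisation (grid-restricted NPML)
# ---------------------------------------------------------------------------


def _loglik_of_weights(L: ScaledLikelihood, w: np.ndarray) -> float:
    mix = L.values @ w
    if np.any(mix <= 0):
        return -np.inf
    return float(np.sum(np.log(mix) + L.log_scale))


def optimize_weights(
    L: ScaledLikelihood | np.ndarray,
    initial: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
    return_trace: bool = False,
):
    """Maximum-likelihood mixture weights on a fixed grid.

    Multiplicative EM updates on the probability simplex; the population
    log-likelihood is non-decreasing every iteration and iteration stops
    when the gain falls below ``tol`` (warning, not failure, at the
    iteration cap).  Returns ``(weights, loglik)`` or, with
    ``return_trace``, ``(weights, loglik, trace)``.
    """
    if isinstance(L, np.ndarray):
        L = ScaledLikelihood(np.asarray(L, dtype=float), np.zeros(L.shape[0]))
    vals = L.values
    n, m = vals.shape
    if np.any(vals < 0):
        raise ValueError("likelihood values must be >= 0")
    if np.any(vals.max(axis=1) <= 0):
        raise DegenerateLikelihoodError("likelihood matrix has an all-zero row")
    w = np.full(m, 1.0 / m) if initial is None else np.asarray(initial, dtype=float)
    w = w / w.sum()
    ll = _loglik_of_weights(L, w)
    trace = [ll]
    for _ in range(max_iter):
        mix = vals @ w
        w = w * ((vals / mix[:, None]).mean(axis=0))
        w = np.maximum(w, 0.0)
        w /= w.sum()
        new_ll = _loglik_of_weights(L, w)
        trace.append(new_ll)
        if new_ll - ll < tol:
            ll = new_ll
            break
        ll = new_ll
    else:
        warnings.warn(
            f"weight optimisation stopped at {max_iter} iterations; last gain "
            f"{trace[-1] - trace[-2]:.3g} above tol {tol:.3g}",
            stacklevel=2,
        )
    if return_trace:
        return w, ll, np.array(trace)
    return w, ll


# ---------------------------------------------------------------------------
# Adaptive-grid fit
# ---------------------------------------------------------------------------


def _prune_support(
    values: np.ndarray, w: np.ndarray, budget: float
) -> np.ndarray:
    """Greedily zero out mixture weights whose removal is (nearly) free.

    The EM iteration distributes weight diffusely across statistically
    similar columns; the exact NPML optimum concentrates on at most
    n_subjects points.  Columns are removed (weight renormalised onto the
    rest) as long as the cumulative population log-likelihood loss stays
    below ``budget``.  Returns the pruned, renormalised weights.
    """
    w = w.copy()
    spent = 0.0
    while True:
        active = np.nonzero(w > 0)[0]
        if active.size <= 1:
            break
        mix = values @ w
        ll_cur = float(np.sum(np.log(np.maximum(mix, 1e-300))))
        # Majority columns are never candidates: the rank-one downdate
        # (mix - wj vj) / (1 - wj) cancels catastrophically as wj -> 1.
        cand = active[w[active] <= 0.5]
        if cand.size == 0:
            break
        wc = w[cand]
        with np.errstate(divide="ignore", invalid="ignore"):
            new_mix = (mix[:, None] - values[:, cand] * wc[None, :]) / (1.0 - wc[None, :])
            cost = ll_cur - np.sum(np.log(np.maximum(new_mix, 1e-300)), axis=0)
        j = cand[int(np.argmin(cost))]
        # Verify the downdate exactly before committing the removal.
        w_try = w.copy()
        w_try[j] = 0.0
        w_try /= w_try.sum()
        ll_new = float(np.sum(np.log(np.maximum(values @ w_try, 1e-300))))
        if spent + (ll_cur - ll_new) > budget:
            break
        spent += ll_cur - ll_new
        w = w_try
    return w


def _sobol_grid(ranges: np.ndarray, n: int, seed: int) -> np.ndarray:
    sampler = qmc.Sobol(d=ranges.shape[0], scramble=True, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-power-of-two draw is fine here
        u = sampler.random(n)
    return qmc.scale(u, ranges[:, 0], ranges[:, 1])


def _condense(
    thetas: np.ndarray,
    w: np.ndarray,
    ranges: np.ndarray,
    cfg: "NPMLConfig",
    logL: np.ndarray | None = None,
    kkt: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Drop negligible-weight points and pool duplicates onto representatives.

    Points are dropped when their weight is negligible or their first-order
    multiplier (``kkt``) certifies they carry no mass at the optimum.  Two
    surviving points are duplicates when they coincide to ``merge_rtol`` of
    the range span in every coordinate, or (when ``logL`` columns are
    supplied) when every subject's log-likelihood difference between them
    is below ``ll_merge_tol`` — such columns are flat directions of the
    weight problem and pooling them changes the population log-likelihood
    by at most n_subjects * ll_merge_tol.
    """
    keep_mask = w >= cfg.drop_weight_frac * w.max()
    if kkt is not None:
        # The multiplier criterion is only reliable for points the weight
        # iteration has already driven small; a mass-carrying point with a
        # mid-iteration multiplier below 1 must not be discarded.
        negligible = (kkt < 1.0 - cfg.kkt_drop_tol) & (w < 1e-3)
        keep_mask &= ~negligible
    keep = np.nonzero(keep_mask)[0]
    if keep.size == 0:
        raise RuntimeError("grid condensation removed every support point")
    span = ranges[:, 1] - ranges[:, 0]
    order = keep[np.argsort(-w[keep])]
    reps: list[int] = []
    assigned: dict[int, int] = {}
    for i in order:
        for r in reps:
            close_theta = np.all(np.abs(thetas[i] - thetas[r]) <= cfg.merge_rtol * span)
            close_ll = logL is not None and np.all(
                np.abs(logL[:, i] - logL[:, r]) <= cfg.ll_merge_tol
            )
            if close_theta or close_ll:
                assigned[i] = r
                break
        else:
            reps.append(i)
            assigned[i] = i
    pos = {r: j for j, r in enumerate(reps)}
    out_w = np.zeros(len(reps))
    for i in order:
        out_w[pos[assigned[i]]] += w[i]
    out_L = None if logL is None else logL[:, reps]
    return thetas[reps], out_w / out_w.sum(), out_L


#: Perturbation scales tried within one refinement pass.  Offering the
#: step at several magnitudes lets coordinate-wise moves track correlated
#: (ridge-shaped) likelihood surfaces instead of overshooting them.
_REFINE_SCALES = (1.0, 0.25, 0.0625)


def _refine(thetas: np.ndarray, ranges: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """New candidate points: coordinate-wise and pairwise-diagonal +/-delta
    perturbations of every point at several scales, clipped to the box
    (parent points themselves are not returned).

    Diagonal (two-coordinate) proposals let the grid travel along correlated
    likelihood ridges (e.g. the K*V ~ clearance valley of infusion data)
    where axis-parallel steps alone stall.
    """
    p = thetas.shape[1]
    steps: list[np.ndarray] = []
    for scale in _REFINE_SCALES:
        for d in range(p):
            for sign in (+1.0, -1.0):
                step = np.zeros(p)
                step[d] = sign * scale * delta[d]
                steps.append(step)
        for d1 in range(p):
            for d2 in range(d1 + 1, p):
                for s1 in (+1.0, -1.0):
                    for s2 in (+1.0, -1.0):
                        step = np.zeros(p)
                        step[d1] = s1 * scale * delta[d1]
                        step[d2] = s2 * scale * delta[d2]
                        steps.append(step)
    proposals = np.unique(
        np.vstack([np.clip(thetas + step, ranges[:, 0], ranges[:, 1]) for step in steps]),
        axis=0,
    )
    parents = {tuple(row) for row in thetas}
    keep = np.array([tuple(row) not in parents for row in proposals], dtype=bool)
    return proposals[keep]


def adaptive_grid_fit(
    subjects: Sequence[SubjectData],
    model_type: str,
    ranges: Mapping[str, tuple[float, float]] | np.ndarray | None = None,
    error: ErrorModel | None = None,
    config: NPMLConfig | None = None,
) -> tuple[DiscreteMixture, FitReport]:
    """Nonparametric adaptive-grid population fit.

    Returns the estimated discrete mixing distribution together with its
    fit diagnostics.  Deterministic given ``config.seed``.
    """
    if len(subjects) < 1:
        raise ValueError("need at least one subject")
    cfg = config or NPMLConfig()
    err = error or ErrorModel()
    if ranges is None:
        ranges = DEFAULT_RANGES[model_type]
    rg = ranges if isinstance(ranges, np.ndarray) else ranges_to_array(ranges, model_type)

    grid = _sobol_grid(rg, cfg.n_initial, cfg.seed)
    delta = 0.2 * (rg[:, 1] - rg[:, 0])

    L = _likelihood_from_thetas(subjects, grid, model_type, err)
    # Reference for the first cycle's gain: the uniform weighting of the
    # initial grid, so a tolerance of +inf returns the one-cycle solution.
    prev_ll = _loglik_of_weights(L, np.full(grid.shape[0], 1.0 / grid.shape[0]))
    w = ll = None
    span = rg[:, 1] - rg[:, 0]
    prune_budget = min(0.1 * cfg.tol, 0.005)
    w_init = None
    for cycle in range(1, cfg.max_cycles + 1):
        w, ll = optimize_weights(
            L, initial=w_init, tol=cfg.em_tol, max_iter=cfg.em_max_iter
        )
        w = _prune_support(L.values, w, prune_budget)
        kkt = (L.values / (L.values @ w)[:, None]).mean(axis=0)
        grid, w, _ = _condense(grid, w, rg, cfg, logL=L.loglik(), kkt=kkt)
        gain = ll - prev_ll
        logger.debug("cycle %d: loglik %.6f (gain %.3g), %d points", cycle, ll, gain, len(w))
        if gain < cfg.tol:
            # The very first cycle's reference is the unrefined grid, so a
            # sub-tolerance gain there means the grid itself suffices.
            if cycle == 1 or np.all(delta <= cfg.delta_min_frac * span):
                break
            # Stalled at this scale: shrink the step and retry.
            delta = np.maximum(delta * cfg.refinement_shrink, cfg.delta_min_frac * span)
        if cycle == cfg.max_cycles:
            break
        prev_ll = ll
        top = np.argsort(-w)[: cfg.max_refine_points]
        proposals = _refine(grid[top], rg, delta)
        # Warm-start the next weight pass: keep 90% of the mass on the
        # current solution, spread 10% over the new proposals, so the EM
        # iteration resumes near the incumbent optimum instead of from
        # scratch on a grid full of near-duplicate columns.
        if proposals.shape[0] > 0:
            grid = np.vstack([grid, proposals])
            w_init = np.concatenate(
                [0.9 * w, np.full(proposals.shape[0], 0.1 / proposals.shape[0])]
            )
        else:
            w_init = w
        L = _likelihood_from_thetas(subjects, grid, model_type, err)
    # Final weight polish on the condensed grid.
    L = _likelihood_from_thetas(subjects, grid, model_type, err)
    w, ll = optimize_weights(L, initial=w, tol=cfg.em_tol, max_iter=cfg.em_max_iter)
    w = _prune_support(L.values, w, prune_budget)
    grid, w, _ = _condense(grid, w, rg, cfg, logL=L.loglik())
    mixture = DiscreteMixture(grid, w, rg, model_type)
    report = fit_metrics(subjects, mixture, err)
    return mixture, report


# ---------------------------------------------------------------------------
# Fit diagnostics
# ---------------------------------------------------------------------------


def aic_bic(neg2LL: float, n_parameters: int, n_observations: int) -> tuple[float, float]:
    """Small-sample-corrected AIC and BIC from a -2 log-likelihood.

    AICc = -2LL + 2P + 2P(P+1)/(N-P-1);  BIC = -2LL + P ln N, with P the
    number of random-effect parameters plus one error parameter and N the
    total number of observations.
    """
    P, N = n_parameters, n_observations
    if N <= P + 1:
        raise ValueError(
            f"N={N} observations cannot support the AIC small-sample correction with P={P}"
        )
    aic = neg2LL + 2.0 * P + 2.0 * P * (P + 1) / (N - P - 1)
    bic = neg2LL + P * math.log(N)
    return aic, bic


def obs_pred_regression(observed, predicted) -> RegressionResult:
    """OLS of observed on predicted with the squared Pearson correlation."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need >= 3 observed/predicted pairs of equal length")
    if np.ptp(pred) == 0:
        raise ValueError("predicted values have zero variance; regression undefined")
    res = stats.linregress(pred, obs)
    return RegressionResult(float(res.slope), float(res.intercept), float(res.rvalue) ** 2)


def fit_metrics(
    subjects: Sequence[SubjectData],
    mixture: DiscreteMixture,
    error: ErrorModel | None = None,
) -> FitReport:
    """Population diagnostics for a fitted mixture.

    Population predictions are prior-weighted mixture curves per subject,
    posterior predictions reweight the same curves by each subject's data.
    Weighted prediction errors (obs - pred)/SD(pred) give bias (their mean)
    and imprecision (their bias-adjusted mean square).  Shrinkage per
    parameter is 100 x the mean individual posterior variance over the
    population mixture variance.
    """
    err = error or ErrorModel()
    L = likelihood_matrix(subjects, mixture, err)
    w = mixture.probabilities
    ll = _loglik_of_weights(L, w)
    neg2ll = -2.0 * ll

    n_obs = sum(s.n_dp for s in subjects)
    n_par = mixture.thetas.shape[1] + 1  # random effects + 1 error parameter
    aic, bic = aic_bic(neg2ll, n_par, n_obs)

    obs_all, pop_all, post_all, wpe = [], [], [], []
    post_var_sum = np.zeros(mixture.thetas.shape[1])
    for i, s in enumerate(subjects):
        preds = predictions_for_subject(mixture, mixture.model_type, s)
        pop_pred = w @ preds
        post_w = w * L.values[i]
        post_w = post_w / post_w.sum()
        post_pred = post_w @ preds
        obs_all.append(s.observations)
        pop_all.append(pop_pred)
        post_all.append(post_pred)
        sd = np.sqrt(np.asarray(err.variance(np.maximum(pop_pred, 0.0))))
        wpe.append((s.observations - pop_pred) / sd)
        mu_i = post_w @ mixture.thetas
        post_var_sum += post_w @ (mixture.thetas - mu_i) ** 2

    wpe = np.concatenate(wpe)
    bias = float(wpe.mean())
    imprecision = float(np.mean(wpe**2) - bias**2)

    pop_var = mixture.variance()
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = 100.0 * (post_var_sum / len(subjects)) / pop_var
    shrinkage = {
        name: (float(s) if np.isfinite(s) else float("nan"))
        for name, s in zip(mixture.param_names, shrink)
    }

    obs_cat = np.concatenate(obs_all)
    reg_pop = obs_pred_regression(obs_cat, np.concatenate(pop_all))
    reg_post = obs_pred_regression(obs_cat, np.concatenate(post_all))
    return FitReport(
        neg2LL=float(neg2ll),
        AIC=float(aic),
        BIC=float(bic),
        bias=bias,
        imprecision=imprecision,
        shrinkage=shrinkage,
        n_support=mixture.n_points,
        n_observations=n_obs,
        n_parameters=n_par,
        regression_population=reg_pop,
        regression_posterior=reg_post,
    )
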