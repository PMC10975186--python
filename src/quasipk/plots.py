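"""Generic plotting helpers for fits and mixtures (matplotlib optional)."""

from __future__ import annotations

import numpy as np

from .npml import DiscreteMixture, SubjectData, predictions_for_subject

__all__ = ["plot_obs_vs_pred", "plot_marginal", "plot_fit"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_obs_vs_pred(observed, predicted, ax=None):
    """Observed-vs-predicted scatter with the identity line."""
    ax = _axes(ax)
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    ax.scatter(pred, obs, s=18, alpha=0.7)
    lim = (0.0, 1.05 * max(obs.max(), pred.max()))
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("predicted concentration (mg/L)")
    ax.set_ylabel("observed concentration (mg/L)")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    return ax


def plot_marginal(mixture: DiscreteMixture, parameter: str, ax=None):
    """Stem plot of one parameter's marginal mixing distribution."""
    ax = _axes(ax)
    idx = mixture.param_names.index(parameter)
    ax.stem(mixture.thetas[:, idx], mixture.probabilities)
    ax.set_xlabel(parameter)
    ax.set_ylabel("probability")
    return ax


def plot_fit(mixture: DiscreteMixture, subject: SubjectData, weights=None, ax=None,
             n_grid: int = 200):
    """Fitted concentration-time curve (mixture-weighted) over the data."""
    ax = _axes(ax)
    w = mixture.probabilities if weights is None else np.asarray(weights, float)
    t_grid = np.linspace(0.0, float(subject.times.max()) * 1.05, n_grid)
    probe = SubjectData(
        id=subject.id, regimen=subject.regimen, times=t_grid,
        observations=np.zeros_like(t_grid), covariates=subject.covariates,
    )
    curves = predictions_for_subject(mixture, mixture.model_type, probe)
    ax.plot(t_grid, w @ curves, lw=1.5, label="fitted")
    ax.plot(subject.times, subject.observations, "ro", label="observed")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (mg/L)")
    ax.legend()
    return ax
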