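"""Run configuration: schema, validation and resolution of defaults.

A run config is a YAML or JSON mapping with these blocks (all optional
except ``model_type``):

    model_type: 1c | 2c | 1c_crcl | 2c_crcl
    ranges: {param: [low, high], ...}            # default: study posterior box
    error:
      degree: 3
      coefficients: [c0, c1, c2, c3]             # default: piperacillin cubic
      dosing_error: 0.0
      model_misspecification: 0.0
      timing_error: 0.0
      gamma: 1.0
    npml: {n_initial: 100, tol: 0.01, max_cycles: 50, seed: 0}
    qm: {n_points: 399, n_models: 30, master_seed: 0}
    estimate: posterior_mean | map

Validation happens before any computation; every run writes its fully
resolved config next to its outputs for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .assay_error import ErrorModel, ErrorPolynomial, NoiseSettings, PIPERACILLIN_CUBIC
from .npml import DEFAULT_RANGES, NPMLConfig, ranges_to_array
from .pk_models import MODEL_PARAM_NAMES
from .quasimodel import DEFAULT_N_MODELS, DEFAULT_N_POINTS

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """The run configuration is malformed or out of range."""


@dataclass(frozen=True)
class QMConfig:
    n_points: int = DEFAULT_N_POINTS
    n_models: int = DEFAULT_N_MODELS
    master_seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    model_type: str
    ranges: dict[str, tuple[float, float]]
    error: ErrorModel
    npml: NPMLConfig = field(default_factory=NPMLConfig)
    qm: QMConfig = field(default_factory=QMConfig)
    estimate: str = "posterior_mean"

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_PARAM_NAMES:
            raise ConfigError(
                f"model_type must be one of {sorted(MODEL_PARAM_NAMES)}, got {self.model_type!r}"
            )
        ranges_to_array(self.ranges, self.model_type)  # validates
        if self.estimate not in ("posterior_mean", "map"):
            raise ConfigError("estimate must be 'posterior_mean' or 'map'")
        if self.qm.n_points < 1 or self.qm.n_models < 1:
            raise ConfigError("qm.n_points and qm.n_models must be >= 1")
        if self.npml.n_initial < 1 or self.npml.max_cycles < 1:
            raise ConfigError("npml.n_initial and npml.max_cycles must be >= 1")

    def resolved_dict(self) -> dict:
        poly = self.error.polynomial
        return {
            "model_type": self.model_type,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "error": {
                "degree": poly.degree,
                "coefficients": list(poly.coefficients),
                "dosing_error": self.error.noise.dosing_error,
                "model_misspecification": self.error.noise.model_misspecification,
                "timing_error": self.error.noise.timing_error,
                "gamma": self.error.gamma,
            },
            "npml": asdict(self.npml),
            "qm": asdict(self.qm),
            "estimate": self.estimate,
        }

    def write_resolved(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.resolved_dict(), fh, indent=2)


def _build_error(block: dict) -> ErrorModel:
    if "coefficients" in block:
        coefs = [float(c) for c in block["coefficients"]]
        if len(coefs) > 4:
            raise ConfigError("error.coefficients takes at most 4 values (c0..c3)")
        coefs += [0.0] * (4 - len(coefs))
        degree = int(block.get("degree", max(
            (i for i, c in enumerate(coefs) if c != 0.0), default=1
        )))
        poly = ErrorPolynomial(tuple(coefs), degree=max(degree, 1))
    else:
        poly = PIPERACILLIN_CUBIC
    noise = NoiseSettings(
        dosing_error=float(block.get("dosing_error", 0.0)),
        model_misspecification=float(block.get("model_misspecification", 0.0)),
        timing_error=float(block.get("timing_error", 0.0)),
    )
    gamma = float(block.get("gamma", 1.0))
    if gamma < 1.0:
        raise ConfigError("error.gamma must be >= 1")
    return ErrorModel(polynomial=poly, noise=noise, gamma=gamma)


def load_config(source) -> RunConfig:
    """Build a validated RunConfig from a path (YAML/JSON) or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(data) - {"model_type", "ranges", "error", "npml", "qm", "estimate"}
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}")
    if "model_type" not in data:
        raise ConfigError("config requires model_type")
    model_type = str(data["model_type"])
    if model_type not in MODEL_PARAM_NAMES:
        raise ConfigError(
            f"model_type must be one of {sorted(MODEL_PARAM_NAMES)}, got {model_type!r}"
        )
    raw_ranges = data.get("ranges") or DEFAULT_RANGES[model_type]
    try:
        ranges = {str(k): (float(v[0]), float(v[1])) for k, v in raw_ranges.items()}
    except (TypeError, IndexError) as exc:
        raise ConfigError(f"malformed ranges block: {exc}") from exc
    try:
        npml_cfg = NPMLConfig(**{k: v for k, v in (data.get("npml") or {}).items()})
        qm_cfg = QMConfig(**{k: v for k, v in (data.get("qm") or {}).items()})
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(
        model_type=model_type,
        ranges=ranges,
        error=_build_error(data.get("error") or {}),
        npml=npml_cfg,
        qm=qm_cfg,
        estimate=str(data.get("estimate", "posterior_mean")),
    )
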