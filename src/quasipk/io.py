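"""File formats: event-record subject tables, mixture tables, reports.

Subject data travel as a single delimited text file in an event-record
layout familiar from PK tooling:

    ID,TIME,EVID,AMT,DUR,CONC[,CRCL,BW,SCR1,SCR2,T_SCR,AGE,SEX]

* ``EVID=1`` rows are dose events and must carry AMT (mg) and DUR (h);
* ``EVID=0`` rows are observations and must carry CONC (mg/L);
* TIME is in hours on each subject's own clock (first dose at 0 or later);
* covariate columns are optional; a CRCL column is used directly, otherwise
  CRCL is derived from (BW, SCR1, SCR2, T_SCR, AGE, SEX) via the
  unstable-renal-function equation (T_SCR in days).

Mixtures (population or quasi-model) serialize as a CSV with one row per
support point: the parameter columns in canonical order plus ``PROB``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .covariates import RenalInput, adjusted_production, jelliffe_crcl
from .npml import DiscreteMixture, SubjectData, ranges_to_array
from .pk_models import MODEL_PARAM_NAMES, DoseEvent, Regimen
from .synthetic_data import SyntheticCohort

__all__ = [
    "SubjectTableError",
    "read_subjects",
    "write_subjects",
    "read_mixture",
    "write_mixture",
]

_DOSE_COLS = ("AMT", "DUR")


class SubjectTableError(ValueError):
    """A subject table violates the event-record contract; messages cite
    1-based file line numbers (header = line 1)."""


def _derive_crcl(row: pd.Series, line: int) -> float | None:
    if not pd.isna(row.get("CRCL", np.nan)):
        return float(row["CRCL"])
    needed = ("BW", "SCR1", "SCR2", "T_SCR", "AGE", "SEX")
    if any(pd.isna(row.get(c, np.nan)) for c in needed):
        return None
    p_adj = adjusted_production(
        age=float(row["AGE"]),
        body_weight=float(row["BW"]),
        sex=str(row["SEX"]),
        mean_scr=0.5 * (float(row["SCR1"]) + float(row["SCR2"])),
    )
    try:
        return jelliffe_crcl(
            RenalInput(
                body_weight=float(row["BW"]),
                c1=float(row["SCR1"]),
                c2=float(row["SCR2"]),
                interval_T=float(row["T_SCR"]),
                p_adj=p_adj,
            )
        )
    except ValueError as exc:
        raise SubjectTableError(f"line {line}: {exc}") from exc


def read_subjects(path) -> list[SubjectData]:
    """Parse an event-record table into validated per-subject records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("ID", "TIME", "EVID"):
        if col not in df.columns:
            raise SubjectTableError(f"missing mandatory column {col!r}")
    df["_line"] = df.index + 2  # header is line 1

    subjects: list[SubjectData] = []
    for sid, grp in df.groupby("ID", sort=False):
        events, obs_t, obs_c = [], [], []
        crcl: float | None = None
        for _, row in grp.iterrows():
            line = int(row["_line"])
            t = float(row["TIME"])
            if t < 0:
                raise SubjectTableError(f"line {line}: negative TIME for subject {sid}")
            if int(row["EVID"]) == 1:
                for c in _DOSE_COLS:
                    if c not in df.columns or pd.isna(row[c]):
                        raise SubjectTableError(
                            f"line {line}: dose row for subject {sid} lacks {c}"
                        )
                events.append(DoseEvent(t, float(row["DUR"]), float(row["AMT"])))
            else:
                if "CONC" not in df.columns or pd.isna(row["CONC"]):
                    raise SubjectTableError(
                        f"line {line}: observation row for subject {sid} lacks CONC"
                    )
                obs_t.append(t)
                obs_c.append(float(row["CONC"]))
            if crcl is None:
                crcl = _derive_crcl(row, line)
        if not events:
            raise SubjectTableError(f"subject {sid}: no dose rows")
        if not obs_t:
            raise SubjectTableError(f"subject {sid}: no observation rows")
        if any(b <= a for a, b in zip(obs_t, obs_t[1:])):
            raise SubjectTableError(
                f"subject {sid}: observation times must be strictly increasing"
            )
        if obs_t and events and obs_t[0] < min(e.start_time for e in events):
            # Pre-dose observations are legal (e.g. a baseline) but notable.
            import logging

            logging.getLogger(__name__).info(
                "subject %s has an observation before the first dose", sid
            )
        covariates = {"CRCL": crcl} if crcl is not None else {}
        subjects.append(
            SubjectData(
                id=str(sid),
                regimen=Regimen.from_events(events),
                times=np.array(obs_t),
                observations=np.array(obs_c),
                covariates=covariates,
            )
        )
    return subjects


def write_subjects(subjects: Sequence[SubjectData] | SyntheticCohort, path) -> None:
    """Write subjects (or a synthetic cohort) in the event-record dialect."""
    if isinstance(subjects, SyntheticCohort):
        subjects = subjects.subjects
    rows = []
    for s in subjects:
        crcl = s.covariates.get("CRCL")
        for e in s.regimen.events:
            rows.append(
                {"ID": s.id, "TIME": e.start_time, "EVID": 1, "AMT": e.amount,
                 "DUR": e.duration, "CONC": np.nan, "CRCL": crcl}
            )
        for t, c in zip(s.times, s.observations):
            rows.append(
                {"ID": s.id, "TIME": t, "EVID": 0, "AMT": np.nan, "DUR": np.nan,
                 "CONC": c, "CRCL": crcl}
            )
    df = pd.DataFrame(rows)
    if df["CRCL"].isna().all():
        df = df.drop(columns=["CRCL"])
    df.to_csv(path, index=False)


def write_mixture(mixture: DiscreteMixture, path, seed: int | None = None) -> None:
    """Support-point table: parameter columns + PROB, with the model type,
    ranges and optional seed in a JSON sidecar comment line."""
    df = pd.DataFrame(mixture.thetas, columns=list(mixture.param_names))
    df["PROB"] = mixture.probabilities
    meta = {
        "model_type": mixture.model_type,
        "ranges": {n: [float(lo), float(hi)] for n, (lo, hi) in
                   zip(mixture.param_names, mixture.ranges)},
    }
    if seed is not None:
        meta["seed"] = int(seed)
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        df.to_csv(fh, index=False)


def read_mixture(path) -> DiscreteMixture:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}: missing metadata header line")
        meta = json.loads(first[2:])
        df = pd.read_csv(fh, float_precision="round_trip")
    model_type = meta["model_type"]
    names = MODEL_PARAM_NAMES[model_type]
    ranges = ranges_to_array({k: tuple(v) for k, v in meta["ranges"].items()}, model_type)
    thetas = df[list(names)].to_numpy()
    probs = df["PROB"].to_numpy()
    return DiscreteMixture(thetas, probs, ranges, model_type)
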