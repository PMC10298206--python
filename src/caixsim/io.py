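"""Reading and writing parameter files, trajectories, and cohort data.

Parameter files are flat YAML or JSON keyed by parameter name.  The composite
interaction parameters may be supplied either directly (``a_star``,
``b_star``) or through their factors (``a``, ``m``, ``mu``, ``b``), which are
multiplied on ingest: a_star = a*m*mu, b_star = b*mu.  Unknown keys are
rejected so unit or spelling drift fails loudly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CohortDataset
from .core import ModelParameters
from .simulator import Trajectory

__all__ = [
    "load_params",
    "save_params",
    "read_cohorts",
    "write_cohorts",
    "write_trajectory",
]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}
_FACTOR_KEYS = {"a", "m", "mu", "b"}


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping of parameters")
    return data


def load_params(path: str | Path, base: ModelParameters | None = None) -> ModelParameters:
    """Load model parameters from a flat YAML/JSON file.

    Keys must be parameter names (or the factors a, m, mu, b of the fitted
    composites).  Values not present fall back to ``base`` (the published
    defaults if omitted).  Unknown keys raise ValueError.
    """
    data = _load_mapping(path)
    unknown = set(data) - _PARAM_FIELDS - _FACTOR_KEYS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    values = dict((base or ModelParameters()).to_dict())
    factors = {k: float(data.pop(k)) for k in list(data) if k in _FACTOR_KEYS}
    if factors:
        have = set(factors)
        if have & {"a", "m"} and not {"a", "m", "mu"} <= have:
            raise ValueError("a_star factors must be supplied together: a, m, mu")
        if "b" in have and "mu" not in have:
            raise ValueError("b_star factors must be supplied together: b, mu")
        if {"a", "m", "mu"} <= have:
            if "a_star" in data:
                raise ValueError("supply either a_star or its factors, not both")
            values["a_star"] = factors["a"] * factors["m"] * factors["mu"]
        if {"b", "mu"} <= have:
            if "b_star" in data:
                raise ValueError("supply either b_star or its factors, not both")
            values["b_star"] = factors["b"] * factors["mu"]
    values.update({k: float(v) for k, v in data.items()})
    return ModelParameters(**values)


def save_params(params: ModelParameters, path: str | Path) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False)


_COHORT_COLUMNS = ["cohort", "day", "volume_mm3"]


def write_cohorts(datasets: list[CohortDataset], path: str | Path) -> None:
    rows = []
    for c in datasets:
        for i, (day, vol) in enumerate(zip(c.days, c.volumes)):
            row = dict(cohort=c.label, day=day, volume_mm3=vol,
                       caix_active=c.caix_active,
                       d1_active=c.active[0], d2_active=c.active[1],
                       d3_active=c.active[2])
            if c.sem is not None:
                row["sem"] = c.sem[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohorts(path: str | Path) -> list[CohortDataset]:
    """Read cohort CSV (columns cohort, day, volume_mm3, flags, sem optional)."""
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    out = []
    for label, grp in df.groupby("cohort", sort=False):
        grp = grp.sort_values("day")
        caix = bool(grp["caix_active"].iloc[0]) if "caix_active" in grp else True
        active = tuple(
            bool(grp[f"d{i}_active"].iloc[0]) if f"d{i}_active" in grp else False
            for i in (1, 2, 3)
        )
        sem = (tuple(float(s) for s in grp["sem"])
               if "sem" in grp and grp["sem"].notna().all() else None)
        out.append(CohortDataset(
            label=str(label), caix_active=caix, active=active,
            days=tuple(float(d) for d in grp["day"]),
            volumes=tuple(float(v) for v in grp["volume_mm3"]),
            sem=sem))
    return out
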