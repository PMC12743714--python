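"""Case-table CSV round trip and YAML/JSON configuration loading.

One row per case; columns are the cohort/label fields followed by the
feature columns. Missing values are empty cells. Real-data tables carry no
latent-class column ``y``; on load it becomes unknown (NaN) for every case.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datagen import (
    COHORT_COLUMNS,
    CostFeature,
    CountFeature,
    GeneratorConfig,
    PUDataset,
)

__all__ = ["write_case_table", "load_case_table", "load_generator_config", "load_config_mapping"]

_MANDATORY = ["case_id", "s"]


def write_case_table(dataset: PUDataset, path: str | Path) -> Path:
    """Write a dataset as CSV with canonical column order."""
    path = Path(path)
    f = dataset.frame
    ordered = [c for c in COHORT_COLUMNS if c in f.columns] + [
        c for c in dataset.feature_columns if c in f.columns
    ]
    out = f[ordered].copy()
    for col in ("has_main_diagnosis", "has_drg"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
    return path


def load_case_table(path: str | Path) -> PUDataset:
    """Read a case-table CSV; empty cells are missing values.

    Raises a schema error listing absent mandatory columns (case_id, s). A
    table without a ``y`` column is treated as real data: the latent class
    is unknown for every case.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise ValueError(f"case table lacks mandatory columns: {missing}")
    if "y" not in frame.columns:
        frame["y"] = np.nan
    for col, default in (
        ("explicit_flag", frame["s"]),
        ("implicit_flag", 0),
        ("has_main_diagnosis", 1),
        ("has_drg", 1),
    ):
        if col not in frame.columns:
            frame[col] = default
    for col in ("has_main_diagnosis", "has_drg"):
        frame[col] = frame[col].astype(bool)
    feature_columns = [c for c in frame.columns if c not in COHORT_COLUMNS]
    ds = PUDataset(frame=frame, feature_columns=feature_columns)
    if frame["s"].sum() == 0:
        ds.flags.append("no labeled positives")
    ds.validate()
    return ds


def load_config_mapping(path: str | Path) -> dict:
    """Load a YAML (or JSON — valid YAML) mapping from disk."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain a mapping")
    return data


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Build a GeneratorConfig from a YAML/JSON mapping.

    Cost and count features may be given as lists of mappings with the
    CostFeature / CountFeature field names; omitted sections fall back to
    the generator defaults.
    """
    data = load_config_mapping(path)
    if "cost_features" in data:
        data["cost_features"] = [
            CostFeature(
                name=d["name"],
                zero_prob=tuple(d["zero_prob"]),
                log_mean=tuple(d["log_mean"]),
                log_sd=float(d.get("log_sd", 1.0)),
            )
            for d in data["cost_features"]
        ]
    if "count_features" in data:
        data["count_features"] = [
            CountFeature(name=d["name"], mean=tuple(d["mean"]))
            for d in data["count_features"]
        ]
    for key in ("base_cost_log_mean", "age_mean", "age_sd", "los_mean"):
        if key in data:
            data[key] = tuple(data[key])
    if "propensity_attributes" in data and data["propensity_attributes"] is not None:
        data["propensity_attributes"] = dict(data["propensity_attributes"])
    return GeneratorConfig(**data)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))
    return path
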