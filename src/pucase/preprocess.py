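"""Cohort filters, coding-strategy flags, undersampling, normalization.

The cohort filters reproduce the inclusion rules of adult acute-care case
selection: cases need a main diagnosis, a DRG code, complete cost data,
positive total costs, at least one day of stay, and an age band of 20-24 or
above. Undersampling keeps every labeled positive and a uniform random
subsample of the unlabeled pool, the standard way to balance a PU learning
sample while preserving all reliable (positive) information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .datagen import COHORT_COLUMNS, PUDataset

__all__ = [
    "CodingStrategyConfig",
    "FilterReport",
    "FILTER_RULE_ORDER",
    "apply_cohort_filters",
    "apply_coding_strategy",
    "undersample",
    "compute_class_label_mean",
    "minmax_fit_transform",
]

#: First-match order in which exclusions are attributed in the report.
#: The order affects only the attribution, never the surviving set.
FILTER_RULE_ORDER = (
    "missing_main_diagnosis",
    "missing_drg",
    "missing_cost",
    "zero_total_costs",
    "zero_length_of_stay",
    "underage",
)

_REQUIRED_COHORT = [
    "age_band",
    "length_of_stay_days",
    "total_costs",
    "has_main_diagnosis",
    "has_drg",
]


@dataclass(frozen=True)
class CodingStrategyConfig:
    """Code sets defining the explicit and implicit case definitions.

    Explicit coding: any diagnosis code naming the condition directly.
    Implicit coding: an infection code together with an organ-dysfunction
    code. Entries act as trailing-wildcard prefixes: "A41" matches "A41.9".
    """

    explicit_codes: frozenset[str] = frozenset()
    infection_codes: frozenset[str] = frozenset()
    organ_dysfunction_codes: frozenset[str] = frozenset()


@dataclass
class FilterReport:
    n_input: int
    n_excluded_by_rule: dict[str, int] = field(default_factory=dict)
    n_output: int = 0

    def validate(self) -> None:
        if self.n_input != self.n_output + sum(self.n_excluded_by_rule.values()):
            raise ValueError("filter report counts do not add up")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_excluded_by_rule": self.n_excluded_by_rule,
                "n_output": self.n_output,
            },
            indent=2,
        )


def _age_lower(age_band: pd.Series) -> pd.Series:
    # Accept both hyphen and en-dash band separators ("20-24", "20–24").
    return (
        age_band.astype(str)
        .str.replace("–", "-", regex=False)
        .str.split("-")
        .str[0]
        .astype(int)
    )


def apply_cohort_filters(dataset: PUDataset) -> tuple[PUDataset, FilterReport]:
    """Drop cases violating any inclusion rule; log exclusions first-match.

    Survivors have a main diagnosis, a DRG code, no missing cost cell,
    total costs > 0, length of stay > 0, and age band >= 20-24. Each
    excluded case is attributed to the first rule it violates in
    :data:`FILTER_RULE_ORDER`. Idempotent: filtering a filtered dataset
    changes nothing.
    """
    f = dataset.frame
    missing_cols = [c for c in _REQUIRED_COHORT if c not in f.columns]
    if missing_cols:
        raise ValueError(f"dataset lacks cohort columns: {missing_cols}")

    violation = {
        "missing_main_diagnosis": ~f["has_main_diagnosis"].astype(bool),
        "missing_drg": ~f["has_drg"].astype(bool),
        "missing_cost": f[dataset.feature_columns].isna().any(axis=1)
        if dataset.feature_columns
        else pd.Series(False, index=f.index),
        "zero_total_costs": ~(f["total_costs"] > 0),
        "zero_length_of_stay": ~(f["length_of_stay_days"] > 0),
        "underage": _age_lower(f["age_band"]) < 20,
    }

    excluded = pd.Series(False, index=f.index)
    counts: dict[str, int] = {}
    for rule in FILTER_RULE_ORDER:
        hit = violation[rule] & ~excluded
        counts[rule] = int(hit.sum())
        excluded |= hit

    survivors = f.loc[~excluded].reset_index(drop=True)
    report = FilterReport(
        n_input=len(f), n_excluded_by_rule=counts, n_output=len(survivors)
    )
    report.validate()
    out = PUDataset(
        frame=survivors,
        feature_columns=list(dataset.feature_columns),
        truth=dataset.truth,
        flags=list(dataset.flags),
    )
    return out, report


def _matches(code: str, patterns: frozenset[str]) -> bool:
    return any(code == p or code.startswith(p) for p in patterns)


def apply_coding_strategy(
    case_codes: list[str], config: CodingStrategyConfig
) -> tuple[int, int]:
    """Derive (explicit_flag, implicit_flag) from a case's diagnosis codes.

    explicit_flag is set when any code matches the explicit set; the
    implicit flag requires both an infection and an organ-dysfunction match
    on the same case.
    """
    explicit = int(any(_matches(c, config.explicit_codes) for c in case_codes))
    infection = any(_matches(c, config.infection_codes) for c in case_codes)
    dysfunction = any(_matches(c, config.organ_dysfunction_codes) for c in case_codes)
    implicit = int(infection and dysfunction)
    return explicit, implicit


def undersample(dataset: PUDataset, n_unlabeled: int, seed: int = 0) -> PUDataset:
    """Keep all labeled positives plus a random unlabeled subsample.

    Draws min(n_unlabeled, available) unlabeled cases uniformly without
    replacement; every labeled positive is retained. Original row order is
    preserved so repeated calls with one seed are byte-identical.
    """
    if n_unlabeled < 1:
        raise ValueError("n_unlabeled must be >= 1")
    f = dataset.frame
    labeled_idx = f.index[f["s"] == 1]
    unlabeled_idx = f.index[f["s"] == 0]
    k = min(n_unlabeled, len(unlabeled_idx))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(unlabeled_idx.to_numpy(), size=k, replace=False)
    keep = labeled_idx.union(pd.Index(chosen)).sort_values()
    out_frame = f.loc[keep].reset_index(drop=True)
    return PUDataset(
        frame=out_frame,
        feature_columns=list(dataset.feature_columns),
        truth=dataset.truth,
        flags=list(dataset.flags),
    )


def compute_class_label_mean(dataset: PUDataset) -> float:
    """Positive class label mean: share of observed labels s = 1."""
    if dataset.n_cases == 0:
        raise ValueError("class label mean undefined on an empty dataset")
    return float(dataset.frame["s"].mean())


def minmax_fit_transform(
    train_features: pd.DataFrame, apply_to_features: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Min-max normalize with bounds fitted on the training partition only.

    Each feature maps to (v - min)/(max - min); constant features map to 0.
    Held-out values outside the training range are *not* clipped, so they
    can fall outside [0, 1] — radial-kernel classifiers tolerate this and
    clipping would distort distances. Returns (train, applied, bounds) where
    bounds has one row per feature with columns min/max.
    """
    scaler = MinMaxScaler(clip=False)
    train_t = pd.DataFrame(
        scaler.fit_transform(train_features),
        columns=train_features.columns,
        index=train_features.index,
    )
    applied = None
    if apply_to_features is not None:
        applied = pd.DataFrame(
            scaler.transform(apply_to_features[train_features.columns]),
            columns=train_features.columns,
            index=apply_to_features.index,
        )
    bounds = pd.DataFrame(
        {"min": scaler.data_min_, "max": scaler.data_max_},
        index=train_features.columns,
    )
    return train_t, applied, bounds
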