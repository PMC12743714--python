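"""PU-estimable evaluation: recall, recall@k, precision@k, CDF diagnostics.

Real PU data contain no verified negatives, so false positives and true
negatives cannot be counted. Recall against the labeled positives remains
estimable under the SCAR assumption, and ranked-retrieval metrics
(recall@k, precision@k over the top k% of probability-ranked cases) grade
how concentrated the truth positives are at the top of the ranking.
"Truth" here means the observed coding flags, evaluated in five
constellations: A explicit, B explicit-and-implicit, C implicit,
D explicit-or-implicit, E implicit-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .datagen import PUDataset

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "scenario_truth",
    "MetricsReport",
    "make_cv_folds",
    "classify",
    "compute_recall",
    "rank_order",
    "top_k_size",
    "compute_recall_at_k",
    "compute_precision_at_k",
    "evaluate_all",
    "metrics_table",
    "prediction_cdf",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One truth constellation over the (explicit_flag, implicit_flag) pair."""

    name: str
    description: str
    predicate: Callable[[np.ndarray, np.ndarray], np.ndarray]


SCENARIOS: dict[str, ScenarioSpec] = {
    "A": ScenarioSpec("A", "explicit", lambda e, i: e == 1),
    "B": ScenarioSpec("B", "explicit and implicit", lambda e, i: (e == 1) & (i == 1)),
    "C": ScenarioSpec("C", "implicit", lambda e, i: i == 1),
    "D": ScenarioSpec("D", "explicit or implicit", lambda e, i: (e == 1) | (i == 1)),
    "E": ScenarioSpec("E", "implicit only", lambda e, i: (i == 1) & (e == 0)),
}


def scenario_truth(frame: pd.DataFrame, scenario: ScenarioSpec) -> pd.Series:
    """Boolean truth flags for a scenario, indexed by case_id."""
    truth = scenario.predicate(
        frame["explicit_flag"].to_numpy(), frame["implicit_flag"].to_numpy()
    )
    out = pd.Series(truth, index=frame["case_id"].to_numpy())
    out.index.name = "case_id"
    return out


@dataclass
class MetricsReport:
    """Per-fold and pooled PU metrics for one (model, scenario) pair."""

    scenario: ScenarioSpec
    per_fold: pd.DataFrame  # columns: fold, threshold, recall, recall_at_k*, precision_at_k*
    pooled: dict[str, float]
    n_true_positives_available: int


def make_cv_folds(dataset: PUDataset, n_folds: int = 5, seed: int = 0) -> pd.Series:
    """Stratified fold assignment (on the observed label s), case_id -> fold.

    Folds are disjoint, cover the dataset, differ in size by at most one,
    and preserve the label mean within each fold.
    """
    f = dataset.frame
    if n_folds > len(f):
        raise ValueError(f"cannot split {len(f)} cases into {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(f), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(f)), f["s"])):
        assignment[test_idx] = fold
    out = pd.Series(assignment, index=f["case_id"].to_numpy())
    out.index.name = "case_id"
    return out


def classify(predictions: pd.Series, threshold: float) -> pd.Series:
    """Binary decision: positive iff probability >= threshold."""
    return predictions >= threshold


def compute_recall(predicted_labels: pd.Series, truth: pd.Series) -> float:
    """TP / (TP + FN) over the truth positives; NaN when none exist."""
    truth = truth.reindex(predicted_labels.index)
    n_pos = int(truth.sum())
    if n_pos == 0:
        return float("nan")
    tp = int((predicted_labels & truth).sum())
    return tp / n_pos


def rank_order(predictions: pd.Series) -> pd.Index:
    """Case ids by descending probability, ties broken by ascending case_id."""
    frame = pd.DataFrame(
        {"p": predictions.to_numpy(), "case_id": predictions.index.to_numpy()}
    )
    frame = frame.sort_values(["p", "case_id"], ascending=[False, True], kind="mergesort")
    return pd.Index(frame["case_id"].to_numpy())


def top_k_size(n: int, k_percent: float) -> int:
    """floor(k * n / 100) — the floor never inflates precision."""
    return int(np.floor(k_percent * n / 100.0))


def compute_recall_at_k(predictions: pd.Series, truth: pd.Series, k_percent: float) -> float:
    """Share of all truth positives captured in the top k% of the ranking."""
    if not 0 < k_percent <= 100:
        raise ValueError("k_percent must lie in (0, 100]")
    truth = truth.reindex(predictions.index)
    n_pos = int(truth.sum())
    if n_pos == 0:
        return float("nan")
    top = rank_order(predictions)[: top_k_size(len(predictions), k_percent)]
    return int(truth.loc[top].sum()) / n_pos


def compute_precision_at_k(predictions: pd.Series, truth: pd.Series, k_percent: float) -> float:
    """Share of truth positives among the top k% of the ranking; NaN if empty."""
    if not 0 < k_percent <= 100:
        raise ValueError("k_percent must lie in (0, 100]")
    truth = truth.reindex(predictions.index)
    size = top_k_size(len(predictions), k_percent)
    if size == 0:
        return float("nan")
    top = rank_order(predictions)[:size]
    return int(truth.loc[top].sum()) / size


def evaluate_all(
    fold_predictions: Mapping[int, pd.Series],
    fold_thresholds: Mapping[int, float],
    dataset: PUDataset,
    scenarios: Sequence[str] = ("A", "B", "C", "D", "E"),
    ks: Sequence[float] = (10, 20, 30),
) -> dict[str, MetricsReport]:
    """Out-of-fold PU evaluation for every requested scenario.

    ``fold_predictions`` maps fold -> probability Series over that fold's
    test cases; together they must cover every case exactly once.
    ``fold_thresholds`` carries each fold's classification threshold (the
    training-set label mean realized for that fold). Per-fold metrics use
    the fold's own threshold and ranking; pooled metrics are computed on the
    concatenated out-of-fold predictions, classifying each case at its own
    fold's threshold and ranking all cases jointly.
    """
    f = dataset.frame
    all_ids = pd.Index(f["case_id"].to_numpy())
    covered = pd.Index(np.concatenate([p.index.to_numpy() for p in fold_predictions.values()]))
    if len(covered) != len(all_ids) or covered.duplicated().any() or not covered.sort_values().equals(all_ids.sort_values()):
        raise ValueError("out-of-fold predictions must cover every case exactly once")

    pooled_pred = pd.concat([fold_predictions[k] for k in sorted(fold_predictions)])
    pooled_decision = pd.concat(
        [
            classify(fold_predictions[k], fold_thresholds[k])
            for k in sorted(fold_predictions)
        ]
    )

    reports: dict[str, MetricsReport] = {}
    for name in scenarios:
        spec = SCENARIOS[name]
        truth = scenario_truth(f, spec)
        rows = []
        for fold in sorted(fold_predictions):
            pred = fold_predictions[fold]
            thr = fold_thresholds[fold]
            row: dict[str, float] = {
                "fold": fold,
                "threshold": thr,
                "recall": compute_recall(classify(pred, thr), truth),
            }
            for k in ks:
                row[f"recall_at_{int(k)}"] = compute_recall_at_k(pred, truth, k)
                row[f"precision_at_{int(k)}"] = compute_precision_at_k(pred, truth, k)
            rows.append(row)
        pooled: dict[str, float] = {
            "recall": compute_recall(pooled_decision, truth),
        }
        for k in ks:
            pooled[f"recall_at_{int(k)}"] = compute_recall_at_k(pooled_pred, truth, k)
            pooled[f"precision_at_{int(k)}"] = compute_precision_at_k(pooled_pred, truth, k)
        reports[name] = MetricsReport(
            scenario=spec,
            per_fold=pd.DataFrame(rows),
            pooled=pooled,
            n_true_positives_available=int(truth.sum()),
        )
    return reports


def metrics_table(reports: Mapping[str, MetricsReport], which: str = "pooled") -> pd.DataFrame:
    """Tabular layout: rows = metrics, columns = scenarios A-E.

    ``which`` selects "pooled" metrics or "fold_mean" (average of per-fold
    values); both readings are emitted because pooling across folds and
    averaging per fold are both defensible summaries.
    """
    cols = {}
    for name, rep in reports.items():
        if which == "pooled":
            col = dict(rep.pooled)
        elif which == "fold_mean":
            col = rep.per_fold.drop(columns=["fold", "threshold"]).mean().to_dict()
        else:
            raise ValueError("which must be 'pooled' or 'fold_mean'")
        col["n_true_positives"] = rep.n_true_positives_available
        cols[name] = col
    return pd.DataFrame(cols)


def prediction_cdf(
    predictions: pd.Series, group_labels: pd.Series
) -> dict[str, pd.DataFrame]:
    """Empirical CDF of predicted probabilities per group.

    Returns, per group, a DataFrame of (probability, cumulative_share)
    pairs forming a nondecreasing step function from 0 to 1. Used to
    diagnose separability: a learner respecting the model assumptions piles
    unlabeled mass near probability 0 and labeled-positive mass near 1.
    """
    group_labels = group_labels.reindex(predictions.index)
    out: dict[str, pd.DataFrame] = {}
    for group in group_labels.dropna().unique():
        vals = np.sort(predictions[group_labels == group].to_numpy())
        if len(vals) == 0:
            continue
        uniq, counts = np.unique(vals, return_counts=True)
        out[str(group)] = pd.DataFrame(
            {"probability": uniq, "cumulative_share": np.cumsum(counts) / len(vals)}
        )
    return out
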