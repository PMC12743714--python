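"""External validity check: relabeling thresholds to population disease rates.

A PU learner applied to an undersampled learning sample relabels unlabeled
cases with probabilities above a threshold. The implied population disease
rate follows by transferring the relabeling rate among the learning sample's
unlabeled cases, r/u_t, to the full unlabeled pool of the initial sample:

    new positives  s_i = l_i + u_i * r / u_t
    new rate       s   = s_i / n_i        (n_i = l_i + u_i)

The ratio of the new rate to the raw coded rate l_i / n_i is then compared
with the multiplier that medical record review studies report for the true
rate over the coded rate (2.4 to 4.1 for sepsis): a ratio far above that
band means the learner relabels implausibly many cases, a ratio below it
means the threshold is too conservative. Because the raw rate shares the
denominator n_i, the ratio reduces to (l_i + transferred) / l_i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import classify, compute_recall, rank_order, top_k_size

__all__ = [
    "PopulationFrame",
    "RATE_RATIO_BENCHMARK",
    "derive_topk_threshold",
    "relabel",
    "compute_new_rate",
    "benchmark_ratio",
    "count_false_negatives",
    "build_validity_report",
    "THRESHOLD_RULES",
]

#: Multiplier range of record-review sepsis rates over raw coded rates.
RATE_RATIO_BENCHMARK = (2.4, 4.1)

#: Threshold rules reported in the validity table, loosest last.
THRESHOLD_RULES = ("top5", "top10", "top15", "top20", "top25", "top30", "class_label_mean")


@dataclass(frozen=True)
class PopulationFrame:
    """Counts linking the learning sample to the initial population.

    l_i: labeled positives in the initial sample; u_i: unlabeled cases in
    the initial sample; u_t: unlabeled cases in the (undersampled) learning
    sample. n_i = l_i + u_i and raw_rate = l_i / n_i follow.
    """

    l_i: int
    u_i: int
    u_t: int

    def __post_init__(self) -> None:
        if self.l_i < 0 or self.u_i < 0:
            raise ValueError("counts must be nonnegative")
        if self.u_t <= 0:
            raise ValueError("u_t must be positive")
        if self.u_t > self.u_i:
            raise ValueError("learning-sample unlabeled count cannot exceed the population's")

    @property
    def n_i(self) -> int:
        return self.l_i + self.u_i

    @property
    def raw_rate(self) -> float:
        return self.l_i / self.n_i


def derive_topk_threshold(
    fold_predictions: Mapping[int, pd.Series], k_percent: float
) -> float:
    """Mean across folds of the k-th-percentile ranked probability.

    Per fold, the threshold is the probability of the floor(k*N/100)-th
    ranked case (descending, ties by ascending case_id) — the smallest
    probability a case needs to sit in that fold's top k%.
    """
    if not 0 < k_percent <= 100:
        raise ValueError("k_percent must lie in (0, 100]")
    per_fold = []
    for fold, pred in fold_predictions.items():
        if len(pred) == 0:
            raise ValueError(f"fold {fold} has no predictions")
        size = top_k_size(len(pred), k_percent)
        if size == 0:
            raise ValueError(f"top {k_percent}% of fold {fold} is empty")
        kth_case = rank_order(pred)[size - 1]
        per_fold.append(float(pred.loc[kth_case]))
    return float(np.mean(per_fold))


def relabel(unlabeled_predictions: pd.Series, threshold: float) -> int:
    """Count of unlabeled cases relabeled positive at the threshold (>=)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return int((unlabeled_predictions >= threshold).sum())


def compute_new_rate(
    frame: PopulationFrame,
    relabel_count_t: int | None = None,
    *,
    transferred: float | None = None,
) -> dict[str, float]:
    """Transfer a relabel count to the initial sample and derive the new rate.

    Either ``relabel_count_t`` (relabeled unlabeled cases in the learning
    sample, transferred as u_i * r / u_t) or the already-transferred count
    may be given. The transferred count is kept as a real number; rounding
    happens only at report formatting.
    """
    if (relabel_count_t is None) == (transferred is None):
        raise ValueError("give exactly one of relabel_count_t or transferred")
    if transferred is None:
        if not 0 <= relabel_count_t <= frame.u_t:
            raise ValueError("relabel count must lie in [0, u_t]")
        transferred = frame.u_i * relabel_count_t / frame.u_t
    new_positive_count = frame.l_i + transferred
    new_rate = new_positive_count / frame.n_i
    return {
        "transferred_relabeled": float(transferred),
        "new_positive_count": float(new_positive_count),
        "new_rate": float(new_rate),
        "ratio": float(new_rate / frame.raw_rate),
    }


def benchmark_ratio(
    ratio: float, empirical_range: tuple[float, float] = RATE_RATIO_BENCHMARK
) -> str:
    """Classify a rate ratio against the record-review band (closed interval)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    lo, hi = empirical_range
    if ratio < lo:
        return "below"
    if ratio > hi:
        return "above"
    return "within"


def count_false_negatives(predicted_labels: pd.Series, labeled_positive_ids) -> int:
    """Labeled positives classified negative at the rule's threshold."""
    labeled = pd.Index(labeled_positive_ids)
    missing = labeled.difference(predicted_labels.index)
    if len(missing) > 0:
        raise ValueError("classifications must cover all labeled positives")
    return int((~predicted_labels.loc[labeled]).sum())


def build_validity_report(
    fold_predictions: Mapping[int, pd.Series],
    fold_thresholds: Mapping[int, float],
    dataset_frame: pd.DataFrame,
    population: PopulationFrame,
    rules: Sequence[str] = THRESHOLD_RULES,
) -> pd.DataFrame:
    """One validity row per threshold rule, mirroring the rate-transfer table.

    Thresholds for top-k rules are per-fold k-th-ranked probabilities
    averaged across folds; the class-label-mean rule averages the fold
    thresholds. Relabeling then applies the (single) averaged threshold to
    the pooled out-of-fold predictions so each unlabeled case receives
    exactly one decision. Recall and false negatives are measured on the
    labeled positives (scenario A truth) at the same threshold.
    """
    pooled = pd.concat([fold_predictions[k] for k in sorted(fold_predictions)])
    s = pd.Series(
        dataset_frame["s"].to_numpy(), index=dataset_frame["case_id"].to_numpy()
    ).reindex(pooled.index)
    unlabeled_pred = pooled[s == 0]
    labeled_ids = pooled.index[s == 1]
    truth = pd.Series(False, index=pooled.index)
    truth.loc[labeled_ids] = True

    rows = []
    for rule in rules:
        if rule == "class_label_mean":
            threshold = float(np.mean([fold_thresholds[k] for k in fold_thresholds]))
        elif rule.startswith("top"):
            threshold = derive_topk_threshold(fold_predictions, float(rule[3:]))
        else:
            raise ValueError(f"unknown threshold rule: {rule!r}")
        r_t = relabel(unlabeled_pred, threshold)
        transfer = compute_new_rate(population, r_t)
        decisions = classify(pooled, threshold)
        rec = compute_recall(decisions, truth)
        fn = count_false_negatives(decisions, labeled_ids)
        rows.append(
            {
                "threshold_rule": rule,
                "classification_threshold": threshold,
                "relabel_count_t": r_t,
                "transferred_relabeled": transfer["transferred_relabeled"],
                "new_positive_count": transfer["new_positive_count"],
                "new_rate": transfer["new_rate"],
                "ratio": transfer["ratio"],
                "verdict": benchmark_ratio(transfer["ratio"]) if transfer["ratio"] > 0 else "below",
                "recall": rec,
                "false_negatives": fn,
            }
        )
    return pd.DataFrame(rows)


def format_validity_report(report: pd.DataFrame) -> pd.DataFrame:
    """Display formatting: thresholds 5 d.p., counts rounded, ratio 1 d.p."""
    out = report.copy()
    out["classification_threshold"] = out["classification_threshold"].map(lambda v: f"{v:.5f}")
    for col in ("transferred_relabeled", "new_positive_count"):
        out[col] = out[col].round().astype(int)
    out["new_rate"] = out["new_rate"].map(lambda v: f"{100 * v:.2f}%")
    out["ratio"] = out["ratio"].round(1)
    out["recall"] = out["recall"].round(3)
    return out
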