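"""Two-step "spy" PU learner with a repeat-averaged threshold.

Step 1 seeds a fraction of the labeled positives ("spies") into the
unlabeled pool and fits a probabilistic classifier with positives as class 1
and unlabeled-plus-spies as class 0. Since the spies are known positives,
the lowest predicted probability among them marks how low a genuine
positive's score can fall; unlabeled cases scoring strictly below it are
taken as reliable negatives. A single spy draw makes that minimum fragile —
one outlying spy can drag the threshold arbitrarily low — so step 1 is
repeated with a fresh spy draw each time and the threshold is the arithmetic
mean of the per-repeat minima. Step 2 then trains a supervised classifier on
all labeled positives (spies included) versus the reliable negatives and
scores the remaining cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .classifiers import ClassifierSpec, make_classifier, positive_proba
from .datagen import PUDataset

__all__ = [
    "SpyConfig",
    "SpyFit",
    "select_spies",
    "spy_step1",
    "identify_reliable_negatives",
    "spy_step2_fit",
    "spy_fit",
    "spy_predict",
]


@dataclass
class SpyConfig:
    """Configuration of the two-step spy learner.

    ``spy_fraction`` of the labeled positives serve as spies in each
    repeat; ``n_repeats`` independent spy draws are averaged into the
    reliable-negative threshold. Classifier specs follow
    :func:`pucase.classifiers.make_classifier`.
    """

    spy_fraction: float = 0.10
    n_repeats: int = 1000
    step1_classifier: ClassifierSpec = "logistic"
    step2_classifier: ClassifierSpec = "naive_bayes"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.spy_fraction < 1.0:
            raise ValueError("spy_fraction must lie strictly between 0 and 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class SpyFit:
    """Fitted spy learner; per-repeat minima kept so the threshold is auditable."""

    per_repeat_min: np.ndarray
    threshold_t: float
    step1_probability: pd.Series  # unlabeled case_id -> mean step-1 probability
    reliable_negative_ids: frozenset[int]
    step2_model: BaseEstimator
    step2_train_label_mean: float
    feature_columns: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Serializable audit view: one row per repeat with its spy minimum."""
        return pd.DataFrame(
            {"repeat": np.arange(1, len(self.per_repeat_min) + 1),
             "spy_min_probability": self.per_repeat_min}
        )


def select_spies(
    positive_ids: np.ndarray | list[int], fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split labeled positives into spies and retained positives.

    The spy count is round(fraction * n_positives), but never below 1 so a
    repeat always has at least one spy to bound the threshold.
    """
    positive_ids = np.asarray(positive_ids)
    if len(positive_ids) < 2:
        raise ValueError("need at least 2 labeled positives to draw spies")
    n_spies = max(1, int(np.floor(fraction * len(positive_ids) + 0.5)))
    rng = np.random.default_rng(seed)
    spies = rng.choice(positive_ids, size=n_spies, replace=False)
    spy_set = set(spies.tolist())
    retained = np.array([p for p in positive_ids if p not in spy_set])
    return np.sort(spies), retained


def spy_step1(train: PUDataset, config: SpyConfig) -> tuple[float, pd.Series, np.ndarray]:
    """Run the repeated spy step.

    For each repeat: draw a fresh spy set, fit the step-1 classifier on
    retained positives (1) versus unlabeled plus spies (0), and record the
    minimum predicted positive-class probability among that repeat's spies.
    Returns the averaged threshold, each unlabeled case's step-1 probability
    averaged across repeats, and the per-repeat minima.
    """
    config.validate()
    f = train.frame
    pos_mask = f["s"] == 1
    if not pos_mask.any() or pos_mask.all():
        raise ValueError("spy step 1 needs both labeled positives and unlabeled cases")
    X = f[train.feature_columns].to_numpy(dtype=float)
    pos_idx = np.flatnonzero(pos_mask.to_numpy())
    unl_idx = np.flatnonzero(~pos_mask.to_numpy())
    unl_ids = f["case_id"].to_numpy()[unl_idx]

    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_repeats)]

    minima = np.empty(config.n_repeats)
    prob_sum = np.zeros(len(unl_idx))
    for r, seed_r in enumerate(child_seeds):
        spies_local, retained_local = select_spies(pos_idx, config.spy_fraction, seed_r)
        train_idx = np.concatenate([retained_local, unl_idx, spies_local])
        y_step1 = np.concatenate(
            [np.ones(len(retained_local), dtype=int),
             np.zeros(len(unl_idx) + len(spies_local), dtype=int)]
        )
        clf = make_classifier(config.step1_classifier, seed=seed_r)
        clf.fit(X[train_idx], y_step1)
        minima[r] = positive_proba(clf, X[spies_local]).min()
        prob_sum += positive_proba(clf, X[unl_idx])

    threshold_t = float(minima.mean())
    step1_probability = pd.Series(prob_sum / config.n_repeats, index=unl_ids)
    step1_probability.index.name = "case_id"
    return threshold_t, step1_probability, minima


def identify_reliable_negatives(
    step1_probability: pd.Series, threshold_t: float
) -> frozenset[int]:
    """Unlabeled cases whose step-1 probability is strictly below the threshold."""
    below = step1_probability.index[step1_probability.to_numpy() < threshold_t]
    return frozenset(int(i) for i in below)


def spy_step2_fit(
    train: PUDataset,
    reliable_negative_ids: frozenset[int],
    config: SpyConfig,
    *,
    threshold_t: float,
    step1_probability: pd.Series,
    per_repeat_min: np.ndarray,
) -> SpyFit:
    """Fit the supervised step-2 classifier.

    Training set: all labeled positives (spies are back among the
    positives) as class 1 versus the reliable negatives as class 0.
    Unlabeled cases that are not reliable negatives are excluded from
    training and later scored by the fitted model. The training-set label
    mean is recorded; it serves as the classification threshold downstream.
    """
    if not reliable_negative_ids:
        raise ValueError(
            "no reliable negatives identified; inspect the spy threshold and the "
            "step-1 classifier's probability spread before refitting"
        )
    f = train.frame
    pos_mask = (f["s"] == 1).to_numpy()
    rn_mask = f["case_id"].isin(reliable_negative_ids).to_numpy()
    if not pos_mask.any():
        raise ValueError("step 2 needs labeled positives")
    X = f[train.feature_columns].to_numpy(dtype=float)
    train_mask = pos_mask | rn_mask
    y2 = pos_mask[train_mask].astype(int)
    clf = make_classifier(config.step2_classifier, seed=config.seed)
    clf.fit(X[train_mask], y2)
    return SpyFit(
        per_repeat_min=np.asarray(per_repeat_min, dtype=float),
        threshold_t=float(threshold_t),
        step1_probability=step1_probability,
        reliable_negative_ids=frozenset(reliable_negative_ids),
        step2_model=clf,
        step2_train_label_mean=float(y2.mean()),
        feature_columns=list(train.feature_columns),
    )


def spy_fit(train: PUDataset, config: SpyConfig) -> SpyFit:
    """Run both spy steps on a PU training set."""
    if "no labeled positives" in train.flags:
        raise ValueError("dataset is flagged 'no labeled positives'; spy learning needs s=1 cases")
    threshold_t, step1_probability, minima = spy_step1(train, config)
    rn = identify_reliable_negatives(step1_probability, threshold_t)
    return spy_step2_fit(
        train,
        rn,
        config,
        threshold_t=threshold_t,
        step1_probability=step1_probability,
        per_repeat_min=minima,
    )


def spy_predict(fit: SpyFit, cases: PUDataset | pd.DataFrame) -> pd.Series:
    """Score cases with the step-2 model; returns case_id -> probability."""
    frame = cases.frame if isinstance(cases, PUDataset) else cases
    missing = [c for c in fit.feature_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"cases lack feature columns: {missing}")
    X = frame[fit.feature_columns].to_numpy(dtype=float)
    probs = positive_proba(fit.step2_model, X)
    out = pd.Series(probs, index=frame["case_id"].to_numpy())
    out.index.name = "case_id"
    return out
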