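"""Adaptive-resampling PU ensemble.

Treats unlabeled cases as putative negatives and iteratively estimates each
instance's probability of being mislabeled: at every iteration a training
set is resampled from the data with each instance *excluded* with
probability equal to its current mislabel estimate, a probabilistic
classifier is fitted on the resample, and the mislabel estimate is updated
to the predicted probability of the class opposite the instance's putative
label. Hidden positives sitting in the unlabeled pool thus accumulate high
mislabel probability and drop out of later training sets. The final model is
an ensemble fitted on independent low-mislabel resamples; its prediction is
the unweighted mean of member probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .classifiers import ClassifierSpec, make_classifier, positive_proba
from .datagen import PUDataset

__all__ = ["AdaConfig", "AdaFit", "ada_fit", "ada_predict"]


@dataclass
class AdaConfig:
    """Configuration of the adaptive-resampling learner.

    ``n_iterations`` caps the adaptive loop (early stop when the largest
    mislabel-probability change falls below ``tol``); ``ensemble_size``
    final models are fitted on independent low-mislabel resamples. The
    default base classifier is a radial-kernel SVM on min-max-normalized
    features. ``resample_mode`` "weighted_subsample" draws hard per-class
    resamples with selection weight 1 - mislabel; "weighted_fit" instead
    passes 1 - mislabel as a sample weight where the base classifier
    supports it.
    """

    n_iterations: int = 5
    ensemble_size: int = 20
    base_classifier: ClassifierSpec = "svm_rbf"
    resample_mode: Literal["weighted_subsample", "weighted_fit"] = "weighted_subsample"
    pin_labeled_positives: bool = True
    tol: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.resample_mode not in ("weighted_subsample", "weighted_fit"):
            raise ValueError("resample_mode must be 'weighted_subsample' or 'weighted_fit'")


@dataclass
class AdaFit:
    """Fitted ensemble plus the final per-case mislabel estimates."""

    member_models: list[BaseEstimator]
    per_case_mislabel_probability: pd.Series  # case_id -> final mislabel estimate
    train_label_mean: float
    feature_columns: list[str] = field(default_factory=list)


def _draw_resample(
    rng: np.random.Generator,
    mislabel: np.ndarray,
    putative: np.ndarray,
    pin_labeled_positives: bool,
) -> np.ndarray:
    """Resample indices, per putative class, weighted against mislabeling.

    Each class is bootstrap-resampled at its own size with selection weight
    1 - mislabel, so an instance's exclusion pressure equals its mislabel
    probability while class sizes stay fixed. Keeping the classes at fixed
    size matters: excluding instances globally lets the labeled positives
    thin out faster than the hidden positives sitting among the putative
    negatives, and the fit collapses to the majority class when the label
    frequency is near 1/2.

    With ``pin_labeled_positives`` the positive class is bootstrapped
    uniformly: a labeled positive is positive by construction of PU data
    (p(y=1|s=1) = 1), so down-weighting it by an estimated mislabel
    probability contradicts the labeling mechanism and lets early errors
    evict genuine positives permanently. Exclusion pressure then applies
    only to the putative negatives, where hidden positives actually live.
    """
    parts = []
    for cls in (0, 1):
        idx = np.flatnonzero(putative == cls)
        if cls == 1 and pin_labeled_positives:
            weights = np.ones(len(idx))
        else:
            weights = 1.0 - mislabel[idx]
        total = weights.sum()
        if total <= 0:
            weights = np.ones(len(idx))
            total = float(len(idx))
        parts.append(rng.choice(idx, size=len(idx), replace=True, p=weights / total))
    return np.concatenate(parts)


def _fit_weighted(clf, X, y, weights) -> bool:
    """Fit with per-sample weights if the estimator supports them."""
    from sklearn.pipeline import Pipeline

    try:
        if isinstance(clf, Pipeline):
            last = clf.steps[-1][0]
            clf.fit(X, y, **{f"{last}__sample_weight": weights})
        else:
            clf.fit(X, y, sample_weight=weights)
        return True
    except (TypeError, ValueError):
        return False


def ada_fit(train: PUDataset, config: AdaConfig) -> AdaFit:
    """Run the adaptive loop and fit the final ensemble.

    Putative labels start as the observed PU labels (labeled = positive,
    unlabeled = negative) with mislabel probability 0 everywhere. A labeled
    positive's mislabel probability is its predicted p(y=0|x); an unlabeled
    (putative negative) case's is its predicted p(y=1|x).
    """
    config.validate()
    if "no labeled positives" in train.flags:
        raise ValueError("dataset is flagged 'no labeled positives'; PU learning needs s=1 cases")
    f = train.frame
    putative = (f["s"] == 1).to_numpy().astype(int)
    if putative.sum() == 0 or putative.sum() == len(putative):
        raise ValueError("adaptive resampling needs both labeled positives and unlabeled cases")
    X = f[train.feature_columns].to_numpy(dtype=float)
    ids = f["case_id"].to_numpy()

    ss = np.random.SeedSequence(config.seed)
    loop_ss, ensemble_ss = ss.spawn(2)
    loop_rng = np.random.default_rng(loop_ss)

    mislabel = np.zeros(len(putative))
    for it in range(config.n_iterations):
        clf = make_classifier(
            config.base_classifier, seed=int(loop_ss.generate_state(1)[0] % (2**31)) + it
        )
        if config.resample_mode == "weighted_fit":
            fit_weights = 1.0 - mislabel
            if config.pin_labeled_positives:
                fit_weights = np.where(putative == 1, 1.0, fit_weights)
            if not _fit_weighted(clf, X, putative, fit_weights):
                resample = _draw_resample(loop_rng, mislabel, putative, config.pin_labeled_positives)
                clf.fit(X[resample], putative[resample])
        else:
            resample = _draw_resample(loop_rng, mislabel, putative, config.pin_labeled_positives)
            clf.fit(X[resample], putative[resample])
        p_pos = positive_proba(clf, X)
        new_mislabel = np.where(putative == 1, 1.0 - p_pos, p_pos)
        delta = float(np.abs(new_mislabel - mislabel).max())
        mislabel = new_mislabel
        if delta < config.tol:
            break

    member_models: list[BaseEstimator] = []
    for member_ss in ensemble_ss.spawn(config.ensemble_size):
        member_rng = np.random.default_rng(member_ss)
        resample = _draw_resample(member_rng, mislabel, putative, config.pin_labeled_positives)
        clf = make_classifier(
            config.base_classifier, seed=int(member_ss.generate_state(1)[0] % (2**31))
        )
        clf.fit(X[resample], putative[resample])
        member_models.append(clf)

    mislabel_series = pd.Series(mislabel, index=ids)
    mislabel_series.index.name = "case_id"
    return AdaFit(
        member_models=member_models,
        per_case_mislabel_probability=mislabel_series,
        train_label_mean=float(putative.mean()),
        feature_columns=list(train.feature_columns),
    )


def ada_predict(fit: AdaFit, cases: PUDataset | pd.DataFrame) -> pd.Series:
    """Ensemble probability: unweighted mean of member positive-class outputs."""
    frame = cases.frame if isinstance(cases, PUDataset) else cases
    missing = [c for c in fit.feature_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"cases lack feature columns: {missing}")
    X = frame[fit.feature_columns].to_numpy(dtype=float)
    probs = np.mean([positive_proba(m, X) for m in fit.member_models], axis=0)
    out = pd.Series(probs, index=frame["case_id"].to_numpy())
    out.index.name = "case_id"
    return out
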