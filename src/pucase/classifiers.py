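"""Base-classifier registry shared by both PU learners.

Any estimator exposing ``fit``/``predict_proba`` with a binary ``classes_``
attribute works; string specs name the reference configurations: a
regularized logistic scorer, Gaussian naive Bayes, gradient-boosted trees,
and a radial-kernel SVM whose scores are Platt-calibrated to probabilities.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC

__all__ = ["PlattScaledSVC", "make_classifier", "positive_proba", "ClassifierSpec"]

ClassifierSpec = Union[str, BaseEstimator]


class PlattScaledSVC(BaseEstimator, ClassifierMixin):
    """Radial-kernel SVM with Platt-scaled probability outputs.

    Fits an SVC, then a one-dimensional logistic regression mapping the
    training decision values to class probabilities — the standard
    score-to-probability calibration for maximum-margin classifiers, fitted
    on the training scores directly so a single SVM fit suffices.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale", cache_size: int = 500):
        self.C = C
        self.gamma = gamma
        self.cache_size = cache_size

    def fit(self, X, y, sample_weight=None):
        y = np.asarray(y)
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma, cache_size=self.cache_size)
        self.svc_.fit(X, y, sample_weight=sample_weight)
        scores = self.svc_.decision_function(X).reshape(-1, 1)
        self.platt_ = LogisticRegression()
        self.platt_.fit(scores, y, sample_weight=sample_weight)
        self.classes_ = self.platt_.classes_
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(X)

    def predict_proba(self, X):
        scores = self.svc_.decision_function(X).reshape(-1, 1)
        return self.platt_.predict_proba(scores)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


_REGISTRY = {
    # Logistic regression behind a standardizer: raw cost attributes span
    # orders of magnitude and an unscaled solver does not converge reliably.
    "logistic": lambda: Pipeline(
        [("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=1000))]
    ),
    "naive_bayes": lambda: GaussianNB(),
    "svm_rbf": lambda: Pipeline(
        [("scale", MinMaxScaler(clip=False)), ("clf", PlattScaledSVC())]
    ),
}


def _make_xgboost():
    from xgboost import XGBClassifier

    return XGBClassifier(n_jobs=1, tree_method="hist", verbosity=0)


def make_classifier(spec: ClassifierSpec, seed: int | None = None) -> BaseEstimator:
    """Instantiate a fresh, unfitted classifier from a spec.

    ``spec`` is a registry name ("logistic", "naive_bayes", "xgboost",
    "svm_rbf") or an estimator instance, which is cloned. When the estimator
    exposes a ``random_state`` parameter it is seeded for reproducibility.
    """
    if isinstance(spec, str):
        if spec == "xgboost":
            clf = _make_xgboost()
        elif spec in _REGISTRY:
            clf = _REGISTRY[spec]()
        else:
            raise ValueError(
                f"unknown classifier spec {spec!r}; known: "
                f"{sorted(_REGISTRY) + ['xgboost']}"
            )
    else:
        clf = clone(spec)
    if seed is not None:
        params = clf.get_params()
        seeds = {k: seed for k in params if k == "random_state" or k.endswith("__random_state")}
        if seeds:
            clf.set_params(**seeds)
    return clf


def positive_proba(clf: BaseEstimator, X) -> np.ndarray:
    """Predicted probability of the positive class (label 1)."""
    proba = clf.predict_proba(X)
    classes = list(getattr(clf, "classes_", [0, 1]))
    if 1 not in classes:
        # Degenerate single-class fit: everything scored as that class.
        return np.zeros(len(proba)) if classes == [0] else np.ones(len(proba))
    return np.asarray(proba)[:, classes.index(1)]
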