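"""Spy learner: spy selection, repeat-averaged threshold, reliable negatives."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from pucase import (
    SpyConfig,
    identify_reliable_negatives,
    select_spies,
    spy_fit,
    spy_predict,
    spy_step1,
    spy_step2_fit,
)
from pucase.datagen import GeneratorConfig, generate_pu_dataset, strong_shift_cost_features

from .conftest import toy_dataset


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class FixedScorer(BaseEstimator, ClassifierMixin):
    """Deterministic scorer: probability = sigmoid of the first feature.

    Ignores the training data, which makes spy-threshold arithmetic
    verifiable in closed form: the only randomness left is the spy draw.
    """

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = sigmoid(np.asarray(X)[:, 0])
        return np.column_stack([1 - p, p])


@pytest.fixture(scope="module")
def pu_separable():
    cfg = GeneratorConfig(
        n_cases=600,
        class_prior=0.25,
        label_frequency=0.5,
        cost_features=strong_shift_cost_features(),
        seed=21,
    )
    return generate_pu_dataset(cfg)


class TestSelectSpies:
    def test_ten_percent_of_hundred(self):
        spies, retained = select_spies(np.arange(100), 0.10, seed=0)
        assert len(spies) == 10 and len(retained) == 90
        assert set(spies).isdisjoint(retained)

    def test_rounding_floor_at_least_one(self):
        spies, retained = select_spies(np.arange(11), 0.10, seed=0)
        assert len(spies) == 1 and len(retained) == 10
        spies2, _ = select_spies(np.arange(2), 0.10, seed=0)
        assert len(spies2) == 1

    def test_seed_determinism(self):
        a, _ = select_spies(np.arange(50), 0.2, seed=9)
        b, _ = select_spies(np.arange(50), 0.2, seed=9)
        assert np.array_equal(a, b)

    def test_too_few_positives(self):
        with pytest.raises(ValueError):
            select_spies([1], 0.1, seed=0)


class TestSpyStep1:
    def _toy(self, pos_vals, unl_vals):
        n_pos, n_unl = len(pos_vals), len(unl_vals)
        return toy_dataset(
            {
                "case_id": list(range(1, n_pos + n_unl + 1)),
                "s": [1] * n_pos + [0] * n_unl,
                "x": list(pos_vals) + list(unl_vals),
            },
            ["x"],
        )

    def test_identical_positives_closed_form(self):
        """With identical positives the spy minimum is the same every repeat."""
        ds = self._toy([2.0] * 6, [-3.0, -1.0, 0.5])
        cfg = SpyConfig(spy_fraction=0.34, n_repeats=7, step1_classifier=FixedScorer(), seed=0)
        t, probs, minima = spy_step1(ds, cfg)
        assert t == pytest.approx(sigmoid(2.0))
        assert np.allclose(minima, sigmoid(2.0))
        # unlabeled probabilities are exact sigmoids, averaged over repeats
        np.testing.assert_allclose(probs.to_numpy(), sigmoid(np.array([-3.0, -1.0, 0.5])))

    def test_threshold_is_mean_over_spy_draws(self):
        """With one spy per repeat the threshold converges to the average of
        the per-positive sigmoids (uniform spy draw -> sampling-law oracle)."""
        pos_vals = [0.0, 1.0, 2.0]
        ds = self._toy(pos_vals, [-1.0, -2.0])
        cfg = SpyConfig(spy_fraction=0.34, n_repeats=400, step1_classifier=FixedScorer(), seed=1)
        t, _, minima = spy_step1(ds, cfg)
        expected = np.mean(sigmoid(np.array(pos_vals)))
        sd = np.std(sigmoid(np.array(pos_vals))) / np.sqrt(400)
        assert abs(t - expected) < 4 * sd
        assert t == pytest.approx(minima.mean())

    def test_single_repeat_threshold_is_that_runs_minimum(self):
        ds = self._toy([0.0, 1.0, 2.0, 3.0], [-1.0])
        cfg = SpyConfig(spy_fraction=0.5, n_repeats=1, step1_classifier=FixedScorer(), seed=5)
        t, _, minima = spy_step1(ds, cfg)
        assert len(minima) == 1 and t == minima[0]
        assert t in set(sigmoid(np.array([0.0, 1.0, 2.0, 3.0])))


class TestReliableNegatives:
    def test_strict_inequality(self):
        probs = pd.Series({1: 0.05, 2: 0.20, 3: 0.50})
        assert identify_reliable_negatives(probs, 0.21) == {1, 2}
        assert identify_reliable_negatives(probs, 0.20) == {1}

    def test_zero_threshold_empty(self):
        probs = pd.Series({1: 0.0, 2: 0.3})
        assert identify_reliable_negatives(probs, 0.0) == frozenset()

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(3)
        probs = pd.Series(rng.random(20), index=np.arange(100, 120))
        t = 0.4
        expected = frozenset(int(i) for i, p in probs.items() if p < t)
        assert identify_reliable_negatives(probs, t) == expected

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        probs = pd.Series(rng.random(50))
        sets = [identify_reliable_negatives(probs, t) for t in (0.1, 0.3, 0.6, 0.9)]
        for lo, hi in zip(sets, sets[1:]):
            assert lo <= hi


class TestStep2AndPredict:
    def test_empty_reliable_negatives_error(self, pu_separable):
        with pytest.raises(ValueError, match="no reliable negatives"):
            spy_step2_fit(
                pu_separable,
                frozenset(),
                SpyConfig(),
                threshold_t=0.5,
                step1_probability=pd.Series(dtype=float),
                per_repeat_min=np.array([0.5]),
            )

    def test_separable_fit_and_train_label_mean(self, pu_separable):
        cfg = SpyConfig(n_repeats=15, seed=2)
        fit = spy_fit(pu_separable, cfg)
        f = pu_separable.frame
        n_pos = int((f["s"] == 1).sum())
        n_rn = len(fit.reliable_negative_ids)
        assert fit.step2_train_label_mean == pytest.approx(n_pos / (n_pos + n_rn))
        # reliable negatives live among the unlabeled and score below threshold
        unl_ids = set(f.loc[f["s"] == 0, "case_id"])
        assert set(fit.reliable_negative_ids) <= unl_ids
        assert (fit.step1_probability.loc[list(fit.reliable_negative_ids)]
                < fit.threshold_t).all()
        # in the near-separable limit reliable negatives are latent negatives
        y = pd.Series(f["y"].to_numpy(), index=f["case_id"].to_numpy())
        purity = (y.loc[list(fit.reliable_negative_ids)] == 0).mean()
        assert purity > 0.95

    def test_predict_bounds_order_invariance_and_determinism(self, pu_separable):
        cfg = SpyConfig(n_repeats=10, seed=8)
        fit = spy_fit(pu_separable, cfg)
        preds = spy_predict(fit, pu_separable)
        assert ((preds >= 0) & (preds <= 1)).all()
        shuffled = pu_separable.frame.sample(frac=1, random_state=0).reset_index(drop=True)
        preds_shuffled = spy_predict(fit, shuffled)
        pd.testing.assert_series_equal(
            preds.sort_index(), preds_shuffled.sort_index(), check_names=False
        )
        fit2 = spy_fit(pu_separable, cfg)
        preds2 = spy_predict(fit2, pu_separable)
        pd.testing.assert_series_equal(preds, preds2)

    def test_predict_missing_features_error(self, pu_separable):
        fit = spy_fit(pu_separable, SpyConfig(n_repeats=5, seed=1))
        with pytest.raises(ValueError, match="feature columns"):
            spy_predict(fit, pu_separable.frame.drop(columns=["cost_icu"]))

    def test_recall_under_full_labeling(self, separable_dataset):
        """c=1 + strong separation: spy recall at the label-mean threshold
        is near-perfect (parameter-recovery property)."""
        cfg = SpyConfig(n_repeats=10, step1_classifier="logistic",
                        step2_classifier="xgboost", seed=3)
        fit = spy_fit(separable_dataset, cfg)
        preds = spy_predict(fit, separable_dataset)
        f = separable_dataset.frame
        pos_ids = f.loc[f["s"] == 1, "case_id"]
        recall = (preds.loc[pos_ids] >= fit.step2_train_label_mean).mean()
        assert recall >= 0.95
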