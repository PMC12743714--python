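"""Ranked-retrieval metrics, scenario logic, folds, CDF diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pucase import (
    SCENARIOS,
    classify,
    compute_precision_at_k,
    compute_recall,
    compute_recall_at_k,
    evaluate_all,
    make_cv_folds,
    prediction_cdf,
    scenario_truth,
)
from pucase.evaluation import rank_order, top_k_size

from .conftest import toy_dataset


def brute_force_topk(predictions: pd.Series, k_percent: float) -> list:
    """Independent oracle: sort (desc prob, asc id), slice floor(k*n/100)."""
    pairs = sorted(predictions.items(), key=lambda kv: (-kv[1], kv[0]))
    size = int(np.floor(k_percent * len(pairs) / 100.0))
    return [cid for cid, _ in pairs[:size]]


class TestFolds:
    def test_partition_and_sizes(self, small_dataset):
        folds = make_cv_folds(small_dataset, n_folds=5, seed=1)
        assert sorted(folds.index) == sorted(small_dataset.frame["case_id"])
        sizes = folds.value_counts()
        assert len(sizes) == 5 and sizes.max() - sizes.min() <= 1

    def test_stratification_preserves_label_mean(self, small_dataset):
        folds = make_cv_folds(small_dataset, n_folds=5, seed=2)
        f = small_dataset.frame
        s = pd.Series(f["s"].to_numpy(), index=f["case_id"].to_numpy())
        overall = s.mean()
        for fold in range(5):
            assert abs(s[folds == fold].mean() - overall) < 0.01

    def test_too_many_folds(self):
        ds = toy_dataset({"case_id": [1, 2], "s": [1, 0], "x": [0.1, 0.2]}, ["x"])
        with pytest.raises(ValueError):
            make_cv_folds(ds, n_folds=5)


class TestClassify:
    def test_threshold_conventions(self):
        preds = pd.Series({1: 0.2024, 2: 0.1, 3: 0.9})
        assert classify(preds, 0.2024).tolist() == [True, False, True]  # >= at boundary
        assert classify(preds, 0.0).all()


class TestRecall:
    def test_arithmetic(self):
        truth = pd.Series([True] * 500, index=range(500))
        labels = pd.Series([True] * 443 + [False] * 57, index=range(500))
        assert compute_recall(labels, truth) == pytest.approx(0.886)

    def test_extremes_and_missing(self):
        truth = pd.Series({1: True, 2: False})
        assert compute_recall(pd.Series({1: True, 2: True}), truth) == 1.0
        assert compute_recall(pd.Series({1: False, 2: False}), truth) == 0.0
        no_pos = pd.Series({1: False, 2: False})
        assert np.isnan(compute_recall(pd.Series({1: True, 2: True}), no_pos))


class TestTopK:
    def test_hand_example(self):
        # 10 cases, 4 truth positives, top 30% = 3 cases holding 2 of them
        probs = pd.Series([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.0],
                          index=range(10))
        truth = pd.Series([True, False, True, False, True, False, True, False,
                           False, False], index=range(10))
        assert compute_recall_at_k(probs, truth, 30) == pytest.approx(2 / 4)
        assert compute_precision_at_k(probs, truth, 30) == pytest.approx(2 / 3)

    def test_k_100_captures_everything(self):
        rng = np.random.default_rng(0)
        probs = pd.Series(rng.random(20), index=range(20))
        truth = pd.Series(rng.random(20) < 0.4, index=range(20))
        if truth.sum() > 0:
            assert compute_recall_at_k(probs, truth, 100) == 1.0

    def test_ties_broken_by_ascending_case_id(self):
        probs = pd.Series({5: 0.5, 1: 0.5, 3: 0.9})
        assert list(rank_order(probs)) == [3, 1, 5]

    def test_oracle_equivalence_randomized(self):
        """recall@k / precision@k match brute force exactly on random fixtures."""
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(5, 51))
            ids = rng.permutation(1000)[:n]
            probs = pd.Series(np.round(rng.random(n), 2), index=ids)  # forces ties
            truth = pd.Series(rng.random(n) < 0.3, index=ids)
            if truth.sum() == 0:
                continue
            for k in (10, 20, 30, 50):
                top = brute_force_topk(probs, k)
                expected_r = sum(truth[c] for c in top) / truth.sum()
                assert compute_recall_at_k(probs, truth, k) == expected_r
                if top:
                    expected_p = sum(truth[c] for c in top) / len(top)
                    assert compute_precision_at_k(probs, truth, k) == expected_p

    def test_recall_at_k_nondecreasing_in_k(self):
        rng = np.random.default_rng(7)
        probs = pd.Series(rng.random(40), index=range(40))
        truth = pd.Series(rng.random(40) < 0.3, index=range(40))
        vals = [compute_recall_at_k(probs, truth, k) for k in (10, 20, 30, 50, 100)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    probs=st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=2, max_size=40
    ),
    truth_bits=st.lists(st.booleans(), min_size=2, max_size=40),
    k=st.sampled_from([10, 20, 30, 50, 100]),
)
def test_topk_metric_invariants(probs, truth_bits, k):
    """Ranked metrics stay in [0,1]; the top set is a prefix of the ranking;
    recall@100 is 1 whenever any truth positive exists."""
    n = min(len(probs), len(truth_bits))
    preds = pd.Series(probs[:n], index=range(n))
    truth = pd.Series(truth_bits[:n], index=range(n))
    order = rank_order(preds)
    assert sorted(order) == list(range(n))
    p_sorted = preds.loc[order].to_numpy()
    assert all(a >= b for a, b in zip(p_sorted, p_sorted[1:]))
    if truth.sum() > 0:
        r = compute_recall_at_k(preds, truth, k)
        assert 0.0 <= r <= 1.0
        assert compute_recall_at_k(preds, truth, 100) == 1.0
    if top_k_size(n, k) > 0:
        p = compute_precision_at_k(preds, truth, k)
        assert 0.0 <= p <= 1.0


class TestScenarios:
    def test_predicate_set_relations(self, small_dataset):
        f = small_dataset.frame
        counts = {k: int(scenario_truth(f, v).sum()) for k, v in SCENARIOS.items()}
        assert counts["D"] == counts["A"] + counts["C"] - counts["B"]
        e = scenario_truth(f, SCENARIOS["E"])
        c = scenario_truth(f, SCENARIOS["C"])
        d = scenario_truth(f, SCENARIOS["D"])
        b = scenario_truth(f, SCENARIOS["B"])
        a = scenario_truth(f, SCENARIOS["A"])
        assert (e <= c).all() and (c <= d).all()
        assert (b <= a).all() and (a <= d).all()

    def test_hand_enumerated_truth_counts(self):
        ds = toy_dataset(
            {
                "case_id": [1, 2, 3, 4, 5, 6],
                "s": [1, 1, 0, 0, 0, 0],
                "explicit_flag": [1, 1, 0, 0, 0, 0],
                "implicit_flag": [1, 0, 1, 1, 0, 0],
                "x": [0.0] * 6,
            },
            ["x"],
        )
        counts = {k: int(scenario_truth(ds.frame, v).sum()) for k, v in SCENARIOS.items()}
        assert counts == {"A": 2, "B": 1, "C": 3, "D": 4, "E": 2}

    def test_explicit_equals_implicit_collapses_scenarios(self):
        ds = toy_dataset(
            {
                "case_id": [1, 2, 3, 4],
                "s": [1, 1, 0, 0],
                "explicit_flag": [1, 1, 0, 0],
                "implicit_flag": [1, 1, 0, 0],
                "x": [0.0] * 4,
            },
            ["x"],
        )
        counts = {k: int(scenario_truth(ds.frame, v).sum()) for k, v in SCENARIOS.items()}
        assert counts["A"] == counts["B"] == counts["C"] == counts["D"] == 2
        assert counts["E"] == 0


class TestEvaluateAll:
    def _setup(self):
        ds = toy_dataset(
            {
                "case_id": list(range(1, 11)),
                "s": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                "explicit_flag": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                "implicit_flag": [1, 0, 0, 1, 1, 0, 0, 0, 0, 0],
                "x": [0.0] * 10,
            },
            ["x"],
        )
        rng = np.random.default_rng(1)
        fold_preds = {
            0: pd.Series(rng.random(5), index=[1, 3, 5, 7, 9]),
            1: pd.Series(rng.random(5), index=[2, 4, 6, 8, 10]),
        }
        thresholds = {0: 0.3, 1: 0.3}
        return ds, fold_preds, thresholds

    def test_reports_cover_scenarios_and_bounds(self):
        ds, preds, thr = self._setup()
        reports = evaluate_all(preds, thr, ds, ks=(20, 50))
        assert set(reports) == {"A", "B", "C", "D", "E"}
        for rep in reports.values():
            vals = rep.per_fold.drop(columns=["fold", "threshold"]).to_numpy()
            finite = vals[~np.isnan(vals)]
            assert ((finite >= 0) & (finite <= 1)).all()

    def test_incomplete_coverage_rejected(self):
        ds, preds, thr = self._setup()
        del preds[1]
        with pytest.raises(ValueError, match="cover every case"):
            evaluate_all(preds, thr, ds)


class TestPredictionCdf:
    def test_step_function_values(self):
        preds = pd.Series([0.1, 0.1, 0.9, 0.9], index=range(4))
        groups = pd.Series(["u"] * 4, index=range(4))
        curve = prediction_cdf(preds, groups)["u"]
        assert curve["probability"].tolist() == [0.1, 0.9]
        assert curve["cumulative_share"].tolist() == [0.5, 1.0]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        preds = pd.Series(rng.random(50), index=range(50))
        groups = pd.Series(["a"] * 25 + ["b"] * 25, index=range(50))
        curves = prediction_cdf(preds, groups)
        for g in ("a", "b"):
            vals = np.sort(preds[groups == g].to_numpy())
            curve = curves[g]
            # oracle: share of values <= each reported probability
            for p, share in zip(curve["probability"], curve["cumulative_share"]):
                assert share == pytest.approx((vals <= p).mean())
            assert curve["cumulative_share"].is_monotonic_increasing
            assert curve["cumulative_share"].iloc[-1] == 1.0
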