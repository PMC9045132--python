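"""Splitting, SVM/Bi-GRU training and metric/ROC evaluation tests."""

import numpy as np
import pandas as pd
import pytest

from sleepmci.classify import (SvmConfig, evaluate, split_data, train_bigru,
                               train_svm)
from sleepmci.features import WAKE_FEATURES, FeatureTable
from sleepmci.gru import GruConfig


def _table(n=100, seed=0):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(rng.standard_normal((n, 21)), columns=WAKE_FEATURES)
    meta = pd.DataFrame({"subject": [f"s{i % 10}" for i in range(n)],
                         "group": [i % 2 for i in range(n)],
                         "state": "W", "start_s": 0.0})
    return FeatureTable(values=values, meta=meta, state="W")


def _blobs(n=200, d=36, sep=5.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = (np.arange(n) % 2).astype(int)
    X[y == 1, :4] += sep
    return X, y


class TestSplitData:
    def test_80_20_counts(self):
        train, test = split_data(_table(), 0.8, seed=0)
        assert train.size == 80 and test.size == 20

    def test_stratified(self):
        table = _table()
        train, test = split_data(table, 0.8, seed=1)
        y = table.y
        assert np.bincount(y[train]).tolist() == [40, 40]
        assert np.bincount(y[test]).tolist() == [10, 10]

    def test_subject_grouping_no_leakage(self):
        table = _table()
        train, test = split_data(table, 0.8, seed=2, grouping="subject")
        subj = table.meta["subject"].to_numpy()
        assert set(subj[train]).isdisjoint(set(subj[test]))

    def test_deterministic(self):
        t1 = split_data(_table(), 0.8, seed=3)
        t2 = split_data(_table(), 0.8, seed=3)
        assert np.array_equal(t1[0], t2[0]) and np.array_equal(t1[1], t2[1])

    def test_single_class_rejected(self):
        table = _table()
        table.meta["group"] = 0
        with pytest.raises(ValueError):
            split_data(table, 0.8, seed=0)


class TestTrainSvm:
    def test_separable_classes_high_accuracy(self):
        X, y = _blobs()
        model, cv_acc = train_svm(X[:160], y[:160], seed=0)
        acc = (model.predict(X[160:]) == y[160:]).mean()
        assert acc >= 0.95
        assert cv_acc >= 0.95

    def test_permuted_labels_chance_level(self):
        X, y = _blobs(seed=1)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        _, cv_acc = train_svm(X, y_perm, seed=0)
        assert cv_acc == pytest.approx(0.5, abs=0.10)

    def test_fixed_hyperparameters_accepted_without_search(self):
        X, y = _blobs(n=60, seed=2)
        model, _ = train_svm(X, y, SvmConfig(gamma=2.15, C=1.0), seed=0)
        assert model.gamma == 2.15 and model.C == 1.0

    def test_scores_in_unit_interval(self):
        X, y = _blobs(n=80, seed=3)
        model, _ = train_svm(X, y, seed=0)
        s = model.score01(X)
        assert np.all((s >= 0) & (s <= 1))


class TestTrainBigru:
    def test_separable_classes_learned(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((240, 36))
        y = (np.arange(240) % 2).astype(int)
        X[y == 1, :8] += 4.0  # widely separated class means
        cfg = GruConfig(hidden_size=12, n_layers=2, dropout=0.0,
                        max_epochs=80)
        model, info = train_bigru(X[:180], y[:180], cfg, cv_folds=5, seed=0)
        acc = ((model.predict_scores(X[180:]) >= 0.5) == y[180:]).mean()
        assert acc >= 0.95
        assert 1 <= info["best_epoch"] <= 80

    def test_width_mismatch_rejected(self):
        X, y = _blobs(n=20, d=21)
        with pytest.raises(ValueError):
            train_bigru(X, y, GruConfig(input_size=36), seed=0)


class TestEvaluate:
    def test_formula_oracle(self):
        # TP=14, FN=1, TN=14, FP=1: all four metrics are 93.33%
        scores = np.r_[np.ones(14), 0.0, np.zeros(14), 1.0]
        labels = np.r_[np.ones(15), np.zeros(15)].astype(int)
        rep = evaluate(scores, labels)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (14, 1, 14, 1)
        for value in (rep.accuracy, rep.sensitivity, rep.specificity, rep.f1):
            assert value == pytest.approx(93.33, abs=0.01)

    def test_metrics_match_bruteforce_counts(self, rng):
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        rep = evaluate(scores, labels)
        tp = sum(int(s >= 0.5 and y == 1) for s, y in zip(scores, labels))
        fn = sum(int(s < 0.5 and y == 1) for s, y in zip(scores, labels))
        tn = sum(int(s < 0.5 and y == 0) for s, y in zip(scores, labels))
        fp = sum(int(s >= 0.5 and y == 0) for s, y in zip(scores, labels))
        assert rep.accuracy == (tp + tn) / 500 * 100
        assert rep.sensitivity == tp / (tp + fn) * 100
        assert rep.specificity == tn / (tn + fp) * 100

    def test_perfect_ranking_auc_one(self):
        scores = np.r_[np.linspace(0.6, 0.9, 10), np.linspace(0.1, 0.4, 10)]
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        assert evaluate(scores, labels).auc == pytest.approx(1.0)

    def test_random_scores_auc_half(self, rng):
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert evaluate(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_auc_invariant_to_monotone_transform(self, rng):
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        a1 = evaluate(scores, labels).auc
        a2 = evaluate(1 / (1 + np.exp(-7 * scores)), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.random(400)
        labels = rng.integers(0, 2, 400)
        assert evaluate(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))
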