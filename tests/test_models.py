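"""Splitting, LOOCV, kNN, CFS/wrapper selection, ROC and evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from miredit.dfl import entropy, mutual_information
from miredit.models import (
    ClassifierSpec,
    ModelError,
    SplitSpec,
    cfs_select,
    evaluate_on_test,
    knn_classify,
    loocv,
    make_dfl_spec,
    make_knn_spec,
    roc_auc,
    stratified_split,
    wrapper_select,
    LabelGuard,
)


def _metadata(n_case, n_ctl):
    idx = [f"s{i:03d}" for i in range(n_case + n_ctl)]
    return pd.DataFrame(
        {
            "batch": ["b1"] * (n_case + n_ctl),
            "class": ["LUAD"] * n_case + ["CTL"] * n_ctl,
        },
        index=pd.Index(idx, name="sample"),
    )


class TestSplit:
    def test_study_sized_cohort_gives_316_train_79_test(self):
        meta = _metadata(197, 198)
        train, test = stratified_split(meta, SplitSpec(train_fraction=0.8, seed=0))
        assert len(train) == 316
        assert len(test) == 79

    def test_small_balanced_cohort_splits_4_4_1_1(self):
        meta = _metadata(5, 5)
        train, test = stratified_split(meta, SplitSpec(train_fraction=0.8, seed=1))
        classes = meta.loc[train, "class"].value_counts()
        assert classes["LUAD"] == 4 and classes["CTL"] == 4
        assert len(test) == 2

    def test_split_is_disjoint_and_exhaustive(self):
        meta = _metadata(23, 31)
        train, test = stratified_split(meta, SplitSpec(seed=7))
        assert set(train) | set(test) == set(meta.index)
        assert set(train) & set(test) == set()

    def test_class_proportions_preserved_within_one_sample(self):
        meta = _metadata(41, 59)
        train, _ = stratified_split(meta, SplitSpec(train_fraction=0.7, seed=3))
        got = meta.loc[train, "class"].value_counts()
        assert abs(got["LUAD"] - 0.7 * 41) <= 1
        assert abs(got["CTL"] - 0.7 * 59) <= 1

    def test_same_seed_reproduces_different_seed_changes(self):
        meta = _metadata(50, 50)
        a = stratified_split(meta, SplitSpec(seed=5))
        b = stratified_split(meta, SplitSpec(seed=5))
        c = stratified_split(meta, SplitSpec(seed=6))
        assert a == b
        assert a != c

    def test_single_sample_class_rejected(self):
        meta = _metadata(1, 9)
        with pytest.raises(ModelError):
            stratified_split(meta, SplitSpec())


class TestKNN:
    def test_query_equal_to_training_point_returns_its_label(self):
        x = np.array([[0.0, 0], [5, 5], [9, 9]])
        y = np.array(["a", "b", "c"])
        pred, _ = knn_classify(x, y, np.array([[5.0, 5]]), k=1)
        assert pred[0] == "b"

    def test_well_separated_clusters_classified_perfectly(self, rng):
        a = rng.normal(0, 0.5, (20, 3))
        b = rng.normal(10, 0.5, (20, 3))
        x = np.vstack([a, b])
        y = np.array(["A"] * 20 + ["B"] * 20)
        queries = np.vstack([rng.normal(0, 0.5, (5, 3)), rng.normal(10, 0.5, (5, 3))])
        pred, score = knn_classify(x, y, queries, k=6)
        assert pred.tolist() == ["A"] * 5 + ["B"] * 5
        assert np.all(score[:5] == 0.0) and np.all(score[5:] == 1.0)

    def test_k_equals_n_balanced_tie_resolved_by_mean_distance(self):
        # two votes each; the query sits nearer the "A" pair
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array(["A", "A", "B", "B"])
        pred, _ = knn_classify(x, y, np.array([[2.0]]), k=4)
        assert pred[0] == "A"

    def test_exact_tie_falls_back_to_smaller_label(self):
        x = np.array([[-1.0], [1.0]])
        y = np.array(["B", "A"])
        pred, _ = knn_classify(x, y, np.array([[0.0]]), k=2)
        assert pred[0] == "A"

    def test_invalid_k_rejected(self):
        x = np.zeros((3, 1))
        y = np.array([0, 1, 0])
        with pytest.raises(ModelError):
            knn_classify(x, y, x, k=0)
        with pytest.raises(ModelError):
            knn_classify(x, y, x, k=4)


class TestLOOCV:
    def test_duplicated_agreeing_points_score_perfectly(self):
        x = pd.DataFrame({"f": [0.0, 0.0, 5.0, 5.0]})
        y = np.array(["A", "A", "B", "B"])
        assert loocv(make_knn_spec(k=1), x, y) == 1.0

    def test_majority_classifier_flips_on_balanced_data(self):
        # leaving out one sample makes the other class the majority
        def fit(matrix, y):
            values, counts = np.unique(y, return_counts=True)
            return values[np.argmax(counts)]

        spec = ClassifierSpec(
            name="majority",
            fit=fit,
            predict=lambda model, m: np.repeat(model, len(m)),
        )
        x = pd.DataFrame({"f": np.arange(10.0)})
        y = np.array(["A"] * 5 + ["B"] * 5)
        assert loocv(spec, x, y) == 0.0

    def test_knn1_equals_nearest_neighbour_excluding_self(self, rng):
        x = pd.DataFrame(rng.random((20, 3)))
        y = rng.choice(["A", "B"], 20)
        acc = loocv(make_knn_spec(k=1), x, y)
        # brute-force oracle
        xm = x.to_numpy()
        correct = 0
        for i in range(20):
            d = np.linalg.norm(xm - xm[i], axis=1)
            d[i] = np.inf
            correct += int(y[np.argmin(d)] == y[i])
        assert acc == pytest.approx(correct / 20)


class TestCFS:
    def _su(self, a, b):
        ha, hb = entropy(a), entropy(b)
        return 0.0 if ha + hb == 0 else 2 * mutual_information(a, b) / (ha + hb)

    def _merit_oracle(self, x, y, subset):
        m = len(subset)
        if m == 0:
            return 0.0
        r_cf = np.mean([self._su(x[:, j], y) for j in subset])
        if m == 1:
            return r_cf
        pairs = [self._su(x[:, i], x[:, j]) for i, j in itertools.combinations(subset, 2)]
        r_ff = np.mean(pairs)
        return m * r_cf / np.sqrt(m + m * (m - 1) * r_ff)

    @pytest.mark.parametrize("strategy", ["best-first", "greedy-stepwise"])
    def test_perfect_feature_selected_alone(self, strategy, rng):
        n = 80
        y = rng.integers(0, 2, n)
        noise = rng.integers(0, 2, (n, 6))
        x = np.column_stack([noise[:, :3], y, noise[:, 3:]])
        matrix = pd.DataFrame(
            x.astype(float), columns=[f"n{i}" for i in range(3)] + ["hit"] + [f"n{i}" for i in range(3, 6)]
        )
        selected = cfs_select(matrix, y, strategy=strategy, n_bins=2)
        assert selected == ["hit"]
        # merit oracle agrees that the singleton beats every pair containing it
        j = 3
        best_merit = self._merit_oracle(x, y, (j,))
        for other in range(7):
            if other != j:
                assert self._merit_oracle(x, y, (j, other)) <= best_merit + 1e-9

    def test_duplicated_informative_feature_enters_once(self, rng):
        n = 100
        y = rng.integers(0, 2, n)
        f = y ^ (rng.random(n) < 0.1)
        x = pd.DataFrame(
            {
                "f1": f.astype(float),
                "f2": f.astype(float),  # exact duplicate: r_ff = 1 penalizes
                "n1": rng.integers(0, 2, n).astype(float),
            }
        )
        selected = cfs_select(x, y, strategy="greedy-stepwise", n_bins=2)
        assert "f1" in selected
        assert "f2" not in selected

    def test_all_noise_data_returns_nothing_informative(self, rng):
        y = np.array([0, 1] * 25)
        x = pd.DataFrame({"c1": np.ones(50), "c2": np.ones(50)})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-feature warnings expected
            selected = cfs_select(x, y, n_bins=2)
        assert len(selected) <= 1

    def test_adding_duplicate_of_best_feature_never_raises_merit(self, rng):
        n = 90
        y = rng.integers(0, 2, n)
        f = y ^ (rng.random(n) < 0.2)
        noise = rng.integers(0, 2, n)
        x = np.column_stack([f, f, noise])
        assert self._merit_oracle(x, y, (0, 1)) <= self._merit_oracle(x, y, (0,)) + 1e-9


class TestWrapper:
    def test_single_separating_feature_found_first(self, rng):
        n = 60
        y = np.array(["A", "B"] * (n // 2))
        sep = np.where(y == "A", 0.0, 10.0) + rng.normal(0, 0.1, n)
        x = pd.DataFrame({"sep": sep, "n1": rng.random(n), "n2": rng.random(n)})
        selected = wrapper_select(x, y, make_knn_spec(k=3), strategy="greedy-stepwise")
        assert selected[0] == "sep"
        assert len(selected) <= 2

    def test_all_noise_selection_stays_small_and_near_chance(self, rng):
        # forward search on noise stalls after at most a couple of chance
        # improvements; held-out accuracy of the result stays near 0.5
        y = np.array(["A", "B"] * 20)
        x = pd.DataFrame(rng.random((40, 4)), columns=list("abcd"))
        selected = wrapper_select(x, y, make_knn_spec(k=3), strategy="greedy-stepwise")
        assert len(selected) <= 3
        if selected:
            fresh = pd.DataFrame(rng.random((40, len(selected))), columns=selected)
            acc = loocv(make_knn_spec(k=3), fresh, y)
            assert abs(acc - 0.5) < 0.25

    def test_xor_pair_needs_best_first_with_table_classifier(self, rng):
        n = 80
        x1 = rng.integers(0, 2, n)
        x2 = rng.integers(0, 2, n)
        y = x1 ^ x2
        x = pd.DataFrame(
            {
                "p1": x1.astype(float),
                "p2": x2.astype(float),
                "n1": rng.integers(0, 2, n).astype(float),
            }
        )
        selected = wrapper_select(
            x, y, make_dfl_spec(), strategy="best-first", folds=4
        )
        assert {"p1", "p2"} <= set(selected)


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        curve, auc = roc_auc(scores, labels)
        assert auc == 1.0
        assert curve[0].tolist() == [0.0, 0.0]
        assert curve[-1].tolist() == [1.0, 1.0]

    def test_constant_scores_give_auc_half(self):
        _, auc = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == 0.5

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(25):
            n = 60
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice(np.linspace(0, 1, 15), n)  # heavy ties
            _, auc = roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)))
            assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_labels_rejected(self):
        with pytest.raises(ModelError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_staircase_is_monotone(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        curve, _ = roc_auc(scores, labels)
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)


class TestEvaluate:
    def test_all_correct_predictions_give_100_percent(self, rng):
        x = pd.DataFrame(rng.random((10, 2)))
        y = np.array(["A"] * 5 + ["B"] * 5)
        spec = ClassifierSpec("echo", fit=lambda m, yy: yy, predict=lambda mod, m: mod)
        report = evaluate_on_test(y, spec, x, y)
        assert report.accuracy == 100.0

    def test_confusion_counts_sum_to_n(self, rng):
        x = pd.DataFrame(rng.random((30, 2)))
        y = rng.choice(["A", "B"], 30)
        spec = ClassifierSpec(
            "random", fit=lambda m, yy: None,
            predict=lambda mod, m: np.random.default_rng(0).choice(["A", "B"], len(m)),
        )
        report = evaluate_on_test(None, spec, x, y)
        assert sum(report.confusion.values()) == 30


class TestLabelGuard:
    def test_training_access_to_test_labels_raises(self):
        meta = _metadata(4, 4)
        guard = LabelGuard(meta["class"], train_ids=list(meta.index[:6]))
        with pytest.raises(ModelError, match="forbidden"):
            guard.training_labels(list(meta.index))

    def test_test_labels_only_after_release(self):
        meta = _metadata(3, 3)
        guard = LabelGuard(meta["class"], train_ids=list(meta.index[:4]))
        with pytest.raises(ModelError):
            guard.test_labels(list(meta.index[4:]))
        guard.release()
        assert list(guard.test_labels(list(meta.index[4:]))) == ["CTL", "CTL"]
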