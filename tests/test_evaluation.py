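"""Prototype evaluation, metrics vs counting oracle, classifier heads."""

import numpy as np
import pytest

from ecgfewshot import (
    class_centers,
    compute_metrics,
    downstream_classify,
    fsl_evaluate,
    nearest_center_classify,
    split_database_query,
    split_dataset,
    subset_ablation,
)
from ecgfewshot.evaluation import aggregate_reports


def _embeddings(sizes: dict[str, int], rng, dim=20):
    X, y = [], []
    for label, n in sizes.items():
        X.append(rng.normal(size=(n, dim)))
        y.extend([label] * n)
    return np.vstack(X), np.array(y)


class TestSplitDatabaseQuery:
    def test_even_halves(self, rng):
        X, y = _embeddings({"A": 4, "B": 4}, rng)
        (Xdb, ydb), (Xq, yq) = split_database_query(X, y, rng)
        assert sorted(ydb) == ["A", "A", "B", "B"]
        assert sorted(yq) == ["A", "A", "B", "B"]

    def test_halving_then_truncation(self, rng):
        X, y = _embeddings({"A": 6, "B": 4}, rng)
        (Xdb, ydb), (Xq, yq) = split_database_query(X, y, rng)
        assert sorted(ydb) == ["A", "A", "B", "B"]
        assert sorted(yq) == ["A", "A", "A", "A", "B", "B"]
        assert len(ydb) + len(yq) == 10

    def test_database_classes_equal_cardinality(self, rng):
        X, y = _embeddings({"A": 9, "B": 5, "C": 13}, rng)
        (_, ydb), _ = split_database_query(X, y, rng)
        _, counts = np.unique(ydb, return_counts=True)
        assert len(set(counts)) == 1

    def test_small_class_rejected(self, rng):
        X, y = _embeddings({"A": 4, "B": 1}, rng)
        with pytest.raises(ValueError, match="fewer than 2"):
            split_database_query(X, y, rng)


class TestClassCenters:
    def test_single_member_center(self, rng):
        X, y = _embeddings({"A": 1, "B": 1}, rng)
        centers = class_centers(X, y)
        np.testing.assert_allclose(centers.centers[0], X[0])

    def test_midpoint(self):
        X = np.vstack([np.zeros(20), np.full(20, 2.0)])
        centers = class_centers(X, np.array(["A", "A"]))
        np.testing.assert_allclose(centers.centers[0], 1.0)

    def test_permutation_invariant(self, rng):
        X, y = _embeddings({"A": 5, "B": 3}, rng)
        perm = rng.permutation(len(y))
        a = class_centers(X, y)
        b = class_centers(X[perm], y[perm])
        np.testing.assert_allclose(a.centers, b.centers)

    def test_absent_class_rejected(self, rng):
        X, y = _embeddings({"A": 3}, rng)
        with pytest.raises(ValueError, match="absent"):
            class_centers(X, y, labels=["A", "B"])


class TestNearestCenter:
    def test_query_at_center(self, rng):
        X, y = _embeddings({"A": 3, "B": 3}, rng)
        centers = class_centers(X, y)
        label, scores = nearest_center_classify(centers.centers[1], centers)
        assert label == "B"
        assert scores[1] == 0.0

    def test_one_dimensional_toy(self):
        from ecgfewshot.evaluation import ClassCenters
        centers = ClassCenters(["low", "high"], np.array([[0.0], [10.0]]))
        label, _ = nearest_center_classify(np.array([4.0]), centers)
        assert label == "low"

    def test_tie_broken_by_catalog_order(self):
        from ecgfewshot.evaluation import ClassCenters
        centers = ClassCenters(["first", "second"], np.array([[0.0], [8.0]]))
        label, _ = nearest_center_classify(np.array([4.0]), centers)
        assert label == "first"


def counting_oracle(truth, pred, labels):
    """Nested-loop confusion counting, fully independent of compute_metrics."""
    out = {}
    for c in labels:
        tp = fp = tn = fn = 0
        for t, p in zip(truth, pred):
            if t == c and p == c:
                tp += 1
            elif t != c and p == c:
                fp += 1
            elif t == c and p != c:
                fn += 1
            else:
                tn += 1
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        out[c] = {
            "accuracy": (tp + tn) / len(truth),
            "precision": prec,
            "recall": rec,
            "f1": 2 * prec * rec / (prec + rec) if prec + rec else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
            "sensitivity": rec,
        }
    return out


class TestComputeMetrics:
    def test_stated_formula_values(self):
        # TP=3 FP=1 TN=4 FN=2 for the positive class
        truth = ["pos"] * 5 + ["neg"] * 5
        pred = ["pos"] * 3 + ["neg"] * 2 + ["pos"] * 1 + ["neg"] * 4
        report = compute_metrics(np.array(truth), np.array(pred),
                                 labels=["neg", "pos"])
        pc = report.per_class["pos"]
        assert pc["accuracy"] == pytest.approx(0.7)
        assert pc["precision"] == pytest.approx(0.75)
        assert pc["recall"] == pytest.approx(0.6)
        assert pc["f1"] == pytest.approx(2 / 3, abs=1e-4)
        assert pc["specificity"] == pytest.approx(0.8)
        assert report.metrics["accuracy"] == pytest.approx(0.7)

    def test_perfect_prediction(self, rng):
        truth = np.array(["A"] * 5 + ["B"] * 5)
        scores = np.zeros((10, 2))
        scores[truth == "A", 0] = 1.0
        scores[truth == "B", 1] = 1.0
        report = compute_metrics(truth, truth.copy(), scores, ["A", "B"])
        for name, value in report.metrics.items():
            assert value == pytest.approx(1.0), name

    def test_matches_counting_oracle_on_random_trials(self, rng):
        labels = ["a", "b", "c"]
        for _ in range(200):
            truth = rng.choice(labels, size=30)
            pred = rng.choice(labels, size=30)
            report = compute_metrics(truth, pred, labels=labels)
            oracle = counting_oracle(truth, pred, labels)
            for name in ("precision", "recall", "f1", "specificity", "sensitivity"):
                macro = np.mean([oracle[c][name] for c in labels])
                assert report.metrics[name] == pytest.approx(macro)
            assert report.metrics["accuracy"] == pytest.approx(
                np.mean(truth == pred)
            )
            assert report.confusion.sum() == 30

    def test_auc_invariant_under_monotone_transform(self, rng):
        truth = rng.choice(["A", "B"], size=40)
        scores = rng.normal(size=(40, 2))
        a = compute_metrics(truth, truth.copy(), scores, ["A", "B"]).metrics["auc"]
        b = compute_metrics(
            truth, truth.copy(), np.exp(3 * scores), ["A", "B"]
        ).metrics["auc"]
        assert a == pytest.approx(b)

    def test_single_class_auc_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            compute_metrics(
                np.array(["A", "A"]), np.array(["A", "A"]),
                np.ones((2, 1)), ["A"],
            )

    def test_label_outside_catalog(self):
        with pytest.raises(ValueError, match="catalog"):
            compute_metrics(np.array(["A"]), np.array(["Z"]), labels=["A", "B"])


class TestFslEvaluate:
    def test_recovery_accuracy(self, trained_fsl, two_class_qrs, recovery_config):
        model, _ = trained_fsl
        _, _, test = split_dataset(
            two_class_qrs, recovery_config.fractions, recovery_config.seed
        )
        report = fsl_evaluate(model, test, np.random.default_rng(0))
        assert report.metrics["accuracy"] >= 0.95

    def test_confusion_conservation_and_determinism(self, trained_fsl, two_class_qrs):
        model, _ = trained_fsl
        r1 = fsl_evaluate(model, two_class_qrs, np.random.default_rng(4))
        r2 = fsl_evaluate(model, two_class_qrs, np.random.default_rng(4))
        n_query = r1.confusion.sum()
        # database: floor(n_c/2) per class truncated to the minimum; rest query
        assert n_query == len(two_class_qrs) - 2 * min(
            sum(q.superclass == c for q in two_class_qrs) // 2
            for c in ("classA", "classB")
        )
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        assert r1.metrics == r2.metrics

    def test_singleton_database_equals_query_is_perfect(self, rng):
        # one embedding per class, database = query: each query is its own center
        X, y = _embeddings({"A": 1, "B": 1, "C": 1}, rng)
        centers = class_centers(X, y)
        preds = [nearest_center_classify(x, centers)[0] for x in X]
        assert list(preds) == list(y)


class TestDownstreamClassifiers:
    def test_knn_with_duplicated_test_vectors(self, rng):
        # class clusters offset so the 5-neighborhood of each duplicate is pure
        X, y = _embeddings({"A": 10, "B": 10}, rng)
        X[y == "A"] += 8.0
        X[y == "B"] -= 8.0
        report = downstream_classify(X, y, X[::4], y[::4], "knn-5")
        assert report.metrics["accuracy"] == 1.0

    def test_linear_svm_on_separable_classes(self, rng):
        Xa = rng.normal(size=(12, 20)) + 10.0
        Xb = rng.normal(size=(12, 20)) - 10.0
        X = np.vstack([Xa, Xb])
        y = np.array(["A"] * 12 + ["B"] * 12)
        report = downstream_classify(X[::2], y[::2], X[1::2], y[1::2], "svm-linear")
        assert report.metrics["accuracy"] == 1.0

    @pytest.mark.parametrize("name", ["xgboost", "random-forest", "decision-tree",
                                      "knn-20", "svm-poly", "svm-rbf", "svm-sigmoid"])
    def test_each_model_runs_and_is_deterministic(self, name, rng):
        X, y = _embeddings({"A": 20, "B": 20}, rng)
        train, test = np.arange(40) % 4 != 0, np.arange(40) % 4 == 0
        r1 = downstream_classify(X[train], y[train], X[test], y[test], name, seed=1)
        r2 = downstream_classify(X[train], y[train], X[test], y[test], name, seed=1)
        assert r1.metrics == r2.metrics

    def test_unknown_model_rejected(self, rng):
        X, y = _embeddings({"A": 4, "B": 4}, rng)
        with pytest.raises(ValueError, match="unknown model"):
            downstream_classify(X, y, X, y, "perceptron")


class TestAggregation:
    def test_avg_within_min_max_and_zero_std_when_identical(self, rng):
        truth = rng.choice(["A", "B"], size=20)
        pred = rng.choice(["A", "B"], size=20)
        report = compute_metrics(truth, pred, labels=["A", "B"])
        agg = aggregate_reports([report, report, report])
        for name, entry in agg.items():
            if np.isnan(entry["avg"]):
                continue
            assert entry["min"] - 1e-12 <= entry["avg"] <= entry["max"] + 1e-12
            assert entry["std"] == pytest.approx(0.0, abs=1e-12)


class TestCrossValidate:
    def test_five_repetitions_aggregate(self, two_class_qrs):
        from ecgfewshot import crossvalidate
        from ecgfewshot.training import TrainingConfig

        # larger test fraction: a 15% split of 24 records can leave a
        # class with a single member, which the database/query split rejects
        config = TrainingConfig(batch_size=8, max_epochs=1, patience=1, seed=5,
                                fractions=(0.5, 0.2, 0.3))
        agg, reports, seeds = crossvalidate(two_class_qrs, config, n_folds=5)
        assert len(reports) == 5
        assert len(set(seeds)) == 5
        for name, entry in agg.items():
            assert entry["min"] - 1e-12 <= entry["avg"] <= entry["max"] + 1e-12
            assert entry["std"] >= 0.0


class TestSubsetAblation:
    def test_full_fraction_reproduces_plain_evaluation(self, rng):
        X, y = _embeddings({"A": 30, "B": 30}, rng)
        Xq, yq = _embeddings({"A": 15, "B": 15}, rng)
        acc = subset_ablation(X, y, Xq, yq, fractions=(1.0,), seed=2)
        report = downstream_classify(X, y, Xq, yq, "random-forest", seed=2)
        assert acc[1.0] == pytest.approx(report.metrics["accuracy"])

    def test_one_accuracy_per_fraction(self, rng):
        X, y = _embeddings({"A": 30, "B": 30}, rng)
        Xq, yq = _embeddings({"A": 20, "B": 20}, rng)
        acc = subset_ablation(X, y, Xq, yq, fractions=(0.5, 0.8, 1.0), seed=2)
        assert sorted(acc) == [0.5, 0.8, 1.0]
        assert all(0.0 <= v <= 1.0 for v in acc.values())

    def test_subset_missing_class_rejected(self, rng):
        X, y = _embeddings({"A": 30, "B": 30}, rng)
        Xq, yq = _embeddings({"A": 39, "B": 1}, rng)
        with pytest.raises(ValueError, match="too small"):
            subset_ablation(X, y, Xq, yq, fractions=(0.05,),
                            rng=np.random.default_rng(0), seed=0)
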