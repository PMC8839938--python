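"""Losses, splits, triplet sampling and the two training loops."""

import numpy as np
import pytest
from scipy import stats

from ecgfewshot import (
    cross_entropy,
    euclidean_distance,
    sample_triplet_batch,
    split_dataset,
    train_softmax,
    triplet_margin_loss,
)
from ecgfewshot.training import TrainingConfig, train_fsl


class TestDistance:
    def test_identity(self):
        assert euclidean_distance(np.ones(5), np.ones(5)) == 0.0

    def test_hand_value(self):
        assert euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_symmetry(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 20))
            assert euclidean_distance(x, y) == pytest.approx(euclidean_distance(y, x))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance(np.zeros(3), np.zeros(4))


class TestTripletLoss:
    def test_degenerate_triplet_gives_margin(self):
        v = np.zeros(4)
        assert triplet_margin_loss(v, v, v, m=1.0) == 1.0

    def test_satisfied_margin_gives_zero(self):
        a = np.zeros(2)
        assert triplet_margin_loss(a, a, np.array([2.0, 0.0]), m=1.0) == 0.0

    def test_hand_value(self):
        a, p, n = np.array([0.0, 0.0]), np.array([3.0, 4.0]), np.array([1.0, 0.0])
        assert triplet_margin_loss(a, p, n, m=1.0) == pytest.approx(5.0)

    def test_nonnegative_and_zero_region(self, rng):
        # loss >= 0 everywhere, zero exactly when d(a,p) <= d(a,n) - m
        for _ in range(100):
            a, p, n = rng.normal(size=(3, 6))
            loss = triplet_margin_loss(a, p, n, m=1.0)
            assert loss >= 0
            sep = euclidean_distance(a, p) <= euclidean_distance(a, n) - 1.0
            assert (loss == 0.0) == sep


class TestCrossEntropy:
    def test_perfect_prediction(self):
        assert cross_entropy([0.0, 1.0, 0.0], [0, 1, 0]) == 0.0

    def test_uniform_over_five(self):
        p = np.full(5, 0.2)
        y = np.eye(5)[2]
        assert cross_entropy(p, y) == pytest.approx(np.log(5))

    def test_monotone_in_true_class_probability(self):
        losses = []
        for q in (0.2, 0.5, 0.9):
            p = np.array([q, (1 - q) / 2, (1 - q) / 2])
            losses.append(cross_entropy(p, [1, 0, 0]))
        assert losses[0] > losses[1] > losses[2]

    def test_zero_probability_rejected(self):
        with pytest.raises(ValueError, match="zero probability"):
            cross_entropy([0.0, 1.0], [1, 0])


class TestSplitDataset:
    def test_exact_fractions(self):
        train, val, test = split_dataset(list(range(100)), seed=0)
        assert (len(train), len(val), len(test)) == (70, 15, 15)

    def test_partition(self):
        data = list(range(53))
        train, val, test = split_dataset(data, seed=3)
        combined = sorted(train + val + test)
        assert combined == data

    def test_ptbxl_scale_rounding(self):
        train, val, test = split_dataset(list(range(17232)), seed=1)
        assert len(train) in (12062, 12063)
        assert len(train) + len(val) + len(test) == 17232
        assert abs(len(val) - 2585) <= 1 and abs(len(test) - 2585) <= 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_dataset([], seed=0)


class TestTripletSampling:
    def test_degenerate_count_distribution(self, two_class_qrs, rng):
        eight = [q for q in two_class_qrs if len(q) == 8]
        if len({q.superclass for q in eight}) < 2:
            pytest.skip("fixture draw left a single class at count 8")
        batch = sample_triplet_batch(eight, 4, rng)
        assert batch.qrs_count == 8

    def test_batch_contract(self, two_class_qrs, rng):
        batch = sample_triplet_batch(two_class_qrs, 6, rng)
        for a, p, n in zip(batch.anchors, batch.positives, batch.negatives):
            assert len(a) == len(p) == len(n) == batch.qrs_count
            assert p.superclass == a.superclass
            assert n.superclass != a.superclass

    def test_seed_determinism(self, two_class_qrs):
        b1 = sample_triplet_batch(two_class_qrs, 5, np.random.default_rng(9))
        b2 = sample_triplet_batch(two_class_qrs, 5, np.random.default_rng(9))
        assert [a.record_id for a in b1.anchors] == [a.record_id for a in b2.anchors]
        assert [n.record_id for n in b1.negatives] == [n.record_id for n in b2.negatives]

    def test_infeasible_dataset_rejected(self, two_class_qrs, rng):
        # one record per class at each count: no count supports a triplet
        seen = {}
        for q in two_class_qrs:
            seen.setdefault((len(q), q.superclass), q)
        lonely = [q for (c, lbl), q in seen.items()][:2]
        with pytest.raises(RuntimeError, match="no QRS count"):
            sample_triplet_batch(lonely[:1], 2, rng)

    def test_anchor_class_frequency_convergence(self, two_class_qrs):
        # anchor classes over many draws follow the dataset class frequencies
        rng = np.random.default_rng(11)
        # rebalance: 1:2 class frequencies at one shared cardinality
        eight = [q for q in two_class_qrs if len(q) == 9]
        a = [q for q in eight if q.superclass == "classA"][:3]
        b = [q for q in eight if q.superclass == "classB"][:6]
        dataset = a + b
        draws = []
        for _ in range(250):
            batch = sample_triplet_batch(dataset, 8, rng)
            draws.extend(x.superclass for x in batch.anchors)
        n_a = draws.count("classA")
        n_b = draws.count("classB")
        expected = np.array([len(a), len(b)]) / len(dataset) * (n_a + n_b)
        _, p = stats.chisquare([n_a, n_b], expected)
        assert p > 1e-3


class TestTrainFsl:
    def test_recovery_on_separable_classes(self, trained_fsl):
        _, history = trained_fsl
        assert history.best_val_accuracy >= 0.95
        assert len(history.val_accuracy) <= 200

    def test_checkpoint_is_validation_argmax(self, trained_fsl):
        _, history = trained_fsl
        assert history.val_accuracy[history.best_epoch] == max(history.val_accuracy)

    def test_frozen_optimizer_stops_at_patience(self, two_class_qrs):
        config = TrainingConfig(batch_size=4, max_epochs=50, patience=1,
                                lr=0.0, seed=5)
        _, history = train_fsl(two_class_qrs, config)
        assert len(history.val_accuracy) <= 2


class TestTrainSoftmax:
    def test_recovery_and_descent(self, two_class_qrs):
        config = TrainingConfig(batch_size=8, max_epochs=60, patience=15, seed=5)
        model, history, classes = train_softmax(two_class_qrs, 2, config)
        assert history.best_val_accuracy >= 0.95
        assert classes == ["classA", "classB"]
        # loss decreases from its starting level on separable data
        assert min(history.train_loss[1:]) < history.train_loss[0]

    def test_bit_reproducible_history(self, two_class_qrs):
        config = TrainingConfig(batch_size=8, max_epochs=4, patience=10, seed=3)
        _, h1, _ = train_softmax(two_class_qrs, 2, config)
        _, h2, _ = train_softmax(two_class_qrs, 2, config)
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy

    def test_class_count_mismatch_rejected(self, two_class_qrs):
        with pytest.raises(ValueError, match="classes"):
            train_softmax(two_class_qrs, 5, TrainingConfig(seed=0))
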