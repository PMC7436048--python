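import numpy as np
import pytest

from enosefs.containers import FeatureTable
from enosefs.fitness import (
    DataSplit,
    FitnessWeights,
    cross_validated_error,
    evaluate_subset,
    knn_error_rate,
    make_split,
)


def _table(values, labels):
    return FeatureTable(np.asarray(values, float), np.asarray(labels, int))


def _split_from(train, test):
    return DataSplit(train=train, test=test)


class TestKnnErrorRate:
    def test_self_match_k1(self):
        t = _table(np.random.default_rng(0).normal(size=(20, 3)), np.arange(20) % 2)
        assert knn_error_rate(t, t, np.ones(3), k=1) == 0.0

    def test_separated_gaussians_zero_error(self):
        rng = np.random.default_rng(1)
        a = rng.normal(-5, 0.1, (50, 4))
        b = rng.normal(5, 0.1, (50, 4))
        table = _table(np.vstack([a, b]), [0] * 50 + [1] * 50)
        split = make_split(table, 0.7, seed=0)
        err = knn_error_rate(split.train, split.test, np.ones(4), k=5)
        assert err == 0.0
        # brute-force confirmation: every test point's 5 nearest are same-class
        from scipy.spatial.distance import cdist

        d = cdist(split.test.values, split.train.values)
        nn = np.argsort(d, axis=1)[:, :5]
        assert np.all(split.train.labels[nn] == split.test.labels[:, None])

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(2)
        table = _table(rng.normal(size=(200, 5)), rng.permutation(np.arange(200) % 2))
        split = make_split(table, 0.7, seed=1)
        err = knn_error_rate(split.train, split.test, np.ones(5), k=5)
        assert err == pytest.approx(0.5, abs=0.1)

    def test_empty_mask_rejected(self):
        t = _table(np.zeros((10, 2)), np.arange(10) % 2)
        with pytest.raises(ValueError):
            knn_error_rate(t, t, np.zeros(2))

    def test_k_larger_than_train_rejected(self):
        t = _table(np.zeros((3, 2)), [0, 1, 0])
        with pytest.raises(ValueError):
            knn_error_rate(t, t, np.ones(2), k=5)


class TestEvaluateSubset:
    def _separable_split(self, dim=128):
        rng = np.random.default_rng(3)
        centre = np.ones(dim)
        train = _table(
            np.vstack([5 * centre + rng.normal(0, 0.1, (20, dim)),
                       -5 * centre + rng.normal(0, 0.1, (20, dim))]),
            [0] * 20 + [1] * 20,
        )
        return train

    def test_zero_error_full_mask_gives_size_penalty_only(self):
        train = self._separable_split()
        split = _split_from(train, train)
        res = evaluate_subset(np.ones(128), split)
        assert res.error_rate == 0.0
        assert res.fitness == pytest.approx(0.01, abs=1e-12)

    def test_total_error_full_mask_gives_one(self):
        train = self._separable_split(dim=8)
        flipped = FeatureTable(train.values, 1 - train.labels)
        split = _split_from(train, flipped)
        res = evaluate_subset(np.ones(8), split)
        assert res.error_rate == 1.0
        assert res.fitness == pytest.approx(1.0, abs=1e-12)

    def test_partial_error_arithmetic(self):
        # engineered test set: 2 of 10 rows sit at the wrong class centre
        rng = np.random.default_rng(4)
        dim = 128
        centre = np.ones(dim)
        train = _table(
            np.vstack([5 * centre + rng.normal(0, 0.05, (20, dim)),
                       -5 * centre + rng.normal(0, 0.05, (20, dim))]),
            [0] * 20 + [1] * 20,
        )
        test_vals = np.vstack([5 * centre + rng.normal(0, 0.05, (5, dim)),
                               -5 * centre + rng.normal(0, 0.05, (5, dim))])
        labels = np.array([0] * 5 + [1] * 5)
        labels[[0, 5]] = 1 - labels[[0, 5]]  # exactly 2 of 10 misclassified
        split = _split_from(train, _table(test_vals, labels))
        mask = np.zeros(dim, int)
        mask[:32] = 1
        res = evaluate_subset(mask, split)
        assert res.error_rate == pytest.approx(0.2)
        assert res.fitness == pytest.approx(0.99 * 0.2 + 0.01 * 32 / 128, abs=1e-12)
        assert res.fitness == pytest.approx(0.2005, abs=1e-12)

    def test_empty_mask_worst_fitness(self):
        train = self._separable_split(dim=4)
        split = _split_from(train, train)
        res = evaluate_subset(np.zeros(4), split)
        assert res.fitness == 1.0 and res.error_rate == 1.0 and res.n_selected == 0

    def test_deterministic(self, reference_split):
        mask = (np.arange(128) % 3 == 0).astype(int)
        r1 = evaluate_subset(mask, reference_split)
        r2 = evaluate_subset(mask, reference_split)
        assert r1.fitness == r2.fitness and r1.error_rate == r2.error_rate

    def test_constant_column_does_not_change_error(self, reference_split):
        # a zero-variance column contributes 0 to every distance
        base = reference_split
        aug_train = np.hstack([base.train.values, np.full((base.train.n_samples, 1), 7.0)])
        aug_test = np.hstack([base.test.values, np.full((base.test.n_samples, 1), 7.0)])
        aug = DataSplit(
            train=_table(aug_train, base.train.labels),
            test=_table(aug_test, base.test.labels),
        )
        m_with = np.r_[np.ones(128, int), 1]
        m_without = np.ones(128, int)
        assert (
            evaluate_subset(m_with, aug).error_rate
            == evaluate_subset(m_without, base).error_rate
        )

    def test_fitness_monotone_in_error_and_size(self):
        w = FitnessWeights()
        f = lambda err, ns: w.accuracy_weight * err + w.size_weight * ns / 128
        assert f(0.3, 10) > f(0.2, 10)
        assert f(0.2, 20) > f(0.2, 10)
        assert 0.0 <= f(0.0, 1) and f(1.0, 128) == 1.0


class TestCrossValidatedError:
    def test_separable_zero(self):
        rng = np.random.default_rng(5)
        t = _table(
            np.vstack([rng.normal(-5, 0.1, (30, 3)), rng.normal(5, 0.1, (30, 3))]),
            [0] * 30 + [1] * 30,
        )
        assert cross_validated_error(t, np.ones(3)) == 0.0

    def test_duplicated_rows_k1(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(15, 4))
        t = _table(np.vstack([vals, vals]), list(np.arange(15) % 3) * 2)
        assert cross_validated_error(t, np.ones(4), folds=5, k=1) == 0.0

    def test_chance_level(self):
        rng = np.random.default_rng(7)
        t = _table(rng.normal(size=(300, 4)), rng.permutation(np.arange(300) % 3))
        err = cross_validated_error(t, np.ones(4))
        assert err == pytest.approx(1 - 1 / 3, abs=0.1)

    def test_single_class_rejected(self):
        t = _table(np.random.default_rng(8).normal(size=(10, 2)), np.zeros(10))
        with pytest.raises(ValueError):
            cross_validated_error(t, np.ones(2))


def test_weights_invariant():
    w = FitnessWeights(0.95)
    assert w.size_weight == pytest.approx(0.05)
    with pytest.raises(ValueError):
        FitnessWeights(1.2)
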