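import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pushbroom import classify as cls


class TestSplitCounts:
    def test_reference_dataset_split(self):
        # 296,862 spectra at 0.7 -> 207,803 train / 89,059 test
        assert cls.split_counts(296862, 0.7) == (207803, 89059)

    def test_small_total(self):
        assert cls.split_counts(10, 0.7) == (7, 3)

    @settings(derandomize=True, max_examples=200)
    @given(total=st.integers(2, 10**7),
           frac=st.floats(0.01, 0.99))
    def test_conservation(self, total, frac):
        train, test = cls.split_counts(total, frac)
        assert train + test == total
        assert test >= 1 and train >= 0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            cls.split_counts(100, 1.0)
        with pytest.raises(ValueError):
            cls.split_counts(1, 0.7)

    def test_split_indices_partition(self):
        tr, te = cls.split_indices(1000, 0.7, seed=3)
        assert tr.size == 700 and te.size == 300
        assert np.array_equal(np.sort(np.concatenate([tr, te])),
                              np.arange(1000))


class TestNodeOutput:
    def test_zero_weights_relu(self):
        assert cls.node_output(np.ones(5), np.zeros(5), 0.0, "relu") == 0.0

    def test_zero_weights_logistic(self):
        assert cls.node_output(np.ones(5), np.zeros(5), 0.0,
                               "logistic") == 0.5

    def test_matches_scalar_loop_oracle(self):
        # brute-force oracle: explicit python loop over the weighted sum
        rng = np.random.default_rng(12)
        import math
        for _ in range(1000):
            d = rng.integers(1, 60)
            x = rng.normal(size=d)
            w = rng.normal(size=d)
            b = float(rng.normal())
            z = b
            for i in range(d):
                z += w[i] * x[i]
            assert cls.node_output(x, w, b, "relu") == pytest.approx(
                max(z, 0.0), abs=1e-12)
            assert cls.node_output(x, w, b, "logistic") == pytest.approx(
                1.0 / (1.0 + math.exp(-z)), abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cls.node_output(np.ones(3), np.ones(4), 0.0)


def constant_threshold_model(column: int = 0, n_features: int = 1):
    """Model predicting class B iff feature[column] > 0.5 (steep logistic)."""
    hw = np.zeros((n_features, 25))
    hw[column, 0] = 1.0
    ow = np.zeros((25, 1))
    ow[0, 0] = 1000.0
    return cls.MLPModel(hidden_weights=hw, hidden_biases=np.zeros(25),
                        output_weights=ow, output_bias=-500.0)


class TestTrain:
    def test_separable_blobs_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        n = 2000
        X = rng.normal(size=(n, 50))
        y = (np.arange(n) >= n // 2).astype(int)
        X[y == 1] += 5.0  # 5 sigma separation
        data = cls.LabeledDataset(X, y)
        tr, te = cls.split_indices(n, 0.7, seed=0)
        model = cls.train(data.subset(tr), seed=0)
        report = cls.evaluate(model, data.subset(te))
        assert report.accuracy == 1.0

    def test_reproducible_for_fixed_seed(self, leaf_dataset_small):
        data, _ = leaf_dataset_small
        tr, _ = cls.split_indices(len(data), 0.7, seed=0)
        small = data.subset(tr[:1500])
        m1 = cls.train(small, seed=4, max_iter=60)
        m2 = cls.train(small, seed=4, max_iter=60)
        assert np.array_equal(m1.hidden_weights, m2.hidden_weights)
        assert np.array_equal(m1.output_weights, m2.output_weights)

    def test_seed_stability_of_accuracy(self, leaf_dataset_small):
        data, _ = leaf_dataset_small
        tr, te = cls.split_indices(len(data), 0.7, seed=0)
        accs = []
        for seed in (0, 1):
            model = cls.train(data.subset(tr), seed=seed)
            accs.append(cls.evaluate(model, data.subset(te)).accuracy)
        assert abs(accs[0] - accs[1]) < 0.005

    def test_single_class_rejected(self):
        data = cls.LabeledDataset(np.random.default_rng(0).normal(size=(50, 5)),
                                  np.zeros(50, dtype=int))
        with pytest.raises(ValueError):
            cls.train(data)

    def test_nan_features_rejected(self):
        X = np.ones((10, 5))
        X[3, 2] = np.nan
        with pytest.raises(ValueError):
            cls.train(cls.LabeledDataset(X, np.arange(10) % 2))

    def test_monotone_difficulty_in_class_separation(self):
        # shrinking the blob separation never raises mean test accuracy
        rng = np.random.default_rng(1)
        mean_accs = []
        for sep in (3.0, 1.0, 0.3):
            accs = []
            for seed in range(3):
                n = 600
                X = rng.normal(size=(n, 10))
                y = (np.arange(n) % 2).astype(int)
                X[y == 1, 0] += sep
                data = cls.LabeledDataset(X, y)
                tr, te = cls.split_indices(n, 0.7, seed=seed)
                model = cls.train(data.subset(tr), seed=seed, max_iter=200)
                accs.append(cls.evaluate(model, data.subset(te)).accuracy)
            mean_accs.append(np.mean(accs))
        assert mean_accs[0] >= mean_accs[1] - 0.02
        assert mean_accs[1] >= mean_accs[2] - 0.02


class TestEvaluate:
    def test_perfect_predictions(self):
        model = constant_threshold_model()
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        report = cls.evaluate(model, cls.LabeledDataset(X, y))
        assert np.array_equal(report.confusion_matrix, [[2, 0], [0, 2]])
        assert report.accuracy == 1.0
        assert report.precision == (1.0, 1.0)
        assert report.recall == (1.0, 1.0)
        assert report.f_measure == (1.0, 1.0)

    def test_all_predicted_class_zero(self):
        model = constant_threshold_model()
        X = np.zeros((10, 1))  # every prediction is class 0
        y = np.array([0] * 7 + [1] * 3)
        report = cls.evaluate(model, cls.LabeledDataset(X, y))
        assert report.recall[0] == 1.0
        assert report.precision[0] == pytest.approx(0.7)  # prevalence
        assert np.isnan(report.precision[1])  # undefined, not silently 0
        assert report.recall[1] == 0.0

    def test_hand_built_confusion_arithmetic(self):
        # [[90, 10], [5, 95]]: accuracy 0.925, recall (0.9, 0.95),
        # precision (90/95, 95/105)
        model = constant_threshold_model()
        X = np.concatenate([np.zeros(90), np.ones(10),
                            np.zeros(5), np.ones(95)])[:, None]
        y = np.array([0] * 100 + [1] * 100)
        report = cls.evaluate(model, cls.LabeledDataset(X, y))
        assert np.array_equal(report.confusion_matrix, [[90, 10], [5, 95]])
        assert report.accuracy == pytest.approx(0.925)
        assert report.recall == pytest.approx((0.9, 0.95))
        assert report.precision == pytest.approx((90 / 95, 95 / 105))

    def test_row_sums_and_weighted_recall(self, leaf_dataset_small,
                                          trained_model):
        data, _ = leaf_dataset_small
        _, te = cls.split_indices(len(data), 0.7, seed=0)
        test = data.subset(te)
        report = cls.evaluate(trained_model, test)
        cm = report.confusion_matrix
        # row sums equal the true class counts
        assert cm[0].sum() == np.sum(test.y == 0)
        assert cm[1].sum() == np.sum(test.y == 1)
        # accuracy equals the prevalence-weighted mean of recalls
        weighted = (report.recall[0] * cm[0].sum()
                    + report.recall[1] * cm[1].sum()) / cm.sum()
        assert report.accuracy == pytest.approx(weighted)

    def test_empty_test_set_rejected(self, trained_model):
        with pytest.raises(ValueError):
            cls.evaluate(trained_model,
                         cls.LabeledDataset(np.empty((0, 50)),
                                            np.empty(0, dtype=int)))


class TestModelSerialization:
    def test_json_round_trip_preserves_predictions(self, trained_model,
                                                   leaf_dataset_small):
        data, _ = leaf_dataset_small
        restored = cls.MLPModel.from_json(trained_model.to_json())
        X = data.X[:100]
        assert np.allclose(restored.predict_proba(X),
                           trained_model.predict_proba(X), atol=1e-12)

    def test_wrong_feature_count_rejected(self, trained_model):
        with pytest.raises(ValueError):
            trained_model.predict_proba(np.ones((3, 7)))
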