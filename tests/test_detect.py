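"""Splitting, the threshold and recurrent detectors, and the experiments."""

import numpy as np
import pytest

from hrvnoci._lstm import TinyLSTM
from hrvnoci.detect import (
    DetectorConfig,
    RecurrentDetector,
    ThresholdDetector,
    evaluate,
    fit_detector,
    raw_baseline,
    split_dataset,
    window_size_experiment,
)
from hrvnoci.preprocess import UniformSeries


class TestSplitDataset:
    def test_reference_cohort_splits_71_15_18(self):
        split = split_dataset(104, seed=0)
        assert (len(split["train"]), len(split["validation"]),
                len(split["test"])) == (71, 15, 18)

    def test_largest_remainder_rounding_small_n(self):
        split = split_dataset(10, seed=0)
        assert (len(split["train"]), len(split["validation"]),
                len(split["test"])) == (7, 1, 2)

    def test_partition_is_disjoint_and_covering(self):
        split = split_dataset(53, seed=5)
        allidx = np.concatenate(list(split.values()))
        assert sorted(allidx) == list(range(53))

    def test_deterministic_given_seed(self):
        a = split_dataset(104, seed=9)
        b = split_dataset(104, seed=9)
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(2)


def _toy_features(rng, n_pos, n_neg, pos_scale=10.0, neg_scale=1.0):
    X = [rng.standard_normal(30) * pos_scale for _ in range(n_pos)]
    X += [rng.standard_normal(30) * neg_scale for _ in range(n_neg)]
    y = np.array(["T1"] * n_pos + ["T2"] * n_neg)
    return X, y


class TestThresholdDetector:
    def test_separable_case_is_perfect(self):
        rng = np.random.default_rng(0)
        X, y = _toy_features(rng, 10, 14)
        det = ThresholdDetector().fit(X, y, X, y)
        assert evaluate(det, X, y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            ThresholdDetector().fit([np.ones(5)] * 4, np.array(["T2"] * 4))

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        X, y = _toy_features(rng, 8, 8, pos_scale=2.0)
        d1 = ThresholdDetector().fit(X, y)
        d2 = ThresholdDetector().fit(X, y)
        assert d1.threshold_ == d2.threshold_
        np.testing.assert_array_equal(d1.predict(X), d2.predict(X))

    def test_orientation_follows_larger_statistic_class(self):
        rng = np.random.default_rng(2)
        X, y = _toy_features(rng, 10, 10)
        det = ThresholdDetector().fit(X, y)
        assert det.positive_class_ == "T1"


class TestEvaluate:
    def test_perfect_detector(self):
        class Perfect:
            def predict(self, X):
                return np.array(["T1"] * len(X))

        assert evaluate(Perfect(), [None] * 18, np.array(["T1"] * 18)) == 1.0

    def test_majority_class_arithmetic(self):
        class AlwaysT2:
            def predict(self, X):
                return np.array(["T2"] * len(X))

        y = np.array(["T1"] * 7 + ["T2"] * 11)
        assert evaluate(AlwaysT2(), [None] * 18, y) == pytest.approx(11 / 18)

    def test_matches_hamming_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.choice(["T1", "T2"], size=40)
        pred = rng.choice(["T1", "T2"], size=40)

        class Fixed:
            def predict(self, X):
                return pred

        acc = evaluate(Fixed(), [None] * 40, y)
        hamming = sum(a != b for a, b in zip(pred, y))
        assert acc == pytest.approx(1.0 - hamming / 40)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(None, [], np.array([]))


class TestTinyLSTM:
    def test_gradients_match_finite_differences(self):
        model = TinyLSTM(hidden_size=3, seed=0)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2, 5))
        y = np.array([1.0, 0.0])
        _, grads = model.loss_and_grads(X, y)
        eps = 1e-6
        for name in ("Wx", "Wh", "b", "w_out", "b_out"):
            p = model.params[name]
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = p[ix]
                p[ix] = orig + eps
                lp, _ = model.loss_and_grads(X, y)
                p[ix] = orig - eps
                lm, _ = model.loss_and_grads(X, y)
                p[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][ix] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_learns_mean_shifted_sequences(self):
        rng = np.random.default_rng(4)
        X = [rng.standard_normal(40) + 2.0 for _ in range(12)]
        X += [rng.standard_normal(40) - 2.0 for _ in range(12)]
        y = np.array(["T1"] * 12 + ["T2"] * 12)
        det = RecurrentDetector(hidden_size=8, epochs=40, input_length=40,
                                seed=0)
        det.fit(X, y)
        assert evaluate(det, X, y) >= 0.9

    def test_training_reproducible(self):
        rng = np.random.default_rng(5)
        X = [rng.standard_normal(30) for _ in range(10)]
        y = np.array(["T1", "T2"] * 5)
        p1 = RecurrentDetector(epochs=5, input_length=30, seed=3).fit(X, y).predict_proba(X)
        p2 = RecurrentDetector(epochs=5, input_length=30, seed=3).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_pad_and_truncate_contract(self):
        det = RecurrentDetector(input_length=6)
        short = det._to_fixed_length(np.array([1.0, 2.0]))
        np.testing.assert_array_equal(short, [1, 2, 0, 0, 0, 0])
        long = det._to_fixed_length(np.arange(10.0))
        np.testing.assert_array_equal(long, np.arange(6.0))


class TestFitDetector:
    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_detector([np.ones(5)] * 3, np.array(["T2"] * 3),
                         [np.ones(5)], np.array(["T2"]), DetectorConfig())

    def test_shuffled_labels_sit_in_chance_band(self):
        """With labels permuted, accuracy over 20 resampled splits collapses
        to the chance level for an 18-recording test set."""
        rng = np.random.default_rng(6)
        X, y = _toy_features(rng, 42, 62)
        accs = []
        for r in range(20):
            y_shuf = rng.permutation(y)
            split = split_dataset(104, seed=200 + r)
            det = fit_detector(
                [X[i] for i in split["train"]], y_shuf[split["train"]],
                [X[i] for i in split["validation"]], y_shuf[split["validation"]],
                DetectorConfig(),
            )
            accs.append(evaluate(det, [X[i] for i in split["test"]],
                                 y_shuf[split["test"]]))
        assert 0.35 <= np.mean(accs) <= 0.75


class TestExperiments:
    def _features_by_size(self, rng, n=24):
        y = np.array(["T1"] * (n // 2) + ["T2"] * (n // 2))
        out = {}
        for size in (150, 250, 350, 450, 550, 650):
            sep = size / 650.0 * 6.0  # separability grows with window size
            out[size] = [
                rng.standard_normal(20) + (sep if lbl == "T1" else 0.0)
                for lbl in y
            ]
        return out, y

    def test_returns_one_entry_per_selected_size(self):
        rng = np.random.default_rng(7)
        feats, y = self._features_by_size(rng)
        means, records = window_size_experiment(feats, y, repeats=2, seed=0)
        assert sorted(means) == [150, 250, 350, 450, 550, 650]
        assert set(records.columns) == {"window_size", "repeat", "split_seed",
                                        "accuracy"}
        assert all(0.0 <= a <= 1.0 for a in means.values())

    def test_single_repeat_reruns_identically(self):
        rng = np.random.default_rng(8)
        feats, y = self._features_by_size(rng)
        m1, r1 = window_size_experiment(feats, y, repeats=1, seed=4)
        m2, r2 = window_size_experiment(feats, y, repeats=1, seed=4)
        assert m1 == m2
        assert r1.equals(r2)

    def test_accuracy_invariant_to_recording_order(self):
        rng = np.random.default_rng(9)
        X, y = _toy_features(rng, 6, 6)
        det = ThresholdDetector().fit(X, y)
        perm = np.random.default_rng(0).permutation(len(y))
        acc1 = evaluate(det, X, y)
        acc2 = evaluate(det, [X[i] for i in perm], y[perm])
        assert acc1 == acc2

    def test_raw_baseline_reproducible(self):
        rng = np.random.default_rng(10)
        tachs = [
            UniformSeries(rng.standard_normal(200) +
                          (3.0 if i < 6 else 0.0), sampling_rate_hz=8.0)
            for i in range(12)
        ]
        y = np.array(["T1"] * 6 + ["T2"] * 6)
        cfg = DetectorConfig(backend="recurrent", input_length=50, epochs=5)
        a1, _ = raw_baseline(tachs, y, cfg, repeats=2, seed=0)
        a2, _ = raw_baseline(tachs, y, cfg, repeats=2, seed=0)
        assert a1 == a2
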