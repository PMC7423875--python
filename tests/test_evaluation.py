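"""Tests for the evaluation harness: splits, adapters, top-k curves,
parameter scans, leakage control, and null calibration."""

import numpy as np
import pytest

import sdejs
from sdejs.evaluation import EvalProtocol


class TestAccuracy:
    @pytest.mark.parametrize(
        "pred, true, expected",
        [
            ([0, 1, 1, 0], [0, 1, 0, 0], 0.75),
            ([1, 1], [1, 1], 1.0),
            ([0, 0], [1, 1], 0.0),
        ],
    )
    def test_known_values(self, pred, true, expected):
        assert sdejs.accuracy(pred, true) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sdejs.accuracy([0, 1], [0])


class TestHoldoutSplit:
    def test_balanced_binary_200_gives_150_50(self, rng):
        labels = np.repeat([0, 1], 100)
        tr, te = sdejs.holdout_split(labels, 0.75, rng)
        assert len(tr) == 150 and len(te) == 50
        assert (np.bincount(labels[tr]) == [75, 75]).all()

    def test_exact_partition(self, rng):
        labels = np.array([0] * 7 + [1] * 5 + [2] * 9)
        tr, te = sdejs.holdout_split(labels, 0.6, rng)
        combined = np.sort(np.concatenate([tr, te]))
        assert np.array_equal(combined, np.arange(labels.size))

    def test_half_split_of_four(self, rng):
        labels = np.array([0, 0, 1, 1])
        tr, te = sdejs.holdout_split(labels, 0.5, rng)
        assert len(tr) == 2 and len(te) == 2
        assert set(labels[tr]) == {0, 1} and set(labels[te]) == {0, 1}

    def test_seeded_determinism(self):
        labels = np.repeat([0, 1, 2], 20)
        a = sdejs.holdout_split(labels, 0.75, np.random.default_rng(5))
        b = sdejs.holdout_split(labels, 0.75, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tiny_class_rejected(self, rng):
        with pytest.raises(ValueError):
            sdejs.holdout_split(np.array([0, 0, 1]), 0.75, rng)


class TestAdapters:
    def test_ridge_learns_linear_task(self, rng):
        X = rng.standard_normal((80, 5))
        y = (X[:, 0] + 0.2 * rng.standard_normal(80) > 0).astype(int)
        adapter = sdejs.RidgeAdapter()
        state = adapter.train(X[:60], y[:60], random_state=0)
        assert sdejs.accuracy(adapter.predict(state, X[60:]), y[60:]) > 0.8

    def test_svm_learns_nonlinear_task(self, rng):
        X = rng.standard_normal((120, 2))
        y = (np.linalg.norm(X, axis=1) > 1.2).astype(int)
        adapter = sdejs.SvmAdapter(C=(1.0, 10.0), gamma=("scale", 0.1))
        state = adapter.train(X[:90], y[:90], random_state=0)
        assert sdejs.accuracy(adapter.predict(state, X[90:]), y[90:]) > 0.8

    def test_majority_adapter_is_constant(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.array([0] * 7 + [1] * 3)
        adapter = sdejs.MajorityClassAdapter()
        state = adapter.train(X, y)
        assert (adapter.predict(state, X) == 0).all()


class TestTopkCurve:
    def test_grid_shape_and_repeat_counts(self, small_dataset):
        X, labels, _ = small_dataset
        protocol = EvalProtocol(n_repeats=3, k_grid=(5, 10, 15), seed=1)
        result = sdejs.evaluate_topk_curve(
            X, labels, sdejs.sdejs_ranker(m=0), protocol, sdejs.RidgeAdapter()
        )
        assert len(result.table) == 3 * 3
        counts = result.table.groupby("k")["repeat"].count()
        assert (counts == 3).all()

    def test_default_k_grid_has_20_points(self, default_dataset):
        X, labels, _ = default_dataset
        protocol = EvalProtocol(n_repeats=1, seed=0)
        assert len(protocol.k_grid) == 20
        result = sdejs.evaluate_topk_curve(
            X, labels, sdejs.random_ranker(), protocol, sdejs.MajorityClassAdapter()
        )
        assert sorted(result.table["k"].unique()) == list(range(5, 101, 5))

    def test_majority_adapter_scores_class_proportion(self, small_dataset):
        X, labels, _ = small_dataset
        protocol = EvalProtocol(n_repeats=2, k_grid=(5, 10), seed=3)
        result = sdejs.evaluate_topk_curve(
            X, labels, sdejs.random_ranker(), protocol, sdejs.MajorityClassAdapter()
        )
        # balanced binary task: majority prediction scores ~0.5 on the
        # stratified test side
        assert np.allclose(result.table["accuracy"], 0.5)

    def test_informative_ranking_beats_random(self, small_dataset):
        """A ranking that recovers the planted support must outperform a
        random ranking at the same k (paired repeats)."""
        X, labels, support = small_dataset
        Xs = sdejs.scale_features(X)
        k = len(support)
        protocol = EvalProtocol(n_repeats=20, k_grid=(k,), seed=7)
        informative = sdejs.evaluate_topk_curve(
            Xs, labels, sdejs.sdejs_ranker(theta=0.01, m=0), protocol,
            sdejs.RidgeAdapter(),
        )
        random = sdejs.evaluate_topk_curve(
            Xs, labels, sdejs.random_ranker(), protocol, sdejs.RidgeAdapter()
        )
        assert (
            informative.table["accuracy"].mean() > random.table["accuracy"].mean()
        )

    def test_k_exceeding_d_rejected(self, small_dataset):
        X, labels, _ = small_dataset
        protocol = EvalProtocol(n_repeats=1, k_grid=(X.n_features + 5,))
        with pytest.raises(ValueError):
            sdejs.evaluate_topk_curve(
                X, labels, sdejs.random_ranker(), protocol, sdejs.RidgeAdapter()
            )

    def test_no_test_sample_reaches_the_ranker(self, small_dataset):
        """Instrumented ranker: the sample set it sees per repeat must be
        the training side of the split only."""
        X, labels, _ = small_dataset
        seen = []

        def spying_ranker(X_train, labels_train, seed=0):
            seen.append(set(X_train.sample_ids))
            return sdejs.random_ranker()(X_train, labels_train, seed)

        protocol = EvalProtocol(n_repeats=4, k_grid=(5,), train_fraction=0.75, seed=2)
        sdejs.evaluate_topk_curve(
            X, labels, spying_ranker, protocol, sdejs.MajorityClassAdapter()
        )
        n_train = 0.75 * X.n_samples
        assert len(seen) == 4
        assert all(abs(len(s) - n_train) <= 1 for s in seen)
        assert len(set.union(*seen)) > n_train  # different splits per repeat

    def test_rank_once_mode_accepts_fixed_ranking(self, small_dataset):
        X, labels, _ = small_dataset
        fixed = sdejs.random_ranker()(X, labels, seed=0)
        protocol = EvalProtocol(n_repeats=2, k_grid=(5,), seed=0)
        result = sdejs.evaluate_topk_curve(
            X, labels, fixed, protocol, sdejs.MajorityClassAdapter()
        )
        assert (result.table["selector"] == "fixed").all()


class TestParameterScan:
    def test_grid_dimensions(self, small_dataset):
        X, labels, _ = small_dataset
        protocol = EvalProtocol(
            n_repeats=1, theta_grid=(0.01, 0.1), m_grid=(1, 2, 3),
            fixed_k_for_scan=10, seed=0,
        )
        table = sdejs.parameter_scan(
            X, labels, protocol, sdejs.MajorityClassAdapter()
        )
        assert len(table) == 6
        assert set(table["theta"]) == {0.01, 0.1}
        assert set(table["m"]) == {1, 2, 3}

    def test_default_grid_is_10_by_10(self):
        protocol = EvalProtocol()
        assert len(protocol.theta_grid) * len(protocol.m_grid) == 100

    def test_sigma_zero_rows_identical_across_m(self, small_dataset):
        """With no random shift every layer refits the same problem, so
        the scan must not depend on the layer count."""
        X, labels, _ = small_dataset
        protocol = EvalProtocol(
            n_repeats=2, theta_grid=(0.1,), m_grid=(1, 3), fixed_k_for_scan=8, seed=5
        )
        table = sdejs.parameter_scan(
            X, labels, protocol, sdejs.RidgeAdapter(), sigma=0.0
        )
        accs = table["mean_acc"].to_numpy()
        assert accs[0] == pytest.approx(accs[1], abs=1e-12)

    def test_scan_deterministic_under_seed(self, small_dataset):
        X, labels, _ = small_dataset
        protocol = EvalProtocol(
            n_repeats=2, theta_grid=(0.1,), m_grid=(1,), fixed_k_for_scan=5, seed=9
        )
        t1 = sdejs.parameter_scan(X, labels, protocol, sdejs.RidgeAdapter())
        t2 = sdejs.parameter_scan(X, labels, protocol, sdejs.RidgeAdapter())
        assert t1.equals(t2)


class TestNullCalibration:
    def test_permuted_labels_score_chance(self, rng):
        """With labels permuted, accuracy must sit within 3 standard
        errors of 0.5 on a balanced binary task."""
        spec = sdejs.SyntheticSpec(
            n_samples=100, n_features=40, n_informative=5, n_classes=2, seed=7
        )
        X, labels, _ = sdejs.make_sparse_classification(spec)
        permuted = rng.permutation(labels)
        protocol = EvalProtocol(n_repeats=50, k_grid=(10,), seed=13)
        result = sdejs.evaluate_topk_curve(
            X, permuted, sdejs.sdejs_ranker(m=0), protocol, sdejs.RidgeAdapter()
        )
        acc = result.table["accuracy"]
        se = acc.std(ddof=1) / np.sqrt(len(acc))
        assert abs(acc.mean() - 0.5) <= 3 * se


class TestEvalResult:
    def test_aggregation_bounds(self, small_dataset):
        X, labels, _ = small_dataset
        protocol = EvalProtocol(n_repeats=3, k_grid=(5, 10), seed=4)
        result = sdejs.evaluate_topk_curve(
            X, labels, sdejs.random_ranker(), protocol, sdejs.RidgeAdapter()
        )
        agg = result.aggregate()
        for _, row in agg.iterrows():
            cell = result.table[result.table["k"] == row["k"]]["accuracy"]
            assert cell.min() - 1e-12 <= row["mean_acc"] <= cell.max() + 1e-12

    def test_out_of_range_accuracy_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            sdejs.EvalResult(
                pd.DataFrame(
                    {"selector": ["x"], "classifier": ["y"], "k": [1],
                     "repeat": [0], "accuracy": [1.5]}
                )
            )
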