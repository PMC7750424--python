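"""Logistic predictor: labels, probabilities, metrics, protocol."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import f1_score, precision_score, roc_auc_score

from spyield import (
    LabelScheme,
    LogisticModel,
    SplitPlan,
    VariantRecord,
    categorize,
    dummy_baseline,
    fit,
    load_dataset,
    normalize_rate,
    pairwise_auc,
    run_replicates,
    save_dataset,
    split,
    weighted_f1,
    weighted_precision,
)
from spyield.production_model import (
    fit_penalized_logistic,
    records_to_xy,
)


def make_records(X, rates, ids=None):
    return [
        VariantRecord(id=ids[i] if ids else f"v{i}", features=X[i], production_rate=rates[i])
        for i in range(len(rates))
    ]


def separable_records(n_per_class=30, seed=0, d=20):
    """Three classes split along one feature; linearly separable."""
    rng = np.random.default_rng(seed)
    X, rates = [], []
    for k, (center, rate) in enumerate([(0.0, 5.0), (10.0, 45.0), (20.0, 95.0)]):
        block = rng.uniform(0, 2, size=(n_per_class, d))
        block[:, 0] += center
        X.append(block)
        rates += [rate] * n_per_class
    return make_records(np.vstack(X), rates)


class TestRatesAndLabels:
    def test_normalize_rate(self):
        assert normalize_rate(5, 5) == 100.0
        assert normalize_rate(12, 5) == 240.0
        assert normalize_rate(0, 5) == 0.0
        with pytest.raises(ValueError):
            normalize_rate(1, 0)

    @pytest.mark.parametrize(
        "rate,label",
        [(0, 0), (19.99, 0), (20, 1), (45, 1), (70, 1), (70.01, 2), (240, 2)],
    )
    def test_threshold_scheme(self, rate, label):
        assert categorize(rate) == label

    def test_invalid_rates_rejected(self):
        for bad in (-1.0, math.nan, math.inf):
            with pytest.raises(ValueError):
                categorize(bad)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 500), st.floats(0, 500))
    def test_categorize_is_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert categorize(lo) <= categorize(hi)

    def test_custom_scheme(self):
        scheme = LabelScheme(low_cut=10, high_cut=90)
        assert categorize(15, scheme) == 1
        with pytest.raises(ValueError):
            LabelScheme(low_cut=90, high_cut=10)


class TestClassProbability:
    def test_zero_model_gives_half(self):
        m = LogisticModel(intercepts=np.zeros(3), coefficients=np.zeros((3, 4)))
        assert m.class_probability(np.zeros(4)) == pytest.approx([0.5] * 3)

    def test_large_intercept_saturates(self):
        m = LogisticModel(intercepts=np.array([50.0]), coefficients=np.zeros((1, 2)))
        assert m.class_probability(np.zeros(2))[0] == pytest.approx(1.0)

    def test_hand_computed_affine_score(self):
        m = LogisticModel(intercepts=np.array([2.0]), coefficients=np.array([[1.0, -1.0]]))
        assert m.class_probability(np.array([3.0, 5.0]))[0] == pytest.approx(0.5)

    def test_matches_bruteforce_sigmoid(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            b0 = rng.normal(size=3)
            B = rng.normal(size=(3, 6))
            x = rng.normal(size=6)
            m = LogisticModel(intercepts=b0, coefficients=B)
            expected = [1.0 / (1.0 + math.exp(-(b0[k] + B[k] @ x))) for k in range(3)]
            assert m.class_probability(x) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        m = LogisticModel(intercepts=np.zeros(3), coefficients=np.zeros((3, 4)))
        with pytest.raises(ValueError):
            m.class_probability(np.zeros(5))

    def test_predict_tie_breaks_to_lower_class(self):
        m = LogisticModel(intercepts=np.zeros(3), coefficients=np.zeros((3, 2)))
        assert m.predict(np.ones(2)) == 0

    def test_normalized_scores_sum_to_one(self):
        rng = np.random.default_rng(0)
        m = LogisticModel(intercepts=rng.normal(size=3), coefficients=rng.normal(size=(3, 4)))
        s = m.normalized_scores(rng.normal(size=(5, 4)))
        assert np.allclose(s.sum(axis=1), 1.0)


class TestMetricOracles:
    """Own metric implementations versus the scikit-learn reference."""

    def _random_instance(self, rng):
        n = rng.integers(6, 40)
        y = rng.integers(0, 3, size=n)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 3, size=n)
        pred = rng.integers(0, 3, size=n)
        scores = rng.random((n, 3))
        scores /= scores.sum(axis=1, keepdims=True)
        return y, pred, scores

    def test_weighted_precision_and_f1_match_sklearn(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            y, pred, _ = self._random_instance(rng)
            assert weighted_precision(y, pred) == pytest.approx(
                precision_score(y, pred, average="weighted", zero_division=0), abs=1e-10
            )
            assert weighted_f1(y, pred) == pytest.approx(
                f1_score(y, pred, average="weighted", zero_division=0), abs=1e-10
            )

    def test_pairwise_auc_matches_sklearn_pairwise(self):
        rng = np.random.default_rng(321)
        for _ in range(100):
            y, _, scores = self._random_instance(rng)
            if len(np.unique(y)) < 3:
                continue
            vals = []
            for j in range(3):
                for k in range(j + 1, 3):
                    mask = (y == j) | (y == k)
                    auc_k = roc_auc_score((y[mask] == k).astype(int), scores[mask, k])
                    auc_j = roc_auc_score((y[mask] == j).astype(int), scores[mask, j])
                    vals.append((auc_j + auc_k) / 2)
            assert pairwise_auc(y, scores) == pytest.approx(np.mean(vals), abs=1e-10)

    def test_pairwise_auc_bruteforce_six_samples(self):
        """Exhaustive concordant/discordant pair counting on a tiny case."""
        y = np.array([0, 0, 1, 1, 2, 2])
        rng = np.random.default_rng(5)
        scores = rng.random((6, 3))
        expected = []
        for j in range(3):
            for k in range(j + 1, 3):
                for col, pos in ((k, k), (j, j)):
                    pos_idx = np.where(y == pos)[0]
                    neg_idx = np.where((y == j) | (y == k))[0]
                    neg_idx = [i for i in neg_idx if y[i] != pos]
                    wins = sum(
                        1.0 if scores[p, col] > scores[q, col]
                        else 0.5 if scores[p, col] == scores[q, col]
                        else 0.0
                        for p in pos_idx
                        for q in neg_idx
                    )
                    expected.append(wins / (len(pos_idx) * len(neg_idx)))
        pair_means = np.mean(np.array(expected).reshape(3, 2), axis=1)
        assert pairwise_auc(y, scores) == pytest.approx(np.mean(pair_means), abs=1e-12)

    def test_constant_scores_give_half(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        assert pairwise_auc(y, np.ones((6, 3)) / 3) == pytest.approx(0.5)

    def test_hand_computed_weighted_precision(self):
        y = np.array([0, 1, 2] * 3)
        pred = np.zeros(9, dtype=int)
        assert weighted_precision(y, pred) == pytest.approx(1 / 9)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 1])
        assert weighted_precision(y, y) == 1.0
        assert weighted_f1(y, y) == 1.0

    def test_complement_predictions_zero_f1(self):
        y = np.array([0, 1, 0, 1])
        assert weighted_f1(y, 1 - y) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_precision(np.array([]), np.array([]))


class TestPenalizedFit:
    def test_objective_monotone_along_trajectory(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 5))
        y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(float)
        _, _, trajectory = fit_penalized_logistic(X, y, lam=1.0)
        diffs = np.diff(trajectory)
        assert np.all(diffs <= 1e-8)

    def test_ridge_limit_shrinks_coefficients(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(float)
        _, beta_small, _ = fit_penalized_logistic(X, y, lam=1e-6)
        _, beta_huge, _ = fit_penalized_logistic(X, y, lam=1e6)
        assert np.linalg.norm(beta_huge) < 1e-3 < np.linalg.norm(beta_small)

    def test_separable_data_reaches_full_training_accuracy(self):
        records = separable_records()
        model = fit(records, lambda_grid=[1e-4], folds=5, seed=0)
        X, y = records_to_xy(records)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_huge_lambda_collapses_to_intercept_class(self):
        # imbalanced classes, unweighted: the ridge limit leaves only the
        # intercepts, so every sample gets the most frequent class
        records = separable_records(n_per_class=40)[:40] + separable_records()[30:]
        model = fit(records, lambda_grid=[1e9], folds=5, class_weight=None, seed=0)
        assert np.linalg.norm(model.coefficients) < 1e-3
        X, _ = records_to_xy(records)
        assert np.all(model.predict(X) == 0)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(1)
        records = make_records(rng.uniform(size=(10, 20)), [5.0] * 10)
        with pytest.raises(ValueError):
            fit(records)

    def test_model_json_roundtrip(self, tmp_path):
        records = separable_records()
        model = fit(records, lambda_grid=[1e-2], folds=5, seed=0)
        path = tmp_path / "model.json"
        with open(path, "w") as fh:
            model.to_json(fh)
        import json

        loaded = LogisticModel.from_dict(json.loads(path.read_text()))
        X, _ = records_to_xy(records)
        assert np.allclose(loaded.class_probability(X), model.class_probability(X))


class TestSplitProtocol:
    def test_reference_sizes_at_168(self, small_dataset):
        plan = SplitPlan.proportional(168, seed=3)
        assert plan.sizes == (118, 30, 20)
        m, ta, tb = split(small_dataset.records, plan)
        assert (len(m), len(ta), len(tb)) == (118, 30, 20)
        ids = {r.id for r in m} | {r.id for r in ta} | {r.id for r in tb}
        assert len(ids) == 168  # disjoint and exhaustive

    @pytest.mark.parametrize("n,expected", [(84, (59, 15, 10)), (168, (118, 30, 20))])
    def test_proportional_scaling(self, n, expected):
        assert SplitPlan.proportional(n).sizes == expected

    def test_same_seed_reproduces_partition(self, small_dataset):
        plan = SplitPlan.proportional(168, seed=5)
        first = split(small_dataset.records, plan)
        second = split(small_dataset.records, plan)
        assert [[r.id for r in part] for part in first] == [
            [r.id for r in part] for part in second
        ]

    def test_replicate_index_advances_partition(self, small_dataset):
        a = split(small_dataset.records, SplitPlan.proportional(168, seed=5, replicate=0))
        b = split(small_dataset.records, SplitPlan.proportional(168, seed=5, replicate=1))
        assert [r.id for r in a[0]] != [r.id for r in b[0]]

    def test_inconsistent_sizes_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            split(small_dataset.records, SplitPlan(sizes=(100, 30, 20), seed=0))


class TestDummyBaseline:
    def test_balanced_priors(self):
        records = separable_records(n_per_class=10)
        dummy = dummy_baseline(records, seed=0)
        assert dummy.priors == pytest.approx([1 / 3] * 3)

    def test_constant_scores_give_chance_auc(self):
        records = separable_records(n_per_class=10)
        dummy = dummy_baseline(records, seed=0)
        X, y = records_to_xy(records)
        assert pairwise_auc(y, dummy.class_scores(X)) == pytest.approx(0.5)

    def test_single_class_training_always_predicts_it(self):
        rng = np.random.default_rng(2)
        records = make_records(rng.uniform(size=(6, 20)), [95.0] * 6)
        dummy = dummy_baseline(records, seed=0)
        assert np.all(dummy.predict(np.zeros((4, 20))) == 2)

    def test_most_frequent_strategy(self):
        records = separable_records(n_per_class=5) + separable_records(n_per_class=2, seed=1)[:2]
        dummy = dummy_baseline(records, seed=0, strategy="most_frequent")
        assert len(np.unique(dummy.predict(np.zeros((8, 20))))) == 1


class TestReplicates:
    def test_bookkeeping_and_determinism(self, small_dataset):
        kwargs = dict(n_replicates=2, base_seed=4, lambda_grid=[1e-2, 1.0], folds=5)
        reports = run_replicates(small_dataset.records, **kwargs)
        assert len(reports) == 8  # 2 replicates x 2 test sets x {model, dummy}
        assert sum(r.kind == "model" for r in reports) == 4
        again = run_replicates(small_dataset.records, **kwargs)
        assert [r.to_dict() for r in reports] == [r.to_dict() for r in again]

    def test_model_beats_dummy_on_separated_data(self, small_dataset):
        reports = run_replicates(
            small_dataset.records, n_replicates=3, base_seed=4, lambda_grid=[1e-2], folds=5
        )
        by_key = {(r.replicate, r.test_set, r.kind): r for r in reports}
        for rep in range(3):
            for ts in ("T_a", "T_b"):
                assert (
                    by_key[(rep, ts, "model")].pairwise_auc
                    > by_key[(rep, ts, "dummy")].pairwise_auc
                )


class TestDatasetIO:
    def test_csv_roundtrip(self, tmp_path, small_dataset):
        path = tmp_path / "dataset.csv"
        save_dataset(small_dataset.records, path)
        loaded = load_dataset(path)
        assert [r.id for r in loaded] == [r.id for r in small_dataset.records]
        assert [r.label for r in loaded] == [r.label for r in small_dataset.records]
        X0, _ = records_to_xy(small_dataset.records)
        X1, _ = records_to_xy(loaded)
        assert np.allclose(X0, X1)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,production_rate\nv0,50\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_dataset(path)
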