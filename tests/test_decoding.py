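"""Decoders, permutation nulls, empirical p, transfer and load stratification."""

import numpy as np
import pytest

from wmnet.decoding import (
    DenseModel,
    empirical_p,
    evaluate,
    load_stratified_eval,
    permutation_null,
    select_lambda,
    stage_transfer,
    subject_partition,
    train_dense,
    train_sparse,
)
from wmnet.simulate import simulate_feature_stack


class TestSubjectPartition:
    def test_no_subject_spans_partitions(self):
        stack, _ = simulate_feature_stack(n_subjects=10, seed=0)
        train, hold = subject_partition(stack, seed=1)
        assert not set(train.meta["subject"]) & set(hold.meta["subject"])

    def test_19_subjects_split_14_5_under_rounding(self):
        stack, _ = simulate_feature_stack(
            n_events_per_class=38, n_subjects=19, seed=0
        )
        train, hold = subject_partition(stack, train_frac=0.75, seed=2)
        assert train.meta["subject"].nunique() == 14
        assert hold.meta["subject"].nunique() == 5

    def test_fixed_seed_reproducible(self):
        stack, _ = simulate_feature_stack(n_subjects=8, seed=0)
        a1, _ = subject_partition(stack, seed=3)
        a2, _ = subject_partition(stack, seed=3)
        assert np.array_equal(a1.features, a2.features)

    def test_degenerate_fraction_rejected(self):
        stack, _ = simulate_feature_stack(n_subjects=4, seed=0)
        with pytest.raises(ValueError, match="empty"):
            subject_partition(stack, train_frac=0.999999)


class TestDenseModel:
    def test_separable_training_f1_is_one(self):
        stack, _ = simulate_feature_stack(
            n_events_per_class=24, effect_size=25.0, subject_sd=0.0, seed=1
        )
        y = stack.meta["label"].to_numpy()
        model = train_dense(stack.features, y)
        assert evaluate(model, stack.features, y)["macro_f1"] == 1.0

    def test_zero_effect_holdout_accuracy_near_chance(self):
        stack, _ = simulate_feature_stack(
            n_events_per_class=120, effect_size=0.0, n_subjects=10, seed=2
        )
        train, hold = subject_partition(stack, seed=0)
        model = train_dense(train.features, train.meta["label"].to_numpy())
        acc = evaluate(model, hold.features, hold.meta["label"].to_numpy())["accuracy"]
        assert abs(acc - 1 / 3) < 0.12

    def test_duplicating_rows_preserves_decision(self):
        stack, _ = simulate_feature_stack(n_events_per_class=18, effect_size=3.0, seed=3)
        y = stack.meta["label"].to_numpy()
        m1 = train_dense(stack.features, y)
        m2 = train_dense(np.vstack([stack.features] * 2), np.concatenate([y, y]))
        assert np.array_equal(m1.predict(stack.features), m2.predict(stack.features))

    def test_missing_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.array(["a"] * 9 + ["b"])
        with pytest.raises(ValueError, match="< 2 training rows"):
            train_dense(X, y)


class TestSparseModel:
    def test_true_support_recovered_among_many_nuisance_features(self):
        stack, _ = simulate_feature_stack(
            n_events_per_class=60,
            n_features=100,
            classes=("a", "b", "c"),
            effect_size=3.0,
            n_subjects=10,
            seed=1,
        )
        y = stack.meta["label"].to_numpy()
        model = train_sparse(stack.features, y, seed=0)
        # class k's informative feature is coordinate k by construction
        selected = {idx for feats in model.support.values() for idx in feats}
        assert {0, 1, 2} <= selected
        assert model.n_nonzero <= 10 * 3

    def test_huge_lambda_gives_intercept_only(self):
        stack, _ = simulate_feature_stack(n_events_per_class=20, effect_size=2.0, seed=2)
        y = stack.meta["label"].to_numpy()
        path = np.array([1e4, 5e3, 2.5e3])
        model = train_sparse(stack.features, y, lambda_path=path, seed=0)
        assert model.n_nonzero == 0

    def test_vanishing_lambda_fits_training_data(self):
        stack, _ = simulate_feature_stack(
            n_events_per_class=20, effect_size=25.0, subject_sd=0.0, seed=3
        )
        y = stack.meta["label"].to_numpy()
        path = np.array([3e-5, 2e-5, 1e-5])
        model = train_sparse(stack.features, y, lambda_path=path, seed=0)
        assert evaluate(model, stack.features, y)["accuracy"] > 0.99

    def test_non_finite_features_rejected(self):
        X = np.zeros((10, 3))
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            train_sparse(X, np.array(["a", "b"] * 5))

    def test_sparse_tracks_dense_with_few_features(self):
        """Sparse model stays within 0.05 F1 of dense using <= 20% of features."""
        stack, _ = simulate_feature_stack(
            n_events_per_class=90,
            n_features=60,
            classes=("a", "b", "c"),
            effect_size=2.5,
            n_subjects=10,
            seed=4,
        )
        train, hold = subject_partition(stack, seed=0)
        ytr = train.meta["label"].to_numpy()
        yho = hold.meta["label"].to_numpy()
        dense = train_dense(train.features, ytr)
        sparse = train_sparse(train.features, ytr, seed=0)
        f1_dense = evaluate(dense, hold.features, yho)["macro_f1"]
        f1_sparse = evaluate(sparse, hold.features, yho)["macro_f1"]
        assert f1_sparse >= f1_dense - 0.05
        used = len({i for f in sparse.support.values() for i in f})
        assert used <= 0.2 * stack.n_features


class TestSelectLambda:
    def test_piecewise_linear_knee_found_at_slope_change(self):
        # slope -5 until index 7, then flat: knee at index 7
        curve = np.concatenate([100 - 5 * np.arange(8), np.full(6, 65.0)])
        assert select_lambda(curve) == 7

    def test_linear_curve_tie_breaks_to_largest_lambda(self):
        curve = 50.0 - 2.0 * np.arange(10)
        assert select_lambda(curve) == 1  # first interior index = largest lambda

    def test_two_point_curve_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            select_lambda([1.0, 0.5])

    def test_non_finite_curve_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            select_lambda([1.0, np.nan, 0.2])


class TestEvaluate:
    def test_binary_f1_harmonic_mean(self):
        """Precision 0.8, recall 0.5 -> F1 = 0.615."""

        class Fixed:
            classes = np.array(["neg", "pos"])

            def predict(self, X):
                return self._pred

        m = Fixed()
        # 10 true pos: 5 predicted pos (recall 0.5); 1 extra false pos
        # precision = 5 / (5 + 1.25)... construct directly:
        # 20 positives, predict 10 pos of which 8 correct -> precision 0.8
        # recall = 8 / 16 = 0.5
        y = np.array(["pos"] * 16 + ["neg"] * 14)
        pred = np.array(["pos"] * 8 + ["neg"] * 8 + ["pos"] * 2 + ["neg"] * 12)
        m._pred = pred
        out = evaluate(m, np.zeros((30, 1)), y)
        row = out["per_class"].set_index("class").loc["pos"]
        assert row["precision"] == pytest.approx(0.8)
        assert row["recall"] == pytest.approx(0.5)
        assert row["f1"] == pytest.approx(0.615, abs=5e-4)

    def test_constant_predictor_macro_f1_one_sixth(self):
        """All-one-class prediction on balanced 3-class data -> macro F1 = 1/6."""

        class Fixed:
            classes = np.array(["a", "b", "c"])

            def predict(self, X):
                return np.array(["a"] * len(X))

        y = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        out = evaluate(Fixed(), np.zeros((30, 1)), y)
        assert out["macro_f1"] == pytest.approx(1 / 6)

    def test_unseen_class_rejected(self):
        class Fixed:
            classes = np.array(["a", "b"])

            def predict(self, X):
                return np.array(["a"] * len(X))

        with pytest.raises(ValueError, match="unseen"):
            evaluate(Fixed(), np.zeros((2, 1)), np.array(["a", "z"]))


class TestEmpiricalP:
    def test_formula_values(self):
        assert empirical_p(np.ones(1000), np.zeros(1000)) == pytest.approx(1 / 1001)
        assert empirical_p(np.zeros(5), np.ones(5)) == 1.0
        obs = np.ones(999)
        null = np.concatenate([np.full(49, 2.0), np.zeros(950)])
        assert empirical_p(obs, null) == pytest.approx(0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            empirical_p(np.ones(3), np.ones(4))


class TestPermutationNull:
    def test_strong_effect_attains_minimum_p(self):
        stack, _ = simulate_feature_stack(
            n_events_per_class=48, effect_size=6.0, n_subjects=8, seed=5
        )
        rep = permutation_null(
            stack, label="label", n_partitions=2, n_bootstraps=20, seed=0
        )
        assert rep.p == pytest.approx(1 / 41)
        assert np.all(rep.observed > rep.null)

    def test_zero_effect_indistinguishable_from_null(self):
        """Across independent null datasets, observed - null centers on zero.

        Resamples within one run are correlated, so the test aggregates
        per-dataset mean differences rather than rank-summing raw values.
        """
        from scipy import stats

        diffs, ps = [], []
        for seed in range(6):
            stack, _ = simulate_feature_stack(
                n_events_per_class=60, effect_size=0.0, n_subjects=8, seed=100 + seed
            )
            rep = permutation_null(
                stack, label="label", n_partitions=2, n_bootstraps=10, seed=seed
            )
            diffs.append(rep.observed.mean() - rep.null.mean())
            ps.append(rep.p)
        assert stats.ttest_1samp(diffs, 0.0).pvalue > 0.05
        assert abs(np.mean(diffs)) < 0.03
        assert min(ps) > 0.1

    def test_fixed_seed_identical_distributions(self):
        stack, _ = simulate_feature_stack(n_events_per_class=24, seed=7)
        a = permutation_null(stack, label="label", n_partitions=1, n_bootstraps=5, seed=2)
        b = permutation_null(stack, label="label", n_partitions=1, n_bootstraps=5, seed=2)
        assert np.array_equal(a.observed, b.observed)
        assert np.array_equal(a.null, b.null)

    def test_low_m_warns(self):
        stack, _ = simulate_feature_stack(n_events_per_class=24, seed=8)
        with pytest.warns(UserWarning, match="resamples"):
            permutation_null(stack, label="label", n_partitions=1, n_bootstraps=5, seed=0)


class TestStageTransfer:
    def test_stage_specific_coding_gives_match_above_mismatch(self):
        stack, _ = simulate_feature_stack(
            n_events_per_class=144,
            n_features=30,
            effect_size=2.5,
            stage_specific=True,
            n_subjects=12,
            seed=9,
        )
        out = stage_transfer(stack, label="label", seed=0)
        assert out["match"] > out["mismatch"] + 0.05

    def test_stage_invariant_coding_gives_match_near_mismatch(self):
        stack, _ = simulate_feature_stack(
            n_events_per_class=144,
            n_features=30,
            effect_size=2.5,
            stage_specific=False,
            n_subjects=12,
            seed=10,
        )
        out = stage_transfer(stack, label="label", seed=0)
        assert abs(out["match"] - out["mismatch"]) < 0.08

    def test_single_class_stage_rejected(self):
        stack, _ = simulate_feature_stack(n_events_per_class=108, seed=11)
        stack.meta.loc[stack.meta["stage"] == "encode", "label"] = "a"
        with pytest.raises(ValueError, match="single class"):
            stage_transfer(stack, label="label", seed=0)


class TestLoadStratified:
    def test_load_gain_raises_accuracy_at_high_load(self):
        stack, _ = simulate_feature_stack(
            n_events_per_class=240,
            effect_size=1.2,
            load_gain=3.0,
            n_subjects=20,
            seed=12,
        )
        train, hold = subject_partition(stack, seed=0)
        model = train_dense(train.features, train.meta["label"].to_numpy())
        out = load_stratified_eval(model, hold, label="label")
        tab = out["per_load"].set_index("load")
        assert tab.loc[7, "accuracy"] > tab.loc[3, "accuracy"]
        assert out["high_vs_low_p"] < 0.05

    def test_no_gain_gives_similar_per_load_accuracy(self):
        stack, _ = simulate_feature_stack(
            n_events_per_class=360,
            effect_size=1.5,
            load_gain=1.0,
            n_subjects=10,
            seed=13,
        )
        train, hold = subject_partition(stack, seed=0)
        model = train_dense(train.features, train.meta["label"].to_numpy())
        out = load_stratified_eval(model, hold, label="label")
        tab = out["per_load"].set_index("load")
        assert abs(tab.loc[7, "accuracy"] - tab.loc[3, "accuracy"]) < 0.15

    def test_missing_load_column_rejected(self):
        stack, _ = simulate_feature_stack(n_events_per_class=12, seed=14)
        stack.meta = stack.meta.drop(columns=["load"])
        model = train_dense(stack.features, stack.meta["label"].to_numpy())
        with pytest.raises(ValueError, match="load"):
            load_stratified_eval(model, stack, label="label")
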