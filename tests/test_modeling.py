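"""Undersampling, splitting, folding, grid search and prediction contracts."""

import numpy as np
import pytest

from kcrsite.modeling import (
    ModelSpec,
    grid_search_train,
    kfold_indices,
    predict_scores,
    stratified_split_indices,
    train_test_split,
    undersample_balance,
)
from kcrsite.sequence_encoders import FeatureMatrix


def make_matrix(n_pos, n_neg, d=4, seed=0, separable=False):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_pos + n_neg, d))
    y = np.array([1] * n_pos + [0] * n_neg)
    if separable:
        X[:, 0] = y * 10.0 + rng.normal(scale=0.1, size=len(y))
    return FeatureMatrix(
        sample_ids=tuple(f"s{i}" for i in range(n_pos + n_neg)),
        labels=tuple("positive" if v else "negative" for v in y),
        names=tuple(f"f{j}" for j in range(d)),
        values=X,
    )


class TestUndersample:
    def test_majority_reduced_to_minority_size(self):
        out = undersample_balance(make_matrix(10, 100), seed=0)
        y = out.y()
        assert (y == 1).sum() == 10 and (y == 0).sum() == 10

    def test_every_minority_sample_retained(self):
        matrix = make_matrix(10, 100)
        out = undersample_balance(matrix, seed=0)
        pos_ids = {s for s, lab in zip(matrix.sample_ids, matrix.labels) if lab == "positive"}
        assert pos_ids <= set(out.sample_ids)

    def test_already_balanced_unchanged(self):
        matrix = make_matrix(50, 50)
        out = undersample_balance(matrix, seed=3)
        assert set(out.sample_ids) == set(matrix.sample_ids)

    def test_deterministic_given_seed(self):
        matrix = make_matrix(10, 100)
        a = undersample_balance(matrix, seed=7)
        b = undersample_balance(matrix, seed=7)
        c = undersample_balance(matrix, seed=8)
        assert a.sample_ids == b.sample_ids
        assert a.sample_ids != c.sample_ids

    def test_missing_class_rejected(self):
        matrix = make_matrix(5, 5)
        lone = matrix.subset_rows(np.arange(5))  # positives only
        with pytest.raises(ValueError, match="both classes"):
            undersample_balance(lone, seed=0)


class TestSplit:
    def test_80_20_counts(self):
        train, test = train_test_split(list(range(100)), 0.8, 0,
                                       labels=["positive"] * 50 + ["negative"] * 50)
        assert len(train) == 80 and len(test) == 20

    def test_disjoint_and_exhaustive(self):
        items = list(range(57))
        labels = ["positive" if i % 9 == 0 else "negative" for i in items]
        train, test = train_test_split(items, 0.8, 1, labels=labels)
        assert set(train) | set(test) == set(items)
        assert set(train) & set(test) == set()

    def test_stratification_within_one_sample(self):
        labels = ["positive"] * 13 + ["negative"] * 87
        train_idx, test_idx = stratified_split_indices(labels, 0.8, 2)
        train_pos = sum(1 for i in train_idx if labels[i] == "positive")
        assert abs(train_pos - 0.8 * 13) <= 1

    def test_test_side_keeps_imbalance(self):
        labels = ["positive"] * 20 + ["negative"] * 180
        _, test_idx = stratified_split_indices(labels, 0.8, 0)
        test_pos = sum(1 for i in test_idx if labels[i] == "positive")
        assert test_pos / len(test_idx) == pytest.approx(0.1, abs=0.03)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split_indices(["positive"] + ["negative"] * 9, 0.8, 0)


class TestKFold:
    def test_even_partition(self):
        folds = kfold_indices(10, 5, 0)
        assert [len(f) for f in folds] == [2] * 5

    def test_uneven_partition_sizes(self):
        sizes = sorted((len(f) for f in kfold_indices(11, 5, 0)), reverse=True)
        assert sizes == [3, 2, 2, 2, 2]

    def test_exact_partition(self):
        folds = kfold_indices(23, 5, 4)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(23))
        assert len(seen) == len(set(seen))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kfold_indices(3, 5, 0)


class TestGridSearch:
    def test_one_point_grid_chosen(self):
        matrix = make_matrix(20, 20, separable=True)
        spec = ModelSpec("random_forest", grid={"n_estimators": (50,)}, seed=0)
        model = grid_search_train(matrix, spec, k=4)
        assert model.chosen == {"n_estimators": 50}

    def test_separable_data_fits_perfectly(self):
        matrix = make_matrix(20, 20, separable=True)
        spec = ModelSpec("svm_rbf", grid={"C": (1.0, 4.0), "gamma": (0.01, 0.1)}, seed=0)
        model = grid_search_train(matrix, spec, k=4)
        scores = predict_scores(model, matrix)
        pred = (scores >= 0.5).astype(int)
        assert np.array_equal(pred, matrix.y())

    def test_choice_matches_exhaustive_evaluation(self):
        """The chosen point must be the argmax of the recorded CV scores,
        first point in iteration order winning ties."""
        matrix = make_matrix(25, 25, seed=5, separable=True)
        spec = ModelSpec("svm_rbf", grid={"C": (1.0, 2.0, 4.0), "gamma": (0.05, 0.5)}, seed=1)
        model = grid_search_train(matrix, spec, k=5)
        points = spec.grid_points()
        scores = [model.cv_scores[repr(p)] for p in points]
        best = points[int(np.argmax(scores))]  # argmax returns the first maximum
        assert model.chosen == best

    def test_every_classifier_kind_runs(self):
        matrix = make_matrix(15, 15, separable=True)
        for kind, grid in [
            ("svm_rbf", {"C": (1.0,), "gamma": (0.1,)}),
            ("random_forest", {"n_estimators": (30,)}),
            ("logistic_regression", {}),
        ]:
            model = grid_search_train(matrix, ModelSpec(kind, grid=grid, seed=0), k=3)
            scores = predict_scores(model, matrix)
            assert scores.shape == (30,)
            assert np.all((scores >= 0) & (scores <= 1))

    def test_single_class_fold_detected(self):
        matrix = make_matrix(2, 28)
        spec = ModelSpec("logistic_regression", seed=0)
        with pytest.raises(ValueError, match="single class"):
            grid_search_train(matrix, spec, k=5)


class TestPredict:
    def test_column_mismatch_names_columns(self):
        matrix = make_matrix(10, 10, separable=True)
        model = grid_search_train(
            matrix, ModelSpec("random_forest", grid={"n_estimators": (20,)}, seed=0), k=2
        )
        other = FeatureMatrix(
            matrix.sample_ids, matrix.labels,
            tuple(f"g{j}" for j in range(4)), matrix.values,
        )
        with pytest.raises(ValueError, match="missing"):
            predict_scores(model, other)

    def test_identical_rows_identical_scores(self):
        matrix = make_matrix(10, 10, separable=True)
        model = grid_search_train(
            matrix, ModelSpec("random_forest", grid={"n_estimators": (20,)}, seed=0), k=2
        )
        dup = matrix.subset_rows([0, 0, 0])
        scores = predict_scores(model, dup)
        assert scores[0] == scores[1] == scores[2]

    def test_save_load_round_trip(self, tmp_path):
        from kcrsite.modeling import TrainedModel

        matrix = make_matrix(10, 10, separable=True)
        model = grid_search_train(
            matrix, ModelSpec("random_forest", grid={"n_estimators": (20,)}, seed=0), k=2
        )
        path = tmp_path / "model.joblib"
        model.save(path)
        back = TrainedModel.load(path)
        np.testing.assert_array_equal(
            predict_scores(back, matrix), predict_scores(model, matrix)
        )

    def test_determinism_across_runs(self):
        matrix = make_matrix(12, 90, d=6, seed=2)
        balanced = undersample_balance(matrix, seed=5)
        spec = ModelSpec("random_forest", grid={"n_estimators": (40, 60)}, seed=9)
        m1 = grid_search_train(balanced, spec, k=3)
        m2 = grid_search_train(balanced, ModelSpec("random_forest",
                                                   grid={"n_estimators": (40, 60)}, seed=9), k=3)
        assert m1.chosen == m2.chosen
        np.testing.assert_array_equal(
            predict_scores(m1, matrix), predict_scores(m2, matrix)
        )
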