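import numpy as np
import pytest

from speechmark.tree_sparse_mlp import (
    SparseMLPModel,
    TreeEnsembleSpec,
    build_mask,
    compute_class_weights,
    feature_importance,
    fit_sparse_mlp,
    fit_tree_ensemble,
    grid_search,
    load_model,
    predict,
    save_model,
    train,
)


def separable_data(rng, n=80, p=6, informative=0):
    X = rng.normal(0, 1, (n, p))
    y = (X[:, informative] > 0).astype(int)
    X[:, informative] = X[:, informative] + 3 * (2 * y - 1)  # widen the margin
    return X, y


@pytest.fixture
def toy_mask():
    # 3 hidden units over 4 features, hand-constructed
    return np.array([
        [1, 1, 0, 0],
        [0, 1, 1, 0],
        [1, 0, 0, 0],
    ], dtype=float)


class TestEnsemble:
    def test_informative_feature_always_used(self, rng):
        X, y = separable_data(rng)
        spec = fit_tree_ensemble(X, y, TreeEnsembleSpec(n_trees=10, depth=4, seed=0))
        for used in spec.used_features:
            if used:  # non-degenerate tree
                assert 0 in used

    def test_fixed_seed_deterministic(self, rng):
        X, y = separable_data(rng)
        a = fit_tree_ensemble(X, y, TreeEnsembleSpec(10, 4, seed=5))
        b = fit_tree_ensemble(X, y, TreeEnsembleSpec(10, 4, seed=5))
        assert a.used_features == b.used_features

    def test_depth_limit_respected(self, rng):
        X = rng.normal(0, 1, (200, 8))
        y = rng.integers(0, 2, 200)
        spec = fit_tree_ensemble(X, y, TreeEnsembleSpec(10, 4, seed=1))
        for tree in spec.trees:
            assert tree.get_depth() <= 4

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (20, 3))
        with pytest.raises(ValueError, match="two classes"):
            fit_tree_ensemble(X, np.zeros(20), TreeEnsembleSpec(5, 4))


class TestMask:
    def test_single_feature_trees(self):
        spec = TreeEnsembleSpec(3, 4, used_features=[{0}, {0}, {0}])
        mask = build_mask(spec, 5)
        assert mask[:, 0].sum() == 3
        assert mask[:, 1:].sum() == 0

    def test_hand_constructed_toy(self):
        spec = TreeEnsembleSpec(3, 4, used_features=[{0, 1}, {1, 2}, {0}])
        expected = np.array([[1, 1, 0, 0], [0, 1, 1, 0], [1, 0, 0, 0]], float)
        np.testing.assert_array_equal(build_mask(spec, 4), expected)

    def test_nonzero_bounded(self, rng):
        X, y = separable_data(rng, p=12)
        spec = fit_tree_ensemble(X, y, TreeEnsembleSpec(8, 4, seed=0))
        mask = build_mask(spec, 12)
        # a depth-4 tree has at most 15 internal nodes; far fewer than 12
        # features are typically used, so the mask is strictly sparse
        assert mask.sum() < 8 * 12

    def test_unfitted_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            build_mask(TreeEnsembleSpec(3, 4), 4)


class TestTraining:
    def test_masked_weights_exactly_zero(self, rng, toy_mask):
        X = rng.normal(0, 1, (60, 4))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        model = SparseMLPModel(mask=toy_mask, seed=0, max_epochs=50)
        model, _ = train(model, X[:40], y[:40], X[40:], y[40:])
        assert np.all(model.W1[toy_mask == 0] == 0.0)

    def test_balanced_class_weights_equal(self):
        w = compute_class_weights(np.array([0, 0, 1, 1]))
        assert w == {0: 1.0, 1: 1.0}

    def test_imbalanced_class_weights(self):
        w = compute_class_weights(np.array([0, 0, 0, 1]))
        assert w[0] == pytest.approx(4 / (2 * 3))
        assert w[1] == pytest.approx(4 / (2 * 1))

    def test_early_stop_on_constant_validation(self, rng, toy_mask):
        # lr = 0 freezes the weights, making the validation loss constant by
        # construction: training must halt at epoch patience + 1
        X_train = rng.normal(0, 1, (40, 4))
        y_train = (X_train[:, 0] > 0).astype(int)
        model = SparseMLPModel(mask=toy_mask, seed=0, lr=0.0, patience=10,
                               max_epochs=500)
        model, history = train(model, X_train, y_train, X_train[:10], y_train[:10])
        assert len(history["val_loss"]) == 11  # patience + 1

    def test_empty_validation_rejected(self, rng, toy_mask):
        X = rng.normal(0, 1, (10, 4))
        y = (X[:, 0] > 0).astype(int)
        model = SparseMLPModel(mask=toy_mask)
        with pytest.raises(ValueError, match="validation"):
            train(model, X, y, X[:0], y[:0])

    def test_history_records_losses(self, rng, toy_mask):
        X = rng.normal(0, 1, (40, 4))
        y = (X[:, 0] > 0).astype(int)
        model = SparseMLPModel(mask=toy_mask, max_epochs=20, patience=50)
        _, history = train(model, X[:30], y[:30], X[30:], y[30:])
        assert len(history["train_loss"]) == len(history["val_loss"]) == 20


class TestPredict:
    def test_classification_scores_bounded(self, rng, toy_mask):
        X = rng.normal(0, 1, (40, 4))
        y = (X[:, 0] > 0).astype(int)
        model = SparseMLPModel(mask=toy_mask, max_epochs=30)
        model, _ = train(model, X[:30], y[:30], X[30:], y[30:])
        scores = predict(model, rng.normal(0, 5, (25, 4)))
        assert np.all((scores >= 0) & (scores <= 1))

    def test_identical_rows_identical_scores(self, rng, toy_mask):
        X = rng.normal(0, 1, (40, 4))
        y = (X[:, 0] > 0).astype(int)
        model = SparseMLPModel(mask=toy_mask, max_epochs=30)
        model, _ = train(model, X[:30], y[:30], X[30:], y[30:])
        row = rng.normal(0, 1, 4)
        scores = predict(model, np.vstack([row, row]))
        assert scores[0] == scores[1]

    def test_manual_forward_pass(self):
        # tiny model with known weights: verify the closed-form forward pass
        mask = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = SparseMLPModel(mask=mask)
        model.W1 = np.array([[2.0, 0.0], [0.0, -1.0]])
        model.b1 = np.array([0.5, 0.0])
        model.W2 = np.array([1.0, 3.0])
        model.b2 = -0.25
        x = np.array([[1.0, -2.0]])
        h1 = max(2.0 * 1.0 + 0.5, 0.0)           # 2.5
        h2 = max(-1.0 * -2.0 + 0.0, 0.0)         # 2.0
        z = 1.0 * h1 + 3.0 * h2 - 0.25           # 8.25
        expected = 1.0 / (1.0 + np.exp(-z))
        assert predict(model, x)[0] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self, toy_mask):
        model = SparseMLPModel(mask=toy_mask)
        model._init_weights()
        with pytest.raises(ValueError, match="features"):
            predict(model, np.zeros((3, 7)))

    def test_untrained_rejected(self, toy_mask):
        with pytest.raises(ValueError, match="not trained"):
            predict(SparseMLPModel(mask=toy_mask), np.zeros((2, 4)))


class TestImportance:
    def test_unused_feature_zero(self, toy_mask):
        model = SparseMLPModel(mask=toy_mask)
        imp = feature_importance(model)
        assert imp[3] == 0

    def test_manual_counts(self, toy_mask):
        imp = feature_importance(SparseMLPModel(mask=toy_mask))
        np.testing.assert_array_equal(imp, [2, 2, 1, 0])
        assert imp.sum() == toy_mask.sum()

    def test_feature_used_by_all_trees(self):
        mask = np.ones((5, 2))
        imp = feature_importance(SparseMLPModel(mask=mask))
        assert imp[0] == 5 and imp[1] == 5


class TestParameterCount:
    def test_sparse_leq_dense(self, rng):
        X, y = separable_data(rng, n=100, p=10)
        spec = fit_tree_ensemble(X, y, TreeEnsembleSpec(10, 4, seed=0))
        mask = build_mask(spec, 10)
        model = SparseMLPModel(mask=mask)
        dense_params = 10 * 10 + 10 + 10 + 1
        assert model.n_parameters <= dense_params

    def test_equality_only_full_mask(self):
        model = SparseMLPModel(mask=np.ones((4, 3)))
        assert model.n_parameters == 4 * 3 + 4 + 4 + 1


class TestGridSearch:
    def test_single_cell(self, rng):
        X, y = separable_data(rng, n=60, p=5)
        cell, model, score = grid_search(X, y, tree_grid=[10], depth_grid=[4], seed=0)
        assert cell == (10, 4)
        assert model.W1 is not None

    def test_tie_breaks_to_smaller_model(self, rng):
        # perfectly separable data: every cell reaches AUC 1.0
        X, y = separable_data(rng, n=80, p=4)
        cell, _, score = grid_search(
            X, y, tree_grid=[10, 20], depth_grid=[4, 6], seed=0
        )
        assert score == 1.0
        assert cell == (10, 4)

    def test_empty_grid_rejected(self, rng):
        X, y = separable_data(rng)
        with pytest.raises(ValueError, match="grid"):
            grid_search(X, y, tree_grid=[], depth_grid=[4])

    def test_better_capacity_wins(self, rng):
        # labels need an interaction of many features: deeper/larger
        # ensembles should dominate a 1-tree depth-limited model
        X = rng.normal(0, 1, (160, 6))
        y = ((X[:, 0] * X[:, 1] > 0) ^ (X[:, 2] > 0.5)).astype(int)
        cell, _, score = grid_search(X, y, tree_grid=[1, 40], depth_grid=[6], seed=3)
        assert cell[0] == 40


class TestSerialization:
    def test_roundtrip(self, rng, toy_mask, tmp_path):
        X = rng.normal(0, 1, (40, 4))
        y = (X[:, 0] > 0).astype(int)
        model = SparseMLPModel(mask=toy_mask, max_epochs=20)
        model, _ = train(model, X[:30], y[:30], X[30:], y[30:])
        model.norm_mean = np.zeros(4)
        model.norm_sd = np.ones(4)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        X_new = rng.normal(0, 1, (7, 4))
        np.testing.assert_allclose(predict(back, X_new), predict(model, X_new), atol=1e-12)

    def test_regression_scaling_roundtrips(self, rng, toy_mask, tmp_path):
        X = rng.normal(0, 1, (50, 4))
        y = 20.0 + 3.0 * X[:, 0] + rng.normal(0, 0.5, 50)
        model = SparseMLPModel(mask=toy_mask, task="regression", max_epochs=100)
        model, _ = train(model, X[:40], y[:40], X[40:], y[40:])
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(predict(back, X), predict(model, X), atol=1e-12)


class TestRecoveryProperties:
    def test_regression_learns_linear_signal(self, rng):
        X = rng.normal(0, 1, (200, 5))
        y = 22.0 - 4.0 * X[:, 0] + rng.normal(0, 1.0, 200)
        model = fit_sparse_mlp(X[:150], y[:150], X[150:180], y[150:180],
                               n_trees=20, depth=4, task="regression", seed=0)
        pred = predict(model, X[180:])
        rho = np.corrcoef(pred, y[180:])[0, 1]
        assert rho > 0.7

    def test_classification_learns_separable(self, rng):
        X, y = separable_data(rng, n=150, p=6)
        model = fit_sparse_mlp(X[:100], y[:100], X[100:120], y[100:120],
                               n_trees=20, depth=4, seed=0)
        scores = predict(model, X[120:])
        acc = ((scores > 0.5).astype(int) == y[120:]).mean()
        assert acc >= 0.9
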