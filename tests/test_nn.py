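import numpy as np
import pandas as pd
import pytest

from methylearn import nn


def numeric_gradients(model, X, y, eps=1e-6):
    """Central finite differences of the regularized loss for every parameter."""

    def total():
        c = nn.forward(model, X, training=False)
        return nn._data_loss(model.spec, c["output"], y) + nn._reg_loss(
            model.spec, model.weights
        )

    grads_w, grads_b = [], []
    for arrs, grads in ((model.weights, grads_w), (model.biases, grads_b)):
        for A in arrs:
            G = np.zeros_like(A)
            it = np.nditer(A, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = A[i]
                A[i] = old + eps
                lp = total()
                A[i] = old - eps
                lm = total()
                A[i] = old
                G[i] = (lp - lm) / (2 * eps)
            grads.append(G)
    return grads_w, grads_b


def max_rel_error(analytic, numeric):
    worst = 0.0
    for ga, gn in zip(analytic, numeric):
        rel = np.abs(ga - gn) / np.maximum(1e-8, np.abs(ga) + np.abs(gn))
        worst = max(worst, float(rel.max()))
    return worst


class TestSpecAndInit:
    def test_two_hidden_layers_required(self):
        with pytest.raises(nn.SpecError):
            nn.NetworkSpec(n_inputs=4, hidden_sizes=(8, 8, 8))

    def test_dropout_range(self):
        with pytest.raises(nn.SpecError):
            nn.NetworkSpec(n_inputs=4, input_dropout=0.7)

    def test_same_seed_same_weights(self):
        spec = nn.NetworkSpec(n_inputs=14, hidden_sizes=(8, 8), seed=5)
        a, b = nn.init_network(spec), nn.init_network(spec)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_weight_shapes(self):
        spec = nn.NetworkSpec(n_inputs=14, hidden_sizes=(8, 8), n_classes=2)
        m = nn.init_network(spec)
        assert m.weights[0].shape == (14, 8)
        assert m.weights[2].shape == (8, 2)

    def test_maxout_channel_dimension(self):
        spec = nn.NetworkSpec(
            n_inputs=14, hidden_sizes=(8, 8), activation="maxout", maxout_channels=2
        )
        m = nn.init_network(spec)
        assert m.weights[0].shape == (14, 8, 2)
        assert m.biases[0].shape == (8, 2)


class TestForward:
    def test_zero_weights_give_uniform_softmax(self):
        spec = nn.NetworkSpec(n_inputs=3, hidden_sizes=(4, 4), n_classes=2)
        m = nn.init_network(spec)
        m.weights = [np.zeros_like(W) for W in m.weights]
        out = nn.forward(m, np.ones((5, 3)))["output"]
        np.testing.assert_allclose(out, 0.5)

    def test_probabilities_normalized(self):
        spec = nn.NetworkSpec(n_inputs=6, hidden_sizes=(8, 8), n_classes=3, seed=2)
        m = nn.init_network(spec)
        X = np.random.default_rng(0).normal(size=(20, 6))
        out = nn.forward(m, X)["output"]
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out >= 0).all()

    def test_tanh_odd_symmetry(self):
        """Negating inputs and first-layer weights leaves the output unchanged."""
        spec = nn.NetworkSpec(n_inputs=4, hidden_sizes=(5, 6), activation="tanh", seed=1)
        m = nn.init_network(spec)
        for b in m.biases:
            b[...] = 0.0
        X = np.random.default_rng(3).normal(size=(7, 4))
        out1 = nn.forward(m, X)["output"]
        m.weights[0] = -m.weights[0]
        out2 = nn.forward(m, -X)["output"]
        np.testing.assert_allclose(out1, out2, atol=1e-12)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        spec = nn.NetworkSpec(n_inputs=2, hidden_sizes=(4, 4))
        m = nn.init_network(spec)
        # loss computed directly on a forced one-hot output
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert nn._data_loss(spec, p, np.array([0, 1])) == 0.0

    def test_uniform_prediction_log2(self):
        spec = nn.NetworkSpec(n_inputs=2, hidden_sizes=(4, 4))
        p = np.full((4, 2), 0.5)
        assert nn._data_loss(spec, p, np.array([0, 1, 0, 1])) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_l2_strictly_increases_loss(self):
        spec = nn.NetworkSpec(n_inputs=3, hidden_sizes=(4, 4), seed=0)
        m = nn.init_network(spec)
        X = np.random.default_rng(0).normal(size=(6, 3))
        y = np.array([0, 1, 0, 1, 0, 1])
        m.input_mean, m.input_sd = np.zeros(3), np.ones(3)
        base = nn.loss(m, X, y)
        m2 = nn.init_network(nn.replace_spec(spec, l2=1e-3))
        m2.input_mean, m2.input_sd = np.zeros(3), np.ones(3)
        assert nn.loss(m2, X, y) > base


class TestGradients:
    @pytest.mark.parametrize("activation", ["tanh", "rectifier", "maxout"])
    @pytest.mark.parametrize("task", ["classification", "regression"])
    def test_backprop_matches_finite_differences(self, activation, task):
        spec = nn.NetworkSpec(
            n_inputs=3,
            hidden_sizes=(4, 5),
            activation=activation,
            task=task,
            l1=1e-4,
            l2=1e-4,
            seed=3,
        )
        model = nn.init_network(spec)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 3))
        y = (
            rng.integers(0, 2, size=7)
            if task == "classification"
            else rng.normal(size=7)
        )
        cache = nn.forward(model, X, training=False)
        gw, gb = nn._backprop(model, cache, y)
        nw, nb = numeric_gradients(model, X, y)
        assert max_rel_error(gw + gb, nw + nb) < 1e-5


class TestTraining:
    def test_separable_classification_reaches_zero_error(self, toy_classification):
        X, y = toy_classification
        spec = nn.NetworkSpec(
            n_inputs=2, hidden_sizes=(8, 8), epochs=300, learning_rate=0.05, seed=0
        )
        m = nn.train_sgd(nn.init_network(spec), X, y)
        assert nn.metrics(nn.predict(m, X), y, "classification")["misclassification"] == 0.0

    def test_noiseless_regression_fits(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, size=(50, 1))
        y = X[:, 0]
        spec = nn.NetworkSpec(
            n_inputs=1, hidden_sizes=(8, 8), task="regression",
            epochs=400, learning_rate=0.02, seed=0,
        )
        m = nn.train_sgd(nn.init_network(spec), X, y)
        assert nn.metrics(nn.predict(m, X), y, "regression")["mse"] < 1e-2

    def test_linear_data_matches_least_squares(self):
        """A tanh net in its linear regime reproduces the OLS fit."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        beta = np.array([0.5, -0.3, 0.2])
        y = X @ beta
        spec = nn.NetworkSpec(
            n_inputs=3, hidden_sizes=(8, 8), task="regression",
            epochs=500, learning_rate=0.02, seed=1,
        )
        m = nn.train_sgd(nn.init_network(spec), X, y)
        ols_pred = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert float(np.mean((nn.predict(m, X) - ols_pred) ** 2)) < 1e-2

    def test_deterministic_given_seed(self, toy_classification):
        X, y = toy_classification
        spec = nn.NetworkSpec(n_inputs=2, hidden_sizes=(8, 8), epochs=50, seed=9,
                              hidden_dropout=0.2)
        m1 = nn.train_sgd(nn.init_network(spec), X, y)
        m2 = nn.train_sgd(nn.init_network(spec), X, y)
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_divergence_raises(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20) * 1e3
        spec = nn.NetworkSpec(n_inputs=2, hidden_sizes=(8, 8), task="regression",
                              epochs=50, learning_rate=1e6, momentum=0.99, seed=0)
        with pytest.raises(nn.DivergenceError, match="learning rate"):
            nn.train_sgd(nn.init_network(spec), X, y)

    def test_history_recorded_per_epoch(self, fitted_small_classifier):
        model, X, y = fitted_small_classifier
        assert len(model.history) == model.spec.epochs


class TestPredictAndMetrics:
    def test_duplicate_rows_identical_predictions(self, fitted_small_classifier):
        model, X, _ = fitted_small_classifier
        out = nn.predict(model, np.vstack([X[0], X[0]]))
        np.testing.assert_array_equal(out[0], out[1])

    def test_constant_prediction_r2_zero(self):
        y = np.array([1.0, 2, 3, 4, 5])
        pred = np.full(5, y.mean())
        m = nn.metrics(pred, y, "regression")
        assert m["r2"] == pytest.approx(0.0)
        assert m["adjusted_r2"] == pytest.approx(-1.0 / 3.0)

    def test_worse_than_mean_gives_negative_r2(self):
        y = np.array([1.0, 2, 3, 4, 5])
        pred = y[::-1].copy()
        assert nn.metrics(pred, y, "regression")["adjusted_r2"] < 0

    def test_perfect_classification_metrics(self):
        p = np.array([[1.0, 0], [0, 1.0]])
        m = nn.metrics(p, np.array([0, 1]), "classification")
        assert m["misclassification"] == 0.0
        assert m["log_loss"] == 0.0

    def test_adjusted_r2_needs_three(self):
        with pytest.raises(ValueError):
            nn.metrics(np.array([1.0, 2]), np.array([1.0, 2]), "regression")


class TestCV:
    def test_sevenfold_sizes_and_partition(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(72, 3))
        y = np.tile([0, 1], 36)
        spec = nn.NetworkSpec(n_inputs=3, hidden_sizes=(4, 4), epochs=20, seed=0)
        cv = nn.kfold_cv(spec, X, y, k=7)
        sizes = sorted(len(h) for h in cv.holdout_indices)
        assert sizes == [10, 10, 10, 10, 10, 11, 11]
        all_idx = np.sort(np.concatenate(cv.holdout_indices))
        np.testing.assert_array_equal(all_idx, np.arange(72))

    def test_leave_one_out_degenerate(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        y = np.tile([0, 1], 4)
        spec = nn.NetworkSpec(n_inputs=2, hidden_sizes=(4, 4), epochs=20, seed=0)
        cv = nn.kfold_cv(spec, X, y, k=8)
        assert all(len(h) == 1 for h in cv.holdout_indices)

    def test_metrics_recomputable_from_predictions(self, toy_classification):
        X, y = toy_classification
        spec = nn.NetworkSpec(n_inputs=2, hidden_sizes=(8, 8), epochs=100, seed=0)
        cv = nn.kfold_cv(spec, X, y, k=5)
        recomputed = nn.metrics(cv.predictions, cv.truth, "classification")
        assert recomputed == cv.metrics


class TestGridSearch:
    def test_single_point_grid(self, toy_classification):
        X, y = toy_classification
        spec = nn.NetworkSpec(n_inputs=2, hidden_sizes=(8, 8), epochs=50, seed=0)
        best_spec, model, board = nn.grid_search([spec], X, y, k=4)
        assert best_spec == spec and model.fitted and len(board) == 1

    def test_beats_uniform_baseline(self, toy_classification):
        X, y = toy_classification
        grid = nn.expand_grid(
            nn.NetworkSpec(n_inputs=2, hidden_sizes=(8, 8), epochs=150, seed=0),
            activation=["tanh", "rectifier"],
        )
        _, _, board = nn.grid_search(grid, X, y, k=4)
        assert board["score"].min() <= np.log(2)

    def test_leaderboard_sorted(self, toy_classification):
        X, y = toy_classification
        grid = nn.expand_grid(
            nn.NetworkSpec(n_inputs=2, hidden_sizes=(8, 8), epochs=50, seed=0),
            l2=[0.0, 1e-4, 1e-2],
        )
        _, _, board = nn.grid_search(grid, X, y, k=4)
        scores = board["score"].dropna().to_numpy()
        assert (np.diff(scores) >= 0).all()


class TestExport:
    @pytest.mark.parametrize("activation", ["tanh", "maxout"])
    def test_save_load_predicts_bitwise(self, tmp_path, activation):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 100, size=(20, 5))
        y = rng.integers(0, 2, size=20)
        spec = nn.NetworkSpec(
            n_inputs=5, hidden_sizes=(4, 4), activation=activation, epochs=50, seed=1
        )
        model = nn.train_sgd(nn.init_network(spec), X, y)
        path = tmp_path / "model.npz"
        nn.save_model(model, path)
        loaded = nn.load_model(path)
        np.testing.assert_array_equal(nn.predict(model, X), nn.predict(loaded, X))

    def test_bundle_contents(self, fitted_small_classifier):
        model, _, _ = fitted_small_classifier
        bundle = nn.export_weights_biases(model)
        assert {"W1", "W2", "W3", "b1", "b2", "b3"} <= set(bundle)
        assert bundle["input_mean"] is not None

    def test_maxout_bundle_has_channels(self):
        spec = nn.NetworkSpec(n_inputs=5, hidden_sizes=(4, 4), activation="maxout")
        bundle = nn.export_weights_biases(nn.init_network(spec))
        assert bundle["W1"].ndim == 3
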