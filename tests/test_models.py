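"""Classifier training, tuning and the LSTM implementation itself."""

import numpy as np
import pytest

import tremordetect as td
from tremordetect.lstm import LSTMClassifier


def _toy_sequences(n=240, T=50, seed=0):
    """Separable toy: 6 Hz oscillation vs near-flat windows in [0, 1]."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    t = np.arange(T) / 50.0
    X = np.array([
        0.5 + 0.3 * np.sin(2 * np.pi * 6 * t + rng.uniform(0, 2 * np.pi))
        if yi else 0.5 + 0.02 * rng.standard_normal(T)
        for yi in y])
    return X, y


class TestLSTMInternals:
    def test_bptt_gradients_match_finite_differences(self):
        """Analytic BPTT gradients agree with central differences on a
        tiny float64 network."""
        net = LSTMClassifier(hidden_size=4, seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((3, 7))
        y = np.array([1, 0, 1])
        _, grads = net.loss_and_grads(X, y)
        params = net._params()
        eps = 1e-6
        for name, p in params.items():
            for _ in range(6):
                idx = tuple(rng.integers(0, s) for s in p.shape) if p.ndim else ()
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = net.loss_and_grads(X, y)
                p[idx] = orig - eps
                lm, _ = net.loss_and_grads(X, y)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, rel=1e-3, abs=1e-7)

    def test_scores_in_open_unit_interval(self):
        net = LSTMClassifier(hidden_size=6, seed=1)
        X = np.random.default_rng(0).standard_normal((10, 20))
        p = net.predict_proba(X)
        assert np.all((p > 0) & (p < 1))

    def test_training_deterministic(self):
        X, y = _toy_sequences(n=80)
        losses = []
        for _ in range(2):
            net = LSTMClassifier(hidden_size=8, max_epochs=3, seed=5)
            net.fit(X[:60], y[:60], X[60:], y[60:])
            losses.append(net.history["val_loss"])
        assert losses[0] == losses[1]

    def test_constant_labels_converge_to_entropy_bound(self):
        """On an all-positive training set the BCE approaches 0 (the label
        entropy) and output saturates toward 1."""
        X, _ = _toy_sequences(n=60)
        y = np.ones(60, dtype=int)
        net = LSTMClassifier(hidden_size=6, max_epochs=40, batch_size=16,
                             seed=2)
        net.fit(X[:40], y[:40], X[40:], y[40:])
        assert net.best_val_loss_ < 0.1
        assert net.predict_proba(X[40:]).mean() > 0.85

    def test_checkpoint_is_best_validation(self):
        X, y = _toy_sequences(n=200)
        net = LSTMClassifier(hidden_size=10, max_epochs=25, seed=3)
        net.fit(X[:140], y[:140], X[140:], y[140:])
        final = net.evaluate_loss(X[140:], y[140:])
        assert final == pytest.approx(min(net.history["val_loss"]), rel=1e-5)

    def test_empty_validation_rejected(self):
        X, y = _toy_sequences(n=20)
        net = LSTMClassifier(hidden_size=4, max_epochs=1)
        with pytest.raises(ValueError, match="validation"):
            net.fit(X, y, np.empty((0, 50)), np.empty(0))

    def test_learns_separable_sequences(self):
        X, y = _toy_sequences(n=400)
        net = LSTMClassifier(hidden_size=20, learning_rate=0.005,
                             max_epochs=50, batch_size=32, seed=0)
        net.fit(X[:300], y[:300], X[300:], y[300:])
        acc = (net.predict(X[300:]) == y[300:]).mean()
        assert acc >= 0.9


class TestClassicalTuning:
    def test_single_point_grid(self, rng):
        X = rng.standard_normal((60, 10))
        y = (X[:, 0] > 0).astype(int)
        tm = td.tune_classical("knn", X, y,
                               space={"n_neighbors": [3], "leaf_size": [30],
                                      "metric": ["euclidean"]}, k=5)
        assert len(tm.cv_table) == 1
        assert tm.hyperparams["n_neighbors"] == 3

    def test_knn_selected_on_separable_kinematics(self, medium_datasets):
        """Grid-searched KNN on a separable kinematics set picks few
        neighbours and reaches high CV f1."""
        ds = medium_datasets["kinematic-angle"]
        lws = ds.lws
        parts = td.split(lws, td.SplitSpec(scheme="ml", seed=0))
        tm = td.tune_classical("knn", lws.windows[parts["train"]],
                               lws.labels[parts["train"]], seed=0)
        assert tm.hyperparams["n_neighbors"] <= 10
        assert tm.cv_table["mean_test_score"].max() >= 0.95

    def test_too_many_folds_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        y = np.array([0] * 5 + [1] * 5)
        with pytest.raises(ValueError, match="folds"):
            td.tune_classical("svm", X, y, k=10)

    def test_grids_contain_reported_optima(self):
        """Every per-modality winning configuration is inside the search
        grid it would be selected from."""
        for modality, fams in td.OPTIMAL_HYPERPARAMS.items():
            for fam in ("knn", "svm", "rf"):
                for key, val in fams[fam].items():
                    assert val in td.HYPER_GRIDS[fam][key], (modality, fam, key)
        for modality in td.OPTIMAL_HYPERPARAMS:
            opt = td.OPTIMAL_HYPERPARAMS[modality]["lstm"]
            assert opt["hidden_size"] in td.HYPER_GRIDS["lstm"]["hidden_size"]
            assert opt["learning_rate"] in td.HYPER_GRIDS["lstm"]["learning_rate"]


class TestLstmTuning:
    def test_validation_sweep_selects_best_checkpoint(self):
        """tune_lstm picks the (hidden, lr) pair with the lowest best
        validation loss."""
        X, y = _toy_sequences(n=160)
        space = {"hidden_size": [6], "learning_rate": [0.005, 0.0001]}
        tm = td.tune_lstm(X[:120], y[:120], X[120:], y[120:], space=space,
                          max_epochs=4, seed=0)
        assert tm.hyperparams["hidden_size"] == 6
        assert tm.hyperparams["learning_rate"] in space["learning_rate"]
        assert tm.training_log["best_val_loss"] <= 0.75


class TestPredict:
    def test_one_nn_memorizes_training_data(self, rng):
        X = rng.standard_normal((40, 8))
        y = rng.integers(0, 2, 40)
        tm = td.train_classical("knn", X, y, params={"n_neighbors": 1})
        np.testing.assert_array_equal(td.predict(tm, X), y)

    def test_window_length_mismatch_rejected(self, rng):
        X = rng.standard_normal((30, 50))
        y = rng.integers(0, 2, 30)
        tm = td.train_classical("rf", X, y, params={"n_estimators": 5})
        with pytest.raises(ValueError, match="length"):
            td.predict(tm, rng.standard_normal((5, 49)))

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((30, 10))
        y = (X.sum(axis=1) > 0).astype(int)
        tm = td.train_classical("svm", X, y, params={"C": 1.0, "gamma": 0.1})
        Xt = rng.standard_normal((12, 10))
        perm = rng.permutation(12)
        np.testing.assert_array_equal(td.predict(tm, Xt)[perm],
                                      td.predict(tm, Xt[perm]))

    def test_lstm_scores_with_predict(self):
        X, y = _toy_sequences(n=60)
        tm = td.train_lstm(X[:40], y[:40], X[40:], y[40:],
                           hidden_size=6, max_epochs=2)
        out = td.predict(tm, X[40:])
        assert set(np.unique(out)) <= {0, 1}
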