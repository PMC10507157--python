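"""Network: initialization, forward pass, gradients, training, splitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sersvoc import classify as cl


class TestInit:
    def test_shapes_and_determinism(self):
        a = cl.init_network(7)
        b = cl.init_network(7)
        assert a.W1.shape == (12, 6) and a.b1.shape == (6,)
        assert a.W2.shape == (6, 6) and a.b2.shape == (6,)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.W2, b.W2)
        assert np.all(a.b1 == 0) and np.all(a.b2 == 0)

    def test_glorot_bounds(self):
        p = cl.init_network(0)
        assert np.max(np.abs(p.W1)) <= np.sqrt(6 / 18)
        assert np.max(np.abs(p.W2)) <= np.sqrt(6 / 12)


class TestForward:
    def test_zero_params_give_uniform_probabilities(self):
        p = cl.NetworkParams(np.zeros((12, 6)), np.zeros(6), np.zeros((6, 6)), np.zeros(6))
        out = cl.forward(p, np.arange(12, dtype=float))
        np.testing.assert_allclose(out, np.full(6, 1 / 6), atol=1e-15)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_probabilities_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        p = cl.NetworkParams(rng.normal(size=(12, 6)) * 3, rng.normal(size=6),
                             rng.normal(size=(6, 6)) * 3, rng.normal(size=6))
        out = cl.forward(p, rng.normal(size=12) * 5)
        assert abs(out.sum() - 1.0) < 1e-12
        assert np.all(out > 0) and np.all(out < 1)

    def test_manual_forward_oracle(self):
        """Hand-set single-dominant-hidden-unit params vs step-by-step math."""
        W1 = np.zeros((12, 6)); W1[0, 0] = 2.0
        b1 = np.zeros(6)
        W2 = np.zeros((6, 6)); W2[0, 3] = 4.0
        b2 = np.zeros(6)
        p = cl.NetworkParams(W1, b1, W2, b2)
        x = np.zeros(12); x[0] = 1.0
        h0 = 1 / (1 + np.exp(-2.0))
        z = np.zeros(6); z[3] = 4.0 * h0
        expect = np.exp(z - z.max()); expect /= expect.sum()
        np.testing.assert_allclose(cl.forward(p, x), expect, atol=1e-14)

    def test_non_finite_input_rejected(self):
        p = cl.init_network(0)
        with pytest.raises(ValueError, match="non-finite"):
            cl.forward(p, np.r_[np.nan, np.zeros(11)])


class TestGradients:
    def test_backprop_matches_central_differences(self, rng):
        """Analytic gradients vs finite differences (step 1e-5) on a
        3-sample batch, relative error <= 1e-6."""
        X = rng.normal(size=(3, 12))
        Y = np.zeros((3, 6)); Y[[0, 1, 2], [0, 2, 5]] = 1.0
        for activation in ("sigmoid", "tanh", "relu"):
            params = cl.init_network(1)
            _, g = cl.loss_and_gradients(params, X, Y, activation)
            h = 1e-5
            for name in ("W1", "b1", "W2", "b2"):
                arr = getattr(params, name)
                ana = getattr(g, name)
                num = np.zeros_like(arr)
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + h
                    lp, _ = cl.loss_and_gradients(params, X, Y, activation)
                    arr[idx] = orig - h
                    lm, _ = cl.loss_and_gradients(params, X, Y, activation)
                    arr[idx] = orig
                    num[idx] = (lp - lm) / (2 * h)
                rel = np.abs(ana - num) / np.maximum(np.abs(ana) + np.abs(num), 1e-8)
                assert rel.max() <= 1e-6, (activation, name, rel.max())


class TestTrain:
    def _toy(self, rng, n=60):
        centers = np.eye(6)[:, :6] @ np.eye(6)  # placeholder, replaced below
        X, y = [], []
        proto = rng.normal(size=(6, 12))
        for k in range(6):
            X.append(proto[k] + 0.05 * rng.normal(size=(n // 6, 12)))
            y.extend([k] * (n // 6))
        return np.vstack(X), np.eye(6)[np.asarray(y)]

    def test_zero_epochs_returns_init(self, rng):
        X, Y = self._toy(rng)
        cfg = cl.TrainConfig(epochs=0, seed=4)
        model = cl.train(X, Y, cfg)
        init = cl.init_network(4, 12, 6, 6)
        np.testing.assert_array_equal(model.params.W1, init.W1)
        assert model.loss_history.size == 0

    def test_loss_decreases(self, rng):
        X, Y = self._toy(rng)
        model = cl.train(X, Y, cl.TrainConfig(epochs=2000, seed=0))
        assert model.loss_history[-1] < model.loss_history[0]
        assert model.loss_history.size == 2000

    def test_missing_class_rejected(self, rng):
        X, Y = self._toy(rng)
        Y[:, 3] = 0.0
        with pytest.raises(ValueError, match="absent"):
            cl.train(X, Y, cl.TrainConfig(epochs=1))

    def test_determinism_and_sample_order_invariance(self, rng):
        X, Y = self._toy(rng)
        cfg = cl.TrainConfig(epochs=300, seed=9)
        a = cl.train(X, Y, cfg)
        b = cl.train(X, Y, cfg)
        np.testing.assert_array_equal(a.params.W1, b.params.W1)
        np.testing.assert_array_equal(a.loss_history, b.loss_history)
        perm = np.random.default_rng(0).permutation(X.shape[0])
        c = cl.train(X[perm], Y[perm], cfg)
        np.testing.assert_allclose(a.params.W1, c.params.W1, atol=1e-8)
        np.testing.assert_allclose(a.loss_history, c.loss_history, atol=1e-10)


class TestPredict:
    def test_uniform_ties_to_first_class(self):
        p = cl.NetworkParams(np.zeros((12, 6)), np.zeros(6), np.zeros((6, 6)), np.zeros(6))
        label = cl.predict(p, np.ones(12), class_order=("a", "b", "c", "d", "e", "f"))
        assert label == "a"

    def test_matches_forward_argmax(self, rng):
        params = cl.init_network(2)
        X = rng.normal(size=(100, 12))
        idx = cl.predict(params, X)
        np.testing.assert_array_equal(idx, np.argmax(cl.forward(params, X), axis=1))


class TestSplit:
    def test_648_to_540_leaves_18_per_class(self):
        labels = np.repeat([f"c{k}" for k in range(6)], 108)
        tr, te = cl.split_indices(labels, 540, seed=0)
        assert te.size == 108 and tr.size == 540
        for k in range(6):
            assert np.sum(labels[te] == f"c{k}") == 18

    def test_uneven_stratification(self):
        labels = np.asarray(["a"] * 6 + ["b"] * 6)
        tr, te = cl.split_indices(labels, 10, seed=1)
        assert np.sum(labels[te] == "a") == 1
        assert np.sum(labels[te] == "b") == 1

    def test_partition_property(self, rng):
        labels = rng.choice(["x", "y", "z"], size=50)
        tr, te = cl.split_indices(labels, 30, seed=2)
        assert np.intersect1d(tr, te).size == 0
        np.testing.assert_array_equal(np.union1d(tr, te), np.arange(50))

    def test_train_size_too_large_rejected(self):
        with pytest.raises(ValueError, match=">="):
            cl.split_indices(np.asarray(["a", "b"]), 2, seed=0)

    def test_reproducible(self):
        labels = np.repeat(["a", "b"], 20)
        a = cl.split_indices(labels, 30, seed=5)
        b = cl.split_indices(labels, 30, seed=5)
        np.testing.assert_array_equal(a[0], b[0])


class TestEstimator:
    def test_sklearn_api_roundtrip(self, rng):
        X = rng.normal(size=(60, 12))
        y = np.repeat(np.arange(6), 10)
        X[np.arange(60), y] += 4.0  # separable bumps
        clf = cl.ShallowSoftmaxClassifier(epochs=800, random_state=0)
        clf.fit(X, y)
        assert clf.predict_proba(X).shape == (60, 6)
        assert (clf.predict(X) == y).mean() > 0.9
        from sklearn.base import clone

        assert clone(clf).get_params()["epochs"] == 800
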