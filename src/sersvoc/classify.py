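"""Shallow fully connected softmax classifier (12 -> 6 -> 6).

One hidden layer of six units, a softmax output over the six aldehyde
classes, trained by full-batch gradient descent on the mean categorical
cross-entropy with analytically back-propagated gradients.  The network
is written out in NumPy so every arithmetic step is inspectable and
gradient-checkable; it is deliberately the smallest architecture that
can carve the 12-dimensional peak-position feature space into six
classes.

Numerical conventions: softmax with max-subtraction; cross-entropy with
a 1e-12 probability floor; Glorot-style uniform initialization
(+- sqrt(6/(fan_in + fan_out))) with zero biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

N_INPUT = 12
N_HIDDEN = 6
N_OUTPUT = 6

_PROB_FLOOR = 1e-12


@dataclass
class NetworkParams:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        if self.W1.shape[1] != self.b1.shape[0]:
            raise ValueError("W1/b1 shape mismatch")
        if self.W2.shape != (self.b1.shape[0], self.b2.shape[0]):
            raise ValueError("W2 shape inconsistent with b1/b2")
        for a in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite network parameter")

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.5
    epochs: int = 5000
    seed: int = 0
    hidden_activation: str = "sigmoid"
    features_normalized: bool = True
    train_size: int = 540

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.hidden_activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.hidden_activation!r}")


@dataclass
class TrainedModel:
    params: NetworkParams
    loss_history: np.ndarray
    config: TrainConfig


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACTIVATIONS = {
    "sigmoid": (_sigmoid, lambda z, h: h * (1.0 - h)),
    "tanh": (np.tanh, lambda z, h: 1.0 - h**2),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, h: (z > 0).astype(float)),
}


def init_network(
    seed: int, n_input: int = N_INPUT, n_hidden: int = N_HIDDEN, n_output: int = N_OUTPUT
) -> NetworkParams:
    """Glorot-uniform weights, zero biases, reproducible by seed."""
    rng = np.random.default_rng(seed)
    lim1 = np.sqrt(6.0 / (n_input + n_hidden))
    lim2 = np.sqrt(6.0 / (n_hidden + n_output))
    return NetworkParams(
        W1=rng.uniform(-lim1, lim1, size=(n_input, n_hidden)),
        b1=np.zeros(n_hidden),
        W2=rng.uniform(-lim2, lim2, size=(n_hidden, n_output)),
        b2=np.zeros(n_output),
    )


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def forward(
    params: NetworkParams, features: np.ndarray, activation: str = "sigmoid"
) -> np.ndarray:
    """Class probabilities for one feature vector or a batch."""
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature input")
    single = x.ndim == 1
    if single:
        x = x[None, :]
    act, _ = _ACTIVATIONS[activation]
    h = act(x @ params.W1 + params.b1)
    p = softmax(h @ params.W2 + params.b2)
    return p[0] if single else p


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Mean categorical cross-entropy with a 1e-12 probability floor."""
    p = np.clip(probs, _PROB_FLOOR, None)
    return float(-np.mean(np.sum(onehot * np.log(p), axis=1)))


def loss_and_gradients(
    params: NetworkParams, X: np.ndarray, Y: np.ndarray, activation: str = "sigmoid"
) -> tuple[float, NetworkParams]:
    """Mean cross-entropy and its analytic gradients (backpropagation)."""
    act, dact = _ACTIVATIONS[activation]
    n = X.shape[0]
    Z1 = X @ params.W1 + params.b1
    H = act(Z1)
    P = softmax(H @ params.W2 + params.b2)
    loss = cross_entropy(P, Y)
    dZ2 = (P - Y) / n
    dW2 = H.T @ dZ2
    db2 = dZ2.sum(axis=0)
    dH = dZ2 @ params.W2.T
    dZ1 = dH * dact(Z1, H)
    dW1 = X.T @ dZ1
    db1 = dZ1.sum(axis=0)
    return loss, NetworkParams(dW1, db1, dW2, db2)


def train(
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainConfig,
    init: NetworkParams | None = None,
) -> TrainedModel:
    """Full-batch gradient descent on mean cross-entropy.

    ``Y`` is one-hot (n x n_classes); every class must appear at least
    once.  The loss history records the loss at the parameters each
    epoch starts from, so ``epochs=0`` returns the initialization
    untouched.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if np.any(Y.sum(axis=0) < 1):
        missing = int(np.argmin(Y.sum(axis=0)))
        raise ValueError(f"class {missing} absent from training set")
    params = (init.copy() if init is not None
              else init_network(config.seed, X.shape[1], N_HIDDEN, Y.shape[1]))
    losses = np.empty(config.epochs)
    lr = config.learning_rate
    for epoch in range(config.epochs):
        loss, g = loss_and_gradients(params, X, Y, config.hidden_activation)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at epoch {epoch}; reduce learning_rate")
        losses[epoch] = loss
        params.W1 -= lr * g.W1
        params.b1 -= lr * g.b1
        params.W2 -= lr * g.W2
        params.b2 -= lr * g.b2
    return TrainedModel(params=params, loss_history=losses, config=config)


def predict(
    params: NetworkParams,
    features: np.ndarray,
    class_order: tuple[str, ...] | None = None,
    activation: str = "sigmoid",
):
    """Argmax class (ties to the lowest class index)."""
    p = forward(params, features, activation)
    idx = np.argmax(p, axis=-1)
    if class_order is None:
        return idx
    if p.ndim == 1:
        return class_order[int(idx)]
    return np.asarray([class_order[i] for i in idx])


def split_indices(
    labels: np.ndarray, train_size: int, seed: int, class_order=None
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified, disjoint, exhaustive train/test index split.

    Per-class train counts are the largest-remainder apportionment of
    ``train_size`` across classes, so the split is exact even when the
    proportions do not divide evenly.
    """
    labels = np.asarray(labels)
    n = labels.size
    if train_size >= n:
        raise ValueError(f"train_size {train_size} >= dataset size {n}")
    if train_size < 1:
        raise ValueError("train_size must be >= 1")
    classes = list(class_order) if class_order is not None else list(dict.fromkeys(labels))
    counts = {c: int(np.sum(labels == c)) for c in classes}
    quotas = {c: train_size * counts[c] / n for c in classes}
    base = {c: int(np.floor(quotas[c])) for c in classes}
    remainder = train_size - sum(base.values())
    order = sorted(classes, key=lambda c: -(quotas[c] - base[c]))
    for c in order[:remainder]:
        base[c] += 1
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx.size)
        k = base[c]
        train_idx.extend(idx[perm[:k]])
        test_idx.extend(idx[perm[k:]])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


def split_dataset(features: pd.DataFrame, train_size: int, seed: int):
    """Stratified split of a feature table (label column required)."""
    labels = features["label"].to_numpy()
    tr, te = split_indices(labels, train_size, seed)
    return features.iloc[tr].reset_index(drop=True), features.iloc[te].reset_index(drop=True)


class ShallowSoftmaxClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn-style wrapper around the 12->6->6 network.

    Parameters
    ----------
    hidden_units : int, default 6
    learning_rate : float, default 0.5
    epochs : int, default 5000
    activation : {"sigmoid", "tanh", "relu"}
    random_state : int
        Seeds the Glorot initialization; training itself is
        deterministic (full batch).
    classes : sequence or None
        Fixed class order; np.unique(y) when None.

    Attributes
    ----------
    classes_ : ndarray of class labels in output order
    params_ : NetworkParams
    loss_history_ : ndarray, one mean cross-entropy per epoch
    """

    def __init__(self, hidden_units: int = N_HIDDEN, learning_rate: float = 0.5,
                 epochs: int = 5000, activation: str = "sigmoid",
                 random_state: int = 0, classes=None):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.activation = activation
        self.random_state = random_state
        self.classes = classes

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        self.classes_ = (np.asarray(list(self.classes)) if self.classes is not None
                         else np.unique(y))
        index = {c: i for i, c in enumerate(self.classes_)}
        try:
            yi = np.asarray([index[v] for v in y])
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in classes") from None
        Y = np.zeros((y.size, self.classes_.size))
        Y[np.arange(y.size), yi] = 1.0
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            seed=self.random_state,
            hidden_activation=self.activation,
        )
        init = init_network(self.random_state, X.shape[1], self.hidden_units,
                            self.classes_.size)
        model = train(X, Y, cfg, init=init)
        self.params_ = model.params
        self.loss_history_ = model.loss_history
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        return forward(self.params_, X, self.activation)

    def predict(self, X):
        p = self.predict_proba(X)
        return self.classes_[np.argmax(p, axis=-1)]
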