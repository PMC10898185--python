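"""A funnel-shaped deep network for tabular morphometry, in NumPy.

The architecture is fixed by design: eight fully connected trunk layers of
1024, 512, 256, 128, 64, 32, 16 and 8 units, each followed by batch
normalization, an activation and dropout, then a linear output head sized by
the task (2 for sex, 4 for age groups, 1 for age regression).  The first
seven trunk activations are ReLU; the eighth is a softmax over that layer's
8 units, so the deepest representation lives on a probability simplex.  The
output head itself is a plain linear map — batch normalization and dropout
stop at the trunk, since randomizing or re-scaling the output layer at train
time would corrupt the predictions the loss is fit to.

Training minimizes mean squared error between the head output and the
target (one-hot for classification, standardized values for regression)
with plain stochastic gradient descent, the combination this architecture
is defined with.  Cross-entropy and a softmaxed head are available as
non-default options.  Everything is seeded: the same data, config and seed
reproduce the loss trace bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

DEFAULT_TRUNK: tuple[int, ...] = (1024, 512, 256, 128, 64, 32, 16, 8)

_HEAD_WIDTH = {"sex": 2, "age_class": 4, "age_regression": 1}

_EPS = 1e-5  # batch-norm variance floor
_DTYPE = np.float32


# ---------------------------------------------------------------- activations

def relu(x):
    """max(x, 0), elementwise."""
    return np.maximum(x, 0)


def softmax(x):
    """Row-wise softmax, computed with max subtraction for overflow safety."""
    x = np.asarray(x, dtype=float)
    shifted = x - np.max(x, axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=-1, keepdims=True)


def linear(x):
    """Identity."""
    return x


# ------------------------------------------------------------------- configs

@dataclass(frozen=True)
class NetworkSpec:
    """Shape of one network: input width, trunk widths, activations, head."""

    input_dim: int
    trunk: tuple[int, ...] = DEFAULT_TRUNK
    trunk_activations: tuple[str, ...] = ("relu",) * 7 + ("softmax",)
    head_dim: int = 4
    head_activation: str = "linear"
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be at least 1")
        if any(a <= b for a, b in zip(self.trunk, self.trunk[1:])):
            raise ValueError("trunk widths must be strictly decreasing")
        if len(self.trunk_activations) != len(self.trunk):
            raise ValueError("one activation per trunk layer")
        if self.head_dim < 1:
            raise ValueError("head width must be at least 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")

    @property
    def n_main_layers(self) -> int:
        """Trunk layers plus the output head."""
        return len(self.trunk) + 1


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: SGD on MSE for a fixed number of epochs."""

    epochs: int = 100
    learning_rate: float = 0.05
    batch_size: int = 16
    loss: str = "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be at least 1")
        if self.loss not in ("mse", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")


def build_network(
    input_dim: int,
    task: str,
    trunk: Sequence[int] = DEFAULT_TRUNK,
    dropout: float = 0.1,
    head_activation: str = "linear",
) -> NetworkSpec:
    """Spec for one of the three tasks: sex, age_class or age_regression."""
    if task not in _HEAD_WIDTH:
        raise ValueError(f"unknown task {task!r}")
    trunk = tuple(int(w) for w in trunk)
    return NetworkSpec(
        input_dim=int(input_dim),
        trunk=trunk,
        trunk_activations=("relu",) * (len(trunk) - 1) + ("softmax",),
        head_dim=_HEAD_WIDTH[task],
        head_activation=head_activation,
        dropout=dropout,
    )


# ---------------------------------------------------------------- the engine

class _Layer:
    """Fully connected layer + batch norm; parameters in float32."""

    __slots__ = ("W", "b", "gamma", "beta", "run_mean", "run_var")

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        bound = 1.0 / np.sqrt(n_in)  # fan-in-scaled uniform init
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out)).astype(_DTYPE)
        self.b = rng.uniform(-bound, bound, size=n_out).astype(_DTYPE)
        self.gamma = np.ones(n_out, dtype=_DTYPE)
        self.beta = np.zeros(n_out, dtype=_DTYPE)
        self.run_mean = np.zeros(n_out, dtype=_DTYPE)
        self.run_var = np.ones(n_out, dtype=_DTYPE)


class _Network:
    """Forward/backward engine shared by the classifier and regressor."""

    def __init__(self, spec: NetworkSpec, seed: int, bn_momentum: float = 0.9):
        self.spec = spec
        self.bn_momentum = bn_momentum
        rng = np.random.default_rng(seed)
        widths = [spec.input_dim, *spec.trunk]
        self.layers = [
            _Layer(rng, widths[i], widths[i + 1]) for i in range(len(spec.trunk))
        ]
        bound = 1.0 / np.sqrt(spec.trunk[-1])
        self.head_W = rng.uniform(-bound, bound,
                                  size=(spec.trunk[-1], spec.head_dim)).astype(_DTYPE)
        self.head_b = rng.uniform(-bound, bound, size=spec.head_dim).astype(_DTYPE)

    # -- forward ------------------------------------------------------------

    def _forward_train(self, X: np.ndarray, rng: np.random.Generator):
        """Forward pass with batch statistics and dropout; returns caches."""
        p = self.spec.dropout
        m = self.bn_momentum
        caches = []
        a = X
        for layer, act in zip(self.layers, self.spec.trunk_activations):
            z = a @ layer.W + layer.b
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + _EPS)
            zhat = (z - mu) * inv_std
            h = layer.gamma * zhat + layer.beta
            layer.run_mean = (m * layer.run_mean + (1 - m) * mu).astype(_DTYPE)
            layer.run_var = (m * layer.run_var + (1 - m) * var).astype(_DTYPE)
            if act == "relu":
                out = np.maximum(h, 0)
            elif act == "softmax":
                out = softmax(h).astype(_DTYPE)
            else:
                out = h
            if p > 0:
                keep = (rng.random(out.shape, dtype=_DTYPE) >= p).astype(_DTYPE)
                keep *= _DTYPE(1.0 / (1.0 - p))  # inverted dropout scaling
                dropped = out * keep
            else:
                keep = None
                dropped = out
            caches.append((a, zhat, inv_std, h, out, keep, layer, act))
            a = dropped
        scores = a @ self.head_W + self.head_b
        if self.spec.head_activation == "softmax":
            scores = softmax(scores).astype(_DTYPE)
        return scores, a, caches

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Inference pass: running batch-norm statistics, no dropout."""
        a = np.asarray(X, dtype=_DTYPE)
        for layer, act in zip(self.layers, self.spec.trunk_activations):
            z = a @ layer.W + layer.b
            h = layer.gamma * (z - layer.run_mean) / np.sqrt(layer.run_var + _EPS) \
                + layer.beta
            if act == "relu":
                a = np.maximum(h, 0)
            elif act == "softmax":
                a = softmax(h).astype(_DTYPE)
            else:
                a = h
        scores = a @ self.head_W + self.head_b
        if self.spec.head_activation == "softmax":
            scores = softmax(scores)
        return np.asarray(scores, dtype=float)

    # -- backward -----------------------------------------------------------

    def _train_batch(self, X, Y, lr: float, loss: str, rng) -> float:
        scores, a_last, caches = self._forward_train(X, rng)
        B = X.shape[0]
        if loss == "mse":
            diff = scores - Y
            batch_loss = float(np.mean(diff.astype(np.float64) ** 2))
            dscores = (2.0 / diff.size) * diff
            if self.spec.head_activation == "softmax":
                dscores = scores * (dscores - np.sum(dscores * scores,
                                                     axis=1, keepdims=True))
        else:  # cross-entropy; head output treated as logits
            p = softmax(scores)
            batch_loss = float(-np.mean(np.sum(Y * np.log(p + 1e-12), axis=1)))
            dscores = (p - Y) / B
        dscores = dscores.astype(_DTYPE)

        gW_head = a_last.T @ dscores
        gb_head = dscores.sum(axis=0)
        da = dscores @ self.head_W.T

        grads = []
        for (a_in, zhat, inv_std, h, out, keep, layer, act) in reversed(caches):
            if keep is not None:
                da = da * keep
            if act == "relu":
                dh = da * (h > 0)
            elif act == "softmax":
                dh = out * (da - np.sum(da * out, axis=1, keepdims=True))
            else:
                dh = da
            dgamma = np.sum(dh * zhat, axis=0)
            dbeta = np.sum(dh, axis=0)
            dzhat = dh * layer.gamma
            n = dh.shape[0]
            dz = (inv_std / n) * (
                n * dzhat
                - np.sum(dzhat, axis=0)
                - zhat * np.sum(dzhat * zhat, axis=0)
            )
            dz = dz.astype(_DTYPE)
            gW = a_in.T @ dz
            gb = dz.sum(axis=0)
            da = dz @ layer.W.T
            grads.append((layer, gW, gb, dgamma, dbeta))

        self.head_W -= _DTYPE(lr) * gW_head
        self.head_b -= _DTYPE(lr) * gb_head
        for layer, gW, gb, dgamma, dbeta in grads:
            layer.W -= _DTYPE(lr) * gW
            layer.b -= _DTYPE(lr) * gb
            layer.gamma -= _DTYPE(lr) * dgamma.astype(_DTYPE)
            layer.beta -= _DTYPE(lr) * dbeta.astype(_DTYPE)
        return batch_loss

    def fit(self, X: np.ndarray, Y: np.ndarray, cfg: TrainConfig) -> list[float]:
        """Run SGD for ``cfg.epochs``; returns the per-epoch mean loss trace."""
        X = np.ascontiguousarray(X, dtype=_DTYPE)
        Y = np.ascontiguousarray(Y, dtype=_DTYPE)
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected {self.spec.input_dim} features, got {X.shape[1]}"
            )
        if Y.shape != (X.shape[0], self.spec.head_dim):
            raise ValueError("target shape does not match the head width")
        rng = np.random.default_rng(cfg.seed)
        n = X.shape[0]
        trace: list[float] = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            total, seen = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                # overflow in a diverging run surfaces as the explicit
                # FloatingPointError below, not as a warning flood
                with np.errstate(over="ignore", invalid="ignore"):
                    loss = self._train_batch(X[idx], Y[idx], cfg.learning_rate,
                                             cfg.loss, rng)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged: non-finite loss at epoch {len(trace)}"
                    )
                total += loss * len(idx)
                seen += len(idx)
            trace.append(total / seen)
        return trace


# ------------------------------------------------------------ sklearn facade

class DNNClassifier(BaseEstimator, ClassifierMixin):
    """Funnel deep network classifier with MSE-on-one-hot training.

    Parameters mirror :class:`TrainConfig` plus the architecture knobs of
    :class:`NetworkSpec`.  Fitting is bit-reproducible given
    ``random_state``; prediction runs the network in inference mode (running
    batch-norm statistics, no dropout) and decodes labels by argmax with
    ties broken toward the lowest class index.
    """

    def __init__(self, trunk=DEFAULT_TRUNK, epochs=100, learning_rate=0.05,
                 batch_size=16, dropout=0.1, loss="mse",
                 head_activation="linear", random_state=0):
        self.trunk = trunk
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.dropout = dropout
        self.loss = loss
        self.head_activation = head_activation
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-d with one label per row")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        spec = NetworkSpec(
            input_dim=X.shape[1],
            trunk=tuple(self.trunk),
            trunk_activations=("relu",) * (len(self.trunk) - 1) + ("softmax",),
            head_dim=len(self.classes_),
            head_activation=self.head_activation,
            dropout=self.dropout,
        )
        self.spec_ = spec
        self.n_features_in_ = X.shape[1]
        self.net_ = _Network(spec, seed=self.random_state)
        cfg = TrainConfig(epochs=self.epochs, learning_rate=self.learning_rate,
                          batch_size=self.batch_size, loss=self.loss,
                          seed=self.random_state)
        self.loss_curve_ = self.net_.fit(X, Y, cfg)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.net_.forward(X)

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


class DNNRegressor(BaseEstimator, RegressorMixin):
    """Funnel deep network regressor (single linear output unit).

    Targets are standardized internally before MSE/SGD training and mapped
    back at prediction time, keeping the default learning rate usable for
    targets of any scale (ages in years, for instance).
    """

    def __init__(self, trunk=DEFAULT_TRUNK, epochs=100, learning_rate=0.05,
                 batch_size=16, dropout=0.1, random_state=0):
        self.trunk = trunk
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.dropout = dropout
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-d with one target per row")
        self.y_mean_ = float(y.mean())
        self.y_scale_ = float(y.std()) or 1.0
        Y = ((y - self.y_mean_) / self.y_scale_)[:, None]
        spec = NetworkSpec(
            input_dim=X.shape[1],
            trunk=tuple(self.trunk),
            trunk_activations=("relu",) * (len(self.trunk) - 1) + ("softmax",),
            head_dim=1,
            head_activation="linear",
            dropout=self.dropout,
        )
        self.spec_ = spec
        self.n_features_in_ = X.shape[1]
        self.net_ = _Network(spec, seed=self.random_state)
        cfg = TrainConfig(epochs=self.epochs, learning_rate=self.learning_rate,
                          batch_size=self.batch_size, loss="mse",
                          seed=self.random_state)
        self.loss_curve_ = self.net_.fit(X, Y, cfg)
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        z = self.net_.forward(X)[:, 0]
        return z * self.y_scale_ + self.y_mean_
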