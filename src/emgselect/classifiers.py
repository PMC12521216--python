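"""Classifiers for the retraining protocol.

Two kinds, matching the two retraining philosophies:

* :class:`BatchDiscriminantClassifier` — a shrinkage-regularised linear
  discriminant on time-domain features.  It cannot be updated in place:
  retraining refits from scratch on the cumulative pool of every window
  accepted so far, so old data weighs as much as new data.
* :class:`ConvNetClassifier` — a compact convolutional network on raw
  windows (two temporal convolution blocks with ReLU, global average
  pooling, softmax over 8 classes), trained with Adam at learning rate
  0.001 and *incrementally* retrained on accepted windows only at 0.0001.
  Implemented directly in numpy so the whole protocol runs anywhere.

Both expose ``fit`` / ``retrain`` / ``predict_proba`` / ``predict`` over a
fixed 8-class output space: a session whose accepted windows miss a class
never shrinks the prediction space, keeping confusion matrices comparable
across sessions.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .preprocessing import N_CLASSES

__all__ = ["BatchDiscriminantClassifier", "ConvNetClassifier", "make_classifier"]


def _check_training_inputs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(X) != len(y):
        raise ValueError("data/label length mismatch")
    if not np.all(np.isfinite(X)):
        raise ValueError("training data contains NaN or inf")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    return X, y


class BatchDiscriminantClassifier:
    """LDA on feature vectors with a cumulative training pool.

    The within-class covariance is shrinkage-regularised (lsqr solver,
    Ledoit-Wolf 'auto' shrinkage) so degenerate inputs — duplicated
    feature columns, tiny classes — fit without crashing.
    """

    kind = "batch_discriminant"

    def __init__(self) -> None:
        self._model: LinearDiscriminantAnalysis | None = None
        self._pool_X: np.ndarray | None = None
        self._pool_y: np.ndarray | None = None
        self._classes: np.ndarray | None = None
        self.retrain_count = 0

    @property
    def fitted(self) -> bool:
        return self._model is not None

    @property
    def pool_size(self) -> int:
        return 0 if self._pool_X is None else len(self._pool_X)

    def _refit(self) -> None:
        model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        model.fit(self._pool_X, self._pool_y)
        self._model = model
        self._classes = model.classes_

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BatchDiscriminantClassifier":
        X, y = _check_training_inputs(X, y)
        self._pool_X, self._pool_y = X.copy(), y.copy()
        self._refit()
        return self

    def retrain(self, X: np.ndarray, y: np.ndarray) -> "BatchDiscriminantClassifier":
        """Append accepted windows to the pool and refit from scratch.

        An empty accepted set is a no-op: the pool and therefore the
        predictions are unchanged.
        """
        if not self.fitted:
            raise ValueError("fit before retrain")
        self.retrain_count += 1
        if len(X) == 0:
            return self
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        self._pool_X = np.concatenate([self._pool_X, X])
        self._pool_y = np.concatenate([self._pool_y, y])
        self._refit()
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self._pool_X.shape[1]:
            raise ValueError("wrong input dimensionality")
        p = self._model.predict_proba(X)
        out = np.zeros((len(X), N_CLASSES))
        out[:, self._classes] = p
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


# ---------------------------------------------------------------------------
# Compact numpy convolutional network
# ---------------------------------------------------------------------------


@dataclass
class _Adam:
    """Adam optimiser state over a list of parameter arrays."""

    lr: float
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def init(self, params: list[np.ndarray]) -> None:
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    """Strided temporal convolution.  x: (B,T,C), W: (k,C,F) -> (B,T',F)."""
    k = W.shape[0]
    t_out = (x.shape[1] - k) // stride + 1
    patches = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, T-k+1, C, k)
    patches = patches[:, ::stride][:, :t_out]  # (B, T', C, k)
    return np.einsum("btck,kcf->btf", patches, W, optimize=True) + b


def _conv_backward(x: np.ndarray, W: np.ndarray, stride: int, d_out: np.ndarray):
    """Gradients of the strided temporal convolution."""
    k = W.shape[0]
    t_out = d_out.shape[1]
    patches = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
    patches = patches[:, ::stride][:, :t_out]  # (B, T', C, k)
    dW = np.einsum("btck,btf->kcf", patches, d_out, optimize=True)
    db = d_out.sum(axis=(0, 1))
    dx = np.zeros_like(x)
    for i in range(k):  # scatter-add over kernel taps
        idx = np.arange(t_out) * stride + i
        dx[:, idx] += np.einsum("btf,cf->btc", d_out, W[i], optimize=True)
    return dW, db, dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNetClassifier:
    """Incremental convolutional classifier on raw sEMG windows.

    Architecture: conv(k=11, stride 4, 16 filters) → ReLU →
    conv(k=5, stride 2, 32 filters) → ReLU → global average pool over
    time → dense → softmax(8).  Initial fit uses Adam at ``lr_init``
    (0.001); every retrain continues training *only on the accepted new
    windows* at ``lr_retrain`` (0.0001), so later sessions influence the
    weights more — the property that makes incremental nets attractive
    for drift adaptation.

    Fully deterministic for a fixed seed: one root generator drives
    weight initialisation and every epoch's batch order.
    """

    kind = "incremental_convnet"

    def __init__(self, seed: int = 0, lr_init: float = 1e-3, lr_retrain: float = 1e-4,
                 epochs_init: int = 30, epochs_retrain: int = 10, batch_size: int = 64,
                 n_filters: tuple[int, int] = (16, 32),
                 kernels: tuple[int, int] = (11, 5), strides: tuple[int, int] = (4, 2)):
        self.seed = seed
        self.lr_init = lr_init
        self.lr_retrain = lr_retrain
        self.epochs_init = epochs_init
        self.epochs_retrain = epochs_retrain
        self.batch_size = batch_size
        self.n_filters = n_filters
        self.kernels = kernels
        self.strides = strides
        self.params: list[np.ndarray] | None = None
        self.retrain_count = 0
        self._rng = np.random.default_rng(seed)

    @property
    def fitted(self) -> bool:
        return self.params is not None

    def _init_params(self, n_channels: int) -> None:
        rng = self._rng
        k1, k2 = self.kernels
        f1, f2 = self.n_filters
        he = lambda fan_in, shape: rng.normal(0, np.sqrt(2.0 / fan_in), shape)
        self.params = [
            he(k1 * n_channels, (k1, n_channels, f1)), np.zeros(f1),
            he(k2 * f1, (k2, f1, f2)), np.zeros(f2),
            he(f2, (f2, N_CLASSES)), np.zeros(N_CLASSES),
        ]
        self._adam = _Adam(lr=self.lr_init)
        self._adam.init(self.params)

    def _forward(self, x: np.ndarray, want_cache: bool = False):
        W1, b1, W2, b2, W3, b3 = self.params
        z1 = _conv_forward(x, W1, b1, self.strides[0])
        a1 = np.maximum(z1, 0)
        z2 = _conv_forward(a1, W2, b2, self.strides[1])
        a2 = np.maximum(z2, 0)
        pooled = a2.mean(axis=1)  # global average pool over time
        logits = pooled @ W3 + b3
        if want_cache:
            return logits, (x, z1, a1, z2, a2, pooled)
        return logits

    def _backward(self, cache, d_logits: np.ndarray) -> list[np.ndarray]:
        W1, b1, W2, b2, W3, b3 = self.params
        x, z1, a1, z2, a2, pooled = cache
        dW3 = pooled.T @ d_logits
        db3 = d_logits.sum(axis=0)
        d_pooled = d_logits @ W3.T
        d_a2 = np.repeat(d_pooled[:, None, :], a2.shape[1], axis=1) / a2.shape[1]
        d_z2 = d_a2 * (z2 > 0)
        dW2, db2, d_a1 = _conv_backward(a1, W2, self.strides[1], d_z2)
        d_z1 = d_a1 * (z1 > 0)
        dW1, db1, _ = _conv_backward(x, W1, self.strides[0], d_z1)
        return [dW1, db1, dW2, db2, dW3, db3]

    def _train(self, X: np.ndarray, y: np.ndarray, epochs: int, lr: float) -> list[float]:
        self._adam.lr = lr
        n = len(X)
        losses = []
        for _ in range(epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for s in range(0, n, self.batch_size):
                batch = order[s:s + self.batch_size]
                xb, yb = X[batch], y[batch]
                logits, cache = self._forward(xb, want_cache=True)
                p = _softmax(logits)
                eps = 1e-12
                epoch_loss += -np.log(p[np.arange(len(yb)), yb] + eps).sum()
                d_logits = p.copy()
                d_logits[np.arange(len(yb)), yb] -= 1.0
                d_logits /= len(yb)
                grads = self._backward(cache, d_logits)
                self._adam.step(self.params, grads)
            losses.append(epoch_loss / n)
        return losses

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ConvNetClassifier":
        """Initial training at lr 0.001 on raw windows (n, width, channels)."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3:
            raise ValueError("expected raw windows (n, width, n_channels)")
        if not np.all(np.isfinite(X)):
            raise ValueError("training data contains NaN or inf")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain at least 2 classes")
        self._rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[2])
        self.loss_history = self._train(X, y, self.epochs_init, self.lr_init)
        return self

    def retrain(self, X: np.ndarray, y: np.ndarray) -> "ConvNetClassifier":
        """Continue training on accepted windows only, at lr 0.0001."""
        if not self.fitted:
            raise ValueError("fit before retrain")
        self.retrain_count += 1
        if len(X) == 0:
            return self
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        self.loss_history += self._train(X, y, self.epochs_retrain, self.lr_retrain)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[2] != self.params[0].shape[1]:
            raise ValueError("wrong input dimensionality")
        out = np.empty((len(X), N_CLASSES))
        for s in range(0, len(X), 512):  # bounded memory
            out[s:s + 512] = _softmax(self._forward(X[s:s + 512]))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ConvNetClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def make_classifier(kind: str, seed: int = 0, **kwargs):
    """Factory: 'lda'/'batch' → batch discriminant, 'convnet'/'cnn' → incremental net."""
    kind = kind.lower()
    if kind in ("lda", "batch", "batch_discriminant"):
        return BatchDiscriminantClassifier()
    if kind in ("cnn", "convnet", "incremental", "incremental_convnet"):
        return ConvNetClassifier(seed=seed, **kwargs)
    raise ValueError(f"unknown classifier kind {kind!r}")
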