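"""Minimal seeded SGD training stack shared by the segmenter and classifier.

Both trainable stages use stochastic gradient descent with momentum, L2
weight decay and a piecewise-constant learning schedule that starts at
alpha and drops by 30% every 4th schedule tick:

    lr(k) = alpha * drop_factor ** floor(k / cadence)

One schedule tick corresponds to one epoch (full pass over the training
set); validation runs on the same cadence. Everything is reproducible
from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrainSchedule", "piecewise_lr", "MLP"]


@dataclass
class TrainSchedule:
    """SGD hyper-parameters: momentum method, L2 penalty, piecewise schedule."""

    alpha: float = 1e-3
    drop_factor: float = 0.7
    drop_cadence: int = 4
    l2: float = 5e-3
    momentum: float = 0.9
    validation_cadence: int = 4
    epochs: int = 48
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("learning rate alpha must be positive")
        if not 0 < self.drop_factor < 1:
            raise ValueError("drop factor must be in (0, 1)")
        if self.drop_cadence < 1 or self.validation_cadence < 1:
            raise ValueError("cadences must be >= 1")

    def lr(self, k: int) -> float:
        """Effective learning rate at schedule tick ``k`` (0-based)."""
        return piecewise_lr(self.alpha, self.drop_factor, self.drop_cadence, k)


def piecewise_lr(alpha: float, drop_factor: float, cadence: int, k: int) -> float:
    """Piecewise-constant schedule ``alpha * drop_factor ** (k // cadence)``."""
    if k < 0:
        raise ValueError("tick index must be non-negative")
    return alpha * drop_factor ** (k // cadence)


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


class MLP:
    """Small fully-connected softmax network trained with momentum SGD.

    ``hidden=()`` degenerates to multinomial logistic regression. Weights
    use seeded He initialisation; the cross-entropy loss carries an L2
    penalty applied as weight decay on the weight matrices (not biases).
    """

    def __init__(self, n_features: int, n_classes: int, hidden=(48,), seed: int = 0):
        rng = np.random.default_rng([seed, 101])
        dims = [n_features, *hidden, n_classes]
        self.W = [rng.normal(0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(d) for d in dims[1:]]
        self.hidden = tuple(hidden)
        self.n_features = n_features
        self.n_classes = n_classes

    # -- inference ---------------------------------------------------------
    def _forward(self, X):
        acts = [X]
        a = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            a = np.maximum(z, 0.0) if i < len(self.W) - 1 else z
            acts.append(a)
        return acts

    def predict_proba(self, X) -> np.ndarray:
        z = self._forward(np.asarray(X, dtype=float))[-1]
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- training ----------------------------------------------------------
    def fit(self, X, y, schedule: TrainSchedule, X_val=None, y_val=None):
        """Train in place; returns the per-validation accuracy trace
        (list of ``(epoch, lr, train_acc, val_acc)``)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(X) == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng([schedule.seed, 211])
        self._vW = [np.zeros_like(W) for W in self.W]
        self._vb = [np.zeros_like(b) for b in self.b]
        Y = _one_hot(y, self.n_classes)
        n = len(X)
        trace = []
        for epoch in range(schedule.epochs):
            lr = schedule.lr(epoch)
            order = rng.permutation(n)
            for start in range(0, n, schedule.batch_size):
                idx = order[start:start + schedule.batch_size]
                self._step(X[idx], Y[idx], lr, schedule)
            if (epoch + 1) % schedule.validation_cadence == 0 or epoch == schedule.epochs - 1:
                train_acc = float(np.mean(self.predict(X) == y))
                val_acc = (float(np.mean(self.predict(X_val) == y_val))
                           if X_val is not None else float("nan"))
                trace.append((epoch + 1, lr, train_acc, val_acc))
        return trace

    def _step(self, Xb, Yb, lr, schedule: TrainSchedule):
        acts = self._forward(Xb)
        z = acts[-1] - acts[-1].max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        delta = (p - Yb) / len(Xb)
        vW, vb = self._vel
        for i in range(len(self.W) - 1, -1, -1):
            gW = acts[i].T @ delta + schedule.l2 * self.W[i]
            gb = delta.sum(axis=0)
            vW[i] = schedule.momentum * vW[i] - lr * gW
            vb[i] = schedule.momentum * vb[i] - lr * gb
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
            self.W[i] = self.W[i] + vW[i]
            self.b[i] = self.b[i] + vb[i]

    @property
    def _vel(self):
        if not hasattr(self, "_vW"):
            self._vW = [np.zeros_like(W) for W in self.W]
            self._vb = [np.zeros_like(b) for b in self.b]
        return self._vW, self._vb

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {"version": np.array([1]),
                  "hidden": np.array(self.hidden, dtype=int),
                  "dims": np.array([self.n_features, self.n_classes], dtype=int)}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MLP":
        data = np.load(path)
        if int(data["version"][0]) != 1:
            raise ValueError("unsupported model file version")
        nf, nc = (int(v) for v in data["dims"])
        model = cls(nf, nc, hidden=tuple(int(h) for h in data["hidden"]))
        model.W = [data[f"W{i}"] for i in range(len(model.W))]
        model.b = [data[f"b{i}"] for i in range(len(model.b))]
        return model
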