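"""Training configuration, Adam optimizer, losses and training loops."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ..errors import DomainError
from .model import Sequential


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 25
    learning_rate: float = 1e-3
    batch_size: int = 16
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0

    def with_seed(self, seed: int) -> "TrainingConfig":
        return replace(self, seed=seed)


# published hyperparameter presets
TRANSFER_CONFIG = TrainingConfig(epochs=25, learning_rate=1e-3, batch_size=16)
CNN_CONFIG = TrainingConfig(epochs=230, learning_rate=5e-4, batch_size=16)
AE_CONFIG = TrainingConfig(epochs=100, learning_rate=5e-5, batch_size=16,
                           loss="mse")
AE_CNN_CONFIG = TrainingConfig(epochs=350, learning_rate=5e-5, batch_size=16)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params_and_grads, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pg = params_and_grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pg]
        self.v = [np.zeros_like(p) for p, _ in self.pg]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.pg):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy; returns (loss, dlogits)."""
    n = len(labels)
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n

def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return float((diff ** 2).mean()), 2.0 * diff / diff.size


def accuracy(logits: np.ndarray, labels: np.ndarray) -> float:
    return float((logits.argmax(axis=1) == labels).mean())


def _evaluate(model: Sequential, X, y, batch_size: int):
    logits = model.predict(X, batch_size)
    loss, _ = cross_entropy_loss(logits, y)
    return loss, accuracy(logits, y)


def train_classifier(model: Sequential, train_data, val_data,
                     config: TrainingConfig) -> tuple[Sequential, list[dict]]:
    """Mini-batch Adam training with best-validation-accuracy selection.

    ``train_data``/``val_data`` are (X, y) pairs, X in NHWC [0,1].  Returns
    the model carrying the weights of the best validation epoch plus a
    per-epoch history (train/val loss and accuracy).  Deterministic for a
    fixed seed under single-threaded numpy.
    """
    X, y = train_data
    if len(X) == 0:
        raise DomainError("empty training set")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    Xv, yv = (None, None)
    if val_data is not None and len(val_data[0]):
        Xv = np.asarray(val_data[0], dtype=np.float64)
        yv = np.asarray(val_data[1], dtype=np.int64)

    if config.epochs == 0:
        return model, []

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(
        [config.seed, 0xD1CE])))
    model.seed_dropout(config.seed)
    opt = Adam(model.trainable(), lr=config.learning_rate)
    history: list[dict] = []
    best_acc, best_weights = -1.0, None

    for epoch in range(config.epochs):
        perm = rng.permutation(len(X))
        losses, accs = [], []
        for start in range(0, len(X), config.batch_size):
            idx = perm[start:start + config.batch_size]
            logits = model.forward(X[idx], train=True)
            loss, dlogits = cross_entropy_loss(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            accs.append(accuracy(logits, y[idx]))
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "train_acc": float(np.mean(accs))}
        if Xv is not None:
            vl, va = _evaluate(model, Xv, yv, config.batch_size)
            rec["val_loss"], rec["val_acc"] = vl, va
            if va > best_acc:
                best_acc, best_weights = va, model.get_weights()
        history.append(rec)

    if best_weights is not None:
        model.set_weights(best_weights)
    return model, history


def train_autoencoder(ae: Sequential, X: np.ndarray,
                      config: TrainingConfig) -> tuple[Sequential, list[dict]]:
    """Train a reconstruction autoencoder with MSE loss; returns history."""
    X = np.asarray(X, dtype=np.float64)
    if len(X) == 0:
        raise DomainError("empty training set")
    if config.epochs == 0:
        return ae, []
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(
        [config.seed, 0xAE])))
    ae.seed_dropout(config.seed)
    opt = Adam(ae.trainable(), lr=config.learning_rate)
    history = []
    for epoch in range(config.epochs):
        perm = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = perm[start:start + config.batch_size]
            recon = ae.forward(X[idx], train=True)
            loss, dout = mse_loss(recon, X[idx])
            ae.backward(dout)
            opt.step()
            losses.append(loss)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses))})
    return ae, history
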