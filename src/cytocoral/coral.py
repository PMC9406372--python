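"""CORAL covariance-alignment loss and the two-stream adaptation trainer.

The CORAL loss is the squared Frobenius distance between source and target
batch feature covariances, scaled by 1/(4 d^2).  During adaptation each step
concatenates one labeled source batch with one unlabeled target batch and
pushes both through the *same* network (shared parameters by construction);
classification loss is computed on the source rows only, the CORAL term on
the adapted layer's activations of both streams, and the joint objective
``l_class + lambda * l_coral`` is minimized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ContractError, DomainError
from .nets.model import Sequential
from .nets.train import Adam, TrainingConfig, cross_entropy_loss, train_classifier

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoralConfig:
    """Adaptation hyperparameters.

    The adapted layer defaults to the network output (final dense layer's
    pre-softmax activations).  ``lam`` may be a number or ``"auto"`` to tune
    over ``lambda_grid`` by source-validation accuracy.
    """

    lam: float | str = 1.0
    lambda_grid: tuple[float, ...] = (0.1, 0.5, 1.0, 5.0, 10.0)

    def __post_init__(self) -> None:
        if self.lam != "auto" and float(self.lam) < 0:
            raise DomainError("lambda must be non-negative")


def batch_covariance(D: np.ndarray) -> np.ndarray:
    """Sample covariance of an (n, d) activation batch.

    C = (D^T D - (1/n)(1^T D)^T (1^T D)) / (n - 1); symmetric by
    construction.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2:
        raise ContractError(f"expected (n, d) matrix, got shape {D.shape}")
    n = D.shape[0]
    if n < 2:
        raise DomainError(f"covariance needs n >= 2 rows, got {n}")
    colsum = D.sum(axis=0, keepdims=True)          # 1^T D, shape (1, d)
    C = (D.T @ D - colsum.T @ colsum / n) / (n - 1)
    return (C + C.T) / 2.0


def coral_loss(D_S: np.ndarray, D_T: np.ndarray) -> float:
    """(1/(4 d^2)) * ||C_S - C_T||_F^2 between two activation batches."""
    D_S = np.asarray(D_S, dtype=np.float64)
    D_T = np.asarray(D_T, dtype=np.float64)
    if D_S.ndim != 2 or D_T.ndim != 2 or D_S.shape[1] != D_T.shape[1]:
        raise ContractError(f"feature dimensionality mismatch: "
                            f"{D_S.shape} vs {D_T.shape}")
    d = D_S.shape[1]
    diff = batch_covariance(D_S) - batch_covariance(D_T)
    return float((diff ** 2).sum() / (4.0 * d * d))


def coral_loss_grads(D_S: np.ndarray, D_T: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """CORAL loss plus its analytic gradients w.r.t. both batches."""
    D_S = np.asarray(D_S, dtype=np.float64)
    D_T = np.asarray(D_T, dtype=np.float64)
    d = D_S.shape[1]
    C_S, C_T = batch_covariance(D_S), batch_covariance(D_T)
    diff = C_S - C_T
    loss = float((diff ** 2).sum() / (4.0 * d * d))
    cs = D_S - D_S.mean(axis=0, keepdims=True)
    ct = D_T - D_T.mean(axis=0, keepdims=True)
    g_S = cs @ diff / (d * d * (D_S.shape[0] - 1))
    g_T = -ct @ diff / (d * d * (D_T.shape[0] - 1))
    return loss, g_S, g_T


def joint_loss(l_class: float, l_coral: float, lam: float) -> float:
    """Combined objective l_class + lambda * l_coral."""
    if lam < 0:
        raise DomainError("lambda must be non-negative")
    if not (np.isfinite(l_class) and np.isfinite(l_coral)):
        raise DomainError("loss terms must be finite")
    return float(l_class + lam * l_coral)


def adapt_train(model: Sequential, source_train, source_val,
                target_images: Optional[np.ndarray], coral_cfg: CoralConfig,
                training: TrainingConfig,
                instrument: Optional[Callable[[dict], None]] = None
                ) -> tuple[Sequential, list[dict]]:
    """Two-stream CORAL adaptation with shared weights.

    ``source_train``/``source_val`` are labeled (X, y) pairs; target images
    are unlabeled.  With lambda = 0 (or an empty target set, after a
    warning) this reduces exactly to :func:`train_classifier` under the
    same seed.  ``instrument``, if given, is called per step with the
    captured adapted-layer activations and loss terms.
    """
    lam = coral_cfg.lam
    if lam == "auto":
        raise DomainError("tune lambda via tune_lambda() before adapt_train")
    lam = float(lam)
    if target_images is None or len(target_images) == 0:
        if lam > 0:
            warnings.warn("empty target set: falling back to lambda=0 "
                          "(plain supervised training)", stacklevel=2)
        lam = 0.0
    if lam == 0.0:
        return train_classifier(model, source_train, source_val, training)

    X, y = source_train
    if len(X) == 0:
        raise DomainError("empty source training set")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    Xt = np.asarray(target_images, dtype=np.float64)

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(
        [training.seed, 0xD1CE])))
    target_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(
        [training.seed, 0x7A26E7])))
    model.seed_dropout(training.seed)
    opt = Adam(model.trainable(), lr=training.learning_rate)
    history: list[dict] = []
    bs = training.batch_size
    step = 0
    for epoch in range(training.epochs):
        perm = rng.permutation(len(X))
        tperm = target_rng.permutation(len(Xt))
        tpos = 0
        cls_losses, coral_terms = [], []
        for start in range(0, len(X), bs):
            idx = perm[start:start + bs]
            if tpos + bs > len(Xt):      # cycle the (shorter) target loader
                tperm = target_rng.permutation(len(Xt))
                tpos = 0
            tidx = tperm[tpos:tpos + bs]
            tpos += bs

            xb = np.concatenate([X[idx], Xt[tidx]], axis=0)
            out = model.forward(xb, train=True)
            ns = len(idx)
            logits_s, logits_t = out[:ns], out[ns:]
            l_class, dls = cross_entropy_loss(logits_s, y[idx])
            dout = np.zeros_like(out)
            dout[:ns] = dls
            if ns >= 2 and len(tidx) >= 2:
                l_coral, g_s, g_t = coral_loss_grads(logits_s, logits_t)
                dout[:ns] += lam * g_s
                dout[ns:] += lam * g_t
            else:
                l_coral = 0.0
                logger.info("step %d: batch too small for covariance, "
                            "CORAL term skipped", step)
            model.backward(dout)
            opt.step()
            cls_losses.append(l_class)
            coral_terms.append(l_coral)
            if instrument is not None:
                instrument({"step": step, "epoch": epoch,
                            "logits_source": logits_s.copy(),
                            "logits_target": logits_t.copy(),
                            "class_loss": l_class, "coral_loss": l_coral,
                            "joint_loss": joint_loss(l_class, l_coral, lam)})
            step += 1
        history.append({"epoch": epoch,
                        "train_class_loss": float(np.mean(cls_losses)),
                        "train_coral_loss": float(np.mean(coral_terms))})
    return model, history


def tune_lambda(model_factory: Callable[[], Sequential], source_train,
                source_val, target_images, coral_cfg: CoralConfig,
                training: TrainingConfig) -> tuple[float, dict[float, float]]:
    """Pick lambda from the grid by source-validation accuracy.

    Candidates whose adapted model produces non-finite validation scores
    (degenerate features) are discarded.  Returns (best lambda,
    per-lambda validation accuracy).
    """
    from .nets.train import accuracy as _acc

    Xv, yv = source_val
    results: dict[float, float] = {}
    for lam in coral_cfg.lambda_grid:
        m = model_factory()
        m, _ = adapt_train(m, source_train, source_val, target_images,
                           CoralConfig(lam=lam), training)
        scores = m.predict(np.asarray(Xv, dtype=np.float64))
        if not np.isfinite(scores).all():
            logger.warning("lambda=%g produced degenerate features; skipped",
                           lam)
            continue
        results[lam] = _acc(scores, np.asarray(yv, dtype=np.int64))
    if not results:
        raise DomainError("no lambda in the grid produced finite features")
    best = max(results, key=lambda k: (results[k], -k))
    return best, results


__all__ = ["CoralConfig", "batch_covariance", "coral_loss",
           "coral_loss_grads", "joint_loss", "adapt_train", "tune_lambda"]
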