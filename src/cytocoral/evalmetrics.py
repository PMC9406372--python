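"""Evaluation: confusion matrices, classification reports, ROC/AUC,
binary grouping, multi-run consistency and gradient saliency."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import ContractError, DomainError
from .nets.model import Sequential
from .types import N_CLASSES, BethesdaClass


def confusion_matrix(truth: Sequence[int], pred: Sequence[int],
                     n_classes: int = N_CLASSES) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    truth = np.asarray(truth, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if truth.shape != pred.shape:
        raise ContractError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if truth.size and (truth.min() < 0 or truth.max() >= n_classes
                       or pred.min() < 0 or pred.max() >= n_classes):
        raise ContractError("labels outside [0, n_classes)")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (truth, pred), 1)
    return cm


@dataclass
class MetricsReport:
    """Classification summary derived from one confusion matrix."""

    accuracy: float
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray
    f1_per_class: np.ndarray
    support: np.ndarray
    precision: float   # support-weighted
    recall: float      # support-weighted (== accuracy)
    f1: float
    fpr: float         # macro one-vs-rest false positive rate
    fnr: float         # macro one-vs-rest false negative rate
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "fpr": self.fpr,
            "fnr": self.fnr, "auc": self.auc,
            "precision_per_class": self.precision_per_class.tolist(),
            "recall_per_class": self.recall_per_class.tolist(),
            "f1_per_class": self.f1_per_class.tolist(),
            "support": self.support.tolist(),
        }


def classification_report(cm: np.ndarray, average: str = "weighted") -> MetricsReport:
    """Accuracy and one-vs-rest precision/recall/F1/FPR/FNR from a confusion
    matrix.  Zero-support or zero-prediction classes contribute 0 (with a
    warning), never NaN."""
    cm = np.asarray(cm, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ContractError("confusion matrix must be square")
    k = cm.shape[0]
    total = cm.sum()
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    tp = np.diag(cm)
    fp = predicted - tp
    fn = support - tp
    tn = total - tp - fp - fn

    if (support == 0).any():
        warnings.warn("zero-support class: its metrics are reported as 0",
                      stacklevel=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(predicted > 0, tp / np.maximum(predicted, 1), 0.0)
        rec = np.where(support > 0, tp / np.maximum(support, 1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec, 1e-300), 0.0)
        fpr = np.where(fp + tn > 0, fp / np.maximum(fp + tn, 1), 0.0)
        fnr = np.where(fn + tp > 0, fn / np.maximum(fn + tp, 1), 0.0)

    acc = float(tp.sum() / total) if total else 0.0
    if average == "weighted":
        w = support / total if total else np.zeros(k)
    elif average == "macro":
        w = np.full(k, 1.0 / k)
    else:
        raise DomainError(f"unknown averaging scheme {average!r}")
    return MetricsReport(
        accuracy=acc,
        precision_per_class=prec, recall_per_class=rec, f1_per_class=f1,
        support=support.astype(np.int64),
        precision=float(prec @ w), recall=float(rec @ w), f1=float(f1 @ w),
        fpr=float(fpr.mean()), fnr=float(fnr.mean()))


# ---------------------------------------------------------------------------
# ROC / AUC

def _binary_auc(truth: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), giving tied pairs 0.5 credit."""
    pos = truth == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("AUC undefined: truth contains a single class")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _roc_points(truth: np.ndarray, scores: np.ndarray):
    """(fpr, tpr) arrays over all score thresholds, descending."""
    order = np.argsort(-scores, kind="stable")
    t = truth[order]
    s = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(t == 1)[distinct]
    fps = np.cumsum(t == 0)[distinct]
    tpr = np.r_[0.0, tps / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps / max(fps[-1], 1)]
    return fpr, tpr


def roc_auc(truth: Sequence[int], score_vectors: np.ndarray,
            scheme: str = "multiclass_ovr") -> dict:
    """One-vs-rest ROC curves and macro AUC.

    ``scheme='binary'`` groups labels by :func:`binarize_labels` first and
    uses the summed positive-group score.
    """
    truth = np.asarray(truth, dtype=np.int64)
    S = np.asarray(score_vectors, dtype=np.float64)
    if not np.isfinite(S).all():
        raise ContractError("scores must be finite")
    if scheme == "binary":
        if S.ndim == 2 and S.shape[1] == N_CLASSES:
            S = S[:, 2] + S[:, 3]          # summed HSIL+SCC score
        else:
            S = S.ravel()
        b = binarize_labels(truth) if truth.size and truth.max() > 1 else truth
        auc = _binary_auc(b, S)
        fpr, tpr = _roc_points(b, S)
        return {"auc": auc, "curves": {"positive": (fpr, tpr)},
                "per_class_auc": {"positive": auc}}
    if scheme != "multiclass_ovr":
        raise DomainError(f"unknown scheme {scheme!r}")
    if S.ndim != 2:
        raise ContractError("multiclass scheme needs (n, k) score vectors")
    per, curves = {}, {}
    for k in range(S.shape[1]):
        b = (truth == k).astype(np.int64)
        if b.min() == b.max():
            continue   # class absent (or universal): no one-vs-rest curve
        name = BethesdaClass(k).name if S.shape[1] == N_CLASSES else str(k)
        per[name] = _binary_auc(b, S[:, k])
        curves[name] = _roc_points(b, S[:, k])
    if not per:
        raise DomainError("AUC undefined: truth contains a single class")
    return {"auc": float(np.mean(list(per.values()))), "curves": curves,
            "per_class_auc": per}


def binarize_labels(labels: Sequence[int]) -> np.ndarray:
    """Bethesda -> binary grouping: {NILM, LSIL} -> 0, {HSIL, SCC} -> 1."""
    arr = np.asarray(labels, dtype=np.int64)
    if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
        raise ContractError("labels outside Bethesda range")
    return (arr >= int(BethesdaClass.HSIL)).astype(np.int64)


def collapse_confusion_binary(cm: np.ndarray) -> np.ndarray:
    """Collapse a 4x4 Bethesda confusion matrix into its 2x2 block sums."""
    cm = np.asarray(cm)
    if cm.shape != (4, 4):
        raise ContractError("expected a 4x4 matrix")
    return cm.reshape(2, 2, 2, 2).sum(axis=(1, 3))


# ---------------------------------------------------------------------------
# consistency study

@dataclass
class RunSummary:
    """Accuracy statistics over repeated training runs."""

    accuracies: list[float]
    failures: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std(self) -> float:
        """Sample standard deviation (divisor n-1)."""
        return float(np.std(self.accuracies, ddof=1))

    @property
    def max(self) -> float:
        return float(np.max(self.accuracies))

    @property
    def min(self) -> float:
        return float(np.min(self.accuracies))

    def as_dict(self) -> dict:
        return {"accuracies": self.accuracies, "mean": self.mean,
                "std": self.std, "max": self.max, "min": self.min,
                "failures": self.failures}


def consistency_study(train_callable: Callable[[int], float],
                      seeds: Sequence[int] = (0, 1, 2, 3, 4)) -> RunSummary:
    """Train from scratch per seed (``train_callable(seed) -> accuracy``)
    and summarize.  A failing run is recorded, not fatal."""
    if len(seeds) < 2:
        raise DomainError("consistency study needs at least 2 runs")
    accs, failures = [], []
    for s in seeds:
        try:
            accs.append(float(train_callable(int(s))))
        except Exception:
            failures.append(int(s))
    if len(accs) < 2:
        raise DomainError("fewer than 2 runs succeeded")
    return RunSummary(accuracies=accs, failures=failures)


# ---------------------------------------------------------------------------
# saliency

def gradient_saliency(model: Sequential, image: np.ndarray,
                      class_index: int) -> np.ndarray:
    """|d score_class / d pixel|, max over channels, min-max normalized.

    A constant (zero-gradient) map normalizes to all zeros rather than NaN.
    """
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[0] != 1:
        raise ContractError("expected a single HxWxC image")
    scores = model.forward(x, train=False)
    if not (0 <= class_index < scores.shape[1]):
        raise ContractError(f"class index {class_index} out of range")
    dout = np.zeros_like(scores)
    dout[0, class_index] = 1.0
    dx = model.backward(dout)[0]
    sal = np.abs(dx).max(axis=-1)
    rng = sal.max() - sal.min()
    return (sal - sal.min()) / rng if rng > 0 else np.zeros_like(sal)


__all__ = [
    "confusion_matrix", "classification_report", "MetricsReport", "roc_auc",
    "binarize_labels", "collapse_confusion_binary", "RunSummary",
    "consistency_study", "gradient_saliency",
]
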