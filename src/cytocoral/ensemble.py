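"""Majority-vote combination of independently trained classifiers.

Each classifier contributes one indicator row (a single 1 marking its
predicted class); the ensemble prediction is the class with the largest
column sum.  Ties are broken by the highest summed softmax confidence among
the tied classes, falling back to the lowest class index in severity order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ContractError
from .nets.model import Sequential
from .nets.train import softmax
from .types import N_CLASSES, BethesdaClass


@dataclass
class VoteMatrix:
    """K x N indicator matrix: row per classifier, column per class."""

    indicators: np.ndarray
    confidences: Optional[np.ndarray] = None  # K x N softmax scores

    def __post_init__(self) -> None:
        P = np.asarray(self.indicators)
        if P.ndim != 2:
            raise ContractError("vote matrix must be 2D (classifiers x classes)")
        if not np.isin(P, (0, 1)).all() or not (P.sum(axis=1) == 1).all():
            raise ContractError("each classifier row must contain exactly one 1")
        self.indicators = P.astype(np.int64)
        if self.confidences is not None:
            C = np.asarray(self.confidences, dtype=np.float64)
            if C.shape != P.shape:
                raise ContractError("confidence shape must match indicators")
            self.confidences = C

    @classmethod
    def from_predictions(cls, preds: Sequence[int], n_classes: int = N_CLASSES,
                         confidences: Optional[np.ndarray] = None) -> "VoteMatrix":
        P = np.zeros((len(preds), n_classes), dtype=np.int64)
        for row, p in enumerate(preds):
            P[row, int(p)] = 1
        return cls(P, confidences)


def majority_vote(votes: VoteMatrix, tie_rule: str = "confidence") -> BethesdaClass:
    """Plurality winner of the vote matrix.

    ``tie_rule='confidence'`` resolves ties by the largest summed
    confidence, then lowest class index; ``'lowest_index'`` skips the
    confidence step.
    """
    sums = votes.indicators.sum(axis=0)
    top = sums.max()
    tied = np.flatnonzero(sums == top)
    if len(tied) == 1:
        return BethesdaClass(int(tied[0]))
    if tie_rule == "confidence" and votes.confidences is not None:
        conf = votes.confidences.sum(axis=0)[tied]
        best = tied[np.flatnonzero(conf == conf.max())]
        return BethesdaClass(int(best.min()))
    return BethesdaClass(int(tied.min()))


def ensemble_predict(models: Sequence[Sequential], images: np.ndarray,
                     tie_rule: str = "confidence") -> np.ndarray:
    """Majority-vote predictions of ``models`` over a batch of images."""
    if not models:
        raise ContractError("ensemble requires at least one model")
    X = np.asarray(images, dtype=np.float64)
    all_scores = []
    for m in models:
        scores = m.predict(X)
        if scores.ndim != 2 or scores.shape[1] != N_CLASSES:
            raise ContractError(f"model emitted shape {scores.shape}, "
                                f"expected (n, {N_CLASSES})")
        all_scores.append(softmax(scores))
    stacked = np.stack(all_scores)           # (K, n, 4)
    preds = stacked.argmax(axis=2)           # (K, n)
    out = np.empty(X.shape[0], dtype=np.int64)
    for i in range(X.shape[0]):
        vm = VoteMatrix.from_predictions(preds[:, i],
                                         confidences=stacked[:, i, :])
        out[i] = int(majority_vote(vm, tie_rule))
    return out


__all__ = ["VoteMatrix", "majority_vote", "ensemble_predict"]
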