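"""Confusion-based performance measures and random-guess baselines.

With N+ positives, N- negatives, FN positives predicted negative and FP
negatives predicted positive:

    Sn  = (N+ - FN) / N+          (sensitivity, positive recall)
    Sp  = (N- - FP) / N-          (specificity, negative recall)
    Acc = (N+ + N- - FN - FP) / (N+ + N-)

Acc is algebraically the class-size-weighted mean of Sn and Sp.  All three
are reported both as raw fractions and as percentages rounded to two
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import NEGATIVE, POSITIVE


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class confusion counts: class sizes and the two error counts."""

    n_pos: int
    n_neg: int
    false_neg: int  # positives predicted negative
    false_pos: int  # negatives predicted positive

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.false_neg, self.false_pos) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.false_neg > self.n_pos or self.false_pos > self.n_neg:
            raise ValueError("error counts cannot exceed class sizes")

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must be aligned")
        pos = y_true == POSITIVE
        neg = y_true == NEGATIVE
        return cls(
            n_pos=int(pos.sum()),
            n_neg=int(neg.sum()),
            false_neg=int(np.sum(pos & (y_pred == NEGATIVE))),
            false_pos=int(np.sum(neg & (y_pred == POSITIVE))),
        )


@dataclass(frozen=True)
class Metrics:
    """Sn/Sp/Acc as fractions; percentage views rounded to 2 decimals."""

    sn: float
    sp: float
    acc: float

    @property
    def sn_pct(self) -> float:
        return round(100.0 * self.sn, 2)

    @property
    def sp_pct(self) -> float:
        return round(100.0 * self.sp, 2)

    @property
    def acc_pct(self) -> float:
        return round(100.0 * self.acc, 2)

    def as_dict(self) -> dict[str, float]:
        return {
            "Sn": self.sn_pct,
            "Sp": self.sp_pct,
            "Acc": self.acc_pct,
            "sn_fraction": self.sn,
            "sp_fraction": self.sp,
            "acc_fraction": self.acc,
        }


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and accuracy from confusion counts."""
    if counts.n_pos == 0 or counts.n_neg == 0:
        raise ValueError("both classes must be non-empty")
    sn = (counts.n_pos - counts.false_neg) / counts.n_pos
    sp = (counts.n_neg - counts.false_pos) / counts.n_neg
    acc = (
        counts.n_pos + counts.n_neg - counts.false_neg - counts.false_pos
    ) / (counts.n_pos + counts.n_neg)
    return Metrics(sn=sn, sp=sp, acc=acc)


def crg_accuracy(n_pos: int, n_neg: int, weighted: bool = True) -> float:
    """Accuracy (%) of a completely random guess.

    Unweighted, a coin flip scores 50% regardless of class sizes.  The
    weighted variant guesses each class with its prior probability, giving

        Acc = [n_pos * (n_pos/N) + n_neg * (n_neg/N)] / N,  N = n_pos + n_neg,

    which is >= 50% with equality iff the classes are balanced.
    """
    n = n_pos + n_neg
    if n <= 0:
        raise ValueError("need at least one sample")
    if not weighted:
        return 50.0
    return 100.0 * (n_pos * (n_pos / n) + n_neg * (n_neg / n)) / n


def count_feature_combinations(d: int) -> int:
    """Number of non-empty subsets of ``d`` features: 2**d - 1, exact."""
    if d < 1:
        raise ValueError("d must be >= 1")
    return 2**d - 1
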