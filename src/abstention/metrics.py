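"""Confusion counting with a reject option, MCC, and coverage.

A classifier with a reject option labels each sample positive, negative, or
rejected.  Rejected samples contribute to no cell of the 2x2 confusion matrix;
they are tallied separately so that coverage (the *size fraction*) can be
computed.  The Matthews correlation coefficient (MCC) is evaluated on the
classified samples only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Sentinel label for an abstained (rejected) prediction.  Predictions are
#: integer sequences over {0, 1, REJECT}; ground-truth labels are {0, 1} only.
REJECT: int = -1

__all__ = ["REJECT", "ConfusionWithReject", "count_confusion", "mcc", "size_fraction"]


@dataclass(frozen=True)
class ConfusionWithReject:
    """2x2 confusion counts plus the number of rejected samples.

    Invariant: all five counts are non-negative and sum to the number of
    samples evaluated.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    rejected: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn", "rejected"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
            object.__setattr__(self, name, int(value))

    @property
    def n_classified(self) -> int:
        """Number of samples that received a class label."""
        return self.tp + self.tn + self.fp + self.fn

    @property
    def total(self) -> int:
        """Number of samples evaluated, including rejected ones."""
        return self.n_classified + self.rejected


def count_confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionWithReject:
    """Tally TP/TN/FP/FN over classified samples and count rejections.

    Parameters
    ----------
    labels
        Ground-truth binary labels in {0, 1}; must not contain ``REJECT``.
    predictions
        Trinary predictions in {0, 1, ``REJECT``}, same length as `labels`.

    A rejected prediction is counted as rejected regardless of its label.
    """
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.ndim != 1 or p.ndim != 1 or len(y) != len(p):
        raise ValueError(f"labels and predictions must be 1-D of equal length, got {len(y)} and {len(p)}")
    if len(y) == 0:
        raise ValueError("cannot count confusion over zero samples")
    if not np.isin(y, (0, 1)).all():
        bad = sorted(set(np.unique(y).tolist()) - {0, 1})
        raise ValueError(f"labels must be binary in {{0, 1}}; found {bad} (the reject symbol is not a valid label)")
    if not np.isin(p, (0, 1, REJECT)).all():
        bad = sorted(set(np.unique(p).tolist()) - {0, 1, REJECT})
        raise ValueError(f"predictions must lie in {{0, 1, {REJECT}}}; found {bad}")

    kept = p != REJECT
    yk, pk = y[kept], p[kept]
    return ConfusionWithReject(
        tp=int(np.sum((yk == 1) & (pk == 1))),
        tn=int(np.sum((yk == 0) & (pk == 0))),
        fp=int(np.sum((yk == 0) & (pk == 1))),
        fn=int(np.sum((yk == 1) & (pk == 0))),
        rejected=int(np.sum(~kept)),
    )


def mcc(c: ConfusionWithReject) -> float:
    """Matthews correlation coefficient of the classified samples.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Returns 0.0 whenever any of the four denominator factors is zero (the
    standard convention; it keeps the objective well defined when abstention
    empties a predicted or actual class, including total abstention).  The
    rejected count is ignored.
    """
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    factors = (tp + fp, tp + fn, tn + fp, tn + fn)
    if any(f == 0.0 for f in factors):
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(factors[0] * factors[1] * factors[2] * factors[3])


def size_fraction(c: ConfusionWithReject) -> float:
    """Fraction of evaluated samples that were classified (coverage).

    Ranges from 0 (everything rejected) to 1 (no abstention).
    """
    if c.total == 0:
        raise ValueError("size_fraction undefined for zero evaluated samples")
    return c.n_classified / c.total
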