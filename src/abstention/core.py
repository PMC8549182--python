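"""Abstention intervals and their grid-search optimizers.

The abstaining classifier trichotomizes a positive-class probability score p
against an interval [L, U]:

    positive  if p >= U,
    negative  if p <= L,
    rejected  otherwise (L < p < U).

The interval is parameterized by an *anchor* a (offset of its center from the
default decision threshold 0.5) and a *half-width* w >= 0:

    L = 0.5 + a - w,    U = 0.5 + a + w.

A symmetric interval has a = 0.  The optimizers search a grid of (w, a) pairs
for the one maximizing the product objective

    objective = MCC(classified samples) * size_fraction,

which scalarizes the two conflicting goals (high MCC, high coverage); the full
Pareto front in (MCC, coverage) is returned alongside so other trade-offs can
be inspected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import REJECT, count_confusion, mcc, size_fraction

__all__ = [
    "LabeledScores",
    "AbstentionInterval",
    "GridSpec",
    "EvaluationPoint",
    "OptimizationResult",
    "interval_from_params",
    "classify_with_abstention",
    "cost",
    "evaluate_interval",
    "fit_symmetric",
    "fit_asymmetric",
    "pareto_front",
]


@dataclass(frozen=True)
class LabeledScores:
    """Per-sample positive-class probabilities with binary ground truth."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        y = np.asarray(self.labels)
        if s.ndim != 1 or y.ndim != 1 or len(s) != len(y):
            raise ValueError("scores and labels must be 1-D and of equal length")
        if len(s) == 0:
            raise ValueError("empty score set")
        if np.any(~np.isfinite(s)) or s.min() < 0.0 or s.max() > 1.0:
            raise ValueError("scores must be probabilities in [0, 1]")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary in {0, 1}")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y.astype(np.int64))

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class AbstentionInterval:
    """The score interval [lower, upper] inside which the classifier abstains."""

    anchor: float
    half_width: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError("interval bounds must satisfy 0 <= lower <= upper <= 1")


def interval_from_params(anchor: float, half_width: float) -> AbstentionInterval:
    """Build [L, U] = [0.5 + anchor - half_width, 0.5 + anchor + half_width].

    Bounds are clipped to [0, 1]; clipping is reported as a warning since it
    makes the realized interval narrower than requested.
    """
    if half_width < 0:
        raise ValueError(f"half_width must be >= 0, got {half_width}")
    lower = 0.5 + anchor - half_width
    upper = 0.5 + anchor + half_width
    if lower < 0.0 or upper > 1.0:
        warnings.warn(
            f"abstention interval [{lower:.3f}, {upper:.3f}] clipped to [0, 1]",
            stacklevel=2,
        )
    return AbstentionInterval(
        anchor=float(anchor),
        half_width=float(half_width),
        lower=float(min(max(lower, 0.0), 1.0)),
        upper=float(min(max(upper, 0.0), 1.0)),
    )


def classify_with_abstention(
    scores: LabeledScores | Sequence[float] | np.ndarray,
    interval: AbstentionInterval,
) -> np.ndarray:
    """Trichotomize scores against an abstention interval.

    positive (1) if p >= upper, negative (0) if p <= lower, REJECT otherwise.
    Scores exactly on a bound are classified, not rejected; with a zero-width
    interval this reduces to the plain threshold rule p >= 0.5+anchor -> 1.
    """
    p = scores.scores if isinstance(scores, LabeledScores) else np.asarray(scores, dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("scores must be probabilities in [0, 1]")
    return np.where(p >= interval.upper, 1, np.where(p <= interval.lower, 0, REJECT)).astype(np.int64)


def evaluate_interval(s: LabeledScores, interval: AbstentionInterval) -> tuple[float, float]:
    """(MCC, size_fraction) of a fixed interval on a labeled score set."""
    c = count_confusion(s.labels, classify_with_abstention(s, interval))
    return mcc(c), size_fraction(c)


def cost(s: LabeledScores, anchor: float, half_width: float) -> tuple[float, float]:
    """(MCC, size_fraction) of the interval parameterized by (anchor, half_width).

    half_width must lie in [0, 0.5] (0.5 on each side already spans the whole
    probability range).  With half_width = 0 this is exactly the no-abstention
    classifier thresholded at 0.5 + anchor.
    """
    if not 0.0 <= half_width <= 0.5:
        raise ValueError(f"half_width must lie in [0, 0.5], got {half_width}")
    return evaluate_interval(s, interval_from_params(anchor, half_width))


@dataclass(frozen=True)
class GridSpec:
    """Search grid for the optimizers.

    Half-widths form the half-open arithmetic sequence
    [interval_low, interval_high) with step interval_step; the defaults
    (0, 0.16, 0.01) give widths 0.00..0.15.  Anchors are num_anchors evenly
    spaced values on [-anchor_width, +anchor_width] including both endpoints;
    with the default 20 points over [-0.2, 0.2] the endpoints-inclusive grid
    excludes 0, so include_zero_anchor (default True) injects the zero anchor,
    guaranteeing the symmetric grid is a subset of the asymmetric one.  The
    replication profile keeps the bare 20-point grid.
    """

    interval_low: float = 0.0
    interval_high: float = 0.16
    interval_step: float = 0.01
    anchor_width: float = 0.2
    num_anchors: int = 20
    include_zero_anchor: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.interval_low < self.interval_high <= 0.5):
            raise ValueError("require 0 <= interval_low < interval_high <= 0.5")
        if self.interval_step <= 0:
            raise ValueError("interval_step must be positive")
        if self.num_anchors < 1:
            raise ValueError("num_anchors must be >= 1")
        if self.anchor_width < 0:
            raise ValueError("anchor_width must be >= 0")

    @classmethod
    def replication_profile(cls) -> "GridSpec":
        """Grid pinned to the published defaults: widths 0..0.15 step 0.01,
        20 endpoint-inclusive anchors on [-0.2, 0.2], zero anchor excluded."""
        return cls(include_zero_anchor=False)

    def half_widths(self) -> np.ndarray:
        # half-open [low, high): tolerance guards float noise in the division
        count = int(np.floor((self.interval_high - self.interval_low) / self.interval_step - 1e-9)) + 1
        return self.interval_low + self.interval_step * np.arange(count)

    def anchors(self) -> np.ndarray:
        if self.num_anchors == 1:
            grid = np.array([0.0]) if self.anchor_width == 0 else np.array([-self.anchor_width])
        else:
            grid = np.linspace(-self.anchor_width, self.anchor_width, self.num_anchors)
        if self.include_zero_anchor and not np.any(np.abs(grid) < 1e-12):
            grid = np.sort(np.append(grid, 0.0))
        return grid


@dataclass(frozen=True)
class EvaluationPoint:
    """One grid cell: parameters, both objectives, and their product."""

    half_width: float
    anchor: float
    mcc: float
    size_fraction: float
    objective: float


@dataclass(frozen=True)
class OptimizationResult:
    best: EvaluationPoint
    interval: AbstentionInterval
    grid: tuple[EvaluationPoint, ...]
    pareto_front: tuple[EvaluationPoint, ...] = field(repr=False)


def _tie_key(p: EvaluationPoint) -> tuple[float, float, float]:
    # among equal objectives: least abstention, then most symmetric, then lower anchor
    return (p.half_width, abs(p.anchor), p.anchor)


def _fit(s: LabeledScores, half_widths: np.ndarray, anchors: np.ndarray) -> OptimizationResult:
    if len(half_widths) == 0 or len(anchors) == 0:
        raise ValueError("empty search grid")
    points = []
    for w in half_widths:
        for a in anchors:
            m, f = cost(s, float(a), float(w))
            points.append(EvaluationPoint(float(w), float(a), m, f, m * f))
    best = points[0]
    for p in points[1:]:
        if p.objective > best.objective or (p.objective == best.objective and _tie_key(p) < _tie_key(best)):
            best = p
    return OptimizationResult(
        best=best,
        interval=interval_from_params(best.anchor, best.half_width),
        grid=tuple(points),
        pareto_front=tuple(pareto_front(points)),
    )


def fit_symmetric(s: LabeledScores, g: GridSpec | None = None) -> OptimizationResult:
    """1-D grid search over half-widths with the interval centered at 0.5."""
    g = g or GridSpec()
    return _fit(s, g.half_widths(), np.array([0.0]))


def fit_asymmetric(s: LabeledScores, g: GridSpec | None = None) -> OptimizationResult:
    """2-D grid search over the Cartesian product of half-widths and anchors."""
    g = g or GridSpec()
    return _fit(s, g.half_widths(), g.anchors())


def pareto_front(points: Sequence[EvaluationPoint]) -> list[EvaluationPoint]:
    """All points not strictly dominated in (mcc, size_fraction).

    A point dominates another if it is >= in both coordinates and > in at
    least one.  The front is sorted by size_fraction descending (ties by mcc
    descending); duplicates of a non-dominated point are all retained.
    """
    pts = list(points)
    if not pts:
        raise ValueError("pareto_front of an empty point set")
    front = [
        p
        for p in pts
        if not any(
            q.mcc >= p.mcc and q.size_fraction >= p.size_fraction
            and (q.mcc > p.mcc or q.size_fraction > p.size_fraction)
            for q in pts
        )
    ]
    front.sort(key=lambda p: (-p.size_fraction, -p.mcc))
    return front
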