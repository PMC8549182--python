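"""Synthetic data with the statistical structure of imbalanced diagnostic scores.

Real diagnostic score sets consist of two overlapping class-conditional
distributions on [0, 1] — controls concentrated below the decision threshold,
cases above — with the positive class often rare.  Beta distributions model
this directly: they live on [0, 1], take arbitrary skew, and have a closed-form
CDF, which yields an exact population-level oracle for the grid objective.

All generators draw from named sub-streams of a single integer seed, so the
score, feature and down-sampling draws are mutually decoupled and every output
is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import LabeledScores, interval_from_params

__all__ = [
    "ScoreSimConfig",
    "FeatureSimConfig",
    "simulate_scores",
    "population_objective",
    "simulate_features",
    "downsample_balanced",
]

# sub-stream tags: one fixed integer per generator so operations sharing a
# seed still draw independently
_TAG_SCORES = 101
_TAG_FEATURES = 202
_TAG_DOWNSAMPLE = 303


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([tag, int(seed) & 0x7FFFFFFF]))


@dataclass(frozen=True)
class ScoreSimConfig:
    """Beta-mixture score model.

    Defaults emulate a heavily imbalanced diagnostic setting: ~10% cases, with
    controls ~ Beta(2, 8) (mean 0.2) and cases ~ Beta(8, 2) (mean 0.8) — well
    separated but overlapping around the 0.5 threshold.
    """

    n: int = 1000
    positive_fraction: float = 0.1
    neg_shape: tuple[float, float] = (2.0, 8.0)
    pos_shape: tuple[float, float] = (8.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        for name in ("neg_shape", "pos_shape"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} must be a pair of positive Beta parameters")


def simulate_scores(cfg: ScoreSimConfig) -> LabeledScores:
    """Draw labels ~ Bernoulli(positive_fraction) and class-conditional Beta scores."""
    rng = _rng(cfg.seed, _TAG_SCORES)
    labels = (rng.random(cfg.n) < cfg.positive_fraction).astype(np.int64)
    scores = np.empty(cfg.n)
    pos = labels == 1
    scores[pos] = rng.beta(*cfg.pos_shape, size=int(pos.sum()))
    scores[~pos] = rng.beta(*cfg.neg_shape, size=int((~pos).sum()))
    return LabeledScores(scores=scores, labels=labels)


def population_objective(cfg: ScoreSimConfig, anchor: float, half_width: float) -> float:
    """Expected MCC x coverage of an interval under the configured mixture.

    The four confusion rates are tail integrals of the Beta densities outside
    [L, U]: with prevalence pi,

        TP = pi * (1 - F_pos(U)),   FN = pi * F_pos(L),
        FP = (1-pi) * (1 - F_neg(U)), TN = (1-pi) * F_neg(L),

    MCC is evaluated on these rates with the same zero-denominator convention
    as the sample metric, and multiplied by the classified mass.  The score
    distributions are continuous, so boundary ties carry no mass.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clipping is expected for wide oracle queries
        iv = interval_from_params(anchor, half_width)
    pi = cfg.positive_fraction
    f_pos = stats.beta(*cfg.pos_shape).cdf
    f_neg = stats.beta(*cfg.neg_shape).cdf
    # classify positive iff p >= U, negative iff p <= L; boundary ties and
    # clipped bounds carry no mass under a continuous score distribution
    tp = pi * (1.0 - f_pos(iv.upper))
    fp = (1.0 - pi) * (1.0 - f_neg(iv.upper))
    fn = pi * f_pos(iv.lower)
    tn = (1.0 - pi) * f_neg(iv.lower)
    size = tp + tn + fp + fn
    if size <= 0.0:
        return 0.0
    factors = (tp + fp, tp + fn, tn + fp, tn + fn)
    if any(f <= 0.0 for f in factors):
        return 0.0
    mcc = (tp * tn - fp * fn) / np.sqrt(factors[0] * factors[1] * factors[2] * factors[3])
    return float(mcc * size)


@dataclass(frozen=True)
class FeatureSimConfig:
    """Two isotropic Gaussian point clouds in feature space.

    Class centroids are class_separation apart in every feature; noise_scale
    is the per-feature standard deviation.
    """

    n: int = 200
    n_features: int = 5
    positive_fraction: float = 0.3
    class_separation: float = 2.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")


def simulate_features(cfg: FeatureSimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Seeded feature table (columns f1..fk) and binary label vector."""
    rng = _rng(cfg.seed, _TAG_FEATURES)
    labels = (rng.random(cfg.n) < cfg.positive_fraction).astype(np.int64)
    X = rng.normal(scale=cfg.noise_scale, size=(cfg.n, cfg.n_features))
    X[labels == 1] += cfg.class_separation
    return pd.DataFrame(X, columns=[f"f{j + 1}" for j in range(cfg.n_features)]), labels


def downsample_balanced(labels, seed: int = 0) -> np.ndarray:
    """Indices keeping the whole minority class and an equal-size uniform
    without-replacement subsample of the majority class.

    Already-balanced input is returned in full.  Indices come back sorted, so
    the subset preserves the original sample order.
    """
    y = np.asarray(labels)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to balance")
    if len(pos) == len(neg):
        return np.arange(len(y))
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    rng = _rng(seed, _TAG_DOWNSAMPLE)
    kept_majority = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, kept_majority]))
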