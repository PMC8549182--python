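"""Readers and writers for the CSV/JSON formats.

Score files are RFC-4180 CSV with a header and columns ``sample_id`` (optional
on read), ``score`` and ``label``.  Feature files carry ``sample_id``, feature
columns and ``label``.  JSON is the canonical machine-readable output for
optimization results and reports; grids are additionally written as tidy CSV
(one row per evaluated grid cell) ready for heatmap rendering.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AbstentionInterval, EvaluationPoint, LabeledScores, OptimizationResult
from .experiment import AbstentionReport

__all__ = [
    "canonicalize_labels",
    "read_scores",
    "write_scores",
    "read_features",
    "write_features",
    "result_to_dict",
    "write_result_json",
    "write_grid_csv",
    "read_grid_csv",
    "write_report_json",
    "read_report_json",
]


def canonicalize_labels(values, positive_label=None) -> np.ndarray:
    """Map an arbitrary two-valued label column to {0, 1}.

    Columns already in {0, 1} pass through.  Otherwise the positive label must
    be named explicitly; everything else becomes 0.
    """
    arr = pd.Series(values).to_numpy()
    uniq = pd.unique(arr)
    if positive_label is None:
        as_set = set(np.asarray(uniq).tolist())
        if as_set <= {0, 1}:
            return np.asarray(arr, dtype=np.int64)
        raise ValueError(
            f"labels take values {sorted(map(str, as_set))}; pass positive_label to name the positive class"
        )
    if len(uniq) > 2:
        raise ValueError(f"label column is not binary: {len(uniq)} distinct values")
    if positive_label not in uniq.tolist():
        raise ValueError(f"positive_label {positive_label!r} not found in label column")
    return (arr == positive_label).astype(np.int64)


def _require_columns(df: pd.DataFrame, needed: list[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_scores(path, positive_label=None) -> tuple[LabeledScores, np.ndarray]:
    """Read a score CSV; returns the scores plus the sample ids.

    Missing ``sample_id`` is filled with 0..n-1.  Scores outside [0, 1] or a
    non-binary label column raise with the offending data row number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["score", "label"], path)
    scores = pd.to_numeric(df["score"], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(scores) | (scores < 0) | (scores > 1))
    if len(bad):
        raise ValueError(f"{path}: line {bad[0] + 2}: score {df['score'].iloc[bad[0]]!r} is not a probability in [0, 1]")
    labels = canonicalize_labels(df["label"], positive_label)
    ids = df["sample_id"].to_numpy() if "sample_id" in df.columns else np.arange(len(df))
    return LabeledScores(scores=scores, labels=labels), ids


def write_scores(path, s: LabeledScores, sample_ids=None) -> None:
    """Write a score CSV; full float precision, lossless on round-trip."""
    ids = np.arange(len(s)) if sample_ids is None else np.asarray(sample_ids)
    pd.DataFrame({"sample_id": ids, "score": s.scores, "label": s.labels}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_features(path, positive_label=None) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Read a feature CSV -> (feature table, labels, sample ids)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["label"], path)
    labels = canonicalize_labels(df["label"], positive_label)
    ids = df["sample_id"].to_numpy() if "sample_id" in df.columns else np.arange(len(df))
    X = df.drop(columns=[c for c in ("sample_id", "label") if c in df.columns])
    if X.shape[1] == 0:
        raise ValueError(f"{path}: no feature columns besides sample_id/label")
    return X, labels, ids


def write_features(path, X: pd.DataFrame, labels, sample_ids=None) -> None:
    ids = np.arange(len(X)) if sample_ids is None else np.asarray(sample_ids)
    out = X.copy()
    out.insert(0, "sample_id", ids)
    out["label"] = np.asarray(labels)
    out.to_csv(path, index=False, float_format="%.17g")


def _point_to_dict(p: EvaluationPoint) -> dict:
    return {
        "half_width": p.half_width,
        "anchor": p.anchor,
        "mcc": p.mcc,
        "size_fraction": p.size_fraction,
        "objective": p.objective,
    }


def _interval_to_dict(iv: AbstentionInterval) -> dict:
    return {"anchor": iv.anchor, "half_width": iv.half_width, "lower": iv.lower, "upper": iv.upper}


def result_to_dict(res: OptimizationResult) -> dict:
    return {
        "best": _point_to_dict(res.best),
        "interval": _interval_to_dict(res.interval),
        "grid": [_point_to_dict(p) for p in res.grid],
        "pareto_front": [_point_to_dict(p) for p in res.pareto_front],
    }


def write_result_json(path, res: OptimizationResult) -> None:
    Path(path).write_text(json.dumps(result_to_dict(res), indent=2) + "\n")


def write_grid_csv(path, points) -> None:
    """Tidy grid: one (half_width, anchor, mcc, size_fraction, objective) row per cell."""
    pd.DataFrame([_point_to_dict(p) for p in points]).to_csv(path, index=False, float_format="%.17g")


def read_grid_csv(path) -> list[EvaluationPoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["half_width", "anchor", "mcc", "size_fraction", "objective"], path)
    return [EvaluationPoint(**{k: float(row[k]) for k in
                               ("half_width", "anchor", "mcc", "size_fraction", "objective")})
            for _, row in df.iterrows()]


def write_report_json(path, report: AbstentionReport) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def read_report_json(path) -> AbstentionReport:
    return AbstentionReport.from_dict(json.loads(Path(path).read_text()))
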