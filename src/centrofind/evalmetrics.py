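"""Detection scoring: tolerance matching, precision, recall, F1.

Predicted centres are matched one-to-one to ground-truth centres among
pairs within a distance tolerance, maximizing the number of matches and,
among maximum matchings, minimizing total distance (solved as a min-cost
assignment with a large penalty on out-of-tolerance pairs).  Optimal
matching is order-independent, unlike greedy nearest-first, and never
yields fewer matches.

Precision = tp/(tp+fp), recall = tp/(tp+fn), F1 their harmonic mean.
Edge conventions: empty predictions against non-empty truth score 0; both
empty score 1 (vacuous truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .imgio import DetectionSet

_BIG = 1e9


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    tolerance: float | tuple[float, float, float]
    matches: list[tuple[int, int, float]] = field(default_factory=list)


def _as_coords(obj) -> np.ndarray:
    """Coerce detections/arrays/point lists to an (n, 4) float array (t,z,y,x)."""
    if isinstance(obj, DetectionSet):
        return obj.coordinates()
    arr = np.asarray(obj, dtype=float)
    if arr.size == 0:
        return np.zeros((0, 4))
    if arr.ndim != 2:
        raise ValueError("expected an (n, 3) or (n, 4) coordinate array")
    if arr.shape[1] == 3:  # (z, y, x) for a single timepoint
        arr = np.hstack([np.zeros((arr.shape[0], 1)), arr])
    elif arr.shape[1] != 4:
        raise ValueError(f"expected 3 or 4 coordinate columns, got {arr.shape[1]}")
    return arr


def _scaled_distances(pred: np.ndarray, truth: np.ndarray, tolerance) -> tuple[np.ndarray, float]:
    """Pairwise distances with per-axis scaling for anisotropic tolerances.

    Returns (distance matrix, effective radius): for a scalar tolerance the
    distances are Euclidean in voxels and the radius is the tolerance; for a
    (rz, ry, rx) tolerance each axis is divided by its radius and the
    effective radius is 1.
    """
    dz = pred[:, None, 1] - truth[None, :, 1]
    dy = pred[:, None, 2] - truth[None, :, 2]
    dx = pred[:, None, 3] - truth[None, :, 3]
    if np.isscalar(tolerance):
        if tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        dist = np.sqrt(dz**2 + dy**2 + dx**2)
        radius = float(tolerance)
    else:
        rz, ry, rx = (float(r) for r in tolerance)
        if min(rz, ry, rx) <= 0:
            raise ValueError("tolerance radii must be > 0")
        dist = np.sqrt((dz / rz) ** 2 + (dy / ry) ** 2 + (dx / rx) ** 2)
        radius = 1.0
    # points at different timepoints never match
    dist = np.where(pred[:, None, 0] == truth[None, :, 0], dist, np.inf)
    return dist, radius


def match_and_score(pred, truth, tolerance) -> EvalResult:
    """Match predictions to ground truth within tolerance; score P/R/F1.

    ``pred``/``truth`` are DetectionSets or (n, 3)/(n, 4) coordinate arrays
    ((z,y,x) or (t,z,y,x)).  ``tolerance`` is a scalar radius in voxels or
    an anisotropic ``(rz, ry, rx)`` triple.
    """
    p = _as_coords(pred)
    g = _as_coords(truth)
    matches: list[tuple[int, int, float]] = []
    if len(p) and len(g):
        dist, radius = _scaled_distances(p, g, tolerance)
        cost = np.where(dist <= radius, dist, _BIG)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if cost[r, c] < _BIG:
                matches.append((int(r), int(c), float(dist[r, c])))
    elif np.isscalar(tolerance) and tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    tp = len(matches)
    fp = len(p) - tp
    fn = len(g) - tp
    if tp + fp == 0:
        precision = 1.0 if fn == 0 else 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 1.0 if fp == 0 else 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return EvalResult(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1,
        tolerance=tolerance, matches=matches,
    )


def score_batch(preds: list, truths: list, tolerance) -> dict:
    """Score a list of images; aggregate mean and sample sd of P, R, F1.

    Returns {"per_image": [EvalResult, ...], "summary": {metric: (mean, sd)},
    "n": count}.  With one image the sd is reported as 0.0 (n=1 flagged in
    the summary).
    """
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have the same length")
    results = [match_and_score(p, g, tolerance) for p, g in zip(preds, truths)]
    summary = {}
    for metric in ("precision", "recall", "f1"):
        vals = np.array([getattr(r, metric) for r in results], dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        summary[metric] = (float(vals.mean()) if len(vals) else float("nan"), sd)
    return {"per_image": results, "summary": summary, "n": len(results)}
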