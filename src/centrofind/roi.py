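"""Keyframed polygon ROIs: interpolation across planes/timepoints, filtering.

A PolygonROI is a sparse set of user-drawn closed polygons at keyframe
(t, z) positions.  To query the ROI at an arbitrary plane and timepoint,
each keyframe polygon is resampled to a fixed number of points uniformly by
arc length (from a canonical start vertex, counter-clockwise), giving a
point-to-point correspondence between polygons of different vertex counts;
corresponding points are then interpolated linearly in z and in t (bilinear
across the two axes).  Outside the keyframed range the nearest keyframe is
used (clamped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon

from .imgio import DetectionSet

#: number of arc-length resample points per polygon
RESAMPLE_POINTS = 100


@dataclass
class PolygonROI:
    """Keyframes: list of (t, z, polygon) with polygon = ordered (y, x) vertices."""

    keyframes: list[tuple[int, int, list[tuple[float, float]]]]
    class_scope: str | None = None

    def __post_init__(self) -> None:
        if not self.keyframes:
            raise ValueError("at least one keyframe is required")
        seen: set[tuple[int, int]] = set()
        for (t, z, poly) in self.keyframes:
            if len(poly) < 3:
                raise ValueError(f"keyframe ({t},{z}): polygon needs >= 3 vertices")
            shp = Polygon([(x, y) for (y, x) in poly])
            if not shp.is_valid or shp.area <= 0:
                raise ValueError(f"keyframe ({t},{z}): polygon is degenerate or self-intersecting")
            if (t, z) in seen:
                raise ValueError(f"duplicate keyframe at (t={t}, z={z})")
            seen.add((t, z))


def _resample_closed(poly: list[tuple[float, float]], k: int = RESAMPLE_POINTS) -> np.ndarray:
    """Resample a closed polygon to k points uniform in arc length.

    Orientation is normalized to counter-clockwise (in maths convention on
    (x, y)); the traversal starts at the vertex whose direction from the
    centroid is nearest the +x axis, giving a canonical correspondence
    between keyframes.
    """
    pts = np.asarray(poly, dtype=float)  # (n, 2) as (y, x)
    # signed area in (x, y): positive = counter-clockwise
    x, y = pts[:, 1], pts[:, 0]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed < 0:
        pts = pts[::-1]
    centroid = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    start = int(np.argmin(np.abs(ang)))
    pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.linspace(0.0, total, k, endpoint=False)
    res = np.empty((k, 2))
    res[:, 0] = np.interp(targets, cum, closed[:, 0])
    res[:, 1] = np.interp(targets, cum, closed[:, 1])
    return res


def _interp_stack(frames: list[tuple[int, np.ndarray]], q: float) -> np.ndarray:
    """Linear interpolation between resampled polygons keyed by one axis."""
    keys = [k for k, _ in frames]
    if q <= keys[0]:
        return frames[0][1]
    if q >= keys[-1]:
        return frames[-1][1]
    j = int(np.searchsorted(keys, q, side="right"))
    k0, p0 = frames[j - 1]
    k1, p1 = frames[j]
    if k1 == k0:
        return p0
    w = (q - k0) / (k1 - k0)
    return (1.0 - w) * p0 + w * p1


def interpolate_roi(roi: PolygonROI, t: float, z: float) -> np.ndarray | None:
    """Return the interpolated polygon at (t, z) as an (K, 2) array of (y, x).

    Bilinear: within each keyframe timepoint, polygons are interpolated
    linearly in z (clamped beyond the keyframed z-range); the per-timepoint
    results are then interpolated linearly in t (clamped likewise).
    """
    by_t: dict[int, list[tuple[int, np.ndarray]]] = {}
    for (kt, kz, poly) in roi.keyframes:
        by_t.setdefault(kt, []).append((kz, _resample_closed(poly)))
    t_frames = []
    for kt in sorted(by_t):
        z_frames = sorted(by_t[kt], key=lambda p: p[0])
        t_frames.append((kt, _interp_stack(z_frames, z)))
    return _interp_stack(t_frames, t)


def polygon_contains(polygon: np.ndarray, y: float, x: float) -> bool:
    """Even-odd point-in-polygon test, boundary inclusive."""
    shp = Polygon([(px, py) for (py, px) in polygon])
    return bool(shp.covers(Point(x, y)))


def filter_detections(d: DetectionSet, roi: PolygonROI) -> DetectionSet:
    """Keep detections whose (y, x) lies inside the ROI at their (t, z)."""
    records = []
    flags = [] if d.border_flags is not None else None
    poly_cache: dict[tuple[int, int], np.ndarray] = {}
    for i, (t, z, y, x, s) in enumerate(d.records):
        key = (t, z)
        if key not in poly_cache:
            poly_cache[key] = interpolate_roi(roi, t, z)
        if polygon_contains(poly_cache[key], y, x):
            records.append((t, z, y, x, s))
            if flags is not None:
                flags.append(d.border_flags[i])
    return DetectionSet(class_id=d.class_id, records=records, border_flags=flags)


def save_roi(roi: PolygonROI, path: str | Path) -> None:
    doc = {
        "class_scope": roi.class_scope,
        "keyframes": [
            {"t": t, "z": z, "polygon": [list(p) for p in poly]}
            for (t, z, poly) in roi.keyframes
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_roi(path: str | Path) -> PolygonROI:
    doc = json.loads(Path(path).read_text())
    return PolygonROI(
        keyframes=[
            (int(k["t"]), int(k["z"]), [tuple(p) for p in k["polygon"]])
            for k in doc["keyframes"]
        ],
        class_scope=doc.get("class_scope"),
    )
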