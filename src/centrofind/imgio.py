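"""Data model and I/O: volumes, annotations, detections, trained models.

Conventions used throughout the package:

* Arrays are indexed ``(t, z, y, x, c)``; coordinates are 0-based voxel
  indices in ``(t, z, y, x)`` order.  Physical units enter only through
  ``VolumeImage.spacing``.
* Detections are written as CSV with columns ``t,z,y,x,score,class``.
* Annotations and ROIs are serialized as JSON (one document per file).
* Models are serialized with joblib, with hyperparameters and the feature
  specification embedded so a model refuses to predict on incompatible
  feature stacks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import joblib
import numpy as np
import pandas as pd
import tifffile

CANONICAL_AXES = "TZYXC"


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """An intensity volume over (t, z, y, x, c) with physical voxel spacing.

    Parameters
    ----------
    data
        5D array indexed ``(t, z, y, x, c)``.
    spacing
        Physical voxel size ``(dz, dy, dx)`` in micrometres.
    axis_meta
        Axis-order tag of the source file (informational).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_meta: str = CANONICAL_AXES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"VolumeImage data must be 5D (t,z,y,x,c), got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all dimensions must be >= 1")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (dz, dy, dx)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[4]


def canonicalize(data: np.ndarray, axis_order: str) -> np.ndarray:
    """Rearrange ``data`` whose axes are named by ``axis_order`` into (t,z,y,x,c).

    Missing axes become singleton dimensions.  Idempotent for already
    canonical input (``axis_order="TZYXC"``).
    """
    axis_order = axis_order.upper()
    if len(axis_order) != data.ndim:
        raise ValueError(
            f"axis_order {axis_order!r} names {len(axis_order)} axes but data has {data.ndim}"
        )
    if len(set(axis_order)) != len(axis_order):
        raise ValueError(f"duplicate axis in {axis_order!r}")
    unknown = set(axis_order) - set(CANONICAL_AXES)
    if unknown:
        raise ValueError(f"unknown axes {sorted(unknown)}; expected letters from {CANONICAL_AXES}")
    # insert singletons for missing axes, then transpose into canonical order
    full = data
    order = axis_order
    for ax in CANONICAL_AXES:
        if ax not in order:
            full = full[..., np.newaxis]
            order = order + ax
    perm = [order.index(ax) for ax in CANONICAL_AXES]
    return np.transpose(full, perm)


def load_volume(path: str | Path, axis_order: str, spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> VolumeImage:
    """Read a (multipage) TIFF and return it in canonical (t,z,y,x,c) order.

    ``axis_order`` names each axis of the file from {T,Z,Y,X,C}, e.g. "ZYX"
    for a plain z-stack or "ZCYX" for an interleaved two-channel stack.
    """
    path = Path(path)
    try:
        raw = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    data = canonicalize(np.asarray(raw), axis_order)
    return VolumeImage(data=data, spacing=tuple(spacing), axis_meta=axis_order.upper())


def save_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write the canonical 5D array to a TIFF; reload with axis_order='TZYXC'."""
    tifffile.imwrite(Path(path), vol.data)


def normalize_volume(vol: VolumeImage, p_low: float = 0.1, p_high: float = 99.9) -> VolumeImage:
    """Rescale each (t, c) sub-volume to [0, 1] by percentile clipping.

    Percentile scaling (default 0.1/99.9) is robust to hot pixels and puts
    images of different brightness on a common footing before feature
    computation.  Constant sub-volumes map to zero.
    """
    out = np.empty_like(vol.data, dtype=np.float32)
    for t in range(vol.data.shape[0]):
        for c in range(vol.data.shape[4]):
            sub = vol.data[t, :, :, :, c].astype(np.float32)
            lo, hi = np.percentile(sub, [p_low, p_high])
            if hi <= lo:
                out[t, :, :, :, c] = 0.0
            else:
                out[t, :, :, :, c] = np.clip((sub - lo) / (hi - lo), 0.0, 1.0)
    return VolumeImage(data=out, spacing=vol.spacing, axis_meta=vol.axis_meta)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class TrainingAnnotation:
    """Sparse training labels on one 2D plane: a rectangle plus centre clicks.

    ``region`` is ``(y0, x0, y1, x1)`` with exclusive upper bounds; ``points``
    is a list of ``(y, x)`` cell-centre clicks inside the region.  An empty
    point list is valid and marks a background-only region.
    """

    class_id: str
    t: int
    z: int
    region: tuple[int, int, int, int]
    points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        y0, x0, y1, x1 = self.region
        if y1 <= y0 or x1 <= x0:
            raise ValueError(f"region {self.region} has non-positive area")
        for (py, px) in self.points:
            if not (y0 <= py < y1 and x0 <= px < x1):
                raise ValueError(f"point ({py}, {px}) outside region {self.region}")

    def validate_against(self, vol: VolumeImage) -> None:
        _, nz, ny, nx, _ = vol.shape
        y0, x0, y1, x1 = self.region
        if not (0 <= self.t < vol.shape[0]):
            raise ValueError(f"annotation timepoint {self.t} out of range")
        if not (0 <= self.z < nz):
            raise ValueError(f"annotation plane {self.z} out of range")
        if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
            raise ValueError(f"region {self.region} outside plane bounds ({ny}, {nx})")


def save_annotations(annotations: Sequence[TrainingAnnotation], path: str | Path) -> None:
    docs = [
        {
            "class_id": a.class_id,
            "t": a.t,
            "z": a.z,
            "region": list(a.region),
            "points": [list(p) for p in a.points],
        }
        for a in annotations
    ]
    Path(path).write_text(json.dumps(docs, indent=1))


def load_annotations(path: str | Path) -> list[TrainingAnnotation]:
    docs = json.loads(Path(path).read_text())
    return [
        TrainingAnnotation(
            class_id=d["class_id"],
            t=int(d["t"]),
            z=int(d["z"]),
            region=tuple(d["region"]),
            points=[tuple(p) for p in d["points"]],
        )
        for d in docs
    ]


# ---------------------------------------------------------------------------
# Detections
# ---------------------------------------------------------------------------

@dataclass
class DetectionSet:
    """Discrete cell-centre detections: records of (t, z, y, x, score).

    Coordinates are 0-based voxel indices.  ``border_flags`` marks
    detections lying within one object radius of the volume border (kept,
    but flagged, since blob responses there are less reliable).
    """

    class_id: str
    records: list[tuple[int, int, int, int, float]] = field(default_factory=list)
    coordinate_convention: str = "voxel-index-0-based"
    border_flags: list[bool] | None = None

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = tuple(rec[:4])
            if key in seen:
                raise ValueError(f"duplicate detection at (t,z,y,x)={key}")
            seen.add(key)
        if self.border_flags is not None and len(self.border_flags) != len(self.records):
            raise ValueError("border_flags length mismatch")

    def __len__(self) -> int:
        return len(self.records)

    def coordinates(self) -> np.ndarray:
        """Return an (n, 4) float array of (t, z, y, x)."""
        if not self.records:
            return np.zeros((0, 4))
        return np.asarray([r[:4] for r in self.records], dtype=float)

    def sorted_records(self) -> list[tuple[int, int, int, int, float]]:
        return sorted(self.records, key=lambda r: (r[0], -r[4], r[1], r[2], r[3]))


def save_detections(d: DetectionSet, path: str | Path) -> None:
    """Write detections as CSV (t,z,y,x,score,class), sorted by t then score desc."""
    rows = d.sorted_records()
    df = pd.DataFrame(rows, columns=["t", "z", "y", "x", "score"])
    df["class"] = d.class_id
    df.to_csv(Path(path), index=False)


def load_detections(path: str | Path) -> DetectionSet:
    df = pd.read_csv(Path(path))
    class_id = str(df["class"].iloc[0]) if len(df) else "cell"
    records = [
        (int(r.t), int(r.z), int(r.y), int(r.x), float(r.score))
        for r in df.itertuples(index=False)
    ]
    return DetectionSet(class_id=class_id, records=records)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


@dataclass
class ForestModel:
    """A trained proximity-map regression ensemble plus its provenance.

    ``forests`` maps class id -> fitted sklearn regressor.  ``feature_spec``
    is the ordered filter-bank description the model was trained with; a
    model only predicts for feature stacks matching it.
    """

    forests: dict[str, Any]
    hyperparams: dict[str, Any]
    feature_spec: list[tuple[str, float, int]]
    kernel_sigma: tuple[float, float]
    classes: list[str]
    seed: int
    n_channels: int

    @property
    def n_features(self) -> int:
        return len(self.feature_spec)

    def check_features(self, n_features: int) -> None:
        if n_features != self.n_features:
            raise ValueError(
                f"feature count mismatch: model expects {self.n_features}, got {n_features}"
            )


def save_model(m: ForestModel, path: str | Path) -> None:
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "model": m,
    }
    joblib.dump(payload, Path(path))


def load_model(path: str | Path) -> ForestModel:
    payload = joblib.load(Path(path))
    if not isinstance(payload, dict) or payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unrecognized model file format in {path}")
    m: ForestModel = payload["model"]
    # consistency audit: serialized ensembles must match the declared spec
    for cls, rf in m.forests.items():
        n_in = getattr(rf, "n_features_in_", None)
        if n_in is not None and n_in != m.n_features:
            raise ValueError(
                f"model for class {cls!r} was fit with {n_in} features but "
                f"feature_spec declares {m.n_features}"
            )
    return m


def _asdict_annotation(a: TrainingAnnotation) -> dict:
    return dataclasses.asdict(a)
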