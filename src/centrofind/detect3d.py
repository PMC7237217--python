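"""3D centre detection: determinant-of-Hessian enhancement + maxima finding.

The stacked 2D proximity maps form a 3D volume whose local structure around
a cell centre is a smooth bright blob.  A determinant-of-Hessian (DoH) blob
filter tuned to the expected object radii h = (hx, hy, hz) both smooths the
signal and enhances objects of that size; discrete centres are then the
thresholded strict maxima of the response within an ellipsoidal
neighbourhood of radii h.

Conventions:
* Gaussian derivative scales are (hx/2, hy/2, hz/2) voxels — half the
  radius, following the rule of thumb that the detection scale should sit
  slightly below the object radius.  Anisotropic z-sampling is absorbed by
  choosing hz in voxels.
* The response is sign-flipped so bright blobs are positive: for a bright
  blob the Hessian is negative definite, so det(-H) = -det(H) > 0.
* The maxima threshold is applied after dividing by the per-timepoint
  maximum response, so it is dimensionless and transfers between images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgio import DetectionSet, ForestModel, VolumeImage
from .proximity_model import ProximityVolume, predict_volume

_BOUNDARY = "reflect"

DEFAULT_THRESHOLD = 0.1


@dataclass(frozen=True)
class ObjectSize:
    """Expected object radii in voxels, h = (hx, hy, hz); hx = hy for
    objects that are spherical in-plane."""

    hx: float
    hy: float
    hz: float

    def __post_init__(self) -> None:
        if min(self.hx, self.hy, self.hz) <= 0:
            raise ValueError("object radii must be strictly positive")

    @classmethod
    def isotropic(cls, h: float) -> "ObjectSize":
        return cls(h, h, h)

    @property
    def zyx(self) -> tuple[float, float, float]:
        return (self.hz, self.hy, self.hx)


def _doh_response_3d(volume: np.ndarray, sigma_zyx: tuple[float, float, float]) -> np.ndarray:
    """det(-Hessian) of the Gaussian-smoothed volume, positive at bright blobs."""
    orders = {
        "zz": (2, 0, 0), "yy": (0, 2, 0), "xx": (0, 0, 2),
        "zy": (1, 1, 0), "zx": (1, 0, 1), "yx": (0, 1, 1),
    }
    h = {
        k: ndimage.gaussian_filter(volume, sigma_zyx, order=o, mode=_BOUNDARY)
        for k, o in orders.items()
    }
    det = (
        h["zz"] * (h["yy"] * h["xx"] - h["yx"] ** 2)
        - h["zy"] * (h["zy"] * h["xx"] - h["yx"] * h["zx"])
        + h["zx"] * (h["zy"] * h["yx"] - h["yy"] * h["zx"])
    )
    return -det


def hessian_enhance(pv: ProximityVolume | np.ndarray, size: ObjectSize) -> np.ndarray:
    """Apply the size-tuned DoH blob filter per timepoint.

    Returns an array shaped like the input values (t, z, y, x); bright-blob
    responses are positive, background is ~0.
    """
    values = pv.values if isinstance(pv, ProximityVolume) else np.asarray(pv)
    if values.ndim == 3:
        values = values[np.newaxis]
    if values.ndim != 4:
        raise ValueError("expected (t, z, y, x) or (z, y, x) input")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in proximity volume")
    nz, ny, nx = values.shape[1:]
    if size.hz > nz or size.hy > ny or size.hx > nx:
        raise ValueError(f"object size {size} exceeds volume extent {(nz, ny, nx)}")
    sigma = tuple(0.5 * s for s in size.zyx)
    out = np.empty_like(values, dtype=np.float64)
    for t in range(values.shape[0]):
        out[t] = _doh_response_3d(values[t].astype(np.float64), sigma)
    return out


def _ellipsoid_footprint(size: ObjectSize) -> np.ndarray:
    rz, ry, rx = (max(1, int(round(s))) for s in size.zyx)
    zz, yy, xx = np.mgrid[-rz:rz + 1, -ry:ry + 1, -rx:rx + 1].astype(float)
    return (zz / rz) ** 2 + (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0


def find_maxima(
    enhanced: np.ndarray,
    size: ObjectSize,
    threshold: float = DEFAULT_THRESHOLD,
    class_id: str = "cell",
) -> DetectionSet:
    """Thresholded strict 3D maxima of the enhanced response.

    A voxel is a detection if its response equals the maximum over an
    ellipsoidal neighbourhood of radii h and its normalized response
    (response / per-timepoint max) exceeds ``threshold``.  A plateau of
    equal values yields one detection at its centroid (rounded to the
    nearest voxel, ties toward the lower index).  Detections within one
    radius of the volume border are kept but flagged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    enhanced = np.asarray(enhanced)
    if enhanced.ndim == 3:
        enhanced = enhanced[np.newaxis]
    footprint = _ellipsoid_footprint(size)
    records: list[tuple[int, int, int, int, float]] = []
    flags: list[bool] = []
    nz, ny, nx = enhanced.shape[1:]
    for t in range(enhanced.shape[0]):
        resp = enhanced[t]
        peak = float(resp.max())
        if peak <= 0:
            continue
        norm = resp / peak
        is_max = resp >= ndimage.maximum_filter(resp, footprint=footprint, mode=_BOUNDARY)
        candidates = is_max & (norm > threshold)
        if not candidates.any():
            continue
        labels, n_lab = ndimage.label(candidates)
        for centroid in ndimage.center_of_mass(candidates, labels, range(1, n_lab + 1)):
            # round half toward the lower index for a deterministic plateau centre
            z, y, x = (int(np.floor(c + 0.5 - 1e-9)) for c in centroid)
            score = float(norm[z, y, x])
            if score <= threshold:
                continue
            records.append((t, z, y, x, score))
            near_border = (
                z < size.hz or z >= nz - size.hz
                or y < size.hy or y >= ny - size.hy
                or x < size.hx or x >= nx - size.hx
            )
            flags.append(bool(near_border))
    return DetectionSet(class_id=class_id, records=records, border_flags=flags)


def detect(
    model: ForestModel,
    vol: VolumeImage,
    t: int,
    size: ObjectSize,
    threshold: float = DEFAULT_THRESHOLD,
    roi=None,
    class_id: str | None = None,
) -> DetectionSet:
    """Full detection pipeline for one timepoint.

    predict_volume -> hessian_enhance -> find_maxima, then (optionally)
    keep only detections inside the interpolated ROI at their (t, z).
    The ``t`` of each record is the queried timepoint.
    """
    pv = predict_volume(model, vol, t, class_id=class_id)
    enhanced = hessian_enhance(pv, size)
    det = find_maxima(enhanced, size, threshold, class_id=pv.class_id)
    # records carry the within-prediction index t=0; restamp with the real t
    det = DetectionSet(
        class_id=det.class_id,
        records=[(t, z, y, x, s) for (_, z, y, x, s) in det.records],
        border_flags=det.border_flags,
    )
    if roi is not None:
        from .roi import filter_detections

        det = filter_detections(det, roi)
    return det
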