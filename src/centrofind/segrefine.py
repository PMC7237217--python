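"""Segmentation refinement: seeded spheres -> active contour -> watershed.

Detected centres can be promoted to a crude instance segmentation by
stamping an ellipsoid of the expected object radii around each centre
(overlaps split by nearest centre in radius-scaled distance).  The crude
mask is then evolved for a few iterations of a morphological Chan-Vese
active contour on the intensity image, and re-partitioned into instances by
marker-based watershed from the detected centres, so the final label count
always equals the detection count.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.segmentation import morphological_chan_vese, watershed

from .detect3d import ObjectSize
from .imgio import DetectionSet, VolumeImage


def _reset_curvature_cycle() -> None:
    """Pin the morphological curvature operator to a fixed starting parity.

    skimage's morphsnakes alternates its SIoIS / ISoSI smoothing operators
    through a module-global cycle that persists across calls, which makes
    consecutive identical calls return (slightly) different surfaces.
    Resetting the cycle keeps ``refine`` deterministic for fixed inputs.
    """
    try:
        import skimage.segmentation.morphsnakes as _ms

        _ms._curvop = _ms._fcycle(
            [lambda u: _ms.sup_inf(_ms.inf_sup(u)), lambda u: _ms.inf_sup(_ms.sup_inf(u))]
        )
    except (ImportError, AttributeError):  # internals moved; accept parity drift
        pass


def seeds_to_spheres(d: DetectionSet, size: ObjectSize, shape: tuple[int, int, int]) -> np.ndarray:
    """Stamp one ellipsoid of radii h per detection into a label volume.

    Labels are 1..n in record order; voxels claimed by several ellipsoids go
    to the centre nearest in radius-normalized distance.
    """
    nz, ny, nx = shape
    labels = np.zeros(shape, dtype=np.uint16)
    best = np.full(shape, np.inf)
    rz, ry, rx = size.zyx
    for i, (t, z, y, x, s) in enumerate(d.records, start=1):
        z0, z1 = max(0, int(z - rz) - 1), min(nz, int(z + rz) + 2)
        y0, y1 = max(0, int(y - ry) - 1), min(ny, int(y + ry) + 2)
        x0, x1 = max(0, int(x - rx) - 1), min(nx, int(x + rx) + 2)
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1].astype(float)
        q = ((zz - z) / rz) ** 2 + ((yy - y) / ry) ** 2 + ((xx - x) / rx) ** 2
        sub_best = best[z0:z1, y0:y1, x0:x1]
        sub_lab = labels[z0:z1, y0:y1, x0:x1]
        claim = (q <= 1.0) & (q < sub_best)
        sub_best[claim] = q[claim]
        sub_lab[claim] = i
    return labels


def refine(
    labels: np.ndarray,
    image: VolumeImage | np.ndarray,
    iterations: int = 4,
    centres: DetectionSet | None = None,
    size: ObjectSize | None = None,
) -> np.ndarray:
    """Refine a crude label volume against the intensity image.

    The binary union of ``labels`` is evolved ``iterations`` steps (sensible
    range 2-6) of a morphological Chan-Vese active contour (one curvature
    smoothing pass per step), then re-split into instances by watershed on
    the smoothed inverted intensity with the detection centres as markers.
    """
    if not np.any(labels):
        raise ValueError("empty label volume")
    if isinstance(image, VolumeImage):
        img = image.data[0, :, :, :, 0].astype(float)
    else:
        img = np.asarray(image, dtype=float)
        if img.ndim != 3:
            raise ValueError("image must be a 3D (z, y, x) array or VolumeImage")

    init = labels > 0
    _reset_curvature_cycle()
    evolved = morphological_chan_vese(
        img, num_iter=int(iterations), init_level_set=init, smoothing=1
    ).astype(bool)

    if centres is None or len(centres) == 0:
        out, _ = ndimage.label(evolved)
        return out.astype(np.uint16)

    sigma = tuple(0.5 * s for s in size.zyx) if size is not None else 1.0
    elevation = -ndimage.gaussian_filter(img, sigma, mode="reflect")
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (t, z, y, x, s) in enumerate(centres.records, start=1):
        markers[int(z), int(y), int(x)] = i
    # every marker voxel stays in the mask so each detection keeps a label
    mask = evolved | (markers > 0)
    return watershed(elevation, markers=markers, mask=mask).astype(np.uint16)
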