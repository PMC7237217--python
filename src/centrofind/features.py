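"""Multiscale 2D filter-bank features for per-pixel regression.

Each pixel of a 2D plane is described by a vector of Gaussian-derivative
responses: Gaussian smooth, Gaussian gradient magnitude, Laplacian of
Gaussian, and the minimum and maximum eigenvalues of the Hessian (curvature)
matrix, each at several scales (default sigma = 1, 2, 4, 8, 16 px), plus
optionally the raw intensity.  Features are computed in 2D, per plane and
per channel; 3D structure enters the pipeline only later, through the
determinant-of-Hessian blob step.  All convolutions use reflect padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

DEFAULT_SCALES: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)

FILTER_NAMES = (
    "gaussian",
    "gradient_magnitude",
    "laplacian_of_gaussian",
    "hessian_eig_min",
    "hessian_eig_max",
)

_BOUNDARY = "reflect"


@dataclass
class FeatureStack:
    """Feature values for one 2D plane: array (y, x, f) plus the ordered spec.

    ``spec`` lists ``(filter_name, scale, channel)`` in the exact order of
    the feature axis; the order is deterministic, so training and prediction
    always agree on feature identity.
    """

    data: np.ndarray
    spec: list[tuple[str, float, int]]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("FeatureStack data must be (y, x, f)")
        if self.data.shape[2] != len(self.spec):
            raise ValueError("feature axis length does not match spec")


def build_feature_spec(
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_channels: int = 1,
    include_raw: bool = True,
) -> list[tuple[str, float, int]]:
    """The deterministic feature ordering: channel-major, then scale, then filter."""
    spec: list[tuple[str, float, int]] = []
    for c in range(n_channels):
        if include_raw:
            spec.append(("raw", 0.0, c))
        for s in scales:
            for name in FILTER_NAMES:
                spec.append((name, float(s), c))
    return spec


def _hessian_eigenvalues_2d(plane: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Signed eigenvalues of the 2x2 Hessian of the Gaussian-smoothed plane."""
    hyy = ndimage.gaussian_filter(plane, sigma, order=(2, 0), mode=_BOUNDARY)
    hxx = ndimage.gaussian_filter(plane, sigma, order=(0, 2), mode=_BOUNDARY)
    hyx = ndimage.gaussian_filter(plane, sigma, order=(1, 1), mode=_BOUNDARY)
    # closed-form eigenvalues of [[hyy, hyx], [hyx, hxx]]
    mean = 0.5 * (hyy + hxx)
    root = np.sqrt(0.25 * (hyy - hxx) ** 2 + hyx**2)
    return mean - root, mean + root


def _single_channel_features(plane: np.ndarray, scales: tuple[float, ...]) -> list[np.ndarray]:
    maps: list[np.ndarray] = []
    for s in scales:
        maps.append(ndimage.gaussian_filter(plane, s, mode=_BOUNDARY))
        maps.append(ndimage.gaussian_gradient_magnitude(plane, s, mode=_BOUNDARY))
        maps.append(ndimage.gaussian_laplace(plane, s, mode=_BOUNDARY))
        lo, hi = _hessian_eigenvalues_2d(plane, s)
        maps.append(lo)
        maps.append(hi)
    return maps


def compute_filter_bank(
    plane: np.ndarray,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    include_raw: bool = True,
) -> FeatureStack:
    """Compute the multiscale filter bank for one plane.

    Parameters
    ----------
    plane
        2D array (y, x) or 3D array (y, x, c) of finite intensities.
    scales
        Strictly positive Gaussian scales (px).
    include_raw
        Whether to include the raw intensity of each channel as a feature.

    Returns
    -------
    FeatureStack
        ``data`` has shape (y, x, f) with
        f = n_channels * (len(scales) * 5 + include_raw).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim == 2:
        plane = plane[:, :, np.newaxis]
    if plane.ndim != 3:
        raise ValueError("plane must be 2D (y, x) or 3D (y, x, c)")
    if plane.shape[0] == 0 or plane.shape[1] == 0:
        raise ValueError("empty plane")
    if not np.all(np.isfinite(plane)):
        raise ValueError("plane contains non-finite values")
    scales = tuple(float(s) for s in scales)
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales must be non-empty and strictly positive")

    n_channels = plane.shape[2]
    maps: list[np.ndarray] = []
    for c in range(n_channels):
        ch = plane[:, :, c]
        if include_raw:
            maps.append(ch)
        maps.extend(_single_channel_features(ch, scales))
    data = np.stack(maps, axis=-1)
    spec = build_feature_spec(scales, n_channels, include_raw)
    return FeatureStack(data=data, spec=spec)
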