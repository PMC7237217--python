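"""Synthetic 3D(+T) phantoms of clustered spherical cells with known truth.

The generator emulates a neutral-challenge benchmark of densely clustered
nuclei: solid spheres with Gaussian-softened edges, a configurable fraction
placed touching an existing cell ("clustering"), rendered at a controlled
signal-to-noise ratio.  SNR here is (foreground amplitude) / (additive
Gaussian noise sd).  Ground-truth centre coordinates are returned exactly,
and every volume is bit-reproducible from its seed.

A second entry point renders time series with scheduled cell divisions:
a dividing cell transiently shows an elongated, spindle-like intensity
figure for two frames, after which a small daughter cell appears adjacent
and persists.  These series exercise the tracking / division-signal
pipeline end to end against known division times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imgio import TrainingAnnotation, VolumeImage

#: rendered foreground amplitude (arbitrary units) and background offset
_AMPLITUDE = 1.0
_BACKGROUND = 0.2

_MAX_TRIES = 500


@dataclass
class PhantomSpec:
    """Parameters of one phantom rendering.

    Defaults describe the standard validation condition: 30 heavily
    clustered (75%) cells of radius ~8 voxels in a 40x128x128 volume at low
    SNR (5).
    """

    shape: tuple[int, int, int] = (40, 128, 128)
    n_cells: int = 30
    radius: float = 8.0
    radius_jitter: float = 0.1
    clustering: float = 0.75
    snr: float = 5.0
    n_timepoints: int = 1
    division_schedule: list[tuple[int, int]] | None = None
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.clustering <= 1.0):
            raise ValueError("clustering must be in [0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.radius <= 0 or self.n_cells < 0:
            raise ValueError("invalid radius or cell count")
        if self.n_cells > 0 and 2 * self.radius >= min(self.shape):
            raise ValueError("cells do not fit inside the volume")
        if self.n_channels not in (1, 2):
            raise ValueError("n_channels must be 1 or 2")


def _place_cells(
    spec: PhantomSpec, rng: np.random.Generator, margin_factor: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample non-overlapping centres; a `clustering` fraction touch a neighbour.

    ``margin_factor`` scales the in-plane (y, x) border margin in units of
    the cell radius; the z-margin stays one radius so shallow stacks remain
    usable.
    """
    nz, ny, nx = spec.shape
    centres: list[np.ndarray] = []
    radii: list[float] = []

    def sample_radius() -> float:
        return spec.radius * (1.0 + spec.radius_jitter * rng.uniform(-1.0, 1.0))

    def in_bounds(c: np.ndarray, r: float) -> bool:
        m = margin_factor * r
        return bool(
            r <= c[0] <= nz - 1 - r and m <= c[1] <= ny - 1 - m and m <= c[2] <= nx - 1 - m
        )

    def overlaps(c: np.ndarray, r: float, slack: float = 0.98) -> bool:
        for cj, rj in zip(centres, radii):
            if np.linalg.norm(c - cj) < slack * (r + rj):
                return True
        return False

    n_clustered = int(round(spec.clustering * spec.n_cells))
    n_free = spec.n_cells - n_clustered
    if spec.n_cells > 0 and n_free == 0:
        n_free, n_clustered = 1, spec.n_cells - 1  # need an anchor to cluster onto

    for _ in range(n_free):
        r = sample_radius()
        m = margin_factor * r
        for _ in range(_MAX_TRIES):
            c = rng.uniform([r, m, m], [nz - 1 - r, ny - 1 - m, nx - 1 - m])
            if not overlaps(c, r):
                centres.append(c)
                radii.append(r)
                break
        else:
            raise RuntimeError("could not place non-overlapping cells; reduce n_cells")

    for _ in range(n_clustered):
        r = sample_radius()
        placed = False
        for _ in range(_MAX_TRIES):
            j = int(rng.integers(len(centres)))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            c = centres[j] + direction * (r + radii[j]) * 1.02
            if in_bounds(c, r) and not overlaps(c, r):
                centres.append(c)
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place clustered cell; reduce n_cells or clustering")

    return np.asarray(centres).reshape(-1, 3), np.asarray(radii)


def _render_sphere(canvas: np.ndarray, centre: np.ndarray, r: float, value: float = _AMPLITUDE) -> None:
    nz, ny, nx = canvas.shape
    z0, z1 = max(0, int(centre[0] - r) - 1), min(nz, int(centre[0] + r) + 2)
    y0, y1 = max(0, int(centre[1] - r) - 1), min(ny, int(centre[1] + r) + 2)
    x0, x1 = max(0, int(centre[2] - r) - 1), min(nx, int(centre[2] + r) + 2)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1].astype(float)
    d2 = (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
    mask = d2 <= r * r
    region = canvas[z0:z1, y0:y1, x0:x1]
    region[mask] = np.maximum(region[mask], value)


def _render_ellipsoid(
    canvas: np.ndarray, centre: np.ndarray, semi_axes_world: np.ndarray, value: float = _AMPLITUDE
) -> None:
    """Axis-aligned-bounding-box render of an ellipsoid given 3 orthogonal
    semi-axis vectors (rows of ``semi_axes_world``, in zyx)."""
    lengths = np.linalg.norm(semi_axes_world, axis=1)
    rmax = float(lengths.max())
    nz, ny, nx = canvas.shape
    z0, z1 = max(0, int(centre[0] - rmax) - 1), min(nz, int(centre[0] + rmax) + 2)
    y0, y1 = max(0, int(centre[1] - rmax) - 1), min(ny, int(centre[1] + rmax) + 2)
    x0, x1 = max(0, int(centre[2] - rmax) - 1), min(nx, int(centre[2] + rmax) + 2)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1].astype(float)
    rel = np.stack([zz - centre[0], yy - centre[1], xx - centre[2]], axis=-1)
    axes_unit = semi_axes_world / lengths[:, None]
    proj = rel @ axes_unit.T  # coordinates in the ellipsoid frame
    q = (proj / lengths) ** 2
    mask = q.sum(axis=-1) <= 1.0
    region = canvas[z0:z1, y0:y1, x0:x1]
    region[mask] = np.maximum(region[mask], value)


def _finish_frame(fg_channels: list[np.ndarray], spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Blur edges, add background offset and noise; returns (z, y, x, c)."""
    sigma_edge = spec.radius / 4.0
    noise_sd = _AMPLITUDE / spec.snr
    out = np.empty(spec.shape + (len(fg_channels),), dtype=np.float32)
    for c, fg in enumerate(fg_channels):
        soft = ndimage.gaussian_filter(fg, sigma_edge, mode="reflect")
        out[..., c] = _BACKGROUND + soft + rng.normal(0.0, noise_sd, size=spec.shape)
    return out


def _shell_channel(centres: np.ndarray, radii: np.ndarray, shape) -> np.ndarray:
    """Cytoplasmic-shell channel: spherical shells around each centre."""
    outer = np.zeros(shape, dtype=np.float32)
    inner = np.zeros(shape, dtype=np.float32)
    for c, r in zip(centres, radii):
        _render_sphere(outer, c, 1.2 * r)
        _render_sphere(inner, c, 0.8 * r)
    return np.clip(outer - inner, 0.0, _AMPLITUDE)


def generate(spec: PhantomSpec) -> tuple[VolumeImage, list[np.ndarray]]:
    """Render a phantom; returns (volume, per-timepoint (n, 3) centre arrays).

    Centres are exact (z, y, x) float coordinates.  Without a division
    schedule, timepoints share the same cells but receive independent noise.
    """
    rng = np.random.default_rng(spec.seed)
    centres, radii = _place_cells(spec, rng)
    fg = np.zeros(spec.shape, dtype=np.float32)
    for c, r in zip(centres, radii):
        _render_sphere(fg, c, r)
    channels = [fg]
    if spec.n_channels == 2:
        channels.append(_shell_channel(centres, radii, spec.shape))
    frames = [_finish_frame(channels, spec, rng) for _ in range(spec.n_timepoints)]
    data = np.stack(frames, axis=0)  # (t, z, y, x, c)
    vol = VolumeImage(data=data, spacing=(1.0, 1.0, 1.0), axis_meta="TZYXC")
    truth = [centres.copy() for _ in range(spec.n_timepoints)]
    return vol, truth


#: frames a spindle figure persists at each division
SPINDLE_FRAMES = 2
#: daughter cell size and brightness relative to the mother
DAUGHTER_RADIUS_FRACTION = 0.45
DAUGHTER_AMPLITUDE = 0.7
#: voxels/frame a daughter drifts away from the mother (displacement by
#: subsequent divisions, as in a neuroblast niche)
DAUGHTER_DRIFT = 0.25


def generate_division_series(spec: PhantomSpec) -> tuple[VolumeImage, list[np.ndarray], list[tuple[int, int]]]:
    """Render a 4D series with scheduled divisions.

    ``spec.division_schedule`` lists ``(cell_index, frame)`` events.  At each
    event the mother shows an elongated spindle-like figure for
    ``SPINDLE_FRAMES`` frames, then a small daughter appears adjacent and
    persists.  Returns (volume, per-frame mother centres, events).
    """
    schedule = spec.division_schedule or []
    for (cell, frame) in schedule:
        if not (0 <= frame < spec.n_timepoints):
            raise ValueError(f"division frame {frame} outside [0, {spec.n_timepoints})")
        if not (0 <= cell < spec.n_cells):
            raise ValueError(f"cell index {cell} out of range")
    by_cell: dict[int, list[int]] = {}
    for (cell, frame) in sorted(schedule, key=lambda e: e[1]):
        times = by_cell.setdefault(cell, [])
        if times and frame - times[-1] < SPINDLE_FRAMES + 1:
            raise ValueError(f"conflicting divisions for cell {cell} at frames {times[-1]}, {frame}")
        times.append(frame)

    rng = np.random.default_rng(spec.seed)
    # mothers sit clear of the image border (a niche fits in the field of
    # view); border-clipped cells would distort their apparent shape
    centres, radii = _place_cells(spec, rng, margin_factor=1.6)

    # pre-draw per-event geometry so rendering order cannot perturb the RNG
    spindle_axis: dict[tuple[int, int], np.ndarray] = {}
    daughter_offset: dict[tuple[int, int], np.ndarray] = {}
    for (cell, frame) in sorted(schedule, key=lambda e: (e[1], e[0])):
        axis = rng.normal(size=3)
        axis[0] *= 0.25  # divisions are roughly in-plane
        axis /= np.linalg.norm(axis)
        spindle_axis[(cell, frame)] = axis
        daughter_offset[(cell, frame)] = axis * radii[cell] * 1.5

    frames_out = []
    for t in range(spec.n_timepoints):
        fg = np.zeros(spec.shape, dtype=np.float32)
        for i, (c, r) in enumerate(zip(centres, radii)):
            active = [f for f in by_cell.get(i, []) if f <= t < f + SPINDLE_FRAMES]
            if active:
                f = active[0]
                axis = spindle_axis[(i, f)]
                # orthonormal frame around the spindle axis
                helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
                b = np.cross(axis, helper)
                b /= np.linalg.norm(b)
                cvec = np.cross(axis, b)
                semi = np.vstack([axis * 1.6 * r, b * 0.7 * r, cvec * 0.7 * r])
                _render_ellipsoid(fg, c, semi)
            else:
                _render_sphere(fg, c, r)
            # daughters from past divisions persist and drift away from the
            # mother (displaced by subsequent divisions)
            for f in by_cell.get(i, []):
                if t >= f + SPINDLE_FRAMES:
                    age = t - (f + SPINDLE_FRAMES)
                    offset = daughter_offset[(i, f)]
                    drift = offset / np.linalg.norm(offset) * DAUGHTER_DRIFT * age
                    dc = np.clip(
                        c + offset + drift,
                        [0, 0, 0],
                        np.asarray(spec.shape) - 1.0,
                    )
                    _render_sphere(fg, dc, DAUGHTER_RADIUS_FRACTION * r, DAUGHTER_AMPLITUDE)
        channels = [fg]
        if spec.n_channels == 2:
            channels.append(_shell_channel(centres, radii, spec.shape))
        frames_out.append(_finish_frame(channels, spec, rng))

    data = np.stack(frames_out, axis=0)
    vol = VolumeImage(data=data, spacing=(1.0, 1.0, 1.0), axis_meta="TZYXC")
    truth = [centres.copy() for _ in range(spec.n_timepoints)]
    return vol, truth, sorted(schedule, key=lambda e: (e[0], e[1]))


def annotations_from_truth(
    truth: np.ndarray,
    shape: tuple[int, int, int],
    planes: list[int] | None = None,
    t: int = 0,
    class_id: str = "cell",
    z_tol: float = 2.0,
    n_planes: int = 10,
) -> list[TrainingAnnotation]:
    """Turn ground-truth 3D centres into point-and-click 2D annotations.

    Emulates a user clicking cell centres on a few z-planes: each chosen
    plane becomes a whole-plane annotation whose points are the (y, x)
    positions of cells whose centre lies within ``z_tol`` of the plane.
    Planes default to those of the first cells (where clicks are densest)
    plus, when available, one cell-free plane as pure background.
    """
    truth = np.asarray(truth, dtype=float).reshape(-1, 3)
    nz, ny, nx = shape
    if planes is None:
        cell_planes = sorted({int(round(z)) for z in truth[:, 0]})
        planes = cell_planes[:n_planes]
        occupied = {int(round(z)) for z in truth[:, 0]}
        free = [z for z in range(nz) if min((abs(z - o) for o in occupied), default=nz) > z_tol + 1]
        if free:
            planes = planes + [free[len(free) // 2]]
    anns = []
    for z in planes:
        pts = [
            (float(c[1]), float(c[2]))
            for c in truth
            if abs(c[0] - z) <= z_tol and 0 <= c[1] < ny and 0 <= c[2] < nx
        ]
        anns.append(
            TrainingAnnotation(class_id=class_id, t=t, z=int(z), region=(0, 0, ny, nx), points=pts)
        )
    return anns
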