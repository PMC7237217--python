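"""Tracking and division-rate analysis.

Detections are linked frame to frame by optimal one-to-one assignment
(minimum total displacement among pairs within a gating radius); unmatched
detections seed new tracks, and tracks may bridge a bounded number of
missing frames using linear position extrapolation.

For division analysis, the proximity map of a "dividing" cell class is
sampled along each track (max within a 3x3x3 voxel neighbourhood of the
tracked position).  Slow spatial background differences are removed by
subtracting a centered moving average (default 21 frames); divisions are
then the prominent local maxima of the residual signal.  Inter-event
intervals, converted by the frame interval, are the cell-cycle lengths;
cells with fewer than two events are excluded from cycle statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks

from .imgio import DetectionSet
from .proximity_model import ProximityVolume

_BIG = 1e9

#: moving-average window (frames) for background subtraction
DEFAULT_WINDOW = 21
#: event threshold in units of the signal's median absolute deviation
EVENT_MAD_FACTOR = 3.0
#: absolute event-height floor on the [0, 1] proximity scale; a division
#: must produce an appreciable dividing-class score, so tracks whose signal
#: never leaves the noise floor yield no events
EVENT_MIN_HEIGHT = 0.1


@dataclass
class Track:
    """One linked cell trajectory: points (t, z, y, x), strictly increasing t."""

    cell_id: int
    points: list[tuple[int, float, float, float]]
    gaps: int = 0

    def __post_init__(self) -> None:
        ts = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("track timepoints must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    def position_at(self, t: int) -> np.ndarray | None:
        """Position at frame t, linearly interpolated inside gaps."""
        ts = np.array([p[0] for p in self.points])
        if t < ts[0] or t > ts[-1]:
            return None
        pos = np.array([p[1:] for p in self.points])
        return np.array(
            [np.interp(t, ts, pos[:, k]) for k in range(3)]
        )


@dataclass
class DivisionSignal:
    """Per-track division readout: raw and background-subtracted series."""

    cell_id: int
    values: np.ndarray
    raw: np.ndarray
    frames: np.ndarray
    events: list[int]
    cycle_lengths: list[float]
    frame_interval: float = 1.0


def _frame_detections(detections) -> dict[int, np.ndarray]:
    """Group detection coordinates by frame: t -> (n, 3) array of (z, y, x)."""
    if isinstance(detections, DetectionSet):
        coords = detections.coordinates()
    elif isinstance(detections, dict):
        return {int(t): np.asarray(v, dtype=float).reshape(-1, 3) for t, v in detections.items()}
    else:  # list of per-frame DetectionSets or arrays
        out: dict[int, np.ndarray] = {}
        for t, item in enumerate(detections):
            arr = item.coordinates()[:, 1:] if isinstance(item, DetectionSet) else np.asarray(item, dtype=float).reshape(-1, 3)
            out[t] = arr
        return out
    frames: dict[int, list] = {}
    for row in coords:
        frames.setdefault(int(row[0]), []).append(row[1:])
    return {t: np.asarray(v) for t, v in frames.items()}


def link(detections, max_disp: float, max_gap: int = 0) -> list[Track]:
    """Link detections over time into tracks.

    ``detections`` is a DetectionSet with multiple timepoints, a dict
    {t: (n, 3) array}, or a list of per-frame arrays/DetectionSets.
    Assignment per frame minimizes total displacement among candidate pairs
    within ``max_disp * (gap + 1)``; leftover detections start new tracks.
    Linking is deterministic and independent of detection input order
    (coordinates are canonically sorted before assignment).
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    frames = _frame_detections(detections)
    if not frames:
        return []
    t_min, t_max = min(frames), max(frames)

    active: list[dict] = []  # {'points': [...], 'last_t', 'velocity'}
    finished: list[dict] = []

    for t in range(t_min, t_max + 1):
        dets = frames.get(t, np.zeros((0, 3)))
        order = np.lexsort((dets[:, 2], dets[:, 1], dets[:, 0])) if len(dets) else []
        dets = dets[order] if len(dets) else dets

        # retire tracks that exceeded the allowed gap
        still = []
        for tr in active:
            if t - tr["last_t"] > max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        if len(active) and len(dets):
            pred = np.array([
                tr["points"][-1][1:] + tr["velocity"] * (t - tr["last_t"] - 1)
                for tr in active
            ])
            diff = pred[:, None, :] - dets[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            gate = np.array([max_disp * (t - tr["last_t"]) for tr in active])[:, None]
            cost = np.where(dist <= gate, dist, _BIG)
            rows, cols = linear_sum_assignment(cost)
            matched_cols = set()
            for r, c in zip(rows, cols):
                if cost[r, c] < _BIG:
                    active[r]["velocity"] = (
                        (dets[c] - np.asarray(active[r]["points"][-1][1:]))
                        / (t - active[r]["last_t"])
                    )
                    active[r]["gaps"] += t - active[r]["last_t"] - 1
                    active[r]["points"].append((t, *dets[c]))
                    active[r]["last_t"] = t
                    matched_cols.add(c)
        else:
            matched_cols = set()

        for c in range(len(dets)):
            if c not in matched_cols:
                active.append(
                    {"points": [(t, *dets[c])], "last_t": t, "velocity": np.zeros(3), "gaps": 0}
                )

    finished.extend(active)
    finished.sort(key=lambda tr: (tr["points"][0][0], tr["points"][0][1:]))
    return [
        Track(cell_id=i, points=[(int(p[0]), float(p[1]), float(p[2]), float(p[3])) for p in tr["points"]], gaps=tr["gaps"])
        for i, tr in enumerate(finished)
    ]


def _moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use truncated windows."""
    half = window // 2
    out = np.empty_like(series, dtype=float)
    n = len(series)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = series[lo:hi].mean()
    return out


def division_signal(
    pv_dividing: ProximityVolume | np.ndarray,
    track: Track,
    window: int = DEFAULT_WINDOW,
    frame_interval: float = 1.0,
    event_threshold: float | None = None,
    refractory: int | None = None,
    smooth: int = 3,
) -> DivisionSignal:
    """Extract the division signal of one track from the dividing-class maps.

    ``pv_dividing`` holds the proximity volume of the dividing class for
    every frame, shaped (t, z, y, x).  The raw series is the max proximity
    within a 3x3x3 neighbourhood of the tracked (interpolated) position per
    frame; the signal subtracts a centered moving average of width
    ``window`` (odd, >= 3).  Before peak finding the residual is smoothed
    with a short ``smooth``-frame mean: a genuine division elevates the
    dividing-class score for at least the duration of the spindle figure
    (two or more frames), so single-frame spikes are rejected.  Events are
    local maxima of the smoothed signal above a threshold (default: the
    larger of 3x the signal's median absolute deviation and an absolute
    floor of 0.1 on the proximity scale) separated by at least
    ``refractory`` frames (default window // 2).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    values = pv_dividing.values if isinstance(pv_dividing, ProximityVolume) else np.asarray(pv_dividing)
    if values.ndim != 4:
        raise ValueError("dividing-class proximity series must be (t, z, y, x)")
    t0, t1 = track.points[0][0], track.points[-1][0]
    t1 = min(t1, values.shape[0] - 1)
    frames = np.arange(t0, t1 + 1)
    nz, ny, nx = values.shape[1:]
    raw = np.empty(len(frames))
    for i, t in enumerate(frames):
        pos = track.position_at(int(t))
        z, y, x = (int(round(p)) for p in pos)
        zs = slice(max(0, z - 1), min(nz, z + 2))
        ys = slice(max(0, y - 1), min(ny, y + 2))
        xs = slice(max(0, x - 1), min(nx, x + 2))
        raw[i] = float(values[t, zs, ys, xs].max())

    signal = raw - _moving_average(raw, window)
    peak_signal = _moving_average(signal, smooth) if smooth > 1 else signal

    if event_threshold is None:
        mad = float(np.median(np.abs(peak_signal - np.median(peak_signal))))
        event_threshold = max(EVENT_MAD_FACTOR * mad, EVENT_MIN_HEIGHT)
    if refractory is None:
        refractory = window // 2

    events: list[int] = []
    if len(signal) >= window:
        # find_peaks handles plateaus (2-frame spindle figures produce equal
        # consecutive values) and enforces the refractory spacing directly
        peaks, _ = find_peaks(
            peak_signal, height=event_threshold, distance=max(1, refractory)
        )
        events = sorted(int(frames[p]) for p in peaks)

    cycles = [
        (b - a) * frame_interval for a, b in zip(events, events[1:])
    ]
    return DivisionSignal(
        cell_id=track.cell_id,
        values=signal,
        raw=raw,
        frames=frames,
        events=events,
        cycle_lengths=cycles,
        frame_interval=frame_interval,
    )


def cycle_stats(signals: list[DivisionSignal], frame_interval: float | None = None) -> dict:
    """Per-cell and per-sample cycle-length summaries.

    Cells with fewer than two detected events carry no cycle measurement
    and are excluded.  Returns per-cell mean cycle lengths (minutes, given
    ``frame_interval`` in min/frame), the sample mean and sd, and
    divisions/hour = 60 / mean cycle length.
    """
    per_cell = {}
    for sig in signals:
        if len(sig.events) < 2:
            continue
        fi = frame_interval if frame_interval is not None else sig.frame_interval
        cycles = np.diff(sig.events) * fi
        per_cell[sig.cell_id] = float(np.mean(cycles))
    if not per_cell:
        raise ValueError("no cell with >= 2 division events; cannot compute cycle statistics")
    vals = np.array(list(per_cell.values()))
    mean = float(vals.mean())
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return {
        "per_cell_mean_cycle": per_cell,
        "mean_cycle": mean,
        "sd_cycle": sd,
        "divisions_per_hour": 60.0 / mean,
        "n_cells": len(per_cell),
    }
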