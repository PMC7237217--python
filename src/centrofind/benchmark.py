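"""Self-contained validation studies on synthetic phantoms.

These protocols mirror how the detector is validated in practice and are
used both by the test suite and by ``scripts/acceptance.py``:

* ``run_detection_benchmark`` — train on a single clustered low-SNR phantom,
  tune the detection threshold on a small tuning set, evaluate precision /
  recall / F1 on an independent evaluation set, at a strict 4-voxel matching
  tolerance and at the more generous half-cell-size (one radius) tolerance.
* ``run_division_study`` — render time series with scheduled ~90-minute
  division cycles, train a dividing-class regressor, track mothers, extract
  division signals, and compare recovered cycle lengths to the schedule.
* ``run_training_level_study`` — measure held-out detection F1 as the number
  of annotated planes grows.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .detect3d import ObjectSize, detect, find_maxima, hessian_enhance
from .evalmetrics import match_and_score, score_batch
from .imgio import TrainingAnnotation, VolumeImage
from .proximity_model import predict_volume, train
from .synthgen import PhantomSpec, annotations_from_truth, generate, generate_division_series
from .trackcycle import cycle_stats, division_signal, link

#: thresholds scanned when tuning the detection sensitivity
THRESHOLD_GRID = (0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2)


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_detection_benchmark(
    seed: int,
    n_train: int = 1,
    n_tune: int = 5,
    n_eval: int = 25,
    spec_kwargs: dict | None = None,
    sigma: float | None = None,
) -> dict:
    """Train-1 / tune-5 / evaluate-25 detection study on clustered phantoms.

    Returns summary statistics (mean and sample sd over the evaluation set)
    of precision, recall and F1 at the strict 4-voxel tolerance, the mean F1
    at the generous half-cell-size tolerance, and the tuned threshold.
    """
    rng = np.random.default_rng(seed)
    kw = dict(spec_kwargs or {})
    base = PhantomSpec(**kw)
    radius = base.radius
    size = ObjectSize.isotropic(radius)
    if sigma is None:
        sigma = radius / 2.0

    def phantom():
        return generate(PhantomSpec(**{**kw, "seed": _sub_seed(rng)}))

    # --- train on a single phantom
    assert n_train == 1
    vol, truth = phantom()
    anns = annotations_from_truth(truth[0], base.shape)
    model = train([vol], anns, sigma=sigma, seed=_sub_seed(rng))

    # --- tune the detection threshold on a small independent set
    tune_enhanced = []
    for _ in range(n_tune):
        v, tr = phantom()
        pv = predict_volume(model, v, 0)
        tune_enhanced.append((hessian_enhance(pv, size), tr[0]))
    best_thr, best_f1 = THRESHOLD_GRID[0], -1.0
    for thr in THRESHOLD_GRID:
        f1s = [
            match_and_score(find_maxima(enh, size, thr), tr, 4.0).f1
            for (enh, tr) in tune_enhanced
        ]
        mean_f1 = float(np.mean(f1s))
        if mean_f1 > best_f1:
            best_thr, best_f1 = thr, mean_f1

    # --- evaluate on an independent set
    preds, truths = [], []
    for _ in range(n_eval):
        v, tr = phantom()
        preds.append(detect(model, v, 0, size, best_thr))
        truths.append(tr[0])
    strict = score_batch(preds, truths, 4.0)
    generous = score_batch(preds, truths, radius)  # half the cell diameter

    return {
        "threshold": best_thr,
        "n_eval": n_eval,
        "strict_tolerance": 4.0,
        "generous_tolerance": radius,
        "precision": strict["summary"]["precision"],
        "recall": strict["summary"]["recall"],
        "f1": strict["summary"]["f1"],
        "f1_generous": generous["summary"]["f1"],
        "per_image_f1": [r.f1 for r in strict["per_image"]],
    }


def _division_schedule(n_cells: int, n_frames: int, cycle_frames: float = 22.5):
    """Staggered schedules with the given mean cycle (alternating rounding)."""
    sched = []
    for cell in range(n_cells):
        f = 5 + 3 * cell
        k = 0
        while f < n_frames:
            sched.append((cell, f))
            f += int(np.floor(cycle_frames)) if k % 2 == 0 else int(np.ceil(cycle_frames))
            k += 1
    return sched


def run_single_division_series(
    seed: int,
    n_frames: int = 78,
    n_cells: int = 3,
    frame_interval: float = 4.0,
    shape: tuple[int, int, int] = (16, 64, 64),
    radius: float = 6.0,
) -> dict:
    """One division-series recovery run; returns recovered vs scheduled cycles."""
    sched = _division_schedule(n_cells, n_frames)
    spec = PhantomSpec(
        shape=shape, n_cells=n_cells, radius=radius, radius_jitter=0.05,
        clustering=0.0, snr=5.0, n_timepoints=n_frames,
        division_schedule=sched, seed=seed,
    )
    vol, truth, events = generate_division_series(spec)
    centres = truth[0]
    div_frames = sorted({f for (_, f) in events})
    ny, nx = shape[1], shape[2]
    nz = shape[0]

    # dividing-class annotations: a click on each spindle figure, plus
    # background-only planes (off-centre planes of spindle frames and
    # quiet frames spread across the series)
    anns = []
    for (cell, f) in events:
        c = centres[cell]
        zc = int(round(c[0]))
        anns.append(TrainingAnnotation(
            "dividing", t=f, z=zc, region=(0, 0, ny, nx),
            points=[(float(c[1]), float(c[2]))],
        ))
        zoff = zc + 5 if zc + 5 < nz else zc - 5
        anns.append(TrainingAnnotation("dividing", t=f, z=zoff, region=(0, 0, ny, nx), points=[]))
    quiet = [t for t in range(n_frames) if min(abs(t - f) for f in div_frames) > 4]
    quiet = quiet[:: max(1, len(quiet) // 6)][:6]
    zc0 = int(round(centres[0][0]))
    for t in quiet:
        for z in sorted({max(0, zc0 - 4), zc0, min(nz - 1, zc0 + 4)}):
            anns.append(TrainingAnnotation("dividing", t=t, z=z, region=(0, 0, ny, nx), points=[]))

    model = train([vol], anns, sigma=radius / 2.0, seed=seed)
    pv = np.concatenate(
        [predict_volume(model, vol, t).values for t in range(n_frames)], axis=0
    )

    # track mothers from blob detections on the raw nuclear channel
    size = ObjectSize.isotropic(radius)
    dets = []
    for t in range(n_frames):
        enh = hessian_enhance(vol.data[t, :, :, :, 0][np.newaxis], size)
        d = find_maxima(enh, size, 0.05)
        dets.append(
            np.array([r[1:4] for r in d.records], dtype=float) if len(d) else np.zeros((0, 3))
        )
    tracks = link(dets, max_disp=4.0, max_gap=2)
    # mothers persist through the whole series; transient daughter tracks drop out
    full = [tr for tr in tracks if len(tr) >= int(0.8 * n_frames)]
    sigs = [division_signal(pv, tr, window=21, frame_interval=frame_interval) for tr in full]
    stats = cycle_stats(sigs)

    by_cell: dict[int, list[int]] = {}
    for (c, f) in events:
        by_cell.setdefault(c, []).append(f)
    scheduled_mean = float(np.mean([
        np.mean(np.diff(sorted(fs))) * frame_interval for fs in by_cell.values() if len(fs) > 1
    ]))
    return {
        "recovered_mean_cycle": stats["mean_cycle"],
        "scheduled_mean_cycle": scheduled_mean,
        "divisions_per_hour": stats["divisions_per_hour"],
        "per_cell": stats["per_cell_mean_cycle"],
        "n_tracks": len(full),
    }


def run_division_study(seed: int, n_seeds: int = 5) -> dict:
    """Division-recovery study over several independently seeded series."""
    rng = np.random.default_rng(seed)
    runs = [run_single_division_series(_sub_seed(rng)) for _ in range(n_seeds)]
    cycles = [r["recovered_mean_cycle"] for r in runs]
    scheduled = [r["scheduled_mean_cycle"] for r in runs]
    mean_cycle = float(np.mean(cycles))
    return {
        "mean_cycle": mean_cycle,
        "scheduled_mean_cycle": float(np.mean(scheduled)),
        "divisions_per_hour": 60.0 / mean_cycle,
        "per_seed_cycles": cycles,
    }


def run_training_level_study(
    seed: int,
    levels: tuple[int, ...] = (1, 3, 6),
    n_seeds: int = 5,
    spec_kwargs: dict | None = None,
) -> dict:
    """Held-out F1 as a function of the number of annotated planes.

    For each replicate, one phantom is annotated on 1, 3 or 6 planes; a
    model per level is evaluated on an independently seeded phantom at the
    4-voxel tolerance.  The detection threshold is tuned per level on the
    training phantom itself (as a user would calibrate the sensitivity for
    a given model) before scoring the held-out phantom.
    """
    kw = dict(spec_kwargs or {"shape": (32, 96, 96), "n_cells": 15})
    base = PhantomSpec(**kw)
    radius = base.radius
    size = ObjectSize.isotropic(radius)
    rng = np.random.default_rng(seed)
    f1s = {lev: [] for lev in levels}
    for _ in range(n_seeds):
        train_vol, train_truth = generate(PhantomSpec(**{**kw, "seed": _sub_seed(rng)}))
        test_vol, test_truth = generate(PhantomSpec(**{**kw, "seed": _sub_seed(rng)}))
        all_anns = annotations_from_truth(train_truth[0], base.shape, n_planes=max(levels))
        cell_planes = [a for a in all_anns if a.points]
        bg_planes = [a for a in all_anns if not a.points]
        model_seed = _sub_seed(rng)
        for lev in levels:
            anns = cell_planes[:lev] + bg_planes
            model = train([train_vol], anns, sigma=radius / 2.0, seed=model_seed)
            enh_train = hessian_enhance(predict_volume(model, train_vol, 0), size)
            best_thr, best = THRESHOLD_GRID[0], -1.0
            for thr in THRESHOLD_GRID:
                f = match_and_score(find_maxima(enh_train, size, thr), train_truth[0], 4.0).f1
                if f > best:
                    best_thr, best = thr, f
            det = detect(model, test_vol, 0, size, best_thr)
            f1s[lev].append(match_and_score(det, test_truth[0], 4.0).f1)
    return {
        "levels": list(levels),
        "mean_f1": {lev: float(np.mean(v)) for lev, v in f1s.items()},
        "per_seed_f1": {lev: list(map(float, v)) for lev, v in f1s.items()},
    }
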