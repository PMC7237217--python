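"""Linking, division signals, and cycle statistics."""

import numpy as np
import pytest

import centrofind as cf
from centrofind.trackcycle import _moving_average, division_signal, link


class TestLink:
    def test_stationary_detection_single_track(self):
        frames = [np.array([[5.0, 10.0, 10.0]]) for _ in range(10)]
        tracks = link(frames, max_disp=3.0)
        assert len(tracks) == 1 and len(tracks[0]) == 10

    def test_jump_beyond_max_disp_terminates_tracks(self):
        """Cells that jump farther than max_disp in one frame must not be
        bridged; tracks terminate and new ones start."""
        a, b = np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 20.0])
        a2, b2 = np.array([0.0, 10.0, 0.0]), np.array([0.0, 10.0, 20.0])
        frames = [np.stack([a, b]), np.stack([a, b]), np.stack([a2, b2]), np.stack([a2, b2])]
        tracks = link(frames, max_disp=5.0, max_gap=0)
        assert len(tracks) == 4 and all(len(t) == 2 for t in tracks)

    def test_gap_bridging(self):
        frames = [np.array([[0.0, 5.0, 5.0]]), np.zeros((0, 3)), np.array([[0.0, 5.0, 6.0]])]
        tracks = link(frames, max_disp=2.0, max_gap=1)
        assert len(tracks) == 1 and tracks[0].gaps == 1

    def test_random_walks_recovered_exactly(self):
        """5 random-walking cells, steps < max_disp/2: linked identities must
        equal ground truth (verified against per-frame nearest assignment)."""
        rng = np.random.default_rng(0)
        n_cells, n_frames = 5, 50
        pos = rng.uniform(20, 80, size=(n_cells, 3))
        paths = []
        for _ in range(n_frames):
            pos = pos + rng.uniform(-1.4, 1.4, size=pos.shape)
            paths.append(pos.copy())
        paths = np.asarray(paths)  # (t, cell, 3)
        frames = [paths[t] for t in range(n_frames)]
        tracks = link(frames, max_disp=6.0)
        assert len(tracks) == n_cells
        for tr in tracks:
            assert len(tr) == n_frames
            p0 = np.array(tr.points[0][1:])
            cell = int(np.argmin(np.linalg.norm(paths[0] - p0, axis=1)))
            got = np.array([p[1:] for p in tr.points])
            np.testing.assert_allclose(got, paths[:, cell, :], atol=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        frames = [rng.uniform(0, 50, size=(4, 3)) for _ in range(8)]
        shuffled = [f[rng.permutation(len(f))] for f in frames]
        a = link(frames, max_disp=60.0)
        b = link(shuffled, max_disp=60.0)
        pts_a = sorted(tuple(map(tuple, t.points)) for t in a)
        pts_b = sorted(tuple(map(tuple, t.points)) for t in b)
        assert pts_a == pts_b

    def test_nonpositive_max_disp_rejected(self):
        with pytest.raises(ValueError):
            link([np.zeros((1, 3))], max_disp=0.0)


def _track(n_frames, z=2, y=8, x=8):
    return cf.Track(cell_id=0, points=[(t, float(z), float(y), float(x)) for t in range(n_frames)])


def _pv_from_series(series, z=2, y=8, x=8, shape=(5, 16, 16)):
    pv = np.zeros((len(series),) + shape)
    pv[:, z, y, x] = series
    return pv


class TestDivisionSignal:
    def test_constant_raw_gives_zero_signal_no_events(self):
        pv = _pv_from_series(np.full(60, 0.4))
        sig = division_signal(pv, _track(60), window=21)
        np.testing.assert_allclose(sig.values, 0.0, atol=1e-12)
        assert sig.events == []

    def test_pulses_every_45_frames_give_90_min_cycles(self):
        series = np.zeros(140)
        for f in (10, 55, 100):
            series[f : f + 2] = 0.9
        pv = _pv_from_series(series)
        sig = division_signal(pv, _track(140), window=21, frame_interval=2.0)
        assert len(sig.events) == 3
        assert sig.cycle_lengths == pytest.approx([90.0, 90.0], abs=4.0)

    def test_slow_drift_does_not_shift_events(self):
        """Event spacing is invariant to adding slow background drift
        (period >> window)."""
        base = np.zeros(140)
        for f in (10, 55, 100):
            base[f : f + 2] = 0.9
        drift = 0.3 * np.sin(np.arange(140) / 140 * 2 * np.pi)
        e1 = division_signal(_pv_from_series(base), _track(140), window=21).events
        e2 = division_signal(_pv_from_series(base + drift), _track(140), window=21).events
        assert np.allclose(e1, e2, atol=1)

    def test_track_shorter_than_window_gives_no_events(self):
        pv = _pv_from_series(np.linspace(0, 1, 10))
        sig = division_signal(pv, _track(10), window=21)
        assert sig.events == []
        assert len(sig.values) == 10

    def test_even_or_tiny_window_rejected(self):
        pv = _pv_from_series(np.zeros(30))
        with pytest.raises(ValueError):
            division_signal(pv, _track(30), window=20)
        with pytest.raises(ValueError):
            division_signal(pv, _track(30), window=1)

    def test_moving_average_truncated_edges(self):
        out = _moving_average(np.arange(10, dtype=float), 5)
        assert out[0] == pytest.approx(np.mean([0, 1, 2]))
        assert out[-1] == pytest.approx(np.mean([7, 8, 9]))


class TestCycleStats:
    def _sig(self, cell_id, events, frame_interval=2.0):
        return cf.DivisionSignal(
            cell_id=cell_id, values=np.zeros(10), raw=np.zeros(10),
            frames=np.arange(10), events=events,
            cycle_lengths=list(np.diff(events) * frame_interval),
            frame_interval=frame_interval,
        )

    def test_arithmetic(self):
        stats = cf.cycle_stats([self._sig(0, [0, 45, 90])], frame_interval=2.0)
        assert stats["mean_cycle"] == pytest.approx(90.0)
        assert stats["divisions_per_hour"] == pytest.approx(0.667, abs=1e-3)

    def test_cells_with_fewer_than_two_events_excluded(self):
        stats = cf.cycle_stats(
            [self._sig(0, [0, 45]), self._sig(1, [7])], frame_interval=2.0
        )
        assert stats["n_cells"] == 1

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="2 division events"):
            cf.cycle_stats([self._sig(0, [5]), self._sig(1, [])])

    def test_population_recovery_within_two_sem(self):
        """Cycle lengths drawn from N(90, 15) for 10 cells: the recovered
        sample mean must sit within 2 SEM of 90."""
        rng = np.random.default_rng(6)
        sigs = []
        for cell in range(10):
            cycles = rng.normal(90, 15, size=3)
            events = np.cumsum(np.concatenate([[10], cycles / 2.0])).astype(int)
            sigs.append(self._sig(cell, list(events), frame_interval=2.0))
        stats = cf.cycle_stats(sigs, frame_interval=2.0)
        sem = 15 / np.sqrt(10 * 3)
        assert abs(stats["mean_cycle"] - 90.0) < 2 * sem + 2.0  # +2 for integer rounding
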