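"""Phantom generator: reproducibility, SNR, clustering, division schedules."""

import numpy as np
import pytest

import centrofind as cf
from centrofind.synthgen import _AMPLITUDE, _BACKGROUND


class TestGenerate:
    def test_seed_reproducibility_bit_identical(self):
        spec = cf.PhantomSpec(shape=(16, 48, 48), n_cells=5, radius=5.0, seed=3)
        v1, t1 = cf.generate(spec)
        v2, t2 = cf.generate(spec)
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(t1[0], t2[0])

    def test_zero_cells_pure_noise(self):
        spec = cf.PhantomSpec(shape=(8, 32, 32), n_cells=0, radius=5.0, seed=0)
        vol, truth = cf.generate(spec)
        assert len(truth[0]) == 0
        assert abs(float(vol.data.mean()) - _BACKGROUND) < 0.05

    @pytest.mark.parametrize("snr", [3.0, 5.0, 10.0])
    def test_measured_snr_within_ten_percent(self, snr):
        """(mean foreground - mean background) / background sd must equal the
        requested SNR; measured on deep-interior vs far-from-cell voxels."""
        spec = cf.PhantomSpec(shape=(24, 96, 96), n_cells=8, radius=8.0,
                              clustering=0.0, snr=snr, seed=1)
        vol, truth = cf.generate(spec)
        data = vol.data[0, :, :, :, 0]
        zz, yy, xx = np.mgrid[: data.shape[0], : data.shape[1], : data.shape[2]]
        dist = np.full(data.shape, np.inf)
        for c in truth[0]:
            d = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
            dist = np.minimum(dist, d)
        fg = data[dist < 0.5 * spec.radius]
        bg = data[dist > 2.0 * spec.radius]
        measured = (fg.mean() - bg.mean()) / bg.std()
        assert measured == pytest.approx(snr, rel=0.10)

    def test_clustering_fraction_has_touching_neighbours(self):
        spec = cf.PhantomSpec(shape=(40, 128, 128), n_cells=30, radius=8.0,
                              clustering=0.75, seed=2)
        _, truth = cf.generate(spec)
        centres = truth[0]
        dmat = np.linalg.norm(centres[:, None] - centres[None, :], axis=-1)
        np.fill_diagonal(dmat, np.inf)
        n_touching = int(np.sum(dmat.min(axis=1) < 2.2 * spec.radius))
        assert n_touching >= 0.75 * spec.n_cells

    def test_nonclustered_centres_separated(self):
        spec = cf.PhantomSpec(shape=(32, 96, 96), n_cells=10, radius=7.0,
                              clustering=0.0, radius_jitter=0.0, seed=4)
        _, truth = cf.generate(spec)
        centres = truth[0]
        dmat = np.linalg.norm(centres[:, None] - centres[None, :], axis=-1)
        np.fill_diagonal(dmat, np.inf)
        assert dmat.min() >= 2 * spec.radius * 0.95

    def test_two_channel_shell_option(self):
        spec = cf.PhantomSpec(shape=(16, 48, 48), n_cells=3, radius=5.0,
                              n_channels=2, clustering=0.0, seed=5)
        vol, truth = cf.generate(spec)
        assert vol.n_channels == 2
        c = truth[0][0]
        data = vol.data[0]
        zz, yy, xx = np.mgrid[: data.shape[0], : data.shape[1], : data.shape[2]]
        dist = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        centre_ball = dist < 0.4 * spec.radius
        ring = np.abs(dist - spec.radius) < 0.15 * spec.radius
        # nuclear channel bright at the centre; shell channel bright at radius
        assert data[centre_ball, 0].mean() > _BACKGROUND + 0.5 * _AMPLITUDE
        assert data[ring, 1].mean() > data[centre_ball, 1].mean() + 0.2

    def test_impossible_packing_raises(self):
        spec = cf.PhantomSpec(shape=(16, 40, 40), n_cells=60, radius=6.0,
                              clustering=0.0, seed=0)
        with pytest.raises(RuntimeError):
            cf.generate(spec)


class TestDivisionSeries:
    def _spec(self, schedule, n_frames=60, seed=0, snr=5.0):
        return cf.PhantomSpec(shape=(12, 48, 48), n_cells=2, radius=5.0,
                              clustering=0.0, n_timepoints=n_frames, snr=snr,
                              division_schedule=schedule, seed=seed)

    def test_schedule_echoed_in_events(self):
        sched = [(0, 5), (0, 50), (1, 20)]
        _, _, events = cf.generate_division_series(self._spec(sched))
        assert events == sorted(sched)

    def test_no_schedule_static_series(self):
        vol, truth, events = cf.generate_division_series(self._spec(None, n_frames=4, snr=20.0))
        assert events == []
        # frames differ only by noise: foreground structure is unchanged
        a, b = vol.data[0, :, :, :, 0], vol.data[3, :, :, :, 0]
        assert np.corrcoef(a.ravel(), b.ravel())[0, 1] > 0.8

    def test_spindle_frames_show_elongation(self):
        """During a division the mother's intensity figure is elongated:
        its second moment anisotropy exceeds the interphase value."""
        sched = [(0, 20)]
        vol, truth, _ = cf.generate_division_series(self._spec(sched, snr=20.0))
        c = truth[0][0]
        z, cy, cx = int(round(c[0])), c[1], c[2]

        def anisotropy(frame):
            # second-moment eigenratio within a window around the mother
            plane = vol.data[frame, z, :, :, 0]
            y0, y1 = int(cy - 10), int(cy + 11)
            x0, x1 = int(cx - 10), int(cx + 11)
            win = plane[max(0, y0):y1, max(0, x0):x1]
            mask = win > _BACKGROUND + 0.5 * _AMPLITUDE
            ys, xs = np.nonzero(mask)
            ev = np.linalg.eigvalsh(np.cov(np.vstack([ys, xs])))
            return ev[-1] / max(ev[0], 1e-9)

        assert anisotropy(20) > 1.5 * anisotropy(10)

    def test_daughter_appears_after_division(self):
        sched = [(0, 10)]
        vol, truth, _ = cf.generate_division_series(self._spec(sched))
        c = truth[0][0]
        r = 5.0

        def foreground_voxels(frame):
            return int(np.sum(vol.data[frame, :, :, :, 0] > _BACKGROUND + 0.5 * _AMPLITUDE))

        # after the spindle retracts, mother + daughter exceed mother alone
        assert foreground_voxels(15) > foreground_voxels(5)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            cf.generate_division_series(self._spec([(0, 999)]))
        with pytest.raises(ValueError):
            cf.generate_division_series(self._spec([(5, 10)]))
        with pytest.raises(ValueError):  # conflicting (overlapping spindles)
            cf.generate_division_series(self._spec([(0, 10), (0, 11)]))
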