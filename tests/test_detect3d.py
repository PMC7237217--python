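"""DoH blob enhancement and 3D maxima finding against brute-force oracles."""

import numpy as np
import pytest

import centrofind as cf
from centrofind.detect3d import ObjectSize, find_maxima, hessian_enhance


def gaussian_blob(shape, centre, sigma):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(float)
    d2 = ((zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2)
    return np.exp(-d2 / (2 * sigma**2))


def brute_force_doh(volume, sigma):
    """Dense oracle: smooth, then central-difference Hessian at every voxel,
    det of -H.  Interior voxels only (1-voxel border excluded)."""
    from scipy.ndimage import gaussian_filter

    sm = gaussian_filter(volume.astype(float), sigma, mode="reflect")
    out = np.full(volume.shape, np.nan)
    nz, ny, nx = volume.shape
    for z in range(1, nz - 1):
        for y in range(1, ny - 1):
            for x in range(1, nx - 1):
                h = np.empty((3, 3))
                h[0, 0] = sm[z + 1, y, x] - 2 * sm[z, y, x] + sm[z - 1, y, x]
                h[1, 1] = sm[z, y + 1, x] - 2 * sm[z, y, x] + sm[z, y - 1, x]
                h[2, 2] = sm[z, y, x + 1] - 2 * sm[z, y, x] + sm[z, y, x - 1]
                h[0, 1] = h[1, 0] = (
                    sm[z + 1, y + 1, x] - sm[z + 1, y - 1, x]
                    - sm[z - 1, y + 1, x] + sm[z - 1, y - 1, x]
                ) / 4
                h[0, 2] = h[2, 0] = (
                    sm[z + 1, y, x + 1] - sm[z + 1, y, x - 1]
                    - sm[z - 1, y, x + 1] + sm[z - 1, y, x - 1]
                ) / 4
                h[1, 2] = h[2, 1] = (
                    sm[z, y + 1, x + 1] - sm[z, y + 1, x - 1]
                    - sm[z, y - 1, x + 1] + sm[z, y - 1, x - 1]
                ) / 4
                out[z, y, x] = np.linalg.det(-h)
    return out


class TestHessianEnhance:
    def test_zero_volume_zero_response(self):
        out = hessian_enhance(np.zeros((1, 8, 8, 8)), ObjectSize.isotropic(3.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    @pytest.mark.parametrize("case_seed", range(5))
    def test_blob_maximum_matches_brute_force(self, case_seed):
        """Single blobs at random positions: the analytic-derivative response
        peaks at the same voxel (within 1) as the finite-difference oracle."""
        rng = np.random.default_rng(case_seed)
        centre = rng.uniform(7, 14, size=3)
        vol = gaussian_blob((21, 21, 21), centre, sigma=2.5)
        size = ObjectSize.isotropic(5.0)
        resp = hessian_enhance(vol[np.newaxis], size)[0]
        oracle = brute_force_doh(vol, 2.5)
        peak = np.unravel_index(np.nanargmax(resp), resp.shape)
        peak_oracle = np.unravel_index(np.nanargmax(oracle), oracle.shape)
        assert np.linalg.norm(np.array(peak) - np.array(peak_oracle)) <= 1.0
        assert np.linalg.norm(np.array(peak) - centre) <= 1.0

    def test_rotation_invariance_isotropic(self):
        rng = np.random.default_rng(9)
        vol = rng.random((16, 16, 16))
        size = ObjectSize.isotropic(4.0)
        a = hessian_enhance(vol[np.newaxis], size)[0]
        b = hessian_enhance(np.rot90(vol, axes=(1, 2))[np.newaxis], size)[0]
        np.testing.assert_allclose(np.rot90(a, axes=(1, 2)), b, atol=1e-10)

    def test_oversize_h_rejected(self):
        with pytest.raises(ValueError):
            hessian_enhance(np.zeros((1, 4, 4, 4)), ObjectSize.isotropic(10.0))


class TestFindMaxima:
    def test_zero_volume_empty(self):
        det = find_maxima(np.zeros((1, 8, 8, 8)), ObjectSize.isotropic(2.0), 0.1)
        assert len(det) == 0

    def test_two_separated_blobs_detected_at_centres(self):
        c1, c2 = (5.0, 5.0, 5.0), (15.0, 15.0, 15.0)
        vol = gaussian_blob((21, 21, 21), c1, 2.0) + gaussian_blob((21, 21, 21), c2, 2.0)
        size = ObjectSize.isotropic(4.0)
        resp = hessian_enhance(vol[np.newaxis], size)
        det = find_maxima(resp, size, 0.05)
        assert len(det) == 2
        coords = det.coordinates()[:, 1:]
        for c in (c1, c2):
            assert min(np.linalg.norm(coords - np.array(c), axis=1)) <= 1.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        vol = rng.random((1, 12, 24, 24))
        size = ObjectSize.isotropic(2.0)
        resp = hessian_enhance(vol, size)
        counts = [len(find_maxima(resp, size, thr)) for thr in (0.01, 0.05, 0.2, 0.5)]
        assert counts == sorted(counts, reverse=True)

    def test_all_scores_exceed_threshold(self):
        rng = np.random.default_rng(4)
        vol = rng.random((1, 10, 20, 20))
        size = ObjectSize.isotropic(2.0)
        resp = hessian_enhance(vol, size)
        det = find_maxima(resp, size, 0.1)
        assert all(rec[4] > 0.1 for rec in det.records)

    def test_plateau_yields_single_centroid_detection(self):
        vol = np.zeros((1, 9, 9, 9))
        vol[0, 4, 4:6, 4:6] = 1.0  # 4-voxel plateau
        det = find_maxima(vol, ObjectSize.isotropic(2.0), 0.5)
        assert len(det) == 1
        _, z, y, x, _ = det.records[0]
        assert (z, y, x) == (4, 4, 4)  # centroid 4.5 rounds toward lower index

    def test_border_detections_flagged(self):
        vol = np.zeros((1, 9, 9, 9))
        vol[0, 1, 4, 4] = 1.0
        det = find_maxima(vol, ObjectSize.isotropic(3.0), 0.5)
        assert len(det) == 1 and det.border_flags[0] is True


class TestDetectPipeline:
    def test_roi_covering_volume_is_identity(self, small_phantom, trained_model):
        spec, vol, truth = small_phantom
        size = ObjectSize.isotropic(spec.radius)
        nz, ny, nx = spec.shape
        whole = cf.PolygonROI(keyframes=[
            (0, 0, [(-1.0, -1.0), (-1.0, nx + 1.0), (ny + 1.0, nx + 1.0), (ny + 1.0, -1.0)])
        ])
        plain = cf.detect(trained_model, vol, 0, size, 0.01)
        filtered = cf.detect(trained_model, vol, 0, size, 0.01, roi=whole)
        assert plain.records == filtered.records

    def test_detects_phantom_cells(self, small_phantom, trained_model):
        """End-to-end sanity at generation SNR: high F1 against ground truth
        at half-radius tolerance."""
        spec, vol, truth = small_phantom
        det = cf.detect(trained_model, vol, 0, ObjectSize.isotropic(spec.radius), 0.01)
        res = cf.match_and_score(det, truth[0], spec.radius / 2.0)
        assert res.f1 >= 0.9
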