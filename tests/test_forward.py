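"""Volume -> sensor projectors: linearity, oracles, adjoints, view layout."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from lffusion import forward as F
from lffusion import optics as O


class TestProjectLFM:
    def test_zero_volume_gives_zero_light_field(self, desk_lfm):
        _, _, psf = desk_lfm
        nz = psf.data.shape[0]
        lf = F.project_lfm(F.Volume3D(np.zeros((nz, 16, 16))), psf)
        assert np.all(lf.data == 0)

    def test_matches_bruteforce_convolution(self, desk_lfm, rng):
        _, _, psf = desk_lfm
        small = O.LFMPSF(
            data=psf.data[:3],
            depth_grid_um=psf.depth_grid_um[:3],
            offset_spacing_um=psf.offset_spacing_um,
            sensor_pixel_pitch_um=psf.sensor_pixel_pitch_um,
        )
        vol = rng.random((3, 8, 8))
        lf = F.project_lfm(F.Volume3D(vol), small)
        nn = small.data.shape[3]
        expected = np.zeros_like(lf.data)
        for u in range(nn):
            for v in range(nn):
                for z in range(3):
                    expected[u, v] += convolve2d(
                        vol[z], small.data[z, :, :, v, u], mode="same"
                    )
        assert np.max(np.abs(expected - lf.data)) <= 1e-8

    def test_delta_volume_reproduces_psf_slice(self, desk_lfm):
        _, _, psf = desk_lfm
        nz, ms = psf.data.shape[0], psf.data.shape[1]
        n = 25
        vol = np.zeros((nz, n, n))
        vol[4, 12, 12] = 1.0
        lf = F.project_lfm(F.Volume3D(vol), psf)
        d = np.zeros((n, n))
        d[12, 12] = 1.0
        for u, v in [(0, 0), (3, 2), (4, 4)]:
            expected = convolve2d(d, psf.data[4, :, :, v, u], mode="same")
            assert np.max(np.abs(expected - lf.data[u, v])) <= 1e-8

    def test_linearity(self, desk_lfm, rng):
        _, _, psf = desk_lfm
        nz = psf.data.shape[0]
        a = rng.random((nz, 12, 12))
        b = rng.random((nz, 12, 12))
        la = F.project_lfm(F.Volume3D(a), psf).data
        lb = F.project_lfm(F.Volume3D(b), psf).data
        lab = F.project_lfm(F.Volume3D(a + b), psf).data
        assert np.max(np.abs(lab - la - lb)) <= 1e-8

    def test_flux_conserved_for_interior_support(self, desk_lfm, rng):
        _, _, psf = desk_lfm
        nz = psf.data.shape[0]
        vol = np.zeros((nz, 40, 40))
        vol[:, 14:26, 14:26] = rng.random((nz, 12, 12))
        lf = F.project_lfm(F.Volume3D(vol), psf)
        assert lf.data.sum() == pytest.approx(vol.sum(), rel=1e-6)

    def test_depth_mismatch_rejected(self, desk_lfm):
        _, _, psf = desk_lfm
        with pytest.raises(O.InvalidConfigError):
            F.project_lfm(F.Volume3D(np.zeros((3, 8, 8))), psf)

    def test_adjoint_consistency(self, desk_lfm, rng):
        _, _, psf = desk_lfm
        nz = psf.data.shape[0]
        x = rng.random((nz, 20, 20))
        y = rng.random((psf.data.shape[4], psf.data.shape[3], 20, 20))
        ax = F.project_lfm(F.Volume3D(x), psf).data
        aty = F.backproject_lfm(F.LightField4D(y), psf).data
        assert np.sum(ax * y) == pytest.approx(np.sum(x * aty), rel=1e-10)


class TestProjectFLFM:
    def test_zero_volume(self, desk_flfm):
        _, _, psf = desk_flfm
        views, sensor = F.project_flfm(
            F.Volume3D(np.zeros((psf.n_depths, 24, 24))), psf
        )
        assert np.all(views.data == 0) and np.all(sensor == 0)

    def test_delta_volume_matches_weighted_response(self, desk_flfm):
        _, _, psf = desk_flfm
        nz, n = psf.n_depths, psf.response.shape[1]
        k = nz // 2 + 2
        vol = np.zeros((nz, 32, 32))
        vol[k, 16, 16] = 1.0
        views, _ = F.project_flfm(F.Volume3D(vol), psf, return_sensor=False)
        lo = (n - 32) // 2
        delta = np.zeros((n, n))
        delta[lo + 16, lo + 16] = 1.0
        img = np.fft.ifft2(
            psf.weights[k, 0, 0] * np.fft.fft2(delta) * psf.response[k]
        )
        expected = np.clip(img.real, 0.0, None)[lo : lo + 32, lo : lo + 32]
        assert np.max(np.abs(views.data[3] - expected)) <= 1e-8

    def test_linearity(self, desk_flfm, rng):
        _, _, psf = desk_flfm
        nz = psf.n_depths
        a = rng.random((nz, 24, 24))
        b = rng.random((nz, 24, 24))
        va, _ = F.project_flfm(F.Volume3D(a), psf, return_sensor=False)
        vb, _ = F.project_flfm(F.Volume3D(b), psf, return_sensor=False)
        vab, _ = F.project_flfm(F.Volume3D(a + b), psf, return_sensor=False)
        assert np.max(np.abs(vab.data - va.data - vb.data)) <= 1e-8

    def test_seven_views_in_232_layout(self, desk_flfm, rng):
        _, _, psf = desk_flfm
        vol = rng.random((psf.n_depths, 24, 24))
        views, _ = F.project_flfm(F.Volume3D(vol), psf, return_sensor=False)
        assert views.n_views == 7
        rows = sorted(set(views.view_offsets[:, 0]))
        counts = [int(np.sum(views.view_offsets[:, 0] == r)) for r in rows]
        assert counts == [2, 3, 2]

    def test_adjoint_consistency(self, desk_flfm, rng):
        _, _, psf = desk_flfm
        nz = psf.n_depths
        x = rng.random((nz, 24, 24))
        y = rng.random((7, 24, 24))
        ax, _ = F.project_flfm(F.Volume3D(x), psf, return_sensor=False)
        stack = F.FLFMViewStack(
            data=y, view_offsets=psf.view_offsets, view_centers_px=psf.view_centers_px
        )
        aty = F.backproject_flfm(stack, psf).data
        assert np.sum(ax.data * y) == pytest.approx(np.sum(x * aty), rel=1e-9)

    def test_depth_mismatch_rejected(self, desk_flfm):
        _, _, psf = desk_flfm
        with pytest.raises(O.InvalidConfigError):
            F.project_flfm(F.Volume3D(np.zeros((2, 8, 8))), psf)


class TestViewRearrangement:
    def test_lfm_views_channel_count_and_order(self, rng):
        lf = F.LightField4D(rng.random((11, 11, 6, 7)))
        stack = F.lfm_views(lf)
        assert stack.shape == (121, 6, 7)
        # channel 0 is view (u=0, v=0); channel v_index for u=0 row-major
        np.testing.assert_array_equal(stack[0], lf.data[0, 0])
        np.testing.assert_array_equal(stack[11 * 2 + 5], lf.data[2, 5])

    def test_lfm_views_round_trip_bit_exact(self, rng):
        lf = F.LightField4D(rng.random((5, 5, 9, 9)))
        back = F.lfm_views_to_4d(F.lfm_views(lf), n_u=5)
        np.testing.assert_array_equal(back.data, lf.data)

    def test_flfm_views_crop_recovers_labeled_pattern(self, desk_flfm):
        _, _, psf = desk_flfm
        meta = F.FLFMViewStack(
            data=np.zeros((7, 8, 8)),
            view_offsets=psf.view_offsets,
            view_centers_px=psf.view_centers_px,
        )
        # paint each view's index at its centre on a large sensor canvas
        h = w = 160
        sensor = np.zeros((h, w))
        for i in range(7):
            cy = h // 2 + int(round(psf.view_centers_px[i, 0]))
            cx = w // 2 + int(round(psf.view_centers_px[i, 1]))
            sensor[cy, cx] = i + 1
        crops = F.flfm_views(sensor, meta, crop=9)
        for i in range(7):
            assert crops.data[i, 4, 4] == i + 1

    def test_flfm_views_out_of_bounds_rejected(self, desk_flfm):
        _, _, psf = desk_flfm
        meta = F.FLFMViewStack(
            data=np.zeros((7, 8, 8)),
            view_offsets=psf.view_offsets,
            view_centers_px=psf.view_centers_px,
        )
        with pytest.raises(O.InvalidConfigError):
            F.flfm_views(np.zeros((20, 20)), meta, crop=9)

    def test_sensor_mosaic_roundtrips_views(self, desk_flfm, rng):
        _, _, psf = desk_flfm
        vol = rng.random((psf.n_depths, 24, 24))
        views, sensor = F.project_flfm(F.Volume3D(vol), psf)
        crops = F.flfm_views(sensor, views, crop=24)
        np.testing.assert_allclose(crops.data, views.data, atol=1e-12)


class TestVolume3D:
    def test_negative_entries_rejected(self):
        with pytest.raises(O.InvalidConfigError):
            F.Volume3D(-np.ones((2, 3, 3)))

    def test_non_finite_rejected(self):
        bad = np.ones((2, 3, 3))
        bad[0, 0, 0] = np.nan
        with pytest.raises(O.InvalidConfigError):
            F.Volume3D(bad)
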