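"""Wave-optics primitives: quadrature, masks, propagation, PSFs."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss
from scipy.special import j0

from lffusion import optics as O


def _quadrature_oracle(theta_max, rb, lam, z, n, nodes=4096):
    """Independent high-resolution quadrature of the Debye integrand."""
    x, w = leggauss(nodes)
    th = 0.5 * theta_max * (x + 1.0)
    w = 0.5 * theta_max * w
    uo = np.exp(1j * (2 * np.pi / lam) * n * z * np.cos(th))
    return np.sum(w * uo * j0(2 * np.pi * rb * np.sin(th) / lam) * np.sin(th))


class TestDebye:
    def test_on_axis_focus_matches_closed_form(self):
        cfg, _ = O.lfm_desk_config()
        val = O.debye_radial(cfg, 0.0, np.array([0.0]))[0]
        expected = 1.0 - np.cos(cfg.aperture_half_angle)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_matches_independent_quadrature_off_axis(self):
        cfg, _ = O.lfm_desk_config()
        r = np.array([0.0, 0.4, 1.1, 2.7])
        got = O.debye_radial(cfg, 2.0, r)
        want = np.array(
            [
                _quadrature_oracle(
                    cfg.aperture_half_angle, ri, cfg.wavelength_um, 2.0,
                    cfg.refractive_index,
                )
                for ri in r
            ]
        )
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_field_depends_only_on_radius(self):
        cfg, _ = O.lfm_desk_config()
        fld = O.debye_wavefront(cfg, 1.5).data
        n = fld.shape[0]
        c = O.grid_coords(n, cfg.lateral_spacing_um)
        yy, xx = np.meshgrid(c, c, indexing="ij")
        r = np.round(np.hypot(yy, xx), 9)
        for radius in np.unique(r)[:20]:
            vals = fld[r == radius]
            assert np.max(np.abs(vals - vals[0])) < 1e-10

    def test_zero_aperture_angle_gives_zero_field(self):
        cfg, _ = O.lfm_desk_config()
        tiny = O.OpticalConfig(
            numerical_aperture=1e-12,
            magnification=cfg.magnification,
            wavelength_nm=cfg.wavelength_nm,
            refractive_index=cfg.refractive_index,
            sensor_pixel_pitch_um=cfg.sensor_pixel_pitch_um,
            depth_grid_um=cfg.depth_grid_um,
            lateral_spacing_um=cfg.lateral_spacing_um,
            lateral_extent_px=cfg.lateral_extent_px,
        )
        vals = O.debye_radial(tiny, 0.0, np.linspace(0, 3, 7))
        assert np.max(np.abs(vals)) < 1e-10

    def test_quadrature_node_doubling_converges(self):
        cfg, _ = O.lfm_desk_config()
        r = np.linspace(0.0, 4.0, 33)
        a = O.debye_radial(cfg, 3.0, r, n_nodes=256)
        b = O.debye_radial(cfg, 3.0, r, n_nodes=512)
        assert np.max(np.abs(a - b)) / np.max(np.abs(b)) < 1e-6

    def test_na_exceeding_index_rejected(self):
        with pytest.raises(O.InvalidConfigError):
            O.OpticalConfig(
                numerical_aperture=1.4,
                magnification=40.0,
                wavelength_nm=580.0,
                refractive_index=1.33,
                sensor_pixel_pitch_um=10.0,
                depth_grid_um=np.arange(-2.0, 3.0),
                lateral_spacing_um=1.0,
                lateral_extent_px=32,
            )


class TestApertureProfile:
    def test_unity_at_center_and_monotone(self):
        rho = np.linspace(0.0, 2.0, 200)
        prof = O.aperture_profile(rho, cutoff=0.7, order=3.0)
        assert prof.transmission[0] == 1.0
        assert np.all(np.diff(prof.transmission) < 0)

    def test_high_order_approaches_disk_indicator(self):
        rho = np.linspace(0.0, 1.0, 2001)
        prof = O.aperture_profile(rho, cutoff=0.5, order=64.0)
        indicator = (rho < 0.5).astype(float)
        err = np.abs(prof.transmission - indicator)
        band = rho[err >= 1e-3]
        assert band.max() - band.min() < 0.05  # narrow transition band ...
        assert band.min() < 0.5 < band.max()  # ... straddling the cutoff
        assert np.max(err[(rho < band.min()) | (rho > band.max())]) < 1e-3

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(O.InvalidConfigError):
            O.aperture_profile(np.linspace(0, 1, 5), cutoff=0.0, order=2.0)


class TestApplyAperture:
    def _field(self, rng, n=16):
        return O.ComplexField2D(
            rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n)), 0.5, 580.0
        )

    def test_identity_profile_is_identity(self, rng):
        fld = self._field(rng)
        prof = O.aperture_profile(np.zeros((16, 16)), cutoff=1.0, order=2.0)
        out = O.apply_aperture(fld, prof)
        np.testing.assert_array_equal(out.data, fld.data)

    def test_energy_contracts(self, rng):
        fld = self._field(rng)
        rho = np.abs(rng.normal(size=(16, 16)))
        prof = O.aperture_profile(rho, cutoff=0.8, order=2.0)
        assert O.apply_aperture(fld, prof).energy() <= fld.energy()

    def test_grid_mismatch_raises(self, rng):
        fld = self._field(rng)
        prof = O.aperture_profile(np.zeros((8, 8)), cutoff=1.0, order=2.0)
        with pytest.raises(ValueError):
            O.apply_aperture(fld, prof)


class TestMLATransmission:
    def test_pure_phase(self):
        mla = O.MLAConfig(pitch_um=50.0, focal_length_um=1500.0, pixels_per_lenslet=5)
        t = O.mla_transmission(mla, 5.0, 40, 580.0)
        np.testing.assert_allclose(np.abs(t.data), 1.0, atol=1e-12)

    def test_lenslet_centers_carry_zero_phase(self):
        mla = O.MLAConfig(pitch_um=50.0, focal_length_um=1500.0, pixels_per_lenslet=5)
        t = O.mla_transmission(mla, 5.0, 40, 580.0)
        n = 40
        # origin sample sits on a lenslet centre; neighbours at +-pitch too
        for idx in (n // 2, n // 2 + 10, n // 2 - 10):
            assert abs(np.angle(t.data[idx, idx])) < 1e-10

    def test_periodicity_over_one_pitch(self):
        mla = O.MLAConfig(pitch_um=50.0, focal_length_um=1500.0, pixels_per_lenslet=5)
        t = O.mla_transmission(mla, 5.0, 40, 580.0).data
        period = 10  # pitch / spacing
        np.testing.assert_allclose(t[:, :-period], t[:, period:], atol=1e-10)
        np.testing.assert_allclose(t[:-period, :], t[period:, :], atol=1e-10)

    def test_undersampled_pitch_rejected(self):
        mla = O.MLAConfig(pitch_um=8.0, focal_length_um=1500.0, pixels_per_lenslet=5)
        with pytest.raises(O.InvalidConfigError):
            O.mla_transmission(mla, 5.0, 40, 580.0)


class TestAngularSpectrum:
    def _random_field(self, rng, n=48):
        return O.ComplexField2D(
            rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n)), 0.4, 580.0
        )

    def test_zero_distance_is_bandlimited_identity(self, rng):
        fld = self._random_field(rng)
        bl = O.angular_spectrum_propagate(fld, 0.0)
        again = O.angular_spectrum_propagate(bl, 0.0)
        assert np.max(np.abs(again.data - bl.data)) < 1e-10

    def test_round_trip_recovers_bandlimited_input(self, rng):
        for _ in range(5):
            fld = self._random_field(rng)
            bl = O.angular_spectrum_propagate(fld, 0.0)
            out = O.angular_spectrum_propagate(
                O.angular_spectrum_propagate(bl, 17.0), -17.0
            )
            assert np.max(np.abs(out.data - bl.data)) < 1e-8

    def test_band_energy_conserved_for_many_fields(self, rng):
        for _ in range(20):
            fld = self._random_field(rng, n=32)
            bl = O.angular_spectrum_propagate(fld, 0.0)
            out = O.angular_spectrum_propagate(bl, 11.3)
            assert abs(out.energy() - bl.energy()) <= 1e-6 * bl.energy()

    def test_plane_wave_phase_advance(self):
        fld = O.ComplexField2D(np.ones((32, 32), complex), 0.5, 580.0)
        d = 7.0
        out = O.angular_spectrum_propagate(fld, d)
        lam = 0.58
        expected = np.exp(1j * 2 * np.pi * d / lam)
        np.testing.assert_allclose(out.data, expected, atol=1e-10)


class TestFLFMBandlimit:
    def test_constant_field_scaled_by_dc_gain(self):
        fld = O.ComplexField2D(np.full((32, 32), 2.0 + 0j), 0.5, 580.0)
        out = O.flfm_bandlimit(fld, cutoff=4.0)
        # DC-normalized response: constant passes unchanged
        np.testing.assert_allclose(out.data, fld.data, atol=1e-10)

    def test_white_noise_energy_beyond_cutoff_suppressed(self, rng):
        n, spacing, cutoff = 64, 0.5, 4.0
        fld = O.ComplexField2D(rng.normal(size=(n, n)), spacing, 580.0)
        out = O.flfm_bandlimit(fld, cutoff)
        spec = np.fft.fft2(out.data)
        f = np.fft.fftfreq(n, d=spacing)
        fyy, fxx = np.meshgrid(f, f, indexing="ij")
        fr = np.hypot(fyy, fxx)
        beyond = fr > 1.25 / cutoff
        ratio = np.sum(np.abs(spec[beyond]) ** 2) / np.sum(np.abs(spec) ** 2)
        assert ratio <= 1e-4

    def test_near_idempotent_on_passband(self, rng):
        n, spacing, cutoff = 64, 0.5, 8.0
        fld = O.ComplexField2D(rng.normal(size=(n, n)), spacing, 580.0)
        once = O.flfm_bandlimit(fld, cutoff)
        twice = O.flfm_bandlimit(once, cutoff)
        # compare passband content only
        spec1 = np.fft.fft2(once.data)
        spec2 = np.fft.fft2(twice.data)
        f = np.fft.fftfreq(n, d=spacing)
        fyy, fxx = np.meshgrid(f, f, indexing="ij")
        band = np.hypot(fyy, fxx) < 0.8 / cutoff
        rel = np.linalg.norm(spec2[band] - spec1[band]) / np.linalg.norm(spec1[band])
        assert rel <= 1e-6

    def test_invalid_cutoff(self, rng):
        fld = O.ComplexField2D(np.ones((8, 8), complex), 0.5, 580.0)
        with pytest.raises(O.InvalidConfigError):
            O.flfm_bandlimit(fld, 0.0)


class TestApertureOptimization:
    def _state(self, rng, n=16, lam1=0.0):
        pupil = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        target_p = O.aperture_profile(
            np.hypot(*np.meshgrid(*(np.linspace(-1, 1, n),) * 2, indexing="ij")),
            cutoff=0.6,
            order=4.0,
        ).transmission
        target = np.abs(np.fft.ifft2(pupil * target_p, norm="ortho")) ** 2
        p0 = np.clip(target_p + 0.2 * rng.normal(size=(n, n)), 0.0, 1.0)
        return O.ApertureOptState(
            profile=p0, pupil_field=pupil, psf_target=target, eta=5e-2, lam1=lam1
        )

    def test_objective_is_squared_frobenius_without_regularizer(self, rng):
        state = self._state(rng)
        sim = np.abs(np.fft.ifft2(state.pupil_field * state.profile, norm="ortho")) ** 2
        expected = np.sum((state.psf_target - sim) ** 2)
        assert O.aperture_objective(state) == pytest.approx(expected, rel=1e-12)

    def test_zero_gradient_at_exact_match(self, rng):
        state = self._state(rng)
        # make the target exactly the simulated PSF of the current profile
        state.psf_target = np.abs(
            np.fft.ifft2(state.pupil_field * state.profile, norm="ortho")
        ) ** 2
        assert O.aperture_objective(state) == pytest.approx(0.0, abs=1e-20)
        assert np.max(np.abs(O.aperture_gradient(state))) < 1e-12
        out = O.optimize_aperture(state, n_iter=3)
        np.testing.assert_array_equal(out.profile, state.profile)
        assert out.j_history[-1] == pytest.approx(0.0, abs=1e-18)

    def test_gradient_matches_finite_differences(self, rng):
        state = self._state(rng, lam1=1e-3)
        grad = O.aperture_gradient(state)
        for _ in range(6):
            i, j = rng.integers(0, 16, size=2)
            eps = 1e-6
            p = state.profile.copy()
            p[i, j] += eps
            jp = O.aperture_objective(state, p)
            p[i, j] -= 2 * eps
            jm = O.aperture_objective(state, p)
            fd = (jp - jm) / (2 * eps)
            assert grad[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_history_non_increasing_under_halving_rule(self, rng):
        state = self._state(rng, lam1=1e-4)
        out = O.optimize_aperture(state, n_iter=25)
        hist = np.array(out.j_history)
        assert np.all(np.diff(hist) <= 1e-15)
        assert hist[-1] < hist[0]


class TestDeskPSFs:
    def test_lfm_psf_shape_and_nonnegativity(self, desk_lfm):
        cfg, mla, psf = desk_lfm
        assert psf.data.shape == (cfg.n_depths, 12, 12, 5, 5)
        assert np.all(psf.data >= 0) and np.all(np.isfinite(psf.data))

    def test_lfm_psf_unit_sum_per_depth(self, desk_lfm):
        _, _, psf = desk_lfm
        sums = psf.data.reshape(psf.data.shape[0], -1).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)

    def test_lfm_psf_point_symmetry(self, desk_lfm):
        _, _, psf = desk_lfm
        mirrored = psf.data[:, ::-1, ::-1, ::-1, ::-1]
        assert np.max(np.abs(psf.data - mirrored)) <= 1e-8

    def test_flfm_weights_complex_off_focus(self, desk_flfm):
        cfg, _, psf = desk_flfm
        assert psf.weights.shape == (cfg.n_depths, 1, 1)
        defocused = np.abs(cfg.depth_grid_um) > 0.5
        assert np.any(np.abs(psf.weights[defocused, 0, 0].imag) > 1e-3)

    def test_flfm_depth_responses_invert_to_real_psfs(self, desk_flfm):
        cfg, _, psf = desk_flfm
        for k in range(0, cfg.n_depths, 3):
            p = psf.depth_psf(k)  # raises if the Hermitian check fails
            assert p.sum() == pytest.approx(1.0, rel=1e-9)
            assert p.min() > -1e-10
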