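"""Fourier phase recovery: spectra, sideband handling, unwrapping, OT."""

import numpy as np
import pytest

import holosperm as hs
from holosperm.reconstruct import (
    OpticsMeta,
    PhaseMap,
    filter_sideband,
    forward_spectrum,
    locate_sideband,
    phase_sensitivity,
    phase_to_ot,
    remove_background,
    unwrap_phase,
    wrapped_phase,
)
from conftest import phase_map_from


def cosine_image(fx, fy, n=128, amp=1.0, offset=2.0):
    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    return offset + amp * np.cos(2 * np.pi * (fx * cols + fy * rows))


class TestForwardSpectrum:
    def test_constant_image_is_pure_dc(self):
        spec = forward_spectrum(np.full((64, 64), 3.0))
        mag = np.abs(spec.values)
        iy, ix = np.unravel_index(mag.argmax(), mag.shape)
        assert spec.fx[ix] == 0.0 and spec.fy[iy] == 0.0
        assert mag.sum() == pytest.approx(mag.max(), rel=1e-9)

    def test_pure_cosine_gives_symmetric_peaks(self):
        spec = forward_spectrum(cosine_image(0.25, 0.125, offset=0.0))
        mag = np.abs(spec.values)
        peaks = np.argsort(mag.ravel())[-2:]
        coords = [np.unravel_index(p, mag.shape) for p in peaks]
        fs = sorted((spec.fx[ix], spec.fy[iy]) for iy, ix in coords)
        assert fs[0] == pytest.approx((-0.25, -0.125))
        assert fs[1] == pytest.approx((0.25, 0.125))

    def test_parseval_identity(self, rng):
        h = rng.random((64, 64))
        spec = forward_spectrum(h)
        assert np.sum(h**2) == pytest.approx(
            np.sum(np.abs(spec.values) ** 2) / h.size, rel=1e-12
        )

    def test_nan_pixels_rejected(self):
        h = np.ones((32, 32))
        h[3, 3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            forward_spectrum(h)


class TestLocateSideband:
    def test_recovers_synthetic_carrier_within_one_bin(self, noiseless_hologram):
        spec = forward_spectrum(noiseless_hologram)
        fx, fy = locate_sideband(spec)
        assert fx == pytest.approx(0.125, abs=1.0 / 512)
        assert fy == pytest.approx(0.125, abs=1.0 / 512)

    def test_agrees_with_bruteforce_argmax(self, noiseless_hologram):
        spec = forward_spectrum(noiseless_hologram)
        # independent oracle: exhaustive argmax over the upper half-plane
        mag = np.abs(spec.values)
        FX, FY = np.meshgrid(spec.fx, spec.fy)
        cand = ((FY > 0) | ((FY == 0) & (FX > 0))) & (np.hypot(FX, FY) > 0.05)
        brute = np.unravel_index(np.argmax(np.where(cand, mag, 0)), mag.shape)
        fx, fy = locate_sideband(spec)
        assert abs(FX[brute] - fx) <= 1.0 / 512
        assert abs(FY[brute] - fy) <= 1.0 / 512

    def test_fringe_free_image_raises(self):
        spec = forward_spectrum(np.full((64, 64), 5.0))
        with pytest.raises(ValueError, match="no sideband"):
            locate_sideband(spec)

    def test_nonpositive_guard_radius_rejected(self, noiseless_hologram):
        spec = forward_spectrum(noiseless_hologram)
        with pytest.raises(ValueError):
            locate_sideband(spec, dc_guard_radius=0.0)


class TestFilterSideband:
    def test_single_tone_gives_constant_magnitude(self):
        # bin-aligned tone (32 and 24 cycles over 128 px): no leakage
        spec = forward_spectrum(cosine_image(0.25, 0.1875))
        fld = filter_sideband(spec, (0.25, 0.1875), radius=0.05)
        mag = np.abs(fld.values)
        assert mag.std() / mag.mean() < 0.01
        assert fld.carrier_removed

    def test_zero_radius_rejected(self):
        spec = forward_spectrum(cosine_image(0.2, 0.15))
        with pytest.raises(ValueError, match="radius"):
            filter_sideband(spec, (0.2, 0.15), radius=0.0)

    def test_window_overlapping_dc_rejected(self):
        spec = forward_spectrum(cosine_image(0.2, 0.15))
        with pytest.raises(ValueError, match="DC"):
            filter_sideband(spec, (0.2, 0.15), radius=0.3, window="hard")
        with pytest.raises(ValueError, match="DC"):
            filter_sideband(spec, (0.2, 0.15), radius=0.2, window="gaussian")

    def test_unknown_window_rejected(self):
        spec = forward_spectrum(cosine_image(0.2, 0.15))
        with pytest.raises(ValueError, match="window"):
            filter_sideband(spec, (0.2, 0.15), radius=0.05, window="boxcar")


class TestWrappedPhase:
    def test_constant_unit_phasor(self):
        from holosperm.reconstruct import ComplexField

        fld = ComplexField(np.full((8, 8), np.exp(1j * 1.0)), True)
        pm = wrapped_phase(fld)
        np.testing.assert_allclose(pm.values, 1.0)
        assert pm.wrapped

    def test_real_positive_gives_zero(self):
        from holosperm.reconstruct import ComplexField

        pm = wrapped_phase(ComplexField(np.ones((4, 4), complex), True))
        np.testing.assert_allclose(pm.values, 0.0)

    def test_wraps_beyond_pi_to_principal_value(self):
        from holosperm.reconstruct import ComplexField

        fld = ComplexField(np.full((4, 4), np.exp(1j * (np.pi + 0.1))), True)
        np.testing.assert_allclose(wrapped_phase(fld).values, -np.pi + 0.1, atol=1e-12)

    def test_zero_magnitude_pixels_counted_and_zeroed(self):
        from holosperm.reconstruct import ComplexField

        v = np.full((4, 4), np.exp(1j * 0.5))
        v[0, 0] = 0.0
        pm = wrapped_phase(ComplexField(v, True))
        assert pm.n_zero_magnitude == 1
        assert pm.values[0, 0] == 0.0


class TestUnwrapPhase:
    def test_recovers_6pi_ramp(self):
        ramp = np.tile(np.linspace(0, 6 * np.pi, 256), (64, 1))
        wrapped = np.angle(np.exp(1j * ramp))
        uw = unwrap_phase(phase_map_from(wrapped, wrapped=True, corrected=False)).values
        # up to a global 2*pi*k offset
        k = np.round((uw - ramp).mean() / (2 * np.pi))
        assert np.abs(uw - ramp - 2 * np.pi * k).max() < 1e-6

    def test_smooth_field_in_principal_range_unchanged(self, rng):
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(rng.normal(0, 0.3, (64, 64)), 5)
        pm = phase_map_from(field, wrapped=True, corrected=False)
        np.testing.assert_allclose(unwrap_phase(pm).values, field, atol=1e-9)

    def test_gaussian_bump_peak_recovered(self):
        yy, xx = np.mgrid[0:128, 0:128]
        bump = 4.0 * np.exp(-(((xx - 64) / 12.0) ** 2 + ((yy - 64) / 12.0) ** 2))
        wrapped = np.angle(np.exp(1j * bump))
        uw = unwrap_phase(phase_map_from(wrapped, wrapped=True, corrected=False)).values
        assert uw.max() == pytest.approx(4.0, abs=0.01)

    def test_congruent_with_wrapped_input_mod_2pi(self, rng):
        field = np.cumsum(rng.normal(0.2, 0.3, (32, 32)), axis=1)
        wrapped = np.angle(np.exp(1j * field))
        pm = phase_map_from(wrapped, wrapped=True, corrected=False)
        uw = unwrap_phase(pm).values
        resid = (uw - wrapped) / (2 * np.pi)
        np.testing.assert_allclose(resid, np.round(resid), atol=1e-9)

    def test_rejects_unwrapped_input(self):
        pm = phase_map_from(np.zeros((8, 8)), wrapped=False)
        with pytest.raises(ValueError):
            unwrap_phase(pm)


class TestRemoveBackground:
    def test_tilted_plane_removed_to_numerical_zero(self):
        yy, xx = np.mgrid[0:64, 0:64]
        plane = 0.01 * xx - 0.02 * yy + 0.5
        pm = phase_map_from(plane, wrapped=False, corrected=False)
        out = remove_background(pm, object_mask=np.zeros((64, 64), bool))
        assert out.values.std() < 1e-9
        assert out.background_corrected

    def test_zero_field_stays_zero(self):
        pm = phase_map_from(np.zeros((32, 32)), wrapped=False, corrected=False)
        out = remove_background(pm, object_mask=np.zeros((32, 32), bool))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_phantom_recovered_under_plane_tilt(self, default_phantom):
        yy, xx = np.mgrid[0:512, 0:512]
        tilt = 0.002 * xx - 0.003 * yy + 0.3
        pm = phase_map_from(default_phantom.phase + tilt, wrapped=False,
                            corrected=False)
        out = remove_background(pm)
        err = out.values - default_phantom.phase
        assert np.sqrt(np.mean(err**2)) < 0.02

    def test_small_background_region_rejected(self):
        pm = phase_map_from(np.zeros((16, 16)), wrapped=False, corrected=False)
        mask = np.ones((16, 16), bool)
        mask[0, 0] = False
        with pytest.raises(ValueError, match="background region too small"):
            remove_background(pm, object_mask=mask)


class TestPhaseSensitivity:
    def test_constant_region_is_zero(self):
        pm = phase_map_from(np.full((32, 32), 0.7))
        assert phase_sensitivity(pm, np.ones((32, 32), bool)) < 1e-9

    def test_injected_gaussian_noise_measured_in_mrad(self, rng):
        pm = phase_map_from(rng.normal(0, 0.02, (100, 100)))
        s = phase_sensitivity(pm, np.ones((100, 100), bool))
        assert s == pytest.approx(20.0, abs=2.0)

    def test_empty_region_rejected(self):
        pm = phase_map_from(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            phase_sensitivity(pm, np.zeros((8, 8), bool))

    def test_pseudo_thermal_preset_matches_reported_band(self, default_phantom):
        holo = hs.synthesize_hologram(
            default_phantom, illum=hs.PSEUDO_THERMAL_PRESET, seed=0
        )
        pm = hs.reconstruct_phase(holo)
        s = phase_sensitivity(pm, default_phantom.background_mask(2.0))
        assert 18.5 <= s <= 21.5

    def test_coherent_preset_near_300_mrad(self, default_phantom):
        holo = hs.synthesize_hologram(
            default_phantom, illum=hs.COHERENT_PRESET, seed=0
        )
        pm = hs.reconstruct_phase(holo)
        s = phase_sensitivity(pm, default_phantom.background_mask(2.0))
        assert 200.0 <= s <= 400.0


class TestPhaseToOT:
    def test_zero_phase_zero_ot(self):
        ot = phase_to_ot(phase_map_from(np.zeros((8, 8))))
        np.testing.assert_allclose(ot.values, 0.0)

    def test_reflection_value_at_4_rad(self):
        ot = phase_to_ot(phase_map_from(np.full((4, 4), 4.0)))
        expected = 4.0 * 632.8 / (4 * np.pi)  # ~201.4 nm
        np.testing.assert_allclose(ot.values, expected, rtol=1e-12)
        assert ot.values[0, 0] == pytest.approx(201.4, abs=0.1)

    def test_transmission_doubles_reflection(self):
        pm = phase_map_from(np.full((4, 4), 1.3))
        refl = phase_to_ot(pm, geometry="reflection")
        trans = phase_to_ot(pm, geometry="transmission")
        np.testing.assert_allclose(trans.values, 2 * refl.values, rtol=1e-12)

    def test_missing_wavelength_rejected(self):
        pm = phase_map_from(np.zeros((4, 4)))
        pm.meta = OpticsMeta(wavelength_nm=0.0)
        with pytest.raises(ValueError, match="wavelength"):
            phase_to_ot(pm)


class TestRoundTripAndLinearity:
    def test_noiseless_roundtrip_rmse(self, default_phantom, reconstructed_noiseless):
        b = 16
        err = (
            reconstructed_noiseless.values[b:-b, b:-b]
            - default_phantom.phase[b:-b, b:-b]
        )
        assert np.sqrt(np.mean(err**2)) < 0.02

    def test_doubling_phantom_phase_doubles_reconstruction(self):
        import dataclasses
        from holosperm.phantom import PhantomConfig

        means = {}
        for k in (1.0, 2.0):
            cfg = dataclasses.replace(
                PhantomConfig(), head_peak_phase_rad=2.0 * k,
                midpiece_phase_rad=0.65 * k, tail_phase_rad=0.15 * k,
            )
            ph = hs.make_phantom(cfg)
            holo = hs.synthesize_hologram(ph, illum=hs.IlluminationModel.noiseless())
            pm = hs.reconstruct_phase(holo, window="hard", radius_frac=0.65)
            means[k] = pm.values[ph.head_mask].mean()
        assert means[2.0] / means[1.0] == pytest.approx(2.0, rel=0.01)

    def test_coherent_noisier_than_pseudo_thermal(self, default_phantom):
        bg = default_phantom.background_mask(2.0)
        hc = hs.synthesize_hologram(default_phantom, illum=hs.COHERENT_PRESET, seed=5)
        hp = hs.synthesize_hologram(
            default_phantom, illum=hs.PSEUDO_THERMAL_PRESET, seed=5
        )
        sc = phase_sensitivity(hs.reconstruct_phase(hc), bg)
        sp = phase_sensitivity(hs.reconstruct_phase(hp), bg)
        assert sc > sp
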