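"""Off-axis interferogram synthesis and Fourier-sideband reconstruction."""

import numpy as np
import pytest

from cimphase.dpm import (CarrierSpec, DpmNoise, NoCarrierError, estimate_carrier,
                          reconstruct_dpm, synthesize_interferogram, unwrap_phase,
                          wavelength_normalize)
from cimphase.scene import PhaseScene, make_bead_scene, peak_phase


def flat_scene(grid=64, wavelength=0.532):
    return PhaseScene(np.zeros((grid, grid)), pixel_size=0.1, wavelength=wavelength)


class TestSynthesis:
    def test_flat_scene_two_beam_closed_form(self):
        carrier = CarrierSpec(0.25, 0.0)
        ig = synthesize_interferogram(flat_scene(), carrier=carrier)
        ny, nx = ig.intensity.shape
        xx = np.arange(nx)[None, :] * np.ones((ny, 1))
        expected = 2.0 + 2.0 * np.cos(2 * np.pi * 0.25 * xx)
        assert np.allclose(ig.intensity, expected, atol=1e-10)
        assert ig.intensity.mean() == pytest.approx(2.0)
        assert ig.intensity.min() == pytest.approx(0.0, abs=1e-10)
        assert ig.intensity.max() == pytest.approx(4.0)

    def test_flat_scene_spectrum_has_three_peaks(self):
        ig = synthesize_interferogram(flat_scene(), carrier=CarrierSpec(0.25, 0.0))
        mag = np.abs(np.fft.fft2(ig.intensity))
        peaks = np.argwhere(mag > 1e-6 * mag.max())
        assert len(peaks) == 3  # DC and +-carrier

    def test_seeded_noise_determinism(self):
        noise = DpmNoise(speckle_contrast=0.3, background_phase_amp=0.5, shot_sigma=0.02, seed=42)
        a = synthesize_interferogram(flat_scene(), noise=noise)
        b = synthesize_interferogram(flat_scene(), noise=noise)
        assert np.array_equal(a.intensity, b.intensity)

    def test_carrier_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            CarrierSpec(0.4, 0.4)

    def test_default_metadata(self):
        ig = synthesize_interferogram(flat_scene())
        assert ig.wavelength == pytest.approx(0.532)
        assert ig.exposure_ms == pytest.approx(2.0)


class TestEstimateCarrier:
    @pytest.mark.parametrize("fx,fy", [(0.2, 0.0), (0.15, 0.15)])
    def test_recovers_carrier_within_one_bin(self, fx, fy):
        grid = 128
        ig = synthesize_interferogram(flat_scene(grid), carrier=CarrierSpec(fx, fy))
        est = estimate_carrier(ig)
        assert abs(est.fx - fx) <= 1.0 / grid + 1e-12
        assert abs(est.fy - fy) <= 1.0 / grid + 1e-12

    def test_constant_image_raises(self):
        from cimphase.dpm import Interferogram
        ig = Interferogram(np.ones((64, 64)), carrier=None)
        with pytest.raises(NoCarrierError):
            estimate_carrier(ig)


class TestReconstruction:
    def test_flat_scene_reconstructs_to_zero(self):
        ig = synthesize_interferogram(flat_scene(128))
        pm = reconstruct_dpm(ig)
        assert pm.modality == "DPM"
        assert np.max(np.abs(pm.phase)) < 1e-6

    def test_bead_peak_after_wavelength_normalization(self, bead):
        # green-laser acquisition, normalized by the wavelength ratio to the
        # red-LED scale; the projected-sphere peak must come back at 0.71 rad
        scene = make_bead_scene(bead, grid=512, pixel_size=0.025)
        ig = synthesize_interferogram(scene)  # lambda = 0.532 um
        pm = wavelength_normalize(reconstruct_dpm(ig), 0.623)
        assert pm.wavelength == pytest.approx(0.623)
        assert pm.phase.max() == pytest.approx(0.71, rel=0.02)

    @pytest.mark.parametrize("seed", range(3))
    def test_round_trip_rmse_below_one_percent(self, smooth_scene_factory, seed):
        scene = smooth_scene_factory(seed, grid=128, max_phase=1.0, wavelength=0.532)
        ig = synthesize_interferogram(scene)
        # no background in the forward model, so no background model in the inverse
        pm = reconstruct_dpm(ig, background_poly_order=None)
        truth = scene.phase - np.median(scene.phase)
        rmse = np.sqrt(np.mean((pm.phase - truth) ** 2))
        assert rmse < 0.01 * np.ptp(scene.phase)

    def test_insensitive_to_global_intensity_scale(self, smooth_scene_factory):
        from cimphase.dpm import Interferogram
        scene = smooth_scene_factory(5, grid=128, max_phase=0.8, wavelength=0.532)
        ig = synthesize_interferogram(scene)
        scaled = Interferogram(ig.intensity * 37.5, ig.carrier, ig.wavelength)
        assert np.allclose(reconstruct_dpm(ig).phase, reconstruct_dpm(scaled).phase, atol=1e-9)

    def test_calibration_frame_subtraction(self, smooth_scene_factory):
        # with a shared deterministic background, subtracting the no-sample
        # reference removes it without any polynomial model
        scene = smooth_scene_factory(7, grid=128, max_phase=0.8, wavelength=0.532)
        noise = DpmNoise(background_phase_amp=0.8, seed=3)
        ig = synthesize_interferogram(scene, noise=noise)
        ref = synthesize_interferogram(flat_scene(128), noise=noise)
        pm = reconstruct_dpm(ig, background=ref, background_poly_order=None)
        truth = scene.phase - np.median(scene.phase)
        rmse = np.sqrt(np.mean((pm.phase - truth) ** 2))
        assert rmse < 0.01 * np.ptp(scene.phase)

    def test_speckle_raises_background_noise(self, smooth_scene_factory):
        scene = smooth_scene_factory(9, grid=128, max_phase=0.8, wavelength=0.532)
        clean = reconstruct_dpm(synthesize_interferogram(scene))
        speckled = reconstruct_dpm(synthesize_interferogram(
            scene, noise=DpmNoise(speckle_contrast=0.3, speckle_correlation_px=4.0, seed=1)))
        resid_clean = np.std(clean.phase - (scene.phase - np.median(scene.phase)))
        resid_speckled = np.std(speckled.phase - (scene.phase - np.median(scene.phase)))
        assert resid_speckled > resid_clean


class TestUnwrap:
    def test_in_range_input_is_identity(self):
        rng = np.random.default_rng(0)
        from scipy import ndimage
        x = ndimage.gaussian_filter(rng.standard_normal((64, 64)), 8)
        x *= 1.2 / np.abs(x).max()  # range < 2*pi, inside (-pi, pi]
        assert np.allclose(unwrap_phase(x), x, atol=1e-9)

    def test_linear_ramp_recovered(self):
        n = 128
        ramp = np.linspace(0, 6 * np.pi, n)[None, :] * np.ones((n, 1))
        wrapped = np.angle(np.exp(1j * ramp))
        un = unwrap_phase(wrapped)
        offset = un - ramp
        assert np.ptp(offset) < 1e-6           # exact up to one global constant
        assert np.allclose(offset[0, 0] % (2 * np.pi), 0, atol=1e-6) or \
            np.allclose(offset[0, 0] % (2 * np.pi), 2 * np.pi, atol=1e-6)

    def test_unwrap_wrap_congruence(self, smooth_scene_factory):
        x = smooth_scene_factory(3, grid=64, max_phase=9.0).phase
        wrapped = np.angle(np.exp(1j * x))
        diff = unwrap_phase(wrapped) - x
        assert np.ptp(diff) < 1e-6
        k = diff[0, 0] / (2 * np.pi)
        assert abs(k - round(k)) < 1e-6
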