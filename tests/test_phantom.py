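"""Synthetic phantoms and the simulated acquisition chain."""

import numpy as np
import pytest

from oximap.errors import PhantomError, UnmixingError
from oximap.optics import SkinParams, forward_reflectance
from oximap.phantom import (
    NoiseModel,
    PhantomSpec,
    generate_parameter_maps,
    led_illumination_gains,
    make_sensitivity_fixture,
    monochromator_sweep,
    occlusion_series,
    render_reflectance_cube,
    simulate_sensor,
)
from oximap.preprocess import (
    DEFAULT_CHANNEL_CENTERS,
    calibrate_reflectance,
    demosaic,
    spectral_response_auc,
    unmix,
)


def patch_params(so2, b=2e-3):
    return SkinParams(B=b, SO2=so2, M=0.02, d_e_um=90.0)


class TestParameterMaps:
    def test_single_patch_constant_maps(self):
        spec = PhantomSpec(patches=[patch_params(0.7)], shape=(16, 24))
        truth = generate_parameter_maps(spec)
        assert np.all(truth.maps["SO2"] == 0.7)
        assert np.all(truth.label_map == 0)

    def test_explicit_half_plane_layout(self):
        layout = np.zeros((10, 20), dtype=int)
        layout[:, 10:] = 1
        spec = PhantomSpec(patches=[patch_params(0.3), patch_params(0.9)],
                           shape=(10, 20), layout=layout)
        truth = generate_parameter_maps(spec)
        assert np.all(truth.maps["SO2"][:, :10] == 0.3)
        assert np.all(truth.maps["SO2"][:, 10:] == 0.9)

    def test_blob_area_fractions(self):
        spec = PhantomSpec(patches=[patch_params(0.3), patch_params(0.9)],
                           fractions=[0.35, 0.65], shape=(272, 272), seed=2)
        truth = generate_parameter_maps(spec)
        fracs = truth.patch_table["area_fraction"].to_numpy()
        np.testing.assert_allclose(fracs, [0.35, 0.65], atol=0.02)

    def test_deterministic_given_seed(self):
        spec = PhantomSpec(patches=[patch_params(0.3), patch_params(0.9)],
                           shape=(64, 64), seed=9)
        a = generate_parameter_maps(spec)
        b = generate_parameter_maps(spec)
        assert np.array_equal(a.label_map, b.label_map)

    def test_zero_area_patch_rejected(self):
        layout = np.zeros((8, 8), dtype=int)
        spec = PhantomSpec(patches=[patch_params(0.3), patch_params(0.9)],
                           shape=(8, 8), layout=layout)
        with pytest.raises(PhantomError, match="zero-area"):
            generate_parameter_maps(spec)


class TestRendering:
    def test_uniform_truth_constant_cube(self, table, bands):
        spec = PhantomSpec(patches=[patch_params(0.8)], shape=(6, 8))
        truth = generate_parameter_maps(spec)
        cube = render_reflectance_cube(truth, bands, table)
        for plane in cube.data:
            assert np.ptp(plane) == 0.0

    def test_matches_per_pixel_forward_evaluation(self, table, bands):
        layout = np.zeros((4, 6), dtype=int)
        layout[2:, 3:] = 1
        patches = [patch_params(0.35, b=4e-3), patch_params(0.95)]
        spec = PhantomSpec(patches=patches, shape=(4, 6), layout=layout)
        truth = generate_parameter_maps(spec)
        cube = render_reflectance_cube(truth, bands, table)
        for i in range(4):
            for j in range(6):
                expected = forward_reflectance(patches[layout[i, j]],
                                               bands, table)
                np.testing.assert_array_equal(cube.data[:, i, j], expected)

    def test_so2_contrast_band_structure(self, table, bands):
        """SO2 contrast is minimal at the near-isosbestic 532 nm band and
        strongest in the 593-625 nm group where oxy/deoxy absorption
        differences dominate."""
        lo = forward_reflectance(patch_params(0.2), bands, table)
        hi = forward_reflectance(patch_params(0.9), bands, table)
        d = np.abs(hi - lo)
        assert bands[np.argmin(d)] == 532.0
        assert bands[np.argmax(d)] >= 593.0


class TestSensitivityFixture:
    def test_zero_crosstalk_collapses_to_diagonal(self, sens_clean):
        m = sens_clean.mixing_matrix()
        np.testing.assert_allclose(m, np.eye(16), rtol=0, atol=1e-9)

    def test_crosstalk_collapses_to_adjacency(self, sens_crosstalk):
        m = sens_crosstalk.mixing_matrix()
        expected = np.eye(16) + 0.2 * (np.eye(16, k=1) + np.eye(16, k=-1))
        np.testing.assert_allclose(m, expected, rtol=0, atol=1e-7)

    def test_rank_deficient_configuration_rejected(self):
        centers = (507.0, 507.0) + DEFAULT_CHANNEL_CENTERS[2:]
        with pytest.raises(UnmixingError):
            make_sensitivity_fixture(centers=centers, crosstalk=0.1)

    def test_sweep_curves_peak_near_own_channel(self, sens_crosstalk):
        """Mixed responses peak within the main lobe (side lobes can pull the
        peak a few nm); unmixed responses re-center onto the sweep grid."""
        in_range = [c for c in sens_crosstalk.channel_centers_nm
                    if 500 <= c <= 625]
        mixed = monochromator_sweep(sens_crosstalk, 500, 625, 2)
        unmixed = monochromator_sweep(sens_crosstalk, 500, 625, 2, unmixed=True)
        assert len(mixed) == len(unmixed) == len(in_range)
        for curve, center in zip(mixed, in_range):
            peak_wl = curve.wavelengths_nm[np.argmax(curve.values)]
            assert abs(peak_wl - center) <= 7.5  # within the 15 nm FWHM lobe
        for curve, center in zip(unmixed, in_range):
            peak_wl = curve.wavelengths_nm[np.argmax(curve.values)]
            assert abs(peak_wl - center) <= 2.0  # sweep-grid resolution

    def test_unmixing_sharpens_response_curves(self, sens_crosstalk):
        mixed = [spectral_response_auc(c)
                 for c in monochromator_sweep(sens_crosstalk)]
        unmixed = [spectral_response_auc(c)
                   for c in monochromator_sweep(sens_crosstalk, unmixed=True)]
        assert all(u < m for u, m in zip(unmixed, mixed))
        factor = np.mean(mixed) / np.mean(unmixed)
        assert 1.0 < factor < 3.0  # order of the reported improvement


class TestSensorSimulation:
    def _scene(self, table, shape=(16, 32)):
        spec = PhantomSpec(patches=[patch_params(0.4), patch_params(0.9)],
                           shape=shape, seed=1)
        truth = generate_parameter_maps(spec)
        return render_reflectance_cube(truth, DEFAULT_CHANNEL_CENTERS, table)

    def test_noiseless_chain_recovers_reflectance(self, table, sens_crosstalk):
        scene = self._scene(table)
        raw, white, dark = simulate_sensor(
            scene, sens_crosstalk, noise=NoiseModel.noiseless(quantize=False))
        cubes = [demosaic(f, sens_crosstalk.channel_centers_nm)
                 for f in (raw, white, dark)]
        cubes = [unmix(c, sens_crosstalk) for c in cubes]
        refl = calibrate_reflectance(*cubes)
        np.testing.assert_allclose(refl.data, scene.data, atol=1e-6)

    def test_dark_frame_statistics(self, table, sens_crosstalk):
        scene = self._scene(table, shape=(272, 272))
        noise = NoiseModel(read_sigma=2.0, dark_offset=8.0)
        _, _, dark = simulate_sensor(scene, sens_crosstalk, noise=noise, seed=4)
        px = np.asarray(dark.pixels, dtype=float)
        assert abs(px.mean() - 8.0) / 8.0 < 0.05
        assert abs(px.std() - 2.0) / 2.0 < 0.05

    def test_exposure_linearity(self, table, sens_crosstalk):
        scene = self._scene(table)
        noise = NoiseModel.noiseless(quantize=False)
        out1 = simulate_sensor(scene, sens_crosstalk, noise=noise,
                               target_white_counts=400.0)
        out2 = simulate_sensor(scene, sens_crosstalk, noise=noise,
                               target_white_counts=800.0)
        sig1 = np.asarray(out1[0].pixels, float) - noise.dark_offset
        sig2 = np.asarray(out2[0].pixels, float) - noise.dark_offset
        np.testing.assert_allclose(sig2, 2.0 * sig1, rtol=1e-12)

    def test_bit_identical_given_seed(self, table, sens_crosstalk):
        scene = self._scene(table)
        a = simulate_sensor(scene, sens_crosstalk, seed=7)
        b = simulate_sensor(scene, sens_crosstalk, seed=7)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.pixels, fb.pixels)

    def test_saturation_warning(self, table, sens_crosstalk):
        scene = self._scene(table)
        with pytest.warns(UserWarning, match="full scale"):
            simulate_sensor(scene, sens_crosstalk,
                            noise=NoiseModel.noiseless(),
                            target_white_counts=5000.0)

    def test_led_gains_shape(self):
        g = led_illumination_gains()
        assert g.shape == (16,) and g.max() == 1.0 and np.all(g > 0)


def test_occlusion_series_structure():
    series = occlusion_series(base_seed=0)
    assert len(series) == 3
    mean_so2 = [np.dot(s.fractions, [p.SO2 for p in s.patches])
                for s in series]
    assert mean_so2[1] < mean_so2[0] and mean_so2[2] > mean_so2[1]
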