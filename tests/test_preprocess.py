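"""Sensor preprocessing: demosaic, unmixing, calibration, band selection,
crop/mask and the response-quality metric."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oximap.errors import (
    BandSelectionError,
    CalibrationReferenceError,
    ShapeError,
    UnmixingError,
)
from oximap.phantom import make_sensitivity_fixture
from oximap.preprocess import (
    DEFAULT_CHANNEL_CENTERS,
    RawMosaicFrame,
    ReflectanceCube,
    ResponseCurve,
    SpectralCube,
    calibrate_reflectance,
    crop_and_mask,
    default_band_layout,
    demosaic,
    disk_mask,
    remosaic,
    select_bands,
    spectral_response_auc,
    unmix,
)


def make_cube(data, centers=None):
    data = np.asarray(data, dtype=float)
    if centers is None:
        centers = DEFAULT_CHANNEL_CENTERS[: data.shape[0]]
    return SpectralCube(data, centers)


class TestDemosaic:
    def test_default_geometry(self):
        frame = RawMosaicFrame(np.zeros((1088, 2048), dtype=np.uint16))
        cube = demosaic(frame)
        assert cube.data.shape == (16, 272, 512)

    def test_constant_frame_gives_constant_planes(self):
        frame = RawMosaicFrame(np.full((8, 8), 7, dtype=np.uint16))
        cube = demosaic(frame)
        assert np.all(cube.data == 7)

    def test_index_bookkeeping_oracle(self):
        """8x8 raster-order frame: each band plane is the 2x2 sub-grid of its
        mosaic position, checked by an explicit double loop."""
        px = np.arange(64, dtype=np.uint16).reshape(8, 8)
        layout = default_band_layout(4)
        cube = demosaic(RawMosaicFrame(px, band_layout=layout))
        for (r, c), ch in layout.items():
            for i in range(2):
                for j in range(2):
                    assert cube.data[ch, i, j] == px[4 * i + r, 4 * j + c]

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ShapeError):
            demosaic(RawMosaicFrame(np.zeros((10, 8), dtype=np.uint16)))

    @given(st.integers(0, 2**31 - 1))
    def test_remosaic_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 1024, size=(16, 16)).astype(np.uint16)
        # random bijective layout
        chans = rng.permutation(16)
        layout = {(r, c): int(chans[4 * r + c])
                  for r in range(4) for c in range(4)}
        cube = demosaic(RawMosaicFrame(px, band_layout=layout))
        assert np.array_equal(remosaic(cube, layout), px)


class TestUnmix:
    def test_identity_sensitivity_is_noop(self, sens_clean):
        rng = np.random.default_rng(0)
        cube = make_cube(rng.random((16, 4, 5)))
        out = unmix(cube, sens_clean)
        assert out.provenance == "unmixed"
        np.testing.assert_allclose(out.data, cube.data, rtol=0, atol=1e-12)

    def test_recovers_forward_mixed_spectra(self, sens_crosstalk):
        m = sens_crosstalk.mixing_matrix()
        rng = np.random.default_rng(1)
        true = rng.random((16, 3, 4)) + 0.1
        mixed = (m @ true.reshape(16, -1)).reshape(16, 3, 4)
        out = unmix(make_cube(mixed), sens_crosstalk)
        np.testing.assert_allclose(out.data, true, rtol=1e-9)

    def test_ill_conditioned_matrix_reports_condition_number(self, sens_crosstalk):
        cube = make_cube(np.ones((16, 2, 2)))
        with pytest.raises(UnmixingError, match="condition number"):
            unmix(cube, sens_crosstalk, cond_threshold=1.0)


class TestCalibration:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.white = make_cube(rng.uniform(500, 900, (16, 6, 8)))
        self.dark = make_cube(rng.uniform(5, 12, (16, 6, 8)))

    def test_white_input_gives_spectralon_reflectance(self):
        r = calibrate_reflectance(self.white, self.white, self.dark)
        assert np.all(r.data == 0.99)

    def test_dark_input_gives_zero(self):
        r = calibrate_reflectance(self.dark, self.white, self.dark)
        assert np.all(r.data == 0.0)

    def test_halfway_input(self):
        mid = make_cube((self.white.data + self.dark.data) / 2)
        r = calibrate_reflectance(mid, self.white, self.dark)
        np.testing.assert_allclose(r.data, 0.495, rtol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_illumination_flattening(self, seed):
        """A common positive gain field on measurement and white cancels."""
        rng = np.random.default_rng(seed)
        gain = rng.uniform(0.2, 5.0, size=(6, 8))
        i0 = rng.uniform(50, 400, (16, 6, 8))
        w0 = i0 + rng.uniform(50, 300, (16, 6, 8))
        zero = make_cube(np.zeros_like(i0))
        r_flat = calibrate_reflectance(make_cube(i0), make_cube(w0), zero)
        r_gain = calibrate_reflectance(make_cube(i0 * gain),
                                       make_cube(w0 * gain), zero)
        np.testing.assert_allclose(r_gain.data, r_flat.data, rtol=1e-10)

    def test_bad_reference_rejected(self):
        with pytest.raises(CalibrationReferenceError):
            calibrate_reflectance(self.white, self.dark, self.white)

    def test_isolated_bad_pixels_masked(self):
        white = make_cube(self.white.data.copy())
        white.data[:, 0, 0] = 0.0  # one dead reference pixel out of 48
        r = calibrate_reflectance(self.dark, white, self.dark,
                                  bad_pixel_tol=0.05)
        assert not r.roi_mask[0, 0] and r.roi_mask.sum() == 47


class TestBandSelection:
    def test_default_ten_bands(self):
        cube = make_cube(np.zeros((16, 2, 2)))
        out = select_bands(cube)
        np.testing.assert_array_equal(
            out.band_centers_nm,
            [507, 518, 532, 544, 568, 580, 593, 604, 617, 625])

    def test_identity_on_existing_centers(self):
        cube = make_cube(np.arange(16 * 4).reshape(16, 2, 2).astype(float))
        out = select_bands(cube, DEFAULT_CHANNEL_CENTERS)
        np.testing.assert_array_equal(out.data, cube.data)

    def test_nearest_neighbor_rule(self):
        cube = SpectralCube(np.zeros((2, 2, 2)), [507.0, 518.0])
        out = select_bands(cube, [510.0])
        assert out.band_centers_nm.tolist() == [507.0]

    def test_idempotent(self):
        cube = make_cube(np.random.default_rng(3).random((16, 2, 2)))
        once = select_bands(cube)
        twice = select_bands(once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_ambiguous_targets_rejected(self):
        cube = SpectralCube(np.zeros((2, 2, 2)), [507.0, 518.0])
        with pytest.raises(BandSelectionError, match="ambiguous"):
            select_bands(cube, [508.0, 509.0])

    def test_out_of_range_target_rejected(self):
        cube = SpectralCube(np.zeros((2, 2, 2)), [507.0, 518.0])
        with pytest.raises(BandSelectionError):
            select_bands(cube, [700.0])


class TestCropAndMask:
    def _refl(self, h, w):
        return ReflectanceCube(np.random.default_rng(4).random((3, h, w)),
                               [507.0, 518.0, 532.0],
                               np.ones((h, w), dtype=bool))

    def test_default_geometry_crop(self):
        out = crop_and_mask(self._refl(272, 512))
        assert out.data.shape == (3, 272, 272)

    def test_square_input_is_spatial_identity(self):
        cube = self._refl(32, 32)
        out = crop_and_mask(cube)
        np.testing.assert_array_equal(out.data, cube.data)

    @pytest.mark.parametrize("side", [7, 8, 272])
    def test_disk_pixel_count_matches_brute_force(self, side):
        mask = disk_mask(side)
        c = (side - 1) / 2.0
        r2 = (side / 2.0) ** 2
        count = sum((i - c) ** 2 + (j - c) ** 2 <= r2
                    for i in range(side) for j in range(side))
        assert mask.sum() == count

    def test_tall_input_rejected(self):
        with pytest.raises(ShapeError):
            crop_and_mask(self._refl(64, 32))


class TestResponseAuc:
    def test_rectangle_area(self):
        wl = np.linspace(0, 30, 3001)
        v = ((wl >= 10) & (wl <= 20)).astype(float)
        auc = spectral_response_auc(ResponseCurve(wl, v))
        assert abs(auc - 10.0) < 0.02

    def test_gaussian_closed_form(self):
        wl = np.arange(500.0, 560.0, 0.1)
        v = np.exp(-0.5 * ((wl - 530) / 4.0) ** 2)
        auc = spectral_response_auc(ResponseCurve.from_samples(wl, v))
        assert abs(auc - 4.0 * np.sqrt(2 * np.pi)) / auc < 1e-3

    def test_side_lobe_strictly_increases_auc(self):
        wl = np.arange(500.0, 560.0, 0.5)
        main = np.exp(-0.5 * ((wl - 520) / 4.0) ** 2)
        lobed = main + 0.3 * np.exp(-0.5 * ((wl - 540) / 4.0) ** 2)
        assert spectral_response_auc(ResponseCurve.from_samples(wl, lobed)) > \
            spectral_response_auc(ResponseCurve.from_samples(wl, main))

    def test_grid_refinement_invariance(self):
        coarse = np.arange(500.0, 560.0, 2.0)
        fine = np.arange(500.0, 558.1, 0.1)
        def auc(wl):
            v = np.exp(-0.5 * ((wl - 530) / 5.0) ** 2)
            return spectral_response_auc(ResponseCurve.from_samples(wl, v))
        assert abs(auc(coarse) - auc(fine)) / auc(fine) < 0.005

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spectral_response_auc(ResponseCurve([500.0, 510.0], [0.5, 1.0]))
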