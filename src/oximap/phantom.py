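"""Synthetic skin phantoms and full acquisition-chain simulation.

Ground-truth phantoms are piecewise-constant maps of the skin parameters
(blood fraction, oxygen saturation, melanosome fraction, epidermis
thickness).  The two-layer diffuse model renders them into reflectance
cubes, and the sensor simulator applies the acquisition chain in the
forward direction: per-band illumination gains (two-LED cyan/lime
illuminator by default), channel cross-talk mixing, shot and read noise,
mosaic interleaving and 10-bit quantization, together with matching white
(99 % reflectance target) and dark reference frames.  Running the
preprocessing pipeline on the noiseless output recovers the scene
reflectance, which makes every downstream stage testable without hardware.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .diagnostics import mottling_index, so2_weighted_mean
from .errors import PhantomError, UnmixingError
from .optics import ChromophoreTable, SkinParams, forward_reflectance
from .preprocess import (
    DEFAULT_CHANNEL_CENTERS,
    RawMosaicFrame,
    ReflectanceCube,
    ResponseCurve,
    SensitivityMatrix,
    SpectralCube,
    default_band_layout,
    remosaic,
)

logger = logging.getLogger(__name__)


def make_sensitivity_fixture(centers=DEFAULT_CHANNEL_CENTERS, fwhm: float = 15.0,
                             crosstalk: float = 0.0,
                             wavelengths_nm=None) -> SensitivityMatrix:
    """Simulated Fabry-Perot channel sensitivities.

    Each channel carries a Gaussian main lobe of the given FWHM at its own
    center plus side lobes of relative amplitude ``crosstalk`` at the two
    adjacent channel centers (the dominant cross-talk path of a mosaic
    sensor).  Every lobe is notched to vanish exactly at the other channel
    centers, so the collapsed mixing matrix is exactly
    ``I + crosstalk * adjacency`` — diagonal for ``crosstalk = 0`` and
    full-rank for ``crosstalk < 0.5``.
    """
    centers = np.asarray(centers, dtype=float)
    if np.any(centers < 470) or np.any(centers > 630):
        raise ValueError("channel centers must lie in 470-630 nm")
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(400.0, 1000.5, 1.0)
    wl = np.asarray(wavelengths_nm, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    notch_sigma = 1.2

    def notched_lobe(j):
        """Unit-peak lobe at centers[j], zero at every other center."""
        out = np.exp(-0.5 * ((wl - centers[j]) / sigma) ** 2)
        for k, ck in enumerate(centers):
            if k != j:
                out = out * (1.0 - np.exp(-0.5 * ((wl - ck) / notch_sigma) ** 2))
        return out

    lobes = [notched_lobe(j) for j in range(len(centers))]
    resp = np.zeros((len(centers), len(wl)))
    for i in range(len(centers)):
        resp[i] = lobes[i]
        for j in (i - 1, i + 1):
            if 0 <= j < len(centers):
                resp[i] += crosstalk * lobes[j]
    sens = SensitivityMatrix(resp, wl, centers)
    sens.validate()
    try:
        m = sens.mixing_matrix()
    except UnmixingError as exc:
        raise UnmixingError(
            f"sensitivity fixture is degenerate at these centers: {exc}"
        ) from exc
    if np.linalg.cond(m) > 1e8:
        raise UnmixingError(
            f"sensitivity fixture is rank-deficient (crosstalk={crosstalk})"
        )
    return sens


def led_illumination_gains(centers=DEFAULT_CHANNEL_CENTERS,
                           cyan_nm: float = 505.0, cyan_fwhm: float = 30.0,
                           lime_nm: float = 568.0, lime_fwhm: float = 100.0,
                           cyan_to_lime: float = 1 / 20) -> np.ndarray:
    """Relative per-band illumination of the two-LED (cyan + lime) source.

    Gaussian emission profiles with the nominal center wavelengths and
    FWHMs of the illuminator LEDs; ``cyan_to_lime`` is the intensity ratio
    between the two groups (default 1/20).
    """
    lam = np.asarray(centers, dtype=float)

    def led(center, fwhm):
        s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((lam - center) / s) ** 2)

    g = cyan_to_lime * led(cyan_nm, cyan_fwhm) + led(lime_nm, lime_fwhm)
    return g / g.max()


@dataclass
class NoiseModel:
    """Sensor noise in counts (DN).

    Shot noise is Gaussian with variance ``shot_scale * signal`` — the
    Gaussian limit of photon noise, adequate at the sensor's operating
    counts.  ``shot_scale`` is therefore the system gain in DN per
    photo-electron; the default 0.08 corresponds to a ~13.5 ke- full well
    digitized to 10 bits, typical of the 2/3" global-shutter CMOS sensors
    used in mosaic hyperspectral cameras.  Read noise is additive Gaussian.
    ``quantize=False`` disables 10-bit rounding; a fully noiseless chain
    (for exact round-trip checks) is ``NoiseModel.noiseless(quantize=False)``.
    """

    shot_scale: float = 0.08
    read_sigma: float = 2.0
    dark_offset: float = 8.0
    bit_depth: int = 10
    quantize: bool = True

    @classmethod
    def noiseless(cls, quantize: bool = True) -> "NoiseModel":
        return cls(shot_scale=0.0, read_sigma=0.0, quantize=quantize)


@dataclass
class PhantomSpec:
    """Ground-truth phantom description.

    Patch geometry is either ``layout="blobs"`` (thresholded smoothed
    noise, mottling-like patches with the requested area fractions) or an
    explicit integer label image.  ``patches[i]`` holds the skin parameters
    of patch i.
    """

    patches: list
    fractions: list | None = None
    shape: tuple = (272, 512)
    layout: object = "blobs"      # "blobs" | integer label image
    blob_smooth_px: float = 12.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    gains: np.ndarray | None = None
    sensitivity: SensitivityMatrix | None = None
    seed: int = 0
    target_white_counts: float = 850.0

    def resolved_sensitivity(self) -> SensitivityMatrix:
        if self.sensitivity is None:
            return make_sensitivity_fixture(crosstalk=0.15)
        return self.sensitivity

    def resolved_gains(self, centers) -> np.ndarray:
        if self.gains is None:
            return led_illumination_gains(centers)
        return np.asarray(self.gains, dtype=float)


@dataclass
class GroundTruth:
    """Per-pixel parameter maps plus recomputable summary diagnostics."""

    label_map: np.ndarray
    maps: dict                  # name -> H x W array (B, SO2, M, d_e_um)
    patch_table: pd.DataFrame
    patches: list
    seed: int

    def so2_stats(self, mask=None, col_slice=None) -> tuple[float, float]:
        """True (weighted mean, mottling SD) in percent over a region.

        ``col_slice`` crops columns the way the pipeline crops the cube;
        ``mask`` restricts to an ROI inside the cropped geometry.
        """
        labels = self.label_map
        if col_slice is not None:
            labels = labels[:, col_slice]
        if mask is not None:
            labels = labels[mask]
        labels = labels.ravel()
        n_patches = len(self.patches)
        w = np.bincount(labels, minlength=n_patches) / labels.size
        so2 = np.array([100.0 * p.SO2 for p in self.patches])
        mean = so2_weighted_mean(so2, w)
        return mean, mottling_index(so2, w, mean)


def generate_parameter_maps(spec: PhantomSpec, seed: int | None = None
                            ) -> GroundTruth:
    """Draw the piecewise-constant ground-truth parameter maps."""
    if seed is None:
        seed = spec.seed
    n = len(spec.patches)
    if n == 0:
        raise PhantomError("phantom needs at least one patch")
    if isinstance(spec.layout, str) and spec.layout == "blobs":
        fractions = spec.fractions or [1.0 / n] * n
        if len(fractions) != n or not np.isclose(np.sum(fractions), 1.0):
            raise PhantomError("patch fractions must match patches and sum to 1")
        if n == 1:
            label_map = np.zeros(spec.shape, dtype=int)
        else:
            rng = np.random.default_rng(seed)
            fld = gaussian_filter(rng.standard_normal(spec.shape),
                                  spec.blob_smooth_px)
            edges = np.quantile(fld, np.cumsum(fractions)[:-1])
            label_map = np.digitize(fld, edges)
    else:
        label_map = np.asarray(spec.layout, dtype=int)
        if label_map.shape != tuple(spec.shape):
            raise PhantomError("explicit label image does not match shape")
    counts = np.bincount(label_map.ravel(), minlength=n)
    if np.any(counts == 0):
        raise PhantomError(f"degenerate layout: zero-area patches "
                           f"{np.flatnonzero(counts == 0).tolist()}")
    fields = {"B": "B", "SO2": "SO2", "M": "M", "d_e_um": "d_e_um"}
    maps = {}
    for name, attr in fields.items():
        vals = np.array([getattr(p, attr) for p in spec.patches])
        maps[name] = vals[label_map]
    patch_table = pd.DataFrame({
        "patch": np.arange(n),
        "area_fraction": counts / counts.sum(),
        "B": [p.B for p in spec.patches],
        "SO2_pct": [100.0 * p.SO2 for p in spec.patches],
        "M": [p.M for p in spec.patches],
        "d_e_um": [p.d_e_um for p in spec.patches],
    })
    return GroundTruth(label_map=label_map, maps=maps,
                       patch_table=patch_table, patches=list(spec.patches),
                       seed=seed)


def render_reflectance_cube(truth: GroundTruth, bands_nm,
                            table: ChromophoreTable) -> ReflectanceCube:
    """Render the scene reflectance cube from the ground truth.

    Spectra are evaluated once per patch (pixels with equal parameters
    share identical spectra by construction).
    """
    bands = np.asarray(bands_nm, dtype=float)
    h, w = truth.label_map.shape
    data = np.empty((len(bands), h, w))
    for k, p in enumerate(truth.patches):
        spectrum = forward_reflectance(p, bands, table)
        data[:, truth.label_map == k] = spectrum[:, None]
    return ReflectanceCube(data, bands, roi_mask=np.ones((h, w), dtype=bool))


def _expose(refl_channels: np.ndarray, mix: np.ndarray, gains: np.ndarray,
            scale: float) -> np.ndarray:
    """Noiseless per-channel signal in counts: scale * mix @ (gains * R)."""
    nb, h, w = refl_channels.shape
    lit = gains[:, None] * refl_channels.reshape(nb, -1)
    return (scale * (mix @ lit)).reshape(nb, h, w)


def simulate_sensor(refl: ReflectanceCube, sens: SensitivityMatrix | None = None,
                    gains: np.ndarray | None = None,
                    noise: NoiseModel | None = None, seed: int = 0,
                    band_layout: dict | None = None,
                    target_white_counts: float = 850.0):
    """Simulate raw, white and dark mosaic frames from a reflectance scene.

    The white frame images a uniform 0.99-reflectance target under the same
    illumination, so that the reflectance calibration of the preprocessing
    chain recovers the scene reflectance.  Returns a
    ``(raw, white, dark)`` triple of :class:`RawMosaicFrame`.
    """
    if sens is None:
        sens = make_sensitivity_fixture(crosstalk=0.15)
    if noise is None:
        noise = NoiseModel()
    centers = sens.channel_centers_nm
    if gains is None:
        gains = led_illumination_gains(centers)
    gains = np.asarray(gains, dtype=float)
    if np.any(gains <= 0):
        raise ValueError("illumination gains must be positive")
    if band_layout is None:
        band_layout = default_band_layout()
    mix = sens.mixing_matrix()
    nb = len(centers)
    if refl.data.shape[0] != nb:
        raise PhantomError("scene must be rendered at the sensor channel centers")

    white_channel = 0.99 * np.ones_like(refl.data)
    white_unit = mix @ (gains * 0.99)
    scale = target_white_counts / white_unit.max()

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    full_scale = 2 ** noise.bit_depth - 1

    def to_frame(channel_signal):
        cube = SpectralCube(channel_signal, centers)
        signal = remosaic(cube, band_layout)
        frame = signal + noise.dark_offset
        if noise.shot_scale > 0:
            # photon noise acts on the photo-signal only, not the offset
            frame = frame + rng.normal(
                0.0, np.sqrt(noise.shot_scale * np.maximum(signal, 0.0)))
        if noise.read_sigma > 0:
            frame = frame + rng.normal(0.0, noise.read_sigma, size=frame.shape)
        if noise.quantize:
            frame = np.clip(np.rint(frame), 0, full_scale).astype(np.uint16)
        return RawMosaicFrame(frame, bit_depth=noise.bit_depth,
                              band_layout=dict(band_layout))

    raw = to_frame(_expose(refl.data, mix, gains, scale))
    white = to_frame(_expose(white_channel, mix, gains, scale))
    dark = to_frame(np.zeros_like(refl.data))

    sat = (np.asarray(raw.pixels, dtype=float) >= full_scale).mean()
    if sat > 1e-3:
        warnings.warn(f"{sat:.2%} of raw pixels at full scale "
                      f"({int(sat * raw.pixels.size)} pixels)")
    return raw, white, dark


def simulate_phantom(spec: PhantomSpec, table: ChromophoreTable):
    """Convenience: maps -> scene -> sensor.  Returns (raw, white, dark, truth)."""
    sens = spec.resolved_sensitivity()
    truth = generate_parameter_maps(spec)
    scene = render_reflectance_cube(truth, sens.channel_centers_nm, table)
    raw, white, dark = simulate_sensor(
        scene, sens, spec.resolved_gains(sens.channel_centers_nm),
        spec.noise, seed=spec.seed,
        target_white_counts=spec.target_white_counts,
    )
    return raw, white, dark, truth


def monochromator_sweep(sens: SensitivityMatrix, start: float = 500.0,
                        stop: float = 625.0, step: float = 2.0,
                        unmixed: bool = False) -> list[ResponseCurve]:
    """Emulate a monochromator scan of the sensor.

    Returns one unit-peak response curve per channel whose center falls in
    the sweep range.  With ``unmixed=True`` the per-wavelength channel
    vectors are first multiplied by the pseudo-inverse of the collapsed
    mixing matrix (negative excursions clipped at zero before
    normalization).
    """
    sweep = np.arange(start, stop + step / 2, step)
    responses = sens.sample(sweep)  # (16, n_sweep)
    if unmixed:
        responses = np.linalg.pinv(sens.mixing_matrix()) @ responses
    curves = []
    for i, c in enumerate(sens.channel_centers_nm):
        if start <= c <= stop:
            curves.append(ResponseCurve.from_samples(sweep, responses[i]))
    return curves


def occlusion_series(base_seed: int = 0, shape: tuple = (272, 512),
                     noise: NoiseModel | None = None) -> list[PhantomSpec]:
    """Three-stage synthetic occlusion scenario: baseline -> occlusion -> hyperemia.

    Baseline and hyperemia are nearly saturated and spatially even;
    the occlusion stage is desaturated and patchy (mottled), so the
    weighted-mean SO2 falls then recovers while the mottling index peaks
    mid-series.
    """
    if noise is None:
        noise = NoiseModel()
    common = dict(M=0.02, d_e_um=90.0)
    stages = [
        ([SkinParams(B=2e-3, SO2=0.98, **common),
          SkinParams(B=2e-3, SO2=1.00, **common)], [0.3, 0.7]),
        ([SkinParams(B=4e-3, SO2=0.30, **common),
          SkinParams(B=2e-3, SO2=0.55, **common)], [0.5, 0.5]),
        ([SkinParams(B=5e-3, SO2=1.00, **common),
          SkinParams(B=3e-3, SO2=0.98, **common)], [0.8, 0.2]),
    ]
    return [
        PhantomSpec(patches=p, fractions=f, shape=shape, noise=noise,
                    seed=base_seed + i)
        for i, (p, f) in enumerate(stages)
    ]
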