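"""Snapshot-mosaic sensor preprocessing.

Turns raw 10-bit mosaic frames into calibrated, band-selected, ROI-masked
reflectance cubes: demosaic -> spectral unmixing (channel cross-talk
removal) -> white/dark reflectance calibration -> band selection -> central
crop with a circular region of interest.  Also provides the area-under-curve
quality metric for normalized spectral response curves.

Conventions: 0-based (row, col); band axis first in all cubes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    BandSelectionError,
    CalibrationReferenceError,
    ShapeError,
    UnmixingError,
)

logger = logging.getLogger(__name__)

#: nominal channel centers of the simulated 16-channel mosaic sensor [nm].
#: The ten working bands sit at well-separated centers; the six spare
#: channels (470-499, 525, 556) carry the strongest mutual overlap and are
#: excluded from tissue analysis, mirroring a mosaic sensor whose bands are
#: picked for minimal spectral mixing.
DEFAULT_CHANNEL_CENTERS = (
    470.0, 479.0, 489.0, 499.0, 507.0, 518.0, 525.0, 532.0,
    544.0, 556.0, 568.0, 580.0, 593.0, 604.0, 617.0, 625.0,
)

#: working bands used for tissue analysis: minimal cross-talk, strong
#: hemoglobin absorption contrast
DEFAULT_TARGET_BANDS = (
    507.0, 518.0, 532.0, 544.0, 568.0, 580.0, 593.0, 604.0, 617.0, 625.0,
)


def default_band_layout(period: int = 4) -> dict:
    """Row-major (row mod p, col mod p) -> channel index mapping."""
    return {(r, c): period * r + c for r in range(period) for c in range(period)}


@dataclass
class RawMosaicFrame:
    """One snapshot with an interleaved spectral mosaic.

    ``pixels`` is the full-resolution sensor image; each ``mosaic_period``
    x ``mosaic_period`` macro-pixel carries every spectral channel once,
    at the positions given by ``band_layout``.  Float pixels are accepted
    for unquantized simulations.
    """

    pixels: np.ndarray
    bit_depth: int = 10
    mosaic_period: int = 4
    band_layout: dict = field(default_factory=default_band_layout)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)

    @property
    def n_channels(self) -> int:
        return self.mosaic_period ** 2

    def validate(self) -> None:
        p = self.mosaic_period
        rows, cols = self.pixels.shape
        if rows % p or cols % p:
            raise ShapeError(
                f"frame {rows}x{cols} not divisible by mosaic period {p}"
            )
        full = 2 ** self.bit_depth - 1
        if self.pixels.min() < 0 or self.pixels.max() > full:
            raise ValueError(f"pixel values outside [0, {full}]")
        positions = set(self.band_layout.keys())
        channels = sorted(self.band_layout.values())
        if positions != {(r, c) for r in range(p) for c in range(p)} or \
                channels != list(range(self.n_channels)):
            raise ValueError("band_layout is not a bijection onto the channels")


@dataclass
class SpectralCube:
    """Band-stacked image (band axis first) with band-center metadata."""

    data: np.ndarray
    band_centers_nm: np.ndarray
    provenance: str = "raw"  # raw | unmixed

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.band_centers_nm = np.asarray(self.band_centers_nm, dtype=float)

    def validate(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] != len(self.band_centers_nm):
            raise ShapeError("cube band axis does not match band centers")
        if np.any(np.diff(self.band_centers_nm) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")


@dataclass
class ReflectanceCube:
    """Calibrated reflectance cube with a boolean region-of-interest mask."""

    data: np.ndarray
    band_centers_nm: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.band_centers_nm = np.asarray(self.band_centers_nm, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)

    def validate(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] != len(self.band_centers_nm):
            raise ShapeError("cube band axis does not match band centers")
        if self.roi_mask.shape != self.data.shape[1:]:
            raise ShapeError("ROI mask does not match cube geometry")
        if self.roi_mask.sum() == 0:
            raise ValueError("ROI mask is empty")
        if self.data.min() < 0 or self.data.max() > 1.5:
            raise ValueError("reflectance outside the clipped range [0, 1.5]")

    def roi_spectra(self) -> np.ndarray:
        """(n_roi_pixels, n_bands) matrix of spectra inside the ROI."""
        return self.data[:, self.roi_mask].T


@dataclass
class SensitivityMatrix:
    """Per-channel spectral sensitivity of the mosaic sensor.

    ``response`` is (16, W) on the ``wavelengths_nm`` grid;
    ``channel_centers_nm`` are the 16 nominal band centers.
    """

    response: np.ndarray
    wavelengths_nm: np.ndarray
    channel_centers_nm: np.ndarray

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.channel_centers_nm = np.asarray(self.channel_centers_nm, dtype=float)

    def validate(self) -> None:
        if self.response.ndim != 2 or \
                self.response.shape[1] != len(self.wavelengths_nm):
            raise ShapeError("response matrix does not match wavelength grid")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.response)) or np.any(self.response < 0):
            raise ValueError("response must be finite and non-negative")
        if np.any(self.response.sum(axis=1) == 0):
            raise ValueError("all-zero sensitivity row")

    def sample(self, lam) -> np.ndarray:
        """Sample every channel response at the given wavelengths."""
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        out = np.empty((self.response.shape[0], len(lam)))
        for i, row in enumerate(self.response):
            out[i] = np.interp(lam, self.wavelengths_nm, row)
        return out

    def mixing_matrix(self) -> np.ndarray:
        """Channel-mixing matrix collapsed onto the nominal channel centers.

        Entry (i, j) is channel i's sensitivity at channel j's center, with
        each row scaled by its own-center value so the diagonal is 1; a
        cross-talk-free sensor therefore collapses to the identity.
        """
        m = self.sample(self.channel_centers_nm)
        diag = np.diag(m).copy()
        if np.any(diag <= 0):
            raise UnmixingError("channel has zero sensitivity at its own center")
        return m / diag[:, None]


@dataclass
class ResponseCurve:
    """A unit-peak normalized spectral response curve."""

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @classmethod
    def from_samples(cls, wavelengths_nm, values) -> "ResponseCurve":
        """Clip negatives to zero and normalize the peak to exactly 1."""
        v = np.clip(np.asarray(values, dtype=float), 0.0, None)
        peak = v.max()
        if peak <= 0:
            raise ValueError("response curve has no positive samples")
        return cls(np.asarray(wavelengths_nm, dtype=float), v / peak)

    def validate(self) -> None:
        if len(self.values) < 3:
            raise ValueError("response curve needs at least 3 samples")
        if self.values.min() < 0 or not np.isclose(self.values.max(), 1.0):
            raise ValueError("curve must be normalized to unit peak")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def demosaic(frame: RawMosaicFrame, band_centers_nm=None) -> SpectralCube:
    """Deinterleave a mosaic frame into a (channels, rows/p, cols/p) cube."""
    frame.validate()
    p = frame.mosaic_period
    rows, cols = frame.pixels.shape
    if band_centers_nm is None:
        band_centers_nm = DEFAULT_CHANNEL_CENTERS[: frame.n_channels]
    data = np.empty((frame.n_channels, rows // p, cols // p))
    for (r, c), ch in frame.band_layout.items():
        data[ch] = frame.pixels[r::p, c::p]
    cube = SpectralCube(data, band_centers_nm, provenance="raw")
    cube.validate()
    return cube


def remosaic(cube: SpectralCube, band_layout: dict | None = None,
             mosaic_period: int = 4) -> np.ndarray:
    """Inverse of :func:`demosaic`: interleave band planes back into a frame."""
    if band_layout is None:
        band_layout = default_band_layout(mosaic_period)
    p = mosaic_period
    nb, h, w = cube.data.shape
    out = np.empty((h * p, w * p))
    for (r, c), ch in band_layout.items():
        out[r::p, c::p] = cube.data[ch]
    return out


def unmix(cube: SpectralCube, sens: SensitivityMatrix,
          cond_threshold: float = 1e8) -> SpectralCube:
    """Remove inter-channel cross-talk by inverting the collapsed mixing matrix.

    Per pixel the raw channel vector is modeled as M_mix @ true; the true
    spectrum is recovered as the minimum-norm least-squares solution
    (pseudo-inverse).
    """
    cube.validate()
    sens.validate()
    m = sens.mixing_matrix()
    if m.shape[0] != cube.data.shape[0]:
        raise ShapeError("cube band count does not match sensitivity channels")
    cond = np.linalg.cond(m)
    if cond > cond_threshold:
        raise UnmixingError(
            f"mixing matrix condition number {cond:.3g} exceeds "
            f"threshold {cond_threshold:.3g}"
        )
    nb, h, w = cube.data.shape
    flat = cube.data.reshape(nb, -1)
    out = np.linalg.pinv(m) @ flat
    return SpectralCube(out.reshape(nb, h, w), cube.band_centers_nm,
                        provenance="unmixed")


def calibrate_reflectance(cube: SpectralCube, white: SpectralCube,
                          dark: SpectralCube, clip: tuple = (0.0, 1.5),
                          bad_pixel_tol: float = 0.01) -> ReflectanceCube:
    """White/dark reflectance calibration: R = 0.99*(I - Idark)/(Iwhite - Idark).

    The 0.99 factor accounts for the reflectance of the white reference
    standard.  Because measurement and white reference share the per-pixel
    illumination, the ratio also flattens uneven illumination.  Pixels where
    white <= dark in any band are flagged bad and excluded from the ROI
    mask; more than ``bad_pixel_tol`` bad pixels is a calibration error.
    """
    for c in (cube, white, dark):
        c.validate()
    if cube.data.shape != white.data.shape or cube.data.shape != dark.data.shape:
        raise ShapeError("measurement, white and dark cubes must share shape")
    if not (np.array_equal(cube.band_centers_nm, white.band_centers_nm)
            and np.array_equal(cube.band_centers_nm, dark.band_centers_nm)):
        raise ValueError("band centers differ between calibration cubes")
    denom = white.data - dark.data
    bad = np.any(denom <= 0, axis=0)
    frac = bad.mean()
    if frac > bad_pixel_tol:
        raise CalibrationReferenceError(
            f"white <= dark at {frac:.2%} of pixels "
            f"(tolerated {bad_pixel_tol:.2%})"
        )
    safe = np.where(denom > 0, denom, 1.0)
    # ratio first: measuring the white standard itself must give exactly 0.99
    r = 0.99 * ((cube.data - dark.data) / safe)
    r = np.clip(r, *clip)
    r[:, bad] = 0.0
    out = ReflectanceCube(r, cube.band_centers_nm, roi_mask=~bad)
    out.validate()
    return out


def select_bands(cube, targets=DEFAULT_TARGET_BANDS):
    """Keep the band nearest each target wavelength, ascending order.

    Works on both :class:`SpectralCube` and :class:`ReflectanceCube`.
    Two targets resolving to the same band is an ambiguity error.
    """
    centers = cube.band_centers_nm
    targets = np.asarray(sorted(targets), dtype=float)
    if targets.min() < centers.min() or targets.max() > centers.max():
        raise BandSelectionError("target band outside the cube's spectral range")
    idx = [int(np.argmin(np.abs(centers - t))) for t in targets]
    if len(set(idx)) != len(idx):
        raise BandSelectionError(
            f"ambiguous band selection: targets {targets} map to bands {idx}"
        )
    if isinstance(cube, ReflectanceCube):
        return ReflectanceCube(cube.data[idx], centers[idx], cube.roi_mask)
    return SpectralCube(cube.data[idx], centers[idx], provenance=cube.provenance)


def disk_mask(side: int) -> np.ndarray:
    """Inscribed centered disk: (i-c)^2 + (j-c)^2 <= r^2 with c=(side-1)/2, r=side/2."""
    c = (side - 1) / 2.0
    r = side / 2.0
    i, j = np.ogrid[:side, :side]
    return (i - c) ** 2 + (j - c) ** 2 <= r ** 2


def crop_and_mask(cube: ReflectanceCube) -> ReflectanceCube:
    """Extract the central square and apply the inscribed circular ROI."""
    nb, h, w = cube.data.shape
    if w < h:
        raise ShapeError("expected width >= height for the central-square crop")
    off = (w - h) // 2
    sl = slice(off, off + h)
    mask = disk_mask(h) & cube.roi_mask[:, sl]
    out = ReflectanceCube(cube.data[:, :, sl], cube.band_centers_nm, mask)
    out.validate()
    return out


def central_crop_slice(height: int, width: int) -> slice:
    """Column slice used by :func:`crop_and_mask` (for cropping side data)."""
    off = (width - height) // 2
    return slice(off, off + height)


def spectral_response_auc(curve: ResponseCurve) -> float:
    """Area under a unit-peak response curve [nm]; smaller means sharper."""
    curve.validate()
    return float(np.trapezoid(curve.values, curve.wavelengths_nm))


_CHANNEL_COL = re.compile(r"channel_.*?([0-9]+(?:\.[0-9]+)?)nm")


def read_sensitivity_csv(path, channel_centers_nm=None) -> SensitivityMatrix:
    """Read a delimited sensitivity table: wavelength column + 16 channel columns.

    Nominal channel centers are taken (in order of preference) from the
    ``channel_centers_nm`` argument, from column names of the form
    ``channel_<center>nm``, or from each channel's peak-response wavelength.
    The last fallback is unreliable when rows carry cross-talk side lobes.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    resp = df.iloc[:, 1:].to_numpy(dtype=float).T
    if channel_centers_nm is None:
        named = [_CHANNEL_COL.fullmatch(c) for c in df.columns[1:]]
        if all(named):
            channel_centers_nm = [float(m.group(1)) for m in named]
        else:
            channel_centers_nm = wl[np.argmax(resp, axis=1)]
            logger.warning("channel centers inferred from response peaks; "
                           "side lobes may bias them")
    sens = SensitivityMatrix(resp, wl, channel_centers_nm)
    sens.validate()
    return sens


def write_sensitivity_csv(sens: SensitivityMatrix, path) -> None:
    cols = {"wavelength_nm": sens.wavelengths_nm}
    for center, row in zip(sens.channel_centers_nm, sens.response):
        cols[f"channel_{center:g}nm"] = row
    pd.DataFrame(cols).to_csv(path, index=False)
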