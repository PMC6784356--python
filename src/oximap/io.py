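"""TIFF and table I/O for frames, maps and run outputs."""

from __future__ import annotations

import numpy as np
import tifffile
import imageio.v3 as iio
import matplotlib

from .preprocess import RawMosaicFrame, default_band_layout


def write_frame(frame: RawMosaicFrame, path) -> None:
    """Write a mosaic frame as 16-bit TIFF (10-bit data in a 16-bit container).

    Unquantized (float) frames are written as 32-bit float TIFF.
    """
    px = np.asarray(frame.pixels)
    if np.issubdtype(px.dtype, np.integer):
        tifffile.imwrite(path, px.astype(np.uint16))
    else:
        tifffile.imwrite(path, px.astype(np.float32))


def read_raw_frame(path, bit_depth: int = 10, mosaic_period: int = 4,
                   band_layout: dict | None = None) -> RawMosaicFrame:
    px = tifffile.imread(path)
    if band_layout is None:
        band_layout = default_band_layout(mosaic_period)
    frame = RawMosaicFrame(px, bit_depth=bit_depth,
                           mosaic_period=mosaic_period,
                           band_layout=band_layout)
    frame.validate()
    return frame


def write_so2_tiff(so2_map: np.ndarray, path) -> None:
    """Raw-valued SO2 map [percent] as 32-bit float TIFF (NaN outside ROI)."""
    tifffile.imwrite(path, np.asarray(so2_map, dtype=np.float32))


def write_so2_png(so2_map: np.ndarray, path, cmap: str = "jet") -> None:
    """Color-coded SO2 map with a fixed 0-100 % colormap; non-ROI is black."""
    m = np.asarray(so2_map, dtype=float)
    norm = np.clip(m / 100.0, 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](np.nan_to_num(norm))
    rgba[~np.isfinite(m)] = (0.0, 0.0, 0.0, 1.0)
    iio.imwrite(path, (rgba[..., :3] * 255).astype(np.uint8))
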