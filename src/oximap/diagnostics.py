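"""Segmented oxygen-saturation maps and the two scalar diagnostics.

The per-cluster SO2 estimates are broadcast to cluster member pixels to
form the segmented map; the scalar summaries are the area-weighted mean
SO2 and the skin-mottling index.  The mottling index is the area-weighted
standard deviation

    SO2_SD = sqrt( K/(K-1) * sum_i w_i * (SO2_i - SO2_mean)^2 )

over the K non-empty clusters.  (The weighted *first* moment of the
deviations is identically zero whenever the weights sum to one, so a
dispersion statistic necessarily carries the square and root; the K/(K-1)
factor debiases the K-cluster average in analogy with the sample SD.)

All diagnostics are reported in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


def _check_weights(weights: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("negative cluster weight")
    if abs(weights.sum() - 1.0) > tol:
        raise ValueError(f"cluster weights sum to {weights.sum()}, not 1")
    return weights


def so2_weighted_mean(cluster_so2, weights) -> float:
    """Area-weighted mean SO2 [percent]: sum_i w_i * SO2_i."""
    weights = _check_weights(weights)
    cluster_so2 = np.asarray(cluster_so2, dtype=float)
    return float(np.dot(weights, cluster_so2))


def mottling_index(cluster_so2, weights, so2_mean: float | None = None) -> float:
    """Skin-mottling index [percent]: weighted SD of cluster SO2 values."""
    weights = _check_weights(weights)
    cluster_so2 = np.asarray(cluster_so2, dtype=float)
    if so2_mean is None:
        so2_mean = so2_weighted_mean(cluster_so2, weights)
    nonempty = weights > 0
    k = int(nonempty.sum())
    if k <= 1:
        logger.info("single non-empty cluster: mottling index is 0 by convention")
        return 0.0
    var = float(np.dot(weights[nonempty],
                       (cluster_so2[nonempty] - so2_mean) ** 2))
    return float(np.sqrt(k / (k - 1) * var))


@dataclass
class SaturationMap:
    """Segmented per-pixel SO2 map [percent] with the scalar diagnostics."""

    so2_map: np.ndarray       # H x W, NaN outside the ROI
    roi_mask: np.ndarray
    cluster_so2: np.ndarray   # percent, NaN for empty clusters
    weights: np.ndarray
    so2_mean: float           # percent
    so2_sd: float             # percent

    def validate(self) -> None:
        inside = self.so2_map[self.roi_mask]
        if inside.size == 0 or not np.all(np.isfinite(inside)):
            raise ValueError("ROI pixels must carry finite SO2 values")
        if inside.min() < 0 or inside.max() > 100:
            raise ValueError("SO2 map values outside [0, 100] percent")
        used = self.weights > 0
        vals = self.cluster_so2[used]
        if not (vals.min() - 1e-9 <= self.so2_mean <= vals.max() + 1e-9):
            raise ValueError("weighted mean outside the cluster SO2 range")
        if self.so2_sd < 0:
            raise ValueError("negative mottling index")


def assemble_saturation_map(labels, roi_mask, cluster_so2) -> SaturationMap:
    """Broadcast per-cluster SO2 [percent] onto the ROI pixels.

    ``labels`` are in ROI raster order (as produced by the segmentation);
    pixels outside the ROI carry NaN.
    """
    labels = np.asarray(labels)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    cluster_so2 = np.asarray(cluster_so2, dtype=float)
    if labels.size != int(roi_mask.sum()):
        raise ValueError("labels do not cover the ROI pixel set")
    used = np.unique(labels)
    if np.any(~np.isfinite(cluster_so2[used])):
        raise ValueError("a used cluster has no fitted SO2 value")
    weights = np.bincount(labels, minlength=len(cluster_so2)) / labels.size
    so2_map = np.full(roi_mask.shape, np.nan)
    so2_map[roi_mask] = cluster_so2[labels]
    vals = np.where(weights > 0, cluster_so2, 0.0)  # empty clusters drop out
    mean = so2_weighted_mean(vals, weights)
    sd = mottling_index(vals, weights, mean)
    out = SaturationMap(so2_map=so2_map, roi_mask=roi_mask,
                        cluster_so2=cluster_so2, weights=weights,
                        so2_mean=mean, so2_sd=sd)
    out.validate()
    return out
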