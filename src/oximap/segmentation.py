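"""Spectral k-means segmentation of the ROI and cluster area weights.

ROI pixels are clustered in B-dimensional reflectance space (plain
Euclidean distance over the selected bands, no spectrum normalization).
Clustering is Lloyd's algorithm from k-means++ initialization, best of
``n_init`` restarts by inertia, deterministic for a fixed seed.  A short
refinement loop after the library fit guarantees that every returned
centroid is exactly the arithmetic mean of its members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import SegmentationError
from .preprocess import ReflectanceCube

logger = logging.getLogger(__name__)

DEFAULT_K = 10


@dataclass
class ClusterResult:
    """K centroid spectra, per-ROI-pixel labels, and area weights."""

    centroids: np.ndarray        # (K, B) mean reflectance spectra
    labels: np.ndarray           # (n_roi_pixels,) cluster index per ROI pixel
    weights: np.ndarray          # (K,) area fractions A_i / A_RoI
    inertia: float               # total within-cluster squared distance
    K: int
    seed: int
    iterations: int

    def validate(self) -> None:
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise ValueError("label outside [0, K)")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        if self.inertia < 0:
            raise ValueError("negative inertia")


def cluster_weights(labels: np.ndarray, n_clusters: int) -> np.ndarray:
    """Area weights w_i = count(label == i) / count(ROI pixels)."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=n_clusters).astype(float)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        logger.info("empty clusters (weight 0): %s", empty.tolist())
    return counts / labels.size


def _refine_lloyd(x: np.ndarray, centroids: np.ndarray, labels: np.ndarray,
                  max_rounds: int = 50):
    """Extra Lloyd rounds until labels are stable and centroids are exact
    member means at the returned assignment."""
    k = centroids.shape[0]
    x_sq = (x ** 2).sum(axis=1)
    for _ in range(max_rounds):
        d2 = x_sq[:, None] + (centroids ** 2).sum(axis=1)[None, :] \
            - 2.0 * x @ centroids.T
        new_labels = np.argmin(d2, axis=1)  # argmin -> lowest index on ties
        new_centroids = centroids.copy()
        for j in range(k):
            members = new_labels == j
            if members.any():
                new_centroids[j] = x[members].mean(axis=0)
            else:
                # reseed an empty cluster to the farthest point
                far = int(np.argmax(d2[np.arange(len(x)), new_labels]))
                new_centroids[j] = x[far]
                new_labels[far] = j
        if np.array_equal(new_labels, labels) and \
                np.allclose(new_centroids, centroids, rtol=0, atol=0):
            break
        labels, centroids = new_labels, new_centroids
    inertia = float(((x - centroids[labels]) ** 2).sum())
    return centroids, labels, inertia


def kmeans_spectra(spectra: np.ndarray, k: int = DEFAULT_K, seed: int = 0,
                   n_init: int = 10, max_iter: int = 300,
                   tol: float = 1e-6) -> ClusterResult:
    """Cluster an (n_pixels, n_bands) spectra matrix into k groups."""
    x = np.asarray(spectra, dtype=float)
    if x.ndim != 2:
        raise SegmentationError("expected an (n_pixels, n_bands) matrix")
    n_bad = int((~np.isfinite(x)).any(axis=1).sum())
    if n_bad:
        raise SegmentationError(f"{n_bad} pixels carry non-finite spectra")
    if x.shape[0] < k:
        raise SegmentationError(
            f"ROI has {x.shape[0]} pixels, fewer than K={k}"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, tol=tol, random_state=seed)
    km.fit(x)
    centroids, labels, inertia = _refine_lloyd(x, km.cluster_centers_.copy(),
                                               km.labels_.copy())
    result = ClusterResult(
        centroids=centroids, labels=labels,
        weights=cluster_weights(labels, k), inertia=inertia,
        K=k, seed=seed, iterations=int(km.n_iter_),
    )
    result.validate()
    return result


def kmeans_cluster(cube: ReflectanceCube, k: int = DEFAULT_K, seed: int = 0,
                   n_init: int = 10, max_iter: int = 300,
                   tol: float = 1e-6) -> ClusterResult:
    """Cluster the ROI pixels of a reflectance cube (labels in ROI raster order)."""
    cube.validate()
    return kmeans_spectra(cube.roi_spectra(), k=k, seed=seed, n_init=n_init,
                          max_iter=max_iter, tol=tol)
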