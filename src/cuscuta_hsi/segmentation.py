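"""Plant/background segmentation of hyperspectral cubes.

The workhorse methods are spectral indices: NDVI thresholding for the
VNIR range (bands 121/64 of the camera profile, i.e. 827.09/620.29 nm)
and NDWI followed by 1-D k-means for the SWIR range (bands 27/136, i.e.
1098.07/1655.20 nm).  Clustering alternatives evaluated against them —
k-means on full spectra, X-means with BIC-guided cluster-count choice,
and LVQ1 prototype classification — are provided as well.

For the clustering methods the plant cluster is identified automatically
as the cluster with the highest mean index value (vegetation is bright
in NIR, water-rich in SWIR); an unattended pipeline cannot pick clusters
visually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus

from .cube_io import SpectralCube
from .pixels import PixelTable

__all__ = [
    "SegmentationMask",
    "ndvi_map",
    "ndvi_segment",
    "ndwi_map",
    "ndwi_kmeans_segment",
    "kmeans_cluster",
    "KMeansResult",
    "xmeans_cluster",
    "lvq_train",
    "LVQModel",
    "label_plant_pixels",
]

logger = logging.getLogger(__name__)

NDVI_NIR_BAND = 121   # 827.09 nm on the VNIR profile
NDVI_RED_BAND = 64    # 620.29 nm
NDVI_THRESHOLD = 0.75
NDWI_NIR_BAND = 27    # 1098.07 nm on the SWIR profile
NDWI_SWIR_BAND = 136  # 1655.20 nm


@dataclass
class SegmentationMask:
    """Per-pixel plant (True) / background (False) decision for one cube."""

    mask: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D (lines, samples)")

    @property
    def n_plant(self) -> int:
        return int(self.mask.sum())


def _normalized_difference(cube: SpectralCube, plus_band: int, minus_band: int) -> np.ndarray:
    if plus_band == minus_band:
        raise ValueError("the two index bands must differ")
    for b in (plus_band, minus_band):
        if not 0 <= b < cube.bands:
            raise IndexError(f"band index {b} out of range [0, {cube.bands})")
    a = cube.reflectance[:, :, plus_band]
    b = cube.reflectance[:, :, minus_band]
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        index = (a - b) / denom
    return np.where(denom == 0, 0.0, index)  # 0/0 -> 0 by convention


def ndvi_map(cube: SpectralCube, nir_band: int = NDVI_NIR_BAND,
             red_band: int = NDVI_RED_BAND) -> np.ndarray:
    """NDVI = (NIR - red) / (NIR + red) per pixel; 0 where both are 0."""
    return _normalized_difference(cube, nir_band, red_band)


def ndvi_segment(cube: SpectralCube, threshold: float = NDVI_THRESHOLD,
                 nir_band: int = NDVI_NIR_BAND,
                 red_band: int = NDVI_RED_BAND) -> SegmentationMask:
    """Plant iff NDVI strictly exceeds ``threshold`` (default 0.75)."""
    if not -1 < threshold < 1 and threshold not in (-1.0, 1.0):
        raise ValueError(f"threshold must lie in [-1, 1], got {threshold}")
    index = ndvi_map(cube, nir_band, red_band)
    return SegmentationMask(index > threshold, "ndvi",
                            {"threshold": threshold, "nir_band": nir_band,
                             "red_band": red_band})


def ndwi_map(cube: SpectralCube, nir_band: int = NDWI_NIR_BAND,
             swir_band: int = NDWI_SWIR_BAND) -> np.ndarray:
    """NDWI = (NIR - SWIR) / (NIR + SWIR) per pixel; 0 where both are 0."""
    return _normalized_difference(cube, nir_band, swir_band)


def ndwi_kmeans_segment(cube: SpectralCube, nir_band: int = NDWI_NIR_BAND,
                        swir_band: int = NDWI_SWIR_BAND, k: int = 2,
                        seed: int = 0) -> SegmentationMask:
    """K-means on the 1-D NDWI values; highest-mean-NDWI cluster = plant."""
    if k < 2:
        raise ValueError("k must be >= 2")
    index = ndwi_map(cube, nir_band, swir_band)
    values = index.reshape(-1, 1)
    if np.ptp(values) == 0:
        raise ValueError("NDWI map is constant; cannot cluster")
    result = kmeans_cluster(values, k=k, seed=seed)
    plant_cluster = int(np.argmax(result.centroids[:, 0]))
    mask = (result.labels == plant_cluster).reshape(index.shape)
    return SegmentationMask(mask, "ndwi-kmeans",
                            {"k": k, "nir_band": nir_band,
                             "swir_band": swir_band, "seed": seed})


# ---------------------------------------------------------------------------
# Clustering primitives

@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    wcss: float
    wcss_trace: np.ndarray  # per Lloyd iteration of the winning restart


def _wcss(points: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(np.sum((points - centroids[labels]) ** 2))


def _assign(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((points[:, None, :] - centroids[None]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _lloyd(points: np.ndarray, centroids: np.ndarray, max_iter: int,
           tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, list[float]]:
    trace: list[float] = []
    labels = _assign(points, centroids)
    trace.append(_wcss(points, centroids, labels))
    for _ in range(max_iter):
        new_centroids = centroids.copy()
        for c in range(centroids.shape[0]):
            members = points[labels == c]
            if members.size:
                new_centroids[c] = members.mean(axis=0)
        labels = _assign(points, new_centroids)
        wcss = _wcss(points, new_centroids, labels)
        centroids = new_centroids
        if trace and trace[-1] - wcss <= tol:
            trace.append(wcss)
            break
        trace.append(wcss)
    return labels, centroids, trace


def kmeans_cluster(pixels: np.ndarray, k: int, seed: int = 0,
                   max_iter: int = 100, n_restarts: int = 10) -> KMeansResult:
    """Euclidean k-means (Lloyd) with k-means++ seeding and restarts.

    Runs ``n_restarts`` seeded initializations and keeps the solution
    with the lowest within-cluster sum of squares (WCSS).  The WCSS
    trace of the winning restart is returned; it is non-increasing.
    """
    points = np.asarray(pixels, dtype=float)
    if points.ndim != 2:
        raise ValueError("pixels must be 2-D (n, features)")
    if not 1 <= k <= points.shape[0]:
        raise ValueError(f"k={k} invalid for {points.shape[0]} points")
    best: Optional[KMeansResult] = None
    for restart in range(n_restarts):
        rs = np.random.RandomState((seed + restart) % (2 ** 31))
        init, _ = kmeans_plusplus(points, n_clusters=k, random_state=rs)
        labels, centroids, trace = _lloyd(points, init, max_iter)
        result = KMeansResult(labels, centroids, trace[-1], np.asarray(trace))
        if best is None or result.wcss < best.wcss:
            best = result
    return best


def _spherical_bic(points: np.ndarray, labels: np.ndarray,
                   centroids: np.ndarray) -> float:
    """BIC of a spherical-Gaussian mixture fit (X-means split criterion)."""
    n, dim = points.shape
    k = centroids.shape[0]
    if n <= k:
        return -np.inf
    rss = np.sum((points - centroids[labels]) ** 2)
    sigma2 = max(rss / (dim * (n - k)), 1e-12)
    loglik = 0.0
    for c in range(k):
        n_c = int(np.sum(labels == c))
        if n_c > 0:
            loglik += n_c * np.log(n_c / n)
    loglik -= 0.5 * n * dim * np.log(2.0 * np.pi * sigma2)
    loglik -= 0.5 * dim * (n - k)
    n_params = k * (dim + 1)
    return loglik - 0.5 * n_params * np.log(n)


def xmeans_cluster(pixels: np.ndarray, k_min: int = 2, k_max: int = 8,
                   seed: int = 0) -> tuple[np.ndarray, int]:
    """X-means: grow k from ``k_min`` by BIC-approved centroid splits.

    Each cluster is tentatively 2-split; the split is kept when the BIC
    of the two-component model on the cluster's points beats the
    one-component model.  Stops when no split is accepted or ``k_max``
    is reached.  Returns (labels, chosen k).
    """
    points = np.asarray(pixels, dtype=float)
    if not 2 <= k_min <= k_max:
        raise ValueError(f"need 2 <= k_min <= k_max, got [{k_min}, {k_max}]")
    if k_min > points.shape[0]:
        raise ValueError("k_min exceeds number of points")
    k = k_min
    result = kmeans_cluster(points, k=k, seed=seed)
    while k < k_max:
        n_splits = 0
        for c in range(result.centroids.shape[0]):
            members = points[result.labels == c]
            if members.shape[0] < 4 or np.ptp(members, axis=0).max() == 0:
                continue
            parent_bic = _spherical_bic(
                members, np.zeros(members.shape[0], dtype=int),
                members.mean(axis=0, keepdims=True))
            child = kmeans_cluster(members, k=2, seed=seed + 1 + c, n_restarts=3)
            child_bic = _spherical_bic(members, child.labels, child.centroids)
            if child_bic > parent_bic and k + n_splits < k_max:
                n_splits += 1
        if n_splits == 0:
            break
        k = min(k + n_splits, k_max)
        result = kmeans_cluster(points, k=k, seed=seed)
    return result.labels, k


# ---------------------------------------------------------------------------
# Learning Vector Quantization (LVQ1)

@dataclass
class LVQModel:
    prototypes: np.ndarray
    prototype_labels: np.ndarray

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        d2 = ((spectra[:, None, :] - self.prototypes[None]) ** 2).sum(axis=2)
        return self.prototype_labels[np.argmin(d2, axis=1)]


def lvq_train(spectra: np.ndarray, labels: np.ndarray,
              prototypes_per_class: int = 1, epochs: int = 20,
              learning_rate: float = 0.1, seed: int = 0) -> LVQModel:
    """LVQ1: prototypes move toward same-class points, away from others.

    The learning rate decays linearly to zero over the run.  Unseen
    pixels are labelled by their nearest prototype (Euclidean).
    """
    spectra = np.asarray(spectra, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 1:
        raise ValueError("need at least one labelled example")
    rng = np.random.default_rng(seed)
    protos, proto_labels = [], []
    for cls in classes:
        members = np.nonzero(labels == cls)[0]
        if members.size == 0:
            raise ValueError(f"class {cls!r} has no examples")
        pick = rng.choice(members, size=min(prototypes_per_class, members.size),
                          replace=False)
        protos.append(spectra[pick])
        proto_labels.extend([cls] * pick.size)
    prototypes = np.vstack(protos).astype(float)
    proto_labels = np.asarray(proto_labels)

    n = spectra.shape[0]
    total_steps = max(epochs * n, 1)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in order:
            lr = learning_rate * (1.0 - step / total_steps)
            step += 1
            if lr <= 0:
                continue
            x = spectra[i]
            d2 = ((prototypes - x) ** 2).sum(axis=1)
            j = int(np.argmin(d2))
            sign = 1.0 if proto_labels[j] == labels[i] else -1.0
            prototypes[j] += sign * lr * (x - prototypes[j])
    return LVQModel(prototypes, proto_labels)


# ---------------------------------------------------------------------------
# Semi-supervised labelling of segmented pixels

def label_plant_pixels(mask: SegmentationMask, cube: SpectralCube,
                       species: str, image_id: str = "") -> PixelTable:
    """Turn every masked pixel into a labelled table row.

    One species per image is assumed (images are cropped per species
    upstream); the species label is applied to all plant pixels.
    """
    if mask.mask.shape != (cube.lines, cube.samples):
        raise ValueError("mask shape does not match cube spatial shape")
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        logger.warning("label_plant_pixels: empty mask for image %r", image_id)
    spectra = cube.reflectance[rows, cols] if rows.size else np.empty((0, cube.bands))
    meta = pd.DataFrame({
        "label": species,
        "image_id": image_id,
        "row": rows,
        "col": cols,
    })
    return PixelTable(spectra, meta, profile=cube.calibration.profile)
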