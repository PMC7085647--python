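"""Unsupervised flower detection by k-means pixel clustering.

Pixels of a unit-rescaled image are partitioned into k color clusters
(Lloyd's algorithm, squared Euclidean distance, k-means++ seeding, several
restarts) and clusters whose *centroid* satisfies a crop-specific color rule
are flagged as flowers.  The defaults (k=6, 3 replicates, iteration cap 100,
singleton action: an empty cluster is re-seeded with the point farthest from
its centroid) mirror the common statistical-toolbox configuration this
workflow was built around.

The clustering itself is implemented here rather than delegated: the
pipeline contracts per-iteration inertia monotonicity, deterministic
replicate seeding (seed, seed+1, seed+2) and the farthest-point singleton
action, none of which a generic library call exposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .raster import RasterImage, rescale_to_unit
from .rules import ThresholdRule

log = logging.getLogger(__name__)


class DegenerateKError(ValueError):
    """Raised when k exceeds the number of distinct pixel colors."""


@dataclass(frozen=True)
class KMeansSpec:
    """Clustering configuration (squared-Euclidean Lloyd with k-means++)."""

    k: int = 6
    replicates: int = 3
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.replicates < 1 or self.max_iter < 1:
            raise ValueError("k, replicates and max_iter must all be >= 1")


@dataclass
class ClusterResult:
    """Labels raster, centroids and the inertia trace of the winning replicate."""

    labels: np.ndarray  # H x W int
    centroids: np.ndarray  # k x 3
    inertia: float
    inertia_history: list[float] = field(default_factory=list)
    n_iter: int = 0


def _sq_dists(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # (n, k) squared Euclidean distances without forming (n, k, 3)
    return (
        np.einsum("ij,ij->i", points, points)[:, None]
        - 2.0 * points @ centroids.T
        + np.einsum("ij,ij->i", centroids, centroids)[None, :]
    )


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: D^2-weighted sampling of successive centers."""
    n = len(points)
    centers = np.empty((k, points.shape[1]))
    centers[0] = points[rng.integers(n)]
    d2 = np.maximum(_sq_dists(points, centers[:1]).ravel(), 0.0)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a center
            centers[i] = points[rng.integers(n)]
            continue
        idx = rng.choice(n, p=d2 / total)
        centers[i] = points[idx]
        d2 = np.minimum(d2, np.maximum(_sq_dists(points, centers[i : i + 1]).ravel(), 0.0))
    return centers


def _lloyd(points: np.ndarray, k: int, max_iter: int, rng: np.random.Generator):
    centroids = _kmeanspp_init(points, k, rng)
    labels = np.zeros(len(points), dtype=int)
    history: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = np.maximum(_sq_dists(points, centroids), 0.0)
        new_labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(points)), new_labels].sum())
        # singleton action: an emptied cluster is re-seeded with the point
        # farthest from its current centroid
        for j in range(k):
            if not np.any(new_labels == j):
                far = int(d2[np.arange(len(points)), new_labels].argmax())
                new_labels[far] = j
        if history and inertia > history[-1] + 1e-9:
            raise AssertionError(
                f"inertia increased across Lloyd iterations: {history[-1]} -> {inertia}"
            )
        history.append(inertia)
        converged = np.array_equal(new_labels, labels) and it > 1
        labels = new_labels
        for j in range(k):
            member = points[labels == j]
            if len(member):
                centroids[j] = member.mean(axis=0)
        if converged:
            break
    # final consistent assignment/inertia under the final centroids
    d2 = np.maximum(_sq_dists(points, centroids), 0.0)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(points)), labels].sum())
    history.append(inertia)
    return labels, centroids, inertia, history


def cluster_pixels(img: RasterImage, spec: KMeansSpec = KMeansSpec()) -> ClusterResult:
    """Cluster the pixels of a unit-scaled image; best of ``replicates`` runs.

    Replicate r uses RNG seed ``spec.seed + r`` so the whole procedure is
    deterministic given ``spec.seed``.
    """
    points = img.pixels.reshape(-1, 3).astype(float)
    if spec.k > len(points):
        raise DegenerateKError(f"k={spec.k} exceeds the {len(points)} pixels")
    best = None
    for r in range(spec.replicates):
        rng = np.random.default_rng(spec.seed + r)
        labels, centroids, inertia, history = _lloyd(points, spec.k, spec.max_iter, rng)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia, history)
    labels, centroids, inertia, history = best
    return ClusterResult(
        labels=labels.reshape(img.shape),
        centroids=centroids,
        inertia=inertia,
        inertia_history=history,
        n_iter=len(history) - 1,
    )


def identify_flower_clusters(result: ClusterResult, rule: ThresholdRule) -> np.ndarray:
    """Union of pixels of clusters whose centroid color satisfies ``rule``.

    Centroids are interpreted as R, G, B on the unit scale.
    """
    channels = {
        "R": result.centroids[:, 0],
        "G": result.centroids[:, 1],
        "B": result.centroids[:, 2],
    }
    flagged = rule.evaluate(channels)
    if not np.any(flagged):
        log.warning("no cluster centroid satisfies the flower color rule")
        return np.zeros(result.labels.shape, bool)
    return np.isin(result.labels, np.flatnonzero(flagged))


def kmeans_flower_mask(
    img: RasterImage,
    spec: KMeansSpec = KMeansSpec(),
    rule: ThresholdRule | None = None,
    canopy_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Rescale to [0, 1], cluster, and flag flower clusters by centroid color.

    ``canopy_mask`` optionally restricts clustering to canopy pixels; the
    default clusters every pixel (which is what lets pale soil glints join a
    white-flower cluster — the method's known failure mode on white flowers).
    """
    if rule is None:
        raise ValueError("a centroid color rule is required")
    unit = rescale_to_unit(img)
    if canopy_mask is None:
        result = cluster_pixels(unit, spec)
        return identify_flower_clusters(result, rule)
    canopy_mask = np.asarray(canopy_mask, bool)
    points = unit.pixels[canopy_mask]
    sub = RasterImage(points.reshape(1, -1, 3), bands=unit.bands, scale=unit.scale)
    result = cluster_pixels(sub, spec)
    mask = np.zeros(img.shape, bool)
    mask[canopy_mask] = identify_flower_clusters(result, rule).ravel()
    return mask
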