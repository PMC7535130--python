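"""Automatic trimap initialisation by Montecarlo-sampled K-means.

Instead of the manual rectangle of classic GrabCut, a random subset of
``l`` pixels is drawn uniformly over the image and clustered into two
groups by colour.  In canopy-dominant plot imagery the larger cluster is
the canopy: its sampled coordinates seed the known-foreground mask T_F,
the smaller cluster's seed the known-background mask T_B, and every
unsampled pixel stays uncertain (T_U).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raster import MultispectralScene


@dataclass
class PixelSample:
    """Sampled colour vectors z_l and their pixel coordinates z_xy."""

    values: np.ndarray  # (l, C) colour vectors
    coords: np.ndarray  # (l, 2) row, col

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if len(self.values) != len(self.coords):
            raise ValueError("values and coords must have equal length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Trimap:
    """Disjoint binary masks: known background, known foreground, uncertain."""

    T_B: np.ndarray
    T_F: np.ndarray
    T_U: np.ndarray

    def __post_init__(self) -> None:
        for name in ("T_B", "T_F", "T_U"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.uint8))
        if not (self.T_B.shape == self.T_F.shape == self.T_U.shape):
            raise ValueError("trimap masks must share one shape")
        if np.any(self.T_B & self.T_F):
            raise ValueError("T_B and T_F overlap")


def sample_pixels(scene: MultispectralScene, l: int, seed: int) -> PixelSample:
    """Draw ``l`` pixels uniformly at random (with replacement) from the scene."""
    if l < 2:
        raise ValueError("need at least 2 samples")
    H, W = scene.shape
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, H, size=l)
    cols = rng.integers(0, W, size=l)
    z = scene.composite
    return PixelSample(values=z[rows, cols], coords=np.stack([rows, cols], axis=1))


def _lloyd_once(X, centroids, max_iter, tol):
    for _ in range(max_iter):
        dist = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(dist, axis=1)
        new_centroids = centroids.copy()
        for j in range(len(centroids)):
            members = X[labels == j]
            if len(members):
                new_centroids[j] = members.mean(axis=0)
        shift = np.max(np.abs(new_centroids - centroids))
        centroids = new_centroids
        if shift < tol:
            break
    dist = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(dist, axis=1)
    inertia = float(np.take_along_axis(dist, labels[:, None], axis=1).sum())
    return labels, centroids, inertia


def lloyd_kmeans(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_init: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded Lloyd iterations with multi-restart random initialisation.

    Each restart seeds the centroids with k distinct random data points;
    the solution with the lowest within-cluster sum of squares wins.
    (A farthest-point seed was tried first but reliably locks onto a
    bright-outlier-versus-rest partition on scenes with clipped
    highlights, a worse local optimum than the canopy/soil split.)
    Deterministic given the generator state.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if n < k:
        raise ValueError(f"need at least {k} points, got {n}")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"fewer than {k} distinct points; cannot form {k} clusters")

    best = None
    for _ in range(n_init):
        seeds = X[rng.choice(n, size=k, replace=False)]
        # resample until the k seed points are distinct
        for _ in range(20):
            if len(np.unique(seeds, axis=0)) == k:
                break
            seeds = X[rng.choice(n, size=k, replace=False)]
        labels, centroids, inertia = _lloyd_once(X, seeds.copy(), max_iter, tol)
        if len(np.unique(labels)) == k and (best is None or inertia < best[2]):
            best = (labels, centroids, inertia)
    if best is None:  # every restart emptied a cluster; fall back to extremes
        order = np.argsort(X.sum(axis=1))
        seeds = X[[order[0], order[-1]]] if k == 2 else X[order[:: max(1, n // k)][:k]]
        best = _lloyd_once(X, seeds.copy(), max_iter, tol)
    return best[0], best[1]


def binary_kmeans(
    sample: PixelSample, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two-way colour clustering of the sampled pixels.

    Returns per-sample labels in {0, 1} and the two centroids.  Raises on
    degenerate input (all colours identical).
    """
    if len(sample) < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(sample.values, axis=0)) < 2:
        raise ValueError("all sampled colours identical; cannot form two clusters")
    rng = np.random.default_rng(seed)
    return lloyd_kmeans(sample.values, 2, rng)


def build_trimap(
    scene: MultispectralScene,
    sample: PixelSample,
    labels: np.ndarray,
    seed: int = 0,
) -> Trimap:
    """Turn clustered samples into the (T_B, T_F, T_U) trimap.

    The larger cluster's sampled coordinates become known foreground
    (canopy), the smaller's known background (soil).  An exact size tie is
    broken in favour of the cluster with the higher mean NIR value
    (vegetation reflects NIR strongly); without a NIR channel the higher
    mean over all channels wins.
    """
    labels = np.asarray(labels)
    n0 = int(np.sum(labels == 0))
    n1 = int(np.sum(labels == 1))
    if n0 == 0 or n1 == 0:
        raise ValueError("both clusters must be non-empty")
    if n0 != n1:
        fg_label = 0 if n0 > n1 else 1
    else:
        if "nir" in scene.composite_order:
            ch = scene.composite_order.index("nir")
        else:
            ch = slice(None)
        m0 = sample.values[labels == 0, ch].mean()
        m1 = sample.values[labels == 1, ch].mean()
        fg_label = 0 if m0 >= m1 else 1

    H, W = scene.shape
    T_F = np.zeros((H, W), dtype=np.uint8)
    T_B = np.zeros((H, W), dtype=np.uint8)
    fg = sample.coords[labels == fg_label]
    bg = sample.coords[labels != fg_label]
    T_F[fg[:, 0], fg[:, 1]] = 1
    T_B[bg[:, 0], bg[:, 1]] = 1
    # a coordinate sampled twice with conflicting labels stays foreground
    both = (T_F == 1) & (T_B == 1)
    if np.any(both):
        warnings.warn("duplicate sampled coordinates with conflicting labels; kept as foreground")
        T_B[both] = 0
    T_U = ((T_F == 0) & (T_B == 0)).astype(np.uint8)
    return Trimap(T_B=T_B, T_F=T_F, T_U=T_U)


def montecarlo_trimap(
    scene: MultispectralScene, l: int = 1000, seed: int = 0
) -> Trimap:
    """Full automatic initialisation: sample, cluster, build the trimap."""
    sample = sample_pixels(scene, l, seed)
    labels, _ = binary_kmeans(sample, seed)
    return build_trimap(scene, sample, labels, seed)
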