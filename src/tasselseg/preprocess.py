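"""Denoising and downsampling chain for raw tassel clouds.

Order of operations in the standard pipeline: HSV foreground masking,
statistical outlier removal, seeded random downsampling, farthest-point
sampling, then normal estimation for the segmentation network input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import rgb_to_hsv
from scipy.spatial import cKDTree

from tasselseg.io_formats import PointCloud, PointCloudError

__all__ = [
    "OutlierFilterParams",
    "HsvRange",
    "hsv_foreground_mask",
    "statistical_outlier_filter",
    "random_downsample",
    "farthest_point_sample",
    "estimate_normals",
    "mean_nn_distance",
]


@dataclass(frozen=True)
class OutlierFilterParams:
    """Statistical outlier-removal parameters.

    ``n_neighbors`` nearest neighbors are averaged per point; a point is an
    outlier when its mean neighbor distance exceeds the global mean of
    those averages by more than ``alpha`` global standard deviations.
    """

    n_neighbors: int = 20
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass(frozen=True)
class HsvRange:
    """HSV acceptance window; hue on the 0-180 (degrees / 2) scale."""

    h_min: float = 15.0
    h_max: float = 180.0
    s_min: float = 0.05
    s_max: float = 1.0
    v_min: float = 0.0
    v_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.h_min <= self.h_max <= 180):
            raise ValueError("hue bounds must satisfy 0 <= h_min <= h_max <= 180")
        for lo, hi, name in ((self.s_min, self.s_max, "s"), (self.v_min, self.v_max, "v")):
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"{name} bounds must satisfy 0 <= min <= max <= 1")


def hsv_foreground_mask(cloud: PointCloud, hsv_range: HsvRange = HsvRange()) -> np.ndarray:
    """Boolean mask of points whose color lies inside the HSV window.

    Uses the standard hexcone RGB->HSV conversion with hue reported on the
    0-180 half-degree scale.
    """
    if cloud.colors is None:
        raise PointCloudError("hsv_foreground_mask requires a color channel")
    hsv = rgb_to_hsv(cloud.colors)
    h = hsv[:, 0] * 180.0  # matplotlib hue is in [0, 1] = [0, 360) degrees
    s = hsv[:, 1]
    v = hsv[:, 2]
    r = hsv_range
    return (
        (h >= r.h_min) & (h <= r.h_max)
        & (s >= r.s_min) & (s <= r.s_max)
        & (v >= r.v_min) & (v <= r.v_max)
    )


def statistical_outlier_filter(
    cloud: PointCloud, params: OutlierFilterParams = OutlierFilterParams()
) -> tuple[PointCloud, np.ndarray]:
    """Remove sparse outliers; returns ``(kept_cloud, removed_indices)``.

    Two-pass scheme: (1) per point, the mean distance to its
    ``n_neighbors`` nearest neighbors; (2) a point is removed iff that
    mean exceeds the global mean of per-point means plus ``alpha`` times
    their sample standard deviation. Order is preserved within the kept
    set.
    """
    n = len(cloud)
    if params.n_neighbors >= n:
        raise PointCloudError(
            f"n_neighbors ({params.n_neighbors}) must be < number of points ({n})"
        )
    tree = cKDTree(cloud.coords)
    dist, _ = tree.query(cloud.coords, k=params.n_neighbors + 1)
    mean_dist = dist[:, 1:].mean(axis=1)  # drop self at distance 0
    threshold = mean_dist.mean() + params.alpha * mean_dist.std(ddof=1)
    # relative epsilon so perfectly symmetric clouds (std ~ rounding noise)
    # are not split by the last ulp of the kd-tree distances
    threshold += 1e-9 * abs(threshold)
    removed = np.flatnonzero(mean_dist > threshold)
    kept = np.flatnonzero(mean_dist <= threshold)
    return cloud.select(kept), removed


def random_downsample(cloud: PointCloud, target_n: int, seed: int) -> PointCloud:
    """Uniform subsample without replacement, original order preserved."""
    n = len(cloud)
    if not (1 <= target_n <= n):
        raise PointCloudError(f"target_n must be in [1, {n}], got {target_n}")
    rng = np.random.default_rng(seed)
    index = np.sort(rng.choice(n, size=target_n, replace=False))
    return cloud.select(index)


def farthest_point_sample(
    cloud: PointCloud, target_n: int, start_index: int = 0
) -> np.ndarray:
    """Greedy maximin index selection (FPS), ties broken by lowest index.

    Returns ``target_n`` distinct indices in selection order; the first is
    ``start_index`` and each later pick maximizes the minimum distance to
    the points already selected.
    """
    coords = cloud.coords
    n = len(coords)
    if not (1 <= target_n <= n):
        raise PointCloudError(f"target_n must be in [1, {n}], got {target_n}")
    if not (0 <= start_index < n):
        raise PointCloudError("start_index out of range")
    selected = np.empty(target_n, dtype=np.int64)
    selected[0] = start_index
    min_d2 = np.sum((coords - coords[start_index]) ** 2, axis=1)
    for i in range(1, target_n):
        nxt = int(np.argmax(min_d2))  # argmax returns the lowest tied index
        selected[i] = nxt
        d2 = np.sum((coords - coords[nxt]) ** 2, axis=1)
        np.minimum(min_d2, d2, out=min_d2)
    return selected


def estimate_normals(cloud: PointCloud, k: int = 16) -> PointCloud:
    """Per-point PCA normals from the k nearest neighbors.

    The normal is the eigenvector of the smallest covariance eigenvalue,
    oriented away from the cloud centroid; degenerate (rank < 2)
    neighborhoods fall back to +z.
    """
    n = len(cloud)
    if not (3 <= k < n):
        raise PointCloudError(f"k must satisfy 3 <= k < N, got k={k}, N={n}")
    tree = cKDTree(cloud.coords)
    _, idx = tree.query(cloud.coords, k=k + 1)
    nbrs = cloud.coords[idx]  # (N, k+1, 3), includes self
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    eigvals, eigvecs = np.linalg.eigh(cov)
    normals = eigvecs[:, :, 0]  # eigh sorts ascending
    centroid = cloud.coords.mean(axis=0)
    flip = np.einsum("ni,ni->n", normals, cloud.coords - centroid) < 0
    normals[flip] *= -1.0
    degenerate = eigvals[:, 1] < 1e-12 * np.maximum(eigvals[:, 2], 1e-300)
    normals[degenerate] = [0.0, 0.0, 1.0]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return cloud.with_(normals=normals)


def mean_nn_distance(cloud: PointCloud) -> float:
    """Mean over points of the distance to the single nearest neighbor."""
    if len(cloud) < 2:
        raise PointCloudError("mean_nn_distance needs at least 2 points")
    tree = cKDTree(cloud.coords)
    dist, _ = tree.query(cloud.coords, k=2)
    return float(dist[:, 1].mean())


def mean_neighbor_distance(cloud: PointCloud, n_neighbors: int = 20) -> float:
    """Mean over points of the mean distance to the n nearest neighbors.

    This is the same per-point statistic the outlier filter averages; it
    is the density scale used for the adaptive clustering radius (the
    single-nearest-neighbor mean is too tight at working resolution).
    """
    n = len(cloud)
    if n < 2:
        raise PointCloudError("mean_neighbor_distance needs at least 2 points")
    k = min(n_neighbors, n - 1)
    tree = cKDTree(cloud.coords)
    dist, _ = tree.query(cloud.coords, k=k + 1)
    return float(dist[:, 1:].mean())
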