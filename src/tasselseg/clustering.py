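"""Density clustering of branch-tip points into branch instances.

The adaptive radius is three times the mean neighbor distance of the tip
cloud (mean over each point's 20 nearest neighbors — the same statistic
the outlier filter uses), with a neighborhood density threshold of
``min_pts`` points and rejection of clusters smaller than
``min_cluster_size``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.spatial import cKDTree

from tasselseg.io_formats import PointCloud, PointCloudError
from tasselseg.preprocess import mean_neighbor_distance

__all__ = ["ClusterParams", "TipInstanceSet", "density_cluster", "branch_count"]

NOISE = -1


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN-style parameters; ``eps="auto"`` uses 3 x mean neighbor distance."""

    eps: Union[float, str] = "auto"
    min_pts: int = 5
    min_cluster_size: int = 10

    def __post_init__(self) -> None:
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if isinstance(self.eps, str) and self.eps != "auto":
            raise ValueError("eps must be a positive number or 'auto'")
        if not isinstance(self.eps, str) and self.eps <= 0:
            raise ValueError("eps must be a positive number or 'auto'")


@dataclass
class TipInstanceSet:
    """Per-tip-point instance assignment; id -1 marks noise or rejected."""

    instance_ids: np.ndarray
    n_instances: int
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.instance_ids = np.asarray(self.instance_ids, dtype=np.int64)

    def members(self, instance: int) -> np.ndarray:
        return np.flatnonzero(self.instance_ids == instance)


def _dbscan_labels(neighbors: list[np.ndarray], min_pts: int) -> np.ndarray:
    """DBSCAN with pinned semantics.

    ``neighbors[i]`` are indices within eps of i (self included, sorted
    ascending). Core points are scanned in ascending index order; each
    unvisited core seeds a FIFO breadth-first expansion, so border points
    join the first cluster whose core reaches them.
    """
    n = len(neighbors)
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, NOISE, dtype=np.int64)
    cid = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        labels[i] = cid
        queue = [i]
        head = 0
        while head < len(queue):
            j = queue[head]
            head += 1
            for q in neighbors[j]:
                if labels[q] == NOISE:
                    labels[q] = cid
                    if core[q]:
                        queue.append(q)
        cid += 1
    return labels


def density_cluster(
    tip_points: PointCloud, params: ClusterParams = ClusterParams()
) -> TipInstanceSet:
    """Cluster tip points into branch instances.

    Clusters below ``min_cluster_size`` are relabeled as noise; the
    survivors are renumbered by descending size (ties by first
    appearance).
    """
    n = len(tip_points)
    if n == 0:
        raise PointCloudError("density_cluster requires a nonempty tip cloud")
    eps = params.eps
    if isinstance(eps, str):
        if n < 2:
            raise PointCloudError("auto eps needs at least 2 tip points")
        eps = 3.0 * mean_neighbor_distance(tip_points, n_neighbors=20)
    tree = cKDTree(tip_points.coords)
    raw = tree.query_ball_point(tip_points.coords, r=float(eps))
    neighbors = [np.sort(np.asarray(nb, dtype=np.int64)) for nb in raw]
    labels = _dbscan_labels(neighbors, params.min_pts)

    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    keep = ids[counts >= params.min_cluster_size]
    keep_counts = counts[counts >= params.min_cluster_size]
    # renumber by descending size; stable for ties (lower original id first)
    order = np.argsort(-keep_counts, kind="stable")
    remap = np.full(int(labels.max()) + 2, NOISE, dtype=np.int64)
    for new_id, k in enumerate(order):
        remap[keep[k]] = new_id
    final = np.where(labels >= 0, remap[labels], NOISE)

    n_instances = len(keep)
    centroids = np.zeros((n_instances, 3))
    for c in range(n_instances):
        centroids[c] = tip_points.coords[final == c].mean(axis=0)
    return TipInstanceSet(instance_ids=final, n_instances=n_instances,
                          centroids=centroids)


def branch_count(instances: TipInstanceSet) -> int:
    """Number of accepted branch-top instances."""
    return instances.n_instances
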