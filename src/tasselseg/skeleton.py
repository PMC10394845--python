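"""Bottom-up minimum-path skeleton extraction.

Given the remainder cloud (tassel minus branch tips) and the clustered
tip instances: find one growth point per instance, select the root as the
candidate maximizing the convex-hull volume formed with all growth
points, build a shortest-path spanning tree over the radius graph, trace
per-branch paths, pick the longest as the main stem, and fuse every
original point onto its nearest skeleton polyline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import cdist

from tasselseg.clustering import TipInstanceSet
from tasselseg.io_formats import PointCloud, PointCloudError
from tasselseg.preprocess import farthest_point_sample, mean_nn_distance

__all__ = [
    "SkeletonTree",
    "BranchSet",
    "SkeletonError",
    "initial_growth_points",
    "convex_hull_volume",
    "select_root",
    "build_spanning_tree",
    "extract_branch_paths",
    "assign_points_to_branches",
    "extend_paths_to_tips",
]

MAIN_STEM_ID = -2
_NO_PARENT = -1


class SkeletonError(RuntimeError):
    """Skeleton construction failed (disconnected graph, bad growth point)."""


@dataclass
class SkeletonTree:
    """Parent-pointer spanning tree over the skeleton nodes."""

    node_coords: np.ndarray          # (M, 3)
    parent: np.ndarray               # (M,), root has -1
    root: int
    edge_length: np.ndarray          # (M,), distance to parent, root = 0
    radii: Optional[np.ndarray] = None   # (M,) final per-node graph radius

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def path_to_root(self, node: int) -> np.ndarray:
        """Node indices from ``node`` to the root, inclusive."""
        path = [node]
        seen = {node}
        while self.parent[path[-1]] != _NO_PARENT:
            nxt = int(self.parent[path[-1]])
            if nxt in seen:
                raise SkeletonError("parent pointers contain a cycle")
            path.append(nxt)
            seen.add(nxt)
        if path[-1] != self.root:
            raise SkeletonError(f"node {node} does not reach the root")
        return np.asarray(path, dtype=np.int64)


@dataclass
class BranchSet:
    """Per-branch skeleton paths plus full-cloud point membership.

    ``paths[i]`` is the full node sequence growth-point -> root for
    instance i; the branch skeleton of a non-stem branch is the prefix up
    to (and including) ``branch_base[i]``, the first node shared with the
    main-stem path. ``apex`` optionally holds one measured tip-apex
    coordinate per branch, prepended when measuring traits so lengths
    include the network-segmented tip extent.
    """

    node_coords: np.ndarray
    growth_points: np.ndarray                # (B,) node index per instance
    paths: list                              # list of (Li,) index arrays, tip->root
    main_stem: int                           # index into paths
    branch_base: np.ndarray                  # (B,) node index
    point_membership: Optional[np.ndarray] = None
    apex: Optional[np.ndarray] = None        # (B, 3) or None
    base_attach: Optional[np.ndarray] = None  # (B, 3) stem attachment points

    @property
    def n_branches(self) -> int:
        return len(self.paths)

    def branch_node_path(self, i: int) -> np.ndarray:
        """Node indices of branch i's skeleton, tip -> branch base."""
        path = self.paths[i]
        if i == self.main_stem:
            return path
        stop = int(np.flatnonzero(path == self.branch_base[i])[0])
        return path[: stop + 1]

    def branch_polyline(self, i: int, include_apex: bool = True) -> np.ndarray:
        """Coordinates of branch i's skeleton, apex/tip first, stem attachment last."""
        coords = self.node_coords[self.branch_node_path(i)]
        if include_apex and self.apex is not None and np.all(np.isfinite(self.apex[i])):
            coords = np.vstack([self.apex[i], coords])
        if (i != self.main_stem and self.base_attach is not None
                and np.linalg.norm(self.base_attach[i] - coords[-1]) > 1e-9):
            coords = np.vstack([coords, self.base_attach[i]])
        return coords

    def main_stem_polyline(self, include_apex: bool = True) -> np.ndarray:
        return self.branch_polyline(self.main_stem, include_apex=include_apex)


def initial_growth_points(
    remainder: PointCloud, instances: TipInstanceSet, tip_points: PointCloud
) -> np.ndarray:
    """For each tip instance, the remainder point nearest to the instance.

    Ties are broken toward the lowest remainder index.
    """
    if len(remainder) == 0:
        raise PointCloudError("initial_growth_points requires a nonempty remainder")
    if instances.n_instances < 1:
        raise PointCloudError("no tip instances")
    growth = np.empty(instances.n_instances, dtype=np.int64)
    for c in range(instances.n_instances):
        inst_coords = tip_points.coords[instances.members(c)]
        d = cdist(remainder.coords, inst_coords).min(axis=1)
        growth[c] = int(np.argmin(d))
    return growth


def convex_hull_volume(points: np.ndarray) -> float:
    """Volume of the 3-D convex hull; degenerate inputs give 0."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (K, 3)")
    if len(points) < 4:
        return 0.0
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return 0.0


def select_root(remainder: PointCloud, growth_points: np.ndarray) -> int:
    """Candidate maximizing hull volume with the growth points.

    Falls back to the maximal distance-sum candidate when every hull is
    degenerate (fewer than 3 growth points, collinear geometry).
    """
    growth_points = np.asarray(growth_points, dtype=np.int64)
    if len(growth_points) < 1:
        raise PointCloudError("select_root needs at least one growth point")
    growth_set = set(int(g) for g in growth_points)
    candidates = [i for i in range(len(remainder)) if i not in growth_set]
    if not candidates:
        raise PointCloudError("remainder contains only growth points")
    gp_coords = remainder.coords[growth_points]
    best, best_vol = candidates[0], -1.0
    for i in candidates:
        vol = convex_hull_volume(np.vstack([gp_coords, remainder.coords[i]]))
        if vol > best_vol + 1e-12:
            best, best_vol = i, vol
    if best_vol > 1e-12:
        return best
    dist_sum = cdist(remainder.coords[candidates], gp_coords).sum(axis=1)
    return candidates[int(np.argmax(dist_sum))]


def _radius_graph(coords: np.ndarray, radii: np.ndarray) -> csr_matrix:
    """Symmetric graph with an edge when d(i, j) <= max(radius_i, radius_j)."""
    tree = cKDTree(coords)
    rows, cols, vals = [], [], []
    # query per distinct radius value to keep it vectorized
    for r in np.unique(radii):
        idx = np.flatnonzero(radii == r)
        neighbor_lists = tree.query_ball_point(coords[idx], r=float(r))
        for i, nbrs in zip(idx, neighbor_lists):
            nbrs = np.asarray(nbrs, dtype=np.int64)
            nbrs = nbrs[nbrs != i]
            if len(nbrs) == 0:
                continue
            d = np.linalg.norm(coords[nbrs] - coords[i], axis=1)
            rows.append(np.full(len(nbrs), i, dtype=np.int64))
            cols.append(nbrs)
            vals.append(d)
    if not rows:
        return csr_matrix((len(coords), len(coords)))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    g = csr_matrix((vals, (rows, cols)), shape=(len(coords), len(coords)))
    return g.maximum(g.T)


def build_spanning_tree(
    remainder: PointCloud,
    root: int,
    radius: Union[float, str] = "auto",
    radius_growth: float = 1.5,
    max_expansions: int = 20,
) -> SkeletonTree:
    """Shortest-path spanning tree over the radius graph rooted at ``root``.

    Edges connect points within ``radius`` (weight = Euclidean distance)
    and Dijkstra predecessors become parent pointers. When some points
    are unreachable, their radius is multiplied by ``radius_growth`` and
    the search repeats — the multi-layer neighborhood that bridges uneven
    sampling density.
    """
    coords = remainder.coords
    m = len(coords)
    if not (0 <= root < m):
        raise PointCloudError("root index out of range")
    if isinstance(radius, str):
        if m < 2:
            raise PointCloudError("auto radius needs at least 2 points")
        radius = 3.0 * mean_nn_distance(remainder)
    radii = np.full(m, float(radius))
    for expansion in range(max_expansions + 1):
        graph = _radius_graph(coords, radii)
        dist, pred = dijkstra(graph, directed=False, indices=root,
                              return_predecessors=True)
        unreachable = ~np.isfinite(dist)
        if not unreachable.any():
            break
        if radius_growth <= 1.0:
            raise SkeletonError(
                "graph disconnected and radius_growth <= 1 cannot bridge it"
            )
        if expansion == max_expansions:
            raise SkeletonError(
                f"graph still disconnected after {max_expansions} radius expansions"
            )
        radii[unreachable] *= radius_growth
    parent = np.where(pred == -9999, _NO_PARENT, pred).astype(np.int64)
    parent[root] = _NO_PARENT
    edge_length = np.zeros(m)
    has_parent = parent != _NO_PARENT
    edge_length[has_parent] = np.linalg.norm(
        coords[has_parent] - coords[parent[has_parent]], axis=1
    )
    return SkeletonTree(node_coords=coords.copy(), parent=parent, root=root,
                        edge_length=edge_length, radii=radii)


def _polyline_length(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(coords, axis=0), axis=1).sum())


def extract_branch_paths(
    tree: SkeletonTree,
    growth_points: np.ndarray,
    merge_tolerance: Union[float, str] = "auto",
) -> BranchSet:
    """Trace per-instance paths to the root and identify the main stem.

    The main stem is the path of maximal polyline length (ties to the
    lowest instance index). Every other branch is truncated at the first
    node (walking from the tip) that merges with the main stem: a node it
    shares with the main-stem path, or one within ``merge_tolerance`` of
    the main-stem polyline — shortest-path chains descending a stem of
    finite thickness can run parallel for a while before sharing a node,
    which would otherwise push the branch base far below the attachment.
    ``"auto"`` tolerance is 1.5 x the mean node spacing.
    """
    growth_points = np.asarray(growth_points, dtype=np.int64)
    paths = []
    for b, g in enumerate(growth_points):
        try:
            paths.append(tree.path_to_root(int(g)))
        except SkeletonError as exc:
            raise SkeletonError(f"growth point of instance {b}: {exc}") from exc
    lengths = [_polyline_length(tree.node_coords[p]) for p in paths]
    main_stem = int(np.argmax(lengths))  # argmax -> lowest tied index
    stem_path = paths[main_stem]
    stem_nodes = set(int(v) for v in stem_path)
    stem_poly = tree.node_coords[stem_path]
    if isinstance(merge_tolerance, str):
        nn = cKDTree(tree.node_coords).query(tree.node_coords, k=2)[0][:, 1]
        merge_tolerance = 1.5 * float(nn.mean())
    branch_base = np.empty(len(paths), dtype=np.int64)
    for b, path in enumerate(paths):
        if b == main_stem:
            branch_base[b] = path[0]
            continue
        d_stem = _points_to_polyline_dist(tree.node_coords[path], stem_poly)
        merged = [i for i, node in enumerate(path)
                  if int(node) in stem_nodes or d_stem[i] <= merge_tolerance]
        branch_base[b] = path[merged[0]] if merged else path[-1]
    base_attach = np.stack([
        _closest_point_on_polyline(tree.node_coords[branch_base[b]], stem_poly)
        for b in range(len(paths))
    ])
    return BranchSet(node_coords=tree.node_coords, growth_points=growth_points,
                     paths=paths, main_stem=main_stem, branch_base=branch_base,
                     base_attach=base_attach)


def smooth_polyline(coords: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Endpoint-preserving moving-average smoothing of a polyline.

    Damps the transverse zigzag that skeleton nodes inherit from surface
    thickness, which otherwise inflates arc-length measurements.
    """
    coords = np.asarray(coords, dtype=np.float64).copy()
    for _ in range(iterations):
        if len(coords) < 3:
            break
        interior = (coords[:-2] + 2.0 * coords[1:-1] + coords[2:]) / 4.0
        coords[1:-1] = interior
    return coords


def _closest_point_on_polyline(point: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Nearest position on the polyline (segments) to ``point``."""
    if len(poly) == 1:
        return poly[0].copy()
    a, b = poly[:-1], poly[1:]
    ab = b - a
    ab2 = np.einsum("sj,sj->s", ab, ab)
    ab2[ab2 == 0] = 1.0
    t = np.clip(np.einsum("sj,sj->s", point - a, ab) / ab2, 0.0, 1.0)
    cand = a + t[:, None] * ab
    return cand[int(np.argmin(np.linalg.norm(cand - point, axis=1)))]


def _points_to_polyline_dist(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point to the polyline (segments, not nodes)."""
    if len(poly) == 1:
        return np.linalg.norm(points - poly[0], axis=1)
    a = poly[:-1]                       # (S, 3)
    ab = poly[1:] - a                   # (S, 3)
    ab2 = np.einsum("sj,sj->s", ab, ab)
    ab2[ab2 == 0] = 1.0
    best = np.full(len(points), np.inf)
    chunk = max(1, int(2e6 // max(len(points), 1)))
    for s0 in range(0, len(a), chunk):
        a_c = a[s0:s0 + chunk]
        ab_c = ab[s0:s0 + chunk]
        ab2_c = ab2[s0:s0 + chunk]
        ap = points[:, None, :] - a_c[None, :, :]            # (N, S, 3)
        t = np.clip(np.einsum("nsj,sj->ns", ap, ab_c) / ab2_c, 0.0, 1.0)
        diff = ap - t[:, :, None] * ab_c[None, :, :]
        d = np.sqrt(np.einsum("nsj,nsj->ns", diff, diff)).min(axis=1)
        np.minimum(best, d, out=best)
    return best


def assign_points_to_branches(full_cloud: PointCloud, branches: BranchSet) -> np.ndarray:
    """Fuse every original point onto its nearest skeleton polyline.

    Returns a per-point id: ``MAIN_STEM_ID`` (-2) for the stem, else the
    branch (instance) index. Ties resolve to the stem first, then to the
    lower branch id.
    """
    if branches.n_branches < 1:
        raise PointCloudError("assign_points_to_branches needs >= 1 branch path")
    points = full_cloud.coords
    order = [(MAIN_STEM_ID, branches.main_stem_polyline(include_apex=False))]
    for b in range(branches.n_branches):
        if b == branches.main_stem:
            continue
        order.append((b, branches.node_coords[branches.branch_node_path(b)]))
    best_id = np.full(len(points), order[0][0], dtype=np.int64)
    best_d = _points_to_polyline_dist(points, order[0][1])
    for bid, poly in order[1:]:
        d = _points_to_polyline_dist(points, poly)
        closer = d < best_d - 1e-12
        best_id[closer] = bid
        np.minimum(best_d, d, out=best_d)
    return best_id


def extend_paths_to_tips(
    branches: BranchSet, tip_points: PointCloud, instances: TipInstanceSet
) -> BranchSet:
    """Attach a tip apex per branch so trait measurements span the tip.

    The skeleton tree covers only the remainder cloud; each path starts at
    the growth point just below the segmented tip. The apex is the tip
    point of the matching instance farthest from the branch base, giving
    polylines that reach the true branch end.
    """
    apex = np.full((branches.n_branches, 3), np.nan)
    for b in range(branches.n_branches):
        members = instances.members(b)
        if len(members) == 0:
            continue
        base = branches.node_coords[branches.branch_base[b]]
        tip_coords = tip_points.coords[members]
        apex[b] = tip_coords[int(np.argmax(np.linalg.norm(tip_coords - base, axis=1)))]
    branches.apex = apex
    return branches
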