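"""Morphological trait computation from skeleton branches.

Six traits per tassel: branch count, per-branch length, insertion angle,
curvature (arc / chord ratio), convex-hull tassel volume, and dispersion
(mean insertion angle over pi/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from tasselseg.clustering import TipInstanceSet
from tasselseg.io_formats import PointCloud
from tasselseg.skeleton import BranchSet, convex_hull_volume

__all__ = [
    "TraitRecord",
    "branch_length",
    "branch_angle",
    "branch_curvature",
    "tassel_volume",
    "tassel_dispersion",
    "extract_traits",
    "ANGLE_ARC_FRACTION",
]

#: Fraction of branch arc length (from the base) used to form the branch
#: direction vector for the insertion angle. A near-base chord keeps the
#: measured angle meaningful on drooping branches.
ANGLE_ARC_FRACTION = 0.25

_CSV_COLUMNS = [
    "tassel_id", "branch_count", "branch_length_mean_cm", "branch_length_sd_cm",
    "branch_angle_mean_deg", "branch_angle_sd_deg", "branch_curvature_mean",
    "branch_curvature_sd", "tassel_volume_cm3", "tassel_dispersion",
]


@dataclass
class TraitRecord:
    """The six traits of one tassel; per-branch lists exclude the main stem."""

    branch_count: int
    branch_lengths: np.ndarray
    branch_angles: np.ndarray
    branch_curvatures: np.ndarray
    tassel_volume: float
    tassel_dispersion: float

    @staticmethod
    def csv_columns() -> list[str]:
        return list(_CSV_COLUMNS)

    def to_row(self, tassel_id: str) -> dict:
        def _stat(arr, f):
            return float(f(arr)) if len(arr) else float("nan")

        return {
            "tassel_id": tassel_id,
            "branch_count": self.branch_count,
            "branch_length_mean_cm": _stat(self.branch_lengths, np.mean),
            "branch_length_sd_cm": _stat(self.branch_lengths, np.std),
            "branch_angle_mean_deg": _stat(self.branch_angles, np.mean),
            "branch_angle_sd_deg": _stat(self.branch_angles, np.std),
            "branch_curvature_mean": _stat(self.branch_curvatures, np.mean),
            "branch_curvature_sd": _stat(self.branch_curvatures, np.std),
            "tassel_volume_cm3": self.tassel_volume,
            "tassel_dispersion": self.tassel_dispersion,
        }


def branch_length(path: np.ndarray) -> float:
    """Polyline arc length (cm) of an ordered node path."""
    path = np.asarray(path, dtype=np.float64)
    if len(path) < 2:
        raise ValueError("branch_length needs at least 2 nodes")
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())


def _point_at_arc_fraction(path_from_base: np.ndarray, fraction: float) -> np.ndarray:
    """Interpolated position ``fraction`` of the arc length from the base."""
    seg = np.linalg.norm(np.diff(path_from_base, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = fraction * cum[-1]
    i = int(np.searchsorted(cum, target, side="right")) - 1
    i = min(i, len(seg) - 1)
    t = 0.0 if seg[i] == 0 else (target - cum[i]) / seg[i]
    return path_from_base[i] + t * (path_from_base[i + 1] - path_from_base[i])


def _point_along(poly: np.ndarray, distance: float) -> np.ndarray:
    """Position ``distance`` along the polyline from its first node."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = min(distance, cum[-1])
    i = int(np.searchsorted(cum, target, side="right")) - 1
    i = min(i, len(seg) - 1)
    t = 0.0 if seg[i] == 0 else (target - cum[i]) / seg[i]
    return poly[i] + t * (poly[i + 1] - poly[i])


def branch_angle(
    branch_path: np.ndarray,
    main_stem_path: np.ndarray,
    arc_fraction: float = ANGLE_ARC_FRACTION,
    stem_span: float = 2.0,
) -> float:
    """Insertion angle (degrees) between a branch and the local main stem.

    ``branch_path`` is ordered tip -> base; ``main_stem_path`` is ordered
    tip -> root and hosts the branch base. The branch direction is base ->
    the point ``arc_fraction`` of the branch arc length above the base;
    the stem direction is the local main-stem chord of ``stem_span`` cm
    above the attachment, oriented toward the tassel top.
    """
    branch_path = np.asarray(branch_path, dtype=np.float64)
    stem = np.asarray(main_stem_path, dtype=np.float64)
    base = branch_path[-1]
    u = _point_at_arc_fraction(branch_path[::-1], arc_fraction) - base
    d = np.linalg.norm(stem - base, axis=1)
    base_idx = int(np.argmin(d))  # nearest stem node hosts the attachment
    if len(stem) < 2:
        raise ValueError("main-stem path is a single node")
    # local stem direction: tip-ward chord centered on the attachment, so a
    # curving spindle above a near-top attachment cannot dominate it
    above = _point_along(stem[base_idx::-1], stem_span / 2.0)
    below = _point_along(stem[base_idx:], stem_span / 2.0)
    v = above - below
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("degenerate branch: zero-length direction vector")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def branch_curvature(path: np.ndarray) -> float:
    """Arc length / endpoint chord ratio; 1 for a straight branch."""
    path = np.asarray(path, dtype=np.float64)
    length = branch_length(path)
    chord = float(np.linalg.norm(path[-1] - path[0]))
    if chord < 1e-12:
        raise ValueError("branch endpoints coincide; curvature undefined")
    return length / chord


def tassel_volume(full_cloud: PointCloud) -> float:
    """Convex-hull volume (cm^3) of the whole tassel cloud."""
    return convex_hull_volume(full_cloud.coords)


def tassel_dispersion(branch_angles_deg: np.ndarray) -> float:
    """Mean insertion angle (radians) divided by pi/2."""
    angles = np.asarray(branch_angles_deg, dtype=np.float64)
    if len(angles) == 0:
        raise ValueError("tassel_dispersion needs at least one angle")
    return float(np.radians(angles).mean() / (math.pi / 2.0))


def extract_traits(
    full_cloud: PointCloud,
    branches: BranchSet,
    instances: TipInstanceSet,
    arc_fraction: float = ANGLE_ARC_FRACTION,
    smooth_iterations: int = 2,
) -> TraitRecord:
    """Assemble the six traits; per-branch lists exclude the main stem."""
    from tasselseg.skeleton import smooth_polyline

    stem_poly = smooth_polyline(branches.main_stem_polyline(), smooth_iterations)
    lengths, angles, curvatures = [], [], []
    for b in range(branches.n_branches):
        if b == branches.main_stem:
            continue
        poly = smooth_polyline(branches.branch_polyline(b), smooth_iterations)
        if len(poly) < 2:
            continue
        lengths.append(branch_length(poly))
        curvatures.append(branch_curvature(poly))
        angles.append(branch_angle(poly, stem_poly, arc_fraction=arc_fraction))
    angles_arr = np.asarray(angles)
    dispersion = tassel_dispersion(angles_arr) if len(angles_arr) else float("nan")
    return TraitRecord(
        branch_count=instances.n_instances,
        branch_lengths=np.asarray(lengths),
        branch_angles=angles_arr,
        branch_curvatures=np.asarray(curvatures),
        tassel_volume=tassel_volume(full_cloud),
        tassel_dispersion=dispersion,
    )
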