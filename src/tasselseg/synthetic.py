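"""Parametric maize-tassel point clouds with analytic ground truth.

A tassel is a gently wandering vertical stem carrying lateral branches on
its upper half. Each branch is a quadratic Bezier curve whose base
tangent realizes the drawn insertion angle and whose bend realizes the
drawn curvature (arc / chord) ratio, so every ground-truth quantity is
analytic. Surfaces are emulated by dense arc-length sampling with
isotropic Gaussian jitter; the distal ``tip_label_length`` cm of every
branch carries the binary tip label.

The longest drawn branch is always placed at the topmost attachment so
that the longest skeleton path — the pipeline's main-stem rule — is the
path through the topmost branch, mirroring the central spike of a real
tassel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.optimize import brentq

from tasselseg.io_formats import PointCloud, write_point_cloud
from tasselseg.preprocess import random_downsample
from tasselseg.traits import TraitRecord, tassel_dispersion

__all__ = [
    "TasselSpec",
    "GroundTruth",
    "QuadraticBezier",
    "generate_tassel",
    "generate_dataset",
    "resample_augment",
]

STEM_ID = -2
OUTLIER_ID = -1

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)
_GL_T = 0.5 * (_GL_NODES + 1.0)          # mapped to [0, 1]
_GL_W = 0.5 * _GL_WEIGHTS


@dataclass(frozen=True)
class TasselSpec:
    """Generation parameters; two-tuples are uniform sampling ranges."""

    n_branches: tuple[int, int] = (6, 16)
    stem_length: tuple[float, float] = (25.0, 40.0)
    branch_length: tuple[float, float] = (10.0, 30.0)
    insertion_angle: tuple[float, float] = (20.0, 60.0)
    curvature_factor: tuple[float, float] = (1.0, 1.4)
    points_per_cm: float = 40.0
    tube_radius: float = 0.1
    radial_jitter_sd: float = 0.03
    fuzz_fraction: float = 0.05
    fuzz_jitter_multiplier: float = 15.0
    tip_label_length: float = 4.0
    stem_wander: float = 0.3
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_branches", "stem_length", "branch_length",
                     "insertion_angle", "curvature_factor"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must be ordered, got ({lo}, {hi})")
        if self.points_per_cm <= 0:
            raise ValueError("points_per_cm must be positive")
        if not (3.0 - 1e-9 <= self.tip_label_length <= 5.0 + 1e-9):
            raise ValueError("tip_label_length must honor the 3-5 cm convention")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must lie in [0, 1]")
        if not (0.0 <= self.fuzz_fraction < 1.0):
            raise ValueError("fuzz_fraction must lie in [0, 1)")
        if self.n_branches[1] > 48:
            raise ValueError(
                "too many branches for non-overlapping azimuths; lower n_branches"
            )


class QuadraticBezier:
    """B(t) = (1-t)^2 P0 + 2 t (1-t) C + t^2 P2 with arc-length helpers."""

    def __init__(self, p0: np.ndarray, c: np.ndarray, p2: np.ndarray):
        self.p0 = np.asarray(p0, dtype=np.float64)
        self.c = np.asarray(c, dtype=np.float64)
        self.p2 = np.asarray(p2, dtype=np.float64)
        ts = np.linspace(0.0, 1.0, 4097)
        speed = np.linalg.norm(self.deriv(ts), axis=-1)
        self._table_t = ts
        self._table_s = np.concatenate(
            [[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(ts))]
        )

    def point(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)[..., None]
        return ((1 - t) ** 2 * self.p0 + 2 * t * (1 - t) * self.c + t**2 * self.p2)

    def deriv(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)[..., None]
        return 2 * ((1 - t) * (self.c - self.p0) + t * (self.p2 - self.c))

    def length(self) -> float:
        """Arc length by Gauss-Legendre quadrature (96 nodes)."""
        speed = np.linalg.norm(self.deriv(_GL_T), axis=-1)
        return float(np.sum(_GL_W * speed))

    def t_at_arc(self, s) -> np.ndarray:
        """Curve parameter at arc length ``s`` from the base."""
        return np.interp(s, self._table_s, self._table_t)

    def point_at_arc(self, s) -> np.ndarray:
        return self.point(self.t_at_arc(s))


def _arc_chord_ratio(phi: float) -> float:
    """Arc/chord ratio of the symmetric unit-chord Bezier with base angle phi."""
    if phi <= 0:
        return 1.0
    p0 = np.zeros(2)
    c = np.array([0.5 / math.cos(phi), 0.0])
    p2 = np.array([math.cos(phi), math.sin(phi)])
    t = _GL_T[:, None]
    d = 2 * ((1 - t) * (c - p0) + t * (p2 - c))
    return float(np.sum(_GL_W * np.linalg.norm(d, axis=1)))


def _solve_bend_angle(curvature: float) -> float:
    """Base angle phi whose symmetric Bezier has the given arc/chord ratio."""
    if curvature <= 1.0 + 1e-12:
        return 0.0
    return float(brentq(lambda p: _arc_chord_ratio(p) - curvature, 1e-9, 1.45,
                        xtol=1e-12))


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _build_branch(
    p0: np.ndarray, stem_up: np.ndarray, azimuth: float,
    length: float, theta_deg: float, curvature: float,
) -> QuadraticBezier:
    """Branch curve with base tangent at ``theta_deg`` from the stem and a
    downward (droop) bend realizing the target curvature."""
    e1, e2 = _perp_basis(stem_up)
    radial = math.cos(azimuth) * e1 + math.sin(azimuth) * e2
    theta = math.radians(theta_deg)
    u = math.cos(theta) * stem_up + math.sin(theta) * radial
    u /= np.linalg.norm(u)
    # droop direction: component of -stem_up orthogonal to u
    w = -(stem_up - np.dot(stem_up, u) * u)
    wn = np.linalg.norm(w)
    w = radial if wn < 1e-9 else w / wn
    phi = _solve_bend_angle(curvature)
    chord = length / _arc_chord_ratio(phi)
    chord_dir = math.cos(phi) * u + math.sin(phi) * w
    p2 = p0 + chord * chord_dir
    c = p0 + u * (chord / 2.0) / math.cos(phi) if phi > 0 else p0 + u * (chord / 2.0)
    return QuadraticBezier(p0, c, p2)


class _Stem:
    """Vertical polyline with analytic sinusoidal lateral wander."""

    def __init__(self, length: float, ax: float, ay: float):
        self.length = length
        self.ax, self.ay = ax, ay

    def point(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        return np.stack(
            [self.ax * np.sin(1.7 * math.pi * t),
             self.ay * np.sin(1.3 * math.pi * t + 0.5),
             self.length * t], axis=-1)

    def tangent(self, t) -> np.ndarray:
        scalar = np.isscalar(t) or np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        d = np.stack([
            self.ax * 1.7 * math.pi * np.cos(1.7 * math.pi * t),
            self.ay * 1.3 * math.pi * np.cos(1.3 * math.pi * t + 0.5),
            np.full_like(t, self.length),
        ], axis=-1)
        d /= np.linalg.norm(d, axis=-1, keepdims=True)
        return d[0] if scalar else d

    def arc_length(self) -> float:
        speed = np.linalg.norm(
            np.stack([
                self.ax * 1.7 * math.pi * np.cos(1.7 * math.pi * _GL_T),
                self.ay * 1.3 * math.pi * np.cos(1.3 * math.pi * _GL_T + 0.5),
                np.full_like(_GL_T, self.length)], axis=-1), axis=-1)
        return float(np.sum(_GL_W * speed))


@dataclass
class GroundTruth:
    """Analytic per-branch and per-point truth for one generated tassel."""

    branch_lengths: np.ndarray          # (B,) arc length, cm
    insertion_angles: np.ndarray        # (B,) programmed base-tangent angle, deg
    implied_angles: np.ndarray          # (B,) base->25%-arc chord angle, deg
    curvatures: np.ndarray              # (B,) arc/chord ratio
    attachment_heights: np.ndarray      # (B,) cm up the stem
    main_branch: int                    # topmost branch; becomes the main stem
    point_branch_id: np.ndarray         # (N,) stem=-2, outlier=-1, else branch
    point_tip_flag: np.ndarray          # (N,) 1 within tip_label_length of the end
    traits: TraitRecord                 # the TraitRecord the pipeline should find


def _stratified_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    """Jittered-grid samples of [0, 1): dense with light-tailed gaps.

    Independent uniform draws exhibit Poisson clumping whose low-density
    stretches the statistical outlier filter would carve out of thin
    structures; stratified positions keep the linear density steady the
    way a real reconstructed surface is.
    """
    return (np.arange(n) + rng.uniform(0.0, 1.0, n)) / n


def _tube_surface(
    centers: np.ndarray, tangents: np.ndarray, rng: np.random.Generator,
    tube_radius: float, jitter_sd: float,
) -> np.ndarray:
    """Scatter points on a thin tube around a curve.

    Local surfaces in multi-view tassel clouds are two-dimensional; a
    tube of small radius plus isotropic jitter reproduces that local
    density structure (a bare curve would fragment under radius-based
    clustering).
    """
    t = tangents / np.linalg.norm(tangents, axis=-1, keepdims=True)
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(t), 1))
    ref[np.abs(t[:, 2]) > 0.99] = [1.0, 0.0, 0.0]
    n1 = np.cross(t, ref)
    n1 /= np.linalg.norm(n1, axis=-1, keepdims=True)
    n2 = np.cross(t, n1)
    psi = rng.uniform(0.0, 2.0 * math.pi, len(t))
    pts = centers + tube_radius * (np.cos(psi)[:, None] * n1
                                   + np.sin(psi)[:, None] * n2)
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
    return pts


def _sample_colors(rng: np.random.Generator, n: int) -> np.ndarray:
    """Green-yellow foliage colors that pass the default HSV mask."""
    h = rng.uniform(35.0, 55.0, n) * 2.0 / 360.0   # 0-180 half-degree scale
    s = rng.uniform(0.45, 0.9, n)
    v = rng.uniform(0.35, 0.8, n)
    return hsv_to_rgb(np.stack([h, s, v], axis=-1))


def generate_tassel(spec: TasselSpec = TasselSpec()) -> tuple[PointCloud, GroundTruth]:
    """Generate one labeled tassel cloud and its analytic ground truth."""
    rng = np.random.default_rng(spec.seed)
    n_branches = int(rng.integers(spec.n_branches[0], spec.n_branches[1] + 1))
    stem_len = rng.uniform(*spec.stem_length)
    stem = _Stem(stem_len, ax=rng.uniform(0, spec.stem_wander),
                 ay=rng.uniform(0, spec.stem_wander))

    attach_t = np.sort(rng.uniform(0.5, 0.95, n_branches))
    lengths = rng.uniform(*spec.branch_length, n_branches)
    # longest branch at the topmost attachment: the path through it is the
    # longest root-to-tip path, so the pipeline's main-stem rule finds it
    top = n_branches - 1
    imax = int(np.argmax(lengths))
    lengths[top], lengths[imax] = lengths[imax], lengths[top]
    thetas = rng.uniform(*spec.insertion_angle, n_branches)
    curvs = rng.uniform(*spec.curvature_factor, n_branches)
    golden = 2.399963229728653
    azimuths = (rng.uniform(0, 2 * math.pi)
                + golden * np.arange(n_branches)
                + rng.uniform(-0.15, 0.15, n_branches))

    branches = []
    for b in range(n_branches):
        p0 = stem.point(attach_t[b])
        branches.append(_build_branch(p0, stem.tangent(float(attach_t[b])),
                                      float(azimuths[b]), float(lengths[b]),
                                      float(thetas[b]), float(curvs[b])))

    coords, ids, tips = [], [], []
    # stem surface
    n_stem = max(2, int(round(stem.arc_length() * spec.points_per_cm)))
    ts = _stratified_unit(rng, n_stem)
    coords.append(_tube_surface(stem.point(ts), stem.tangent(ts), rng,
                                spec.tube_radius, spec.radial_jitter_sd))
    ids.append(np.full(n_stem, STEM_ID, dtype=np.int64))
    tips.append(np.zeros(n_stem, dtype=np.int64))
    # branch surfaces
    branch_arc_lengths = np.empty(n_branches)
    for b, curve in enumerate(branches):
        arc = curve.length()
        branch_arc_lengths[b] = arc
        n_pts = max(2, int(round(arc * spec.points_per_cm)))
        s = _stratified_unit(rng, n_pts) * arc
        t_s = curve.t_at_arc(s)
        coords.append(_tube_surface(curve.point(t_s), curve.deriv(t_s), rng,
                                    spec.tube_radius, spec.radial_jitter_sd))
        ids.append(np.full(n_pts, b, dtype=np.int64))
        tips.append((s > arc - spec.tip_label_length).astype(np.int64))
    coords = np.concatenate(coords)
    ids = np.concatenate(ids)
    tips = np.concatenate(tips)
    if spec.fuzz_fraction > 0:
        # multi-view reconstruction fuzz: a small fraction of points gets a
        # much larger displacement, giving the heavy-tailed neighbor-distance
        # distribution the statistical outlier filter expects
        fuzzy = rng.random(len(coords)) < spec.fuzz_fraction
        extra = spec.fuzz_jitter_multiplier * spec.radial_jitter_sd
        coords[fuzzy] += rng.normal(0.0, extra, (int(fuzzy.sum()), 3))
    colors = _sample_colors(rng, len(coords))

    clean_coords = coords
    n_out = int(round(spec.outlier_fraction * len(coords)))
    if n_out > 0:
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        center, half = (lo + hi) / 2, (hi - lo) / 2
        out = rng.uniform(center - 1.5 * half, center + 1.5 * half, (n_out, 3))
        coords = np.vstack([coords, out])
        ids = np.concatenate([ids, np.full(n_out, OUTLIER_ID, dtype=np.int64)])
        tips = np.concatenate([tips, np.zeros(n_out, dtype=np.int64)])
        gray = np.stack([rng.uniform(0.3, 0.7, n_out)] * 3, axis=-1)
        colors = np.vstack([colors, gray])

    implied_angles = np.empty(n_branches)
    for b, curve in enumerate(branches):
        stem_up = stem.tangent(float(attach_t[b]))
        u = curve.point_at_arc(0.25 * branch_arc_lengths[b]) - curve.p0
        cosang = np.clip(np.dot(u, stem_up) / np.linalg.norm(u), -1.0, 1.0)
        implied_angles[b] = math.degrees(math.acos(cosang))

    lateral = np.array([b for b in range(n_branches) if b != top],
                       dtype=np.int64)
    from tasselseg.skeleton import convex_hull_volume  # no module cycle at runtime

    if len(lateral):
        disp = tassel_dispersion(implied_angles[lateral])
    else:
        disp = float("nan")
    truth_traits = TraitRecord(
        branch_count=n_branches,
        branch_lengths=branch_arc_lengths[lateral],
        branch_angles=implied_angles[lateral],
        branch_curvatures=curvs[lateral],
        tassel_volume=convex_hull_volume(clean_coords),
        tassel_dispersion=disp,
    )
    cloud = PointCloud(coords, colors=colors, labels=tips)
    truth = GroundTruth(
        branch_lengths=branch_arc_lengths,
        insertion_angles=thetas,
        implied_angles=implied_angles,
        curvatures=curvs,
        attachment_heights=attach_t * stem_len,
        main_branch=top,
        point_branch_id=ids,
        point_tip_flag=tips,
        traits=truth_traits,
    )
    return cloud, truth


def _derived_seed(master_seed: int, i: int) -> int:
    return int((master_seed * 1000003 + 7919 * i + 17) % (2**31 - 1))


def generate_dataset(
    n_tassels: int,
    spec: TasselSpec = TasselSpec(),
    seed: int = 0,
    out_dir=None,
) -> "pandas.DataFrame":
    """Generate ``n_tassels`` labeled clouds and a ground-truth manifest.

    When ``out_dir`` is given, writes ``tassel_###.ply`` files and
    ``manifest.csv`` there. Returns the manifest dataframe.
    """
    import pandas as pd

    if n_tassels < 1:
        raise ValueError("n_tassels must be >= 1")
    rows = []
    for i in range(n_tassels):
        tassel_spec = TasselSpec(**{**spec.__dict__, "seed": _derived_seed(seed, i)})
        cloud, truth = generate_tassel(tassel_spec)
        tassel_id = f"tassel_{i:03d}"
        row = truth.traits.to_row(tassel_id)
        row["seed"] = tassel_spec.seed
        row["n_points"] = len(cloud)
        rows.append(row)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_point_cloud(cloud, out_dir / f"{tassel_id}.ply")
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest


def resample_augment(
    cloud: PointCloud, target_n: int, n_copies: int, seed: int = 0
) -> list[PointCloud]:
    """Label-preserving random subsamples; copy ``i`` uses ``seed + i``."""
    return [random_downsample(cloud, target_n, seed + i) for i in range(n_copies)]
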