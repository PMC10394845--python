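"""End-to-end pipeline: preprocess -> tip labels -> cluster -> skeleton -> traits."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from tasselseg import io_formats
from tasselseg.clustering import ClusterParams, TipInstanceSet, density_cluster
from tasselseg.io_formats import PointCloud
from tasselseg.preprocess import (
    HsvRange,
    OutlierFilterParams,
    estimate_normals,
    farthest_point_sample,
    hsv_foreground_mask,
    random_downsample,
    statistical_outlier_filter,
)
from tasselseg.skeleton import (
    BranchSet,
    assign_points_to_branches,
    build_spanning_tree,
    extend_paths_to_tips,
    extract_branch_paths,
    initial_growth_points,
    select_root,
)
from tasselseg.traits import TraitRecord, extract_traits

logger = logging.getLogger("tasselseg")

GROUND_TRUTH_TIPS = "ground-truth-tips"


@dataclass
class PipelineConfig:
    """Stage parameters with paper-default values."""

    # preprocess
    hsv: Optional[HsvRange] = field(default_factory=HsvRange)
    sor_neighbors: int = 20
    sor_alpha: float = 0.5
    random_n: Optional[int] = None        # skip when None or >= N
    fps_n: int = 4000
    normals_k: int = 16
    # clustering
    eps: Union[float, str] = "auto"
    min_pts: int = 5
    min_cluster_size: int = 10
    # skeleton
    skeleton_nodes: int = 1024
    skeleton_radius: Union[float, str] = "auto"
    radius_growth: float = 1.5
    extend_tips: bool = True
    # traits
    angle_arc_fraction: float = 0.25
    # global
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "hsv" in data and isinstance(data["hsv"], (list, tuple)):
            data["hsv"] = HsvRange(*data["hsv"])
        elif "hsv" in data and isinstance(data["hsv"], dict):
            data["hsv"] = HsvRange(**data["hsv"])
        return cls(**data)


@dataclass
class PipelineResult:
    """All intermediate artifacts of one tassel run."""

    preprocessed: PointCloud
    tip_labels: np.ndarray
    instances: TipInstanceSet
    branches: BranchSet
    membership: np.ndarray
    traits: TraitRecord
    timings: dict
    tree: object = None


def preprocess_cloud(cloud: PointCloud, config: PipelineConfig) -> PointCloud:
    """HSV mask (if colors present), outlier filter, random + FPS downsample."""
    if config.hsv is not None and cloud.colors is not None:
        mask = hsv_foreground_mask(cloud, config.hsv)
        if mask.any():
            cloud = cloud.select(np.flatnonzero(mask))
    if config.sor_neighbors < len(cloud):
        cloud, _ = statistical_outlier_filter(
            cloud, OutlierFilterParams(config.sor_neighbors, config.sor_alpha)
        )
    if config.random_n is not None and config.random_n < len(cloud):
        cloud = random_downsample(cloud, config.random_n, config.seed)
    if config.fps_n < len(cloud):
        idx = farthest_point_sample(cloud, config.fps_n)
        cloud = cloud.select(idx)
    return cloud


def run_tassel(
    cloud: PointCloud,
    config: PipelineConfig = PipelineConfig(),
    model=None,
) -> PipelineResult:
    """Run the full pipeline on one tassel cloud.

    ``model=None`` is ground-truth-tips mode: the input's ``labels``
    channel supplies the per-point tip flags. Otherwise ``model`` must be
    a trained tip-segmentation network.
    """
    timings = {}
    t0 = time.perf_counter()
    work = preprocess_cloud(cloud, config)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if model is None:
        if work.labels is None:
            raise ValueError(
                "ground-truth-tips mode requires a label channel on the input"
            )
        tip_labels = (work.labels == 1).astype(np.int64)
    else:
        from tasselseg.tipnet import predict_tips

        if work.normals is None:
            work = estimate_normals(work, k=config.normals_k)
        tip_labels = predict_tips(model, work).labels
    timings["segment"] = time.perf_counter() - t0

    tip_idx = np.flatnonzero(tip_labels == 1)
    rem_idx = np.flatnonzero(tip_labels != 1)
    if len(tip_idx) == 0:
        raise ValueError("no tip points found; cannot cluster branches")
    if len(rem_idx) == 0:
        raise ValueError("no remainder points; cannot build a skeleton")
    tips = work.select(tip_idx)
    remainder = work.select(rem_idx)

    t0 = time.perf_counter()
    instances = density_cluster(
        tips, ClusterParams(config.eps, config.min_pts, config.min_cluster_size)
    )
    if instances.n_instances == 0:
        raise ValueError("density clustering found no branch instances")
    timings["cluster"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.skeleton_nodes < len(remainder):
        nodes = remainder.select(farthest_point_sample(remainder, config.skeleton_nodes))
    else:
        nodes = remainder
    growth = initial_growth_points(nodes, instances, tips)
    root = select_root(nodes, growth)
    tree = build_spanning_tree(nodes, root, radius=config.skeleton_radius,
                               radius_growth=config.radius_growth)
    branches = extract_branch_paths(tree, growth)
    if config.extend_tips:
        branches = extend_paths_to_tips(branches, tips, instances)
    membership = assign_points_to_branches(work, branches)
    branches.point_membership = membership
    timings["skeleton"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    traits = extract_traits(work, branches, instances,
                            arc_fraction=config.angle_arc_fraction)
    timings["traits"] = time.perf_counter() - t0
    for stage, dt in timings.items():
        logger.info("stage %-10s %6.2f s", stage, dt)
    return PipelineResult(
        preprocessed=work,
        tip_labels=tip_labels,
        instances=instances,
        branches=branches,
        membership=membership,
        traits=traits,
        timings=timings,
        tree=tree,
    )


def skeleton_to_json(branches: BranchSet, tree_root: Optional[int] = None) -> dict:
    """JSON-serializable skeleton summary, re-loadable by
    :func:`branchset_from_json`."""
    return {
        "nodes": branches.node_coords.tolist(),
        "main_stem": int(branches.main_stem),
        "growth_points": branches.growth_points.tolist(),
        "paths": [p.tolist() for p in branches.paths],
        "branch_base": branches.branch_base.tolist(),
        "apex": None if branches.apex is None else branches.apex.tolist(),
        "base_attach": (None if branches.base_attach is None
                        else branches.base_attach.tolist()),
    }


def branchset_from_json(data: dict) -> BranchSet:
    """Rebuild a :class:`BranchSet` from its JSON summary."""
    apex = data.get("apex")
    base_attach = data.get("base_attach")
    return BranchSet(
        node_coords=np.asarray(data["nodes"], dtype=np.float64),
        growth_points=np.asarray(data["growth_points"], dtype=np.int64),
        paths=[np.asarray(p, dtype=np.int64) for p in data["paths"]],
        main_stem=int(data["main_stem"]),
        branch_base=np.asarray(data["branch_base"], dtype=np.int64),
        apex=None if apex is None else np.asarray(apex, dtype=np.float64),
        base_attach=(None if base_attach is None
                     else np.asarray(base_attach, dtype=np.float64)),
    )


def run_pipeline(
    input_path,
    config: PipelineConfig = PipelineConfig(),
    checkpoint: Union[str, Path] = GROUND_TRUTH_TIPS,
    out_dir=None,
    keep_going: bool = False,
):
    """Run the pipeline over a PLY file or a directory of PLY files.

    Writes per-tassel intermediate artifacts and a combined traits CSV
    when ``out_dir`` is given; returns the traits dataframe.
    """
    import pandas as pd

    input_path = Path(input_path)
    files = (sorted(input_path.glob("*.ply")) if input_path.is_dir()
             else [input_path])
    if not files:
        raise FileNotFoundError(f"no PLY files under {input_path}")
    model = None
    if checkpoint != GROUND_TRUTH_TIPS:
        from tasselseg.tipnet import load_checkpoint

        model = load_checkpoint(checkpoint)
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for f in files:
        tassel_id = f.stem
        try:
            cloud = io_formats.read_point_cloud(f)
            result = run_tassel(cloud, config, model=model)
        except Exception as exc:
            if keep_going:
                logger.error("tassel %s failed: %s", tassel_id, exc)
                continue
            raise RuntimeError(f"tassel {tassel_id}: {exc}") from exc
        rows.append(result.traits.to_row(tassel_id))
        if out_dir is not None:
            labeled = result.preprocessed.with_(
                labels=result.tip_labels,
                instances=result.membership,
            )
            io_formats.write_point_cloud(labeled, out_dir / f"{tassel_id}_segmented.ply")
            with open(out_dir / f"{tassel_id}_skeleton.json", "w") as fh:
                json.dump(skeleton_to_json(result.branches), fh)
    df = pd.DataFrame(rows, columns=TraitRecord.csv_columns())
    if out_dir is not None:
        df.to_csv(out_dir / "traits.csv", index=False)
    return df
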