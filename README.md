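# tasselseg

Branch segmentation and morphological trait extraction for 3-D maize
tassel point clouds.

Given a colored tassel point cloud (cm units), the pipeline:

1. **preprocess** — HSV foreground masking, statistical outlier removal
   (mean distance to the 20 nearest neighbors, threshold mean + 0.5 σ),
   seeded random downsampling and farthest-point sampling (FPS), plus
   PCA normal estimation;
2. **tipnet** — a hierarchical point-set encoder–decoder (3 set-abstraction
   layers with multi-scale ball grouping, 3 interpolate-and-PointNet
   decoder layers with inverse-distance-squared k-NN interpolation)
   labels each point as branch tip (1) or remainder (0). Implemented in
   pure NumPy with a small reverse-mode autodiff core, Adam training,
   and IoU / accuracy / precision / recall evaluation;
3. **clustering** — DBSCAN-style density clustering of the tip points
   (ε = 3 × mean neighbor distance, minPts = 5) yields one instance per
   branch and the branch count;
4. **skeleton** — bottom-up minimum-path extraction: per-instance growth
   points, root selection by maximal convex-hull volume, a Dijkstra
   shortest-path spanning tree over the radius graph, per-branch paths,
   main-stem identification (longest path), and fusion of every original
   point onto its nearest branch polyline;
5. **traits** — six traits per tassel: branch count, per-branch length,
   insertion angle, curvature (arc/chord), convex-hull tassel volume,
   and dispersion (mean angle over π/2).

A **synthetic** module generates parametric tassels (quadratic-Bézier
branches on a wandering stem, thin-tube surface sampling, reconstruction
fuzz, optional box outliers) with analytic ground-truth labels and
traits, so the whole pipeline is testable without any dataset download.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(brute-force oracle equivalence, closed-form checks, skeleton structure,
parameter recovery on 20 synthetic tassels, network trainability,
rigid-motion invariance, denoising selectivity).

## CLI

```sh
# generate 5 labeled synthetic tassels + ground-truth manifest
tasselseg simulate --n 5 --seed 1 --out data/

# full pipeline (uses the ground-truth tip labels carried in the PLYs)
tasselseg run --in data/ --out results/ --checkpoint ground-truth-tips

# train the tip-segmentation network and use it instead
tasselseg train --data data/ --out model.npz --reduced --epochs 50
tasselseg run --in data/ --out results_net/ --checkpoint model.npz

# or stage by stage
tasselseg preprocess --in data/tassel_000.ply --out pp.ply
tasselseg segment --checkpoint model.npz --in pp.ply --out seg.ply
tasselseg cluster --in seg.ply --out cl.ply
tasselseg skeletonize --in cl.ply --out sk.ply
tasselseg traits --skeleton sk.json --in sk.ply --out traits.csv
```

`tasselseg run --config config.yaml` accepts a YAML file whose keys
mirror `tasselseg.pipeline.PipelineConfig` (HSV bounds, filter
parameters, FPS sizes, clustering and skeleton settings, seed); command
line flags override it.

## File conventions

- PLY (ASCII or binary little-endian) with properties
  `x y z [red green blue] [nx ny nz] [label] [instance]`; colors are
  uchar 0–255 on disk, floats in [0, 1] in memory; `label` is the binary
  tip flag, `instance` the branch id.
- Whitespace text: `x y z [r g b] [label]` per line.
- All coordinates are centimetres; volumes cm³; angles degrees.

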