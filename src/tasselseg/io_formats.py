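"""Point-cloud container and PLY / whitespace-text readers and writers.

Conventions
-----------
* Coordinates are centimetres everywhere in this package.
* PLY colors are stored as uchar 0-255 and exposed as floats in [0, 1].
* The binary tip label lives in an integer vertex property named
  ``label``; branch-instance ids live in a property named ``instance``.
* Text files are whitespace-delimited ``x y z [r g b] [label]`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "PointCloud",
    "PointCloudError",
    "ParseError",
    "read_point_cloud",
    "write_point_cloud",
]


class PointCloudError(ValueError):
    """Invalid point-cloud content or parameters."""


class ParseError(PointCloudError):
    """A file failed to parse as the requested format."""


@dataclass
class PointCloud:
    """N points with optional color, normal, and integer label channels.

    Attributes
    ----------
    coords : (N, 3) float64 array, centimetres.
    colors : optional (N, 3) float64 array, RGB in [0, 1].
    normals : optional (N, 3) float64 array, unit vectors.
    labels : optional (N,) int64 array, per-point class ids.
    instances : optional (N,) int64 array, per-point instance ids.
    """

    coords: np.ndarray
    colors: Optional[np.ndarray] = None
    normals: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    instances: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise PointCloudError("coords must be an (N, 3) array")
        n = len(self.coords)
        if n < 1:
            raise PointCloudError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise PointCloudError("coords must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64)
            if self.colors.shape != (n, 3):
                raise PointCloudError("colors must be (N, 3)")
            if self.colors.min() < -1e-9 or self.colors.max() > 1 + 1e-9:
                raise PointCloudError("colors must lie in [0, 1]")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != (n, 3):
                raise PointCloudError("normals must be (N, 3)")
            norms = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-5):
                raise PointCloudError("normals must have unit length")
        for name in ("labels", "instances"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.int64)
                if arr.shape != (n,):
                    raise PointCloudError(f"{name} must have length N")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Subset or reorder every channel consistently by ``index``."""
        index = np.asarray(index)
        return PointCloud(
            coords=self.coords[index],
            colors=None if self.colors is None else self.colors[index],
            normals=None if self.normals is None else self.normals[index],
            labels=None if self.labels is None else self.labels[index],
            instances=None if self.instances is None else self.instances[index],
        )

    def with_(self, **kwargs) -> "PointCloud":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _parse_ply_header(fh) -> tuple[str, int, list[tuple[str, str]], int]:
    """Return (format, n_vertices, [(name, numpy-dtype)], header_end_offset)."""
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise ParseError("line 1: not a PLY file (missing 'ply' magic)")
    fmt = None
    n_vertices = None
    props: list[tuple[str, str]] = []
    in_vertex_element = False
    lineno = 1
    while True:
        raw = fh.readline()
        lineno += 1
        if not raw:
            raise ParseError(f"line {lineno}: unexpected EOF in PLY header")
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("comment") or line.startswith("obj_info"):
            continue
        parts = line.split()
        if parts[0] == "format":
            if parts[1] not in ("ascii", "binary_little_endian"):
                raise ParseError(f"line {lineno}: unsupported PLY format {parts[1]!r}")
            fmt = parts[1]
        elif parts[0] == "element":
            in_vertex_element = parts[1] == "vertex"
            if in_vertex_element:
                n_vertices = int(parts[2])
            elif int(parts[2]) > 0:
                raise ParseError(
                    f"line {lineno}: non-vertex element {parts[1]!r} not supported"
                )
        elif parts[0] == "property" and in_vertex_element:
            if parts[1] == "list":
                raise ParseError(f"line {lineno}: list properties not supported")
            if parts[1] not in _PLY_TYPES:
                raise ParseError(f"line {lineno}: unknown PLY type {parts[1]!r}")
            props.append((parts[2], _PLY_TYPES[parts[1]]))
        elif parts[0] == "end_header":
            break
    if fmt is None or n_vertices is None:
        raise ParseError("PLY header missing 'format' or vertex element")
    return fmt, n_vertices, props, fh.tell()


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        fmt, n, props, offset = _parse_ply_header(fh)
        if n == 0:
            raise PointCloudError(f"{path}: PLY file contains no vertices")
        names = [p[0] for p in props]
        if fmt == "binary_little_endian":
            dtype = np.dtype([(name, "<" + code) for name, code in props])
            buf = fh.read(dtype.itemsize * n)
            if len(buf) < dtype.itemsize * n:
                raise ParseError(f"{path}: truncated binary PLY payload")
            data = np.frombuffer(buf, dtype=dtype, count=n)
        else:
            dtype = np.dtype([(name, code) for name, code in props])
            try:
                data = np.loadtxt(fh, dtype=dtype, max_rows=n, ndmin=1)
            except ValueError as exc:
                raise ParseError(f"{path}: malformed ASCII PLY row ({exc})") from exc
            if data.shape[0] < n:
                raise ParseError(f"{path}: expected {n} vertices, found {data.shape[0]}")

    for axis in ("x", "y", "z"):
        if axis not in names:
            raise ParseError(f"{path}: vertex element lacks property {axis!r}")
    coords = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    colors = None
    if all(c in names for c in ("red", "green", "blue")):
        colors = np.column_stack(
            [data["red"], data["green"], data["blue"]]
        ).astype(np.float64) / 255.0
    normals = None
    if all(c in names for c in ("nx", "ny", "nz")):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]]).astype(np.float64)
        # re-normalise float32 storage error
        norm = np.linalg.norm(normals, axis=1)
        norm[norm == 0] = 1.0
        normals = normals / norm[:, None]
    labels = data["label"].astype(np.int64) if "label" in names else None
    instances = data["instance"].astype(np.int64) if "instance" in names else None
    return PointCloud(coords, colors=colors, normals=normals, labels=labels,
                      instances=instances)


def _ply_vertex_dtype(cloud: PointCloud) -> tuple[np.dtype, list[str]]:
    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    header = ["property float x", "property float y", "property float z"]
    if cloud.colors is not None:
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    if cloud.normals is not None:
        fields += [("nx", "<f4"), ("ny", "<f4"), ("nz", "<f4")]
        header += ["property float nx", "property float ny", "property float nz"]
    if cloud.labels is not None:
        fields.append(("label", "<i4"))
        header.append("property int label")
    if cloud.instances is not None:
        fields.append(("instance", "<i4"))
        header.append("property int instance")
    return np.dtype(fields), header


def _pack_vertices(cloud: PointCloud, dtype: np.dtype) -> np.ndarray:
    data = np.empty(len(cloud), dtype=dtype)
    data["x"], data["y"], data["z"] = cloud.coords.T.astype(np.float32)
    if cloud.colors is not None:
        rgb = np.clip(np.rint(cloud.colors * 255.0), 0, 255).astype(np.uint8)
        data["red"], data["green"], data["blue"] = rgb.T
    if cloud.normals is not None:
        data["nx"], data["ny"], data["nz"] = cloud.normals.T.astype(np.float32)
    if cloud.labels is not None:
        data["label"] = cloud.labels.astype(np.int32)
    if cloud.instances is not None:
        data["instance"] = cloud.instances.astype(np.int32)
    return data


def _write_ply(cloud: PointCloud, path: Path, binary: bool) -> None:
    dtype, prop_lines = _ply_vertex_dtype(cloud)
    data = _pack_vertices(cloud, dtype)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        ["ply", f"format {fmt} 1.0", f"element vertex {len(cloud)}"]
        + prop_lines
        + ["end_header"]
    )
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(data.tobytes())
        else:
            for row in data:
                cells = []
                for name in dtype.names:
                    v = row[name]
                    if dtype[name].kind == "f":
                        cells.append(np.format_float_positional(float(v), trim="0"))
                    else:
                        cells.append(str(int(v)))
                fh.write((" ".join(cells) + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# Whitespace text
# ---------------------------------------------------------------------------

def _read_xyz_text(path: Path) -> PointCloud:
    rows = []
    width = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if width is None:
                width = len(parts)
                if width not in (3, 4, 6, 7):
                    raise ParseError(
                        f"{path}: line {lineno}: expected 3, 4, 6 or 7 columns, "
                        f"got {width}"
                    )
            elif len(parts) != width:
                raise ParseError(
                    f"{path}: line {lineno}: inconsistent column count "
                    f"({len(parts)} vs {width})"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if not rows:
        raise PointCloudError(f"{path}: empty point-cloud file")
    arr = np.asarray(rows, dtype=np.float64)
    coords = arr[:, :3]
    colors = arr[:, 3:6] if width in (6, 7) else None
    labels = arr[:, -1].astype(np.int64) if width in (4, 7) else None
    return PointCloud(coords, colors=colors, labels=labels)


def _write_xyz_text(cloud: PointCloud, path: Path) -> None:
    cols = [cloud.coords]
    if cloud.colors is not None:
        cols.append(cloud.colors)
    arr = np.column_stack(cols)
    with open(path, "w") as fh:
        for i in range(len(cloud)):
            cells = [np.format_float_positional(v, trim="0") for v in arr[i]]
            if cloud.labels is not None:
                cells.append(str(int(cloud.labels[i])))
            fh.write(" ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    return "ply" if path.suffix.lower() == ".ply" else "xyz-text"


def read_point_cloud(path, format: Optional[str] = None) -> PointCloud:
    """Read a point cloud from ``path`` (``ply`` or ``xyz-text``).

    When ``format`` is omitted it is inferred from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "xyz-text":
        return _read_xyz_text(path)
    raise ValueError(f"unknown point-cloud format {fmt!r}")


def write_point_cloud(cloud: PointCloud, path, format: Optional[str] = None,
                      binary: bool = True) -> None:
    """Write ``cloud`` so that :func:`read_point_cloud` recovers it.

    Coordinates and normals are stored as float32 (round-trip within 1e-6
    for cm-scale data); labels and instances are stored exactly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "xyz-text":
        _write_xyz_text(cloud, path)
    else:
        raise ValueError(f"unknown point-cloud format {fmt!r}")
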