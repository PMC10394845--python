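"""The branch-tip segmentation network: 3 SA encoder + 3 IP decoder layers.

Input per point: 3-D coordinates and a unit normal (6 channels).
Output per point: class probabilities over {remainder: 0, branch tip: 1}.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from tasselseg.io_formats import PointCloud, PointCloudError
from tasselseg.tipnet.autograd import Parameter, Tensor
from tasselseg.tipnet.layers import SharedMLP, ball_group, interpolate_tensor
from tasselseg.preprocess import farthest_point_sample

__all__ = [
    "SaLayerConfig", "IpLayerConfig", "NetworkConfig",
    "TipSegNet", "forward", "default_config", "reduced_config",
    "save_checkpoint", "load_checkpoint",
]

_INF = float("inf")


@dataclass(frozen=True)
class SaLayerConfig:
    """One set-abstraction layer: FPS centroids + multi-scale grouping."""

    n_centroids: int
    radii: tuple                  # grouping radii in cm, strictly increasing
    n_samples: tuple              # per-radius neighbor caps (<=0: group all)
    mlp_channels: tuple           # per-radius tuples of feature widths

    def __post_init__(self) -> None:
        if not (len(self.radii) == len(self.n_samples) == len(self.mlp_channels)):
            raise ValueError("radii, n_samples and mlp_channels must align")
        finite = [r for r in self.radii if math.isfinite(r)]
        if any(b <= a for a, b in zip(finite, finite[1:])):
            raise ValueError("radii must be strictly increasing")
        if self.n_centroids < 1:
            raise ValueError("n_centroids must be >= 1")


@dataclass(frozen=True)
class IpLayerConfig:
    """One interpolate-and-PointNet decoder layer."""

    k_interp: int
    mlp_channels: tuple

    def __post_init__(self) -> None:
        if self.k_interp < 1:
            raise ValueError("k_interp must be >= 1")


@dataclass(frozen=True)
class NetworkConfig:
    sa_layers: tuple              # exactly 3 SaLayerConfig
    ip_layers: tuple              # exactly 3 IpLayerConfig
    n_classes: int = 2
    head_channels: tuple = (128,)
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if len(self.sa_layers) != 3 or len(self.ip_layers) != 3:
            raise ValueError("the architecture uses exactly 3 SA and 3 IP layers")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkConfig":
        def _tup(x):
            return tuple(_tup(v) for v in x) if isinstance(x, (list, tuple)) else x

        sa = tuple(SaLayerConfig(**{k: _tup(v) for k, v in d.items()})
                   for d in data["sa_layers"])
        ip = tuple(IpLayerConfig(**{k: _tup(v) for k, v in d.items()})
                   for d in data["ip_layers"])
        return cls(sa_layers=sa, ip_layers=ip,
                   n_classes=data.get("n_classes", 2),
                   head_channels=_tup(data.get("head_channels", (128,))),
                   dropout=data.get("dropout", 0.5))


def default_config() -> NetworkConfig:
    """Full-size multi-scale-grouping segmentation configuration."""
    return NetworkConfig(
        sa_layers=(
            SaLayerConfig(1024, (1.0, 2.0, 4.0), (16, 32, 64),
                          ((32, 32, 64), (64, 64, 128), (64, 96, 128))),
            SaLayerConfig(256, (4.0, 8.0), (16, 32),
                          ((128, 128, 256), (128, 196, 256))),
            SaLayerConfig(1, (_INF,), (0,), ((256, 512, 1024),)),
        ),
        ip_layers=(
            IpLayerConfig(3, (256, 256)),
            IpLayerConfig(3, (256, 128)),
            IpLayerConfig(3, (128, 128, 128)),
        ),
    )


def reduced_config() -> NetworkConfig:
    """Small configuration (centroids 128/32/8) for CPU-scale training."""
    return NetworkConfig(
        sa_layers=(
            SaLayerConfig(128, (1.5, 3.0), (16, 32),
                          ((16, 16, 32), (32, 32, 64))),
            SaLayerConfig(32, (3.0, 6.0), (16, 32),
                          ((32, 32, 64), (32, 48, 64))),
            SaLayerConfig(8, (12.0,), (32,), ((64, 96, 128),)),
        ),
        ip_layers=(
            IpLayerConfig(3, (128, 128)),
            IpLayerConfig(3, (128, 96)),
            IpLayerConfig(3, (96, 64)),
        ),
        head_channels=(64,),
    )


class _SALayer:
    def __init__(self, cfg: SaLayerConfig, in_channels: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.mlps = [SharedMLP(list(ch), 3 + in_channels, rng)
                     for ch in cfg.mlp_channels]
        self.out_channels = sum(m.out_channels for m in self.mlps)

    def __call__(self, coords: np.ndarray, feats: Tensor, training: bool = False
                 ) -> tuple[np.ndarray, Tensor]:
        n = len(coords)
        n_centroids = min(self.cfg.n_centroids, n)
        fps_idx = (np.arange(n) if n_centroids == n
                   else farthest_point_sample(_CloudView(coords), n_centroids))
        centroids = coords[fps_idx]
        scale_feats = []
        for radius, n_samples, mlp in zip(self.cfg.radii, self.cfg.n_samples,
                                          self.mlps):
            group_idx = ball_group(coords, fps_idx, radius, n_samples)
            rel = coords[group_idx] - centroids[:, None, :]       # (S, k, 3)
            grouped = Tensor.concat(
                [Tensor(rel), feats.gather(group_idx)], axis=-1
            )
            scale_feats.append(mlp(grouped, training).max(axis=1))    # (S, C)
        return centroids, Tensor.concat(scale_feats, axis=-1)

    def parameters(self):
        return [p for m in self.mlps for p in m.parameters()]


class _IPLayer:
    def __init__(self, cfg: IpLayerConfig, in_channels: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.mlp = SharedMLP(list(cfg.mlp_channels), in_channels, rng)
        self.out_channels = self.mlp.out_channels

    def __call__(self, fine_coords: np.ndarray, coarse_coords: np.ndarray,
                 fine_feats: Tensor, coarse_feats: Tensor,
                 training: bool = False) -> Tensor:
        if len(coarse_coords) == 1:
            # single support: broadcast it to every query
            interp = coarse_feats.gather(np.zeros(len(fine_coords), dtype=np.int64))
        else:
            interp = interpolate_tensor(fine_coords, coarse_coords, coarse_feats,
                                        self.cfg.k_interp)
        return self.mlp(Tensor.concat([interp, fine_feats], axis=-1), training)

    def parameters(self):
        return self.mlp.parameters()


class _CloudView:
    """Cheap coords-only adapter accepted by farthest_point_sample."""

    __slots__ = ("coords",)

    def __init__(self, coords: np.ndarray):
        self.coords = coords

    def __len__(self) -> int:
        return len(self.coords)


class TipSegNet:
    """Hierarchical encoder-decoder for per-point binary tip labelling."""

    IN_CHANNELS = 6  # xyz (centered, rescaled) + unit normal

    def __init__(self, config: Optional[NetworkConfig] = None, seed: int = 0):
        self.config = config or default_config()
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.sa_layers: list[_SALayer] = []
        ch = self.IN_CHANNELS
        for cfg in self.config.sa_layers:
            layer = _SALayer(cfg, ch, rng)
            self.sa_layers.append(layer)
            ch = layer.out_channels
        self.ip_layers: list[_IPLayer] = []
        skip_channels = [self.IN_CHANNELS] + [l.out_channels
                                              for l in self.sa_layers[:-1]]
        for cfg, skip in zip(self.config.ip_layers, reversed(skip_channels)):
            layer = _IPLayer(cfg, ch + skip, rng)
            self.ip_layers.append(layer)
            ch = layer.out_channels
        self.head = SharedMLP(list(self.config.head_channels), ch, rng)
        scale = math.sqrt(2.0 / self.head.out_channels)
        self.out_w = Parameter(
            rng.normal(0.0, scale, (self.head.out_channels, self.config.n_classes))
        )
        self.out_b = Parameter(np.zeros(self.config.n_classes))

    def parameters(self) -> list[Parameter]:
        params = []
        for layer in [*self.sa_layers, *self.ip_layers, self.head]:
            params.extend(layer.parameters())
        params.extend([self.out_w, self.out_b])
        return params

    def _norm_layers(self):
        mlps = [m for sa in self.sa_layers for m in sa.mlps]
        mlps += [ip.mlp for ip in self.ip_layers] + [self.head]
        return [n for m in mlps for n in m.norms if n is not None]

    # ------------------------------------------------------------------

    @staticmethod
    def _input_features(cloud: PointCloud) -> np.ndarray:
        if cloud.normals is None:
            raise PointCloudError("the network input requires normals")
        centered = cloud.coords - cloud.coords.mean(axis=0)
        return np.concatenate([centered / 10.0, cloud.normals], axis=1)

    def log_probabilities(
        self, cloud: PointCloud, training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        coords = cloud.coords
        feats = Tensor(self._input_features(cloud))
        levels = [(coords, feats)]
        x = feats
        for sa in self.sa_layers:
            coords, x = sa(levels[-1][0], x, training)
            levels.append((coords, x))
        for i, ip in enumerate(self.ip_layers):
            fine_coords, fine_feats = levels[-2 - i]
            coarse_coords = levels[-1 - i][0]
            x = ip(fine_coords, coarse_coords, fine_feats, x, training)
        x = self.head(x, training)
        if training and self.config.dropout > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an RNG for dropout")
            x = x.dropout(self.config.dropout, rng)
        return x.linear(self.out_w, self.out_b).log_softmax()

    def predict_proba(self, cloud: PointCloud) -> np.ndarray:
        """Per-point class probabilities (rows sum to 1)."""
        return np.exp(self.log_probabilities(cloud, training=False).data)


def forward(model: TipSegNet, cloud: PointCloud) -> np.ndarray:
    """Per-point class probabilities for a cloud with normals."""
    return model.predict_proba(cloud)


def save_checkpoint(model: TipSegNet, path) -> None:
    """Serialize parameters, normalization state and config to .npz."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    for i, norm in enumerate(model._norm_layers()):
        arrays[f"norm_mean_{i}"] = norm.running_mean
        arrays[f"norm_var_{i}"] = norm.running_var
    arrays["config_json"] = np.frombuffer(
        json.dumps({"network": model.config.to_dict(), "seed": model.seed})
        .encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> TipSegNet:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["config_json"]).decode())
        model = TipSegNet(NetworkConfig.from_dict(meta["network"]),
                          seed=meta.get("seed", 0))
        for i, p in enumerate(model.parameters()):
            p.data = data[f"param_{i}"].astype(np.float64)
        for i, norm in enumerate(model._norm_layers()):
            norm.running_mean = data[f"norm_mean_{i}"].astype(np.float64)
            norm.running_var = data[f"norm_var_{i}"].astype(np.float64)
    return model
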