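"""Building blocks of the hierarchical point-set network.

Set-abstraction (SA) layers: farthest-point sampling, multi-scale ball
grouping, a shared per-point MLP, and max-pooling per group. Decoder
interpolate-and-PointNet (IP) layers: inverse-distance-squared k-NN
interpolation, skip concatenation, and a shared MLP.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from tasselseg.tipnet.autograd import Parameter, Tensor

__all__ = ["SharedMLP", "interpolate_features", "ball_group", "interp_weights"]


class BatchNorm:
    """Per-channel normalization over every leading axis.

    Uses batch statistics while training and exponential running
    statistics at evaluation time, mirroring the usual post-conv
    normalization of point-set networks.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        data = x.data
        axes = tuple(range(data.ndim - 1))
        if training:
            mean = data.mean(axis=axes)
            var = data.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (data - mean) * invstd
        out = xhat * self.gamma.data + self.beta.data
        gamma, beta = self.gamma, self.beta
        n = data.size // data.shape[-1]

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                gh = g * gamma.data
                if training:
                    gx = invstd / n * (
                        n * gh - gh.sum(axis=axes)
                        - xhat * (gh * xhat).sum(axis=axes)
                    )
                else:
                    gx = gh * invstd
                x._accumulate(gx)

        return Tensor(out, (x, gamma, beta), backward)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class SharedMLP:
    """Per-point dense stack: linear -> batch norm -> ReLU (He init)."""

    def __init__(self, channels: list[int], in_channels: int,
                 rng: np.random.Generator, use_norm: bool = True):
        self.weights: list[Parameter] = []
        self.biases: list[Parameter] = []
        self.norms: list = []
        fan_in = in_channels
        for out in channels:
            scale = math.sqrt(2.0 / fan_in)
            self.weights.append(Parameter(rng.normal(0.0, scale, (fan_in, out))))
            self.biases.append(Parameter(np.zeros(out)))
            self.norms.append(BatchNorm(out) if use_norm else None)
            fan_in = out
        self.out_channels = fan_in

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        for w, b, norm in zip(self.weights, self.biases, self.norms):
            x = x.linear(w, b)
            if norm is not None:
                x = norm(x, training)
            x = x.relu()
        return x

    def parameters(self) -> list[Parameter]:
        params = [*self.weights, *self.biases]
        for norm in self.norms:
            if norm is not None:
                params.extend(norm.parameters())
        return params


def ball_group(
    coords: np.ndarray, centroid_idx: np.ndarray, radius: float, n_samples: int
) -> np.ndarray:
    """Indices (S, n_samples) of up to ``n_samples`` nearest points within
    ``radius`` of each centroid; short groups are padded with the centroid
    itself (always a member at distance 0).

    ``n_samples <= 0`` or a non-finite radius groups all points (S must
    then be 1 per caller convention).
    """
    if n_samples <= 0 or not np.isfinite(radius):
        return np.tile(np.arange(len(coords)), (len(centroid_idx), 1))
    tree = cKDTree(coords)
    centroids = coords[centroid_idx]
    dist, idx = tree.query(centroids, k=n_samples, distance_upper_bound=radius)
    if n_samples == 1:
        dist, idx = dist[:, None], idx[:, None]
    missing = ~np.isfinite(dist)
    idx[missing] = np.broadcast_to(centroid_idx[:, None], idx.shape)[missing]
    return idx


def interp_weights(
    queries: np.ndarray, supports: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """k-NN indices and normalized inverse-distance-squared weights.

    A query coinciding with a support gets a one-hot weight on it, making
    interpolation exact in the zero-distance limit.
    """
    k = min(k, len(supports))
    tree = cKDTree(supports)
    dist, idx = tree.query(queries, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    w = 1.0 / np.maximum(dist, 1e-12) ** 2
    exact = dist[:, 0] < 1e-12
    w[exact] = 0.0
    w[exact, 0] = 1.0
    w /= w.sum(axis=1, keepdims=True)
    return idx, w


def interpolate_features(
    queries: np.ndarray,
    supports: np.ndarray,
    support_features: np.ndarray,
    k_interp: int = 3,
) -> np.ndarray:
    """Inverse-distance-squared weighted k-NN feature interpolation.

    f(x) = sum_i w_i f_i / sum_i w_i with w_i = 1 / d(x, x_i)^2 over the
    ``k_interp`` nearest supports of each query.
    """
    supports = np.asarray(supports, dtype=np.float64)
    support_features = np.asarray(support_features, dtype=np.float64)
    if len(supports) == 0:
        raise ValueError("interpolate_features requires at least one support")
    if k_interp < 1:
        raise ValueError("k_interp must be >= 1")
    if len(supports) < k_interp:
        raise ValueError("need at least k_interp support points")
    idx, w = interp_weights(np.asarray(queries, dtype=np.float64),
                            supports, k_interp)
    return np.einsum("mk,mkc->mc", w, support_features[idx])


def interpolate_tensor(
    queries: np.ndarray, supports: np.ndarray, features: Tensor, k: int
) -> Tensor:
    """Differentiable version of :func:`interpolate_features`."""
    idx, w = interp_weights(queries, supports, k)
    return features.gather(idx).mul_const(w[:, :, None]).sum(axis=1)
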