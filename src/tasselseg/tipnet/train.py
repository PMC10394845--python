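"""Adam training loop for the tip-segmentation network."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from tasselseg.io_formats import PointCloud, PointCloudError
from tasselseg.preprocess import estimate_normals
from tasselseg.tipnet.network import TipSegNet

__all__ = ["TrainConfig", "TrainHistory", "train", "predict_tips", "Adam"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 24
    lr0: float = 0.001
    lr_halving_period: int = 20
    epochs: int = 100
    weight_decay: float = 0.0001
    momentum: float = 0.9           # Adam beta1
    loss_threshold: float = 0.001   # early-stop on training loss
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "lr0", "lr_halving_period", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def learning_rate(self, epoch: int) -> float:
        """lr0 halved every ``lr_halving_period`` epochs."""
        return self.lr0 * 0.5 ** (epoch // self.lr_halving_period)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _prepare(cloud: PointCloud, normals_k: int = 16) -> PointCloud:
    if cloud.normals is None:
        cloud = estimate_normals(cloud, k=normals_k)
    return cloud


def train(
    model: TipSegNet,
    train_set: Sequence[PointCloud],
    val_set: Sequence[PointCloud] = (),
    config: TrainConfig = TrainConfig(),
) -> tuple[TipSegNet, TrainHistory]:
    """Optimize the model in place; returns it with the epoch history.

    Every training cloud needs per-point binary labels; normals are
    estimated when absent. Training stops early once the epoch loss
    drops below ``config.loss_threshold``.
    """
    if len(train_set) == 0:
        raise PointCloudError("train() requires a nonempty training set")
    for cloud in train_set:
        if cloud.labels is None:
            raise PointCloudError("every training cloud needs per-point labels")
    train_set = [_prepare(c) for c in train_set]
    val_set = [_prepare(c) for c in val_set]
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), beta1=config.momentum,
                     weight_decay=config.weight_decay)
    history = TrainHistory()
    for epoch in range(config.epochs):
        lr = config.learning_rate(epoch)
        order = rng.permutation(len(train_set))
        losses = []
        correct = 0
        total = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            optimizer.zero_grad()
            for ci in batch:
                cloud = train_set[ci]
                logp = model.log_probabilities(cloud, training=True, rng=rng)
                loss = logp.nll_loss(cloud.labels)
                loss.mul_const(1.0 / len(batch)).backward()
                losses.append(float(loss.data))
                pred = logp.data.argmax(axis=1)
                correct += int(np.sum(pred == cloud.labels))
                total += len(pred)
            optimizer.step(lr)
        epoch_loss = float(np.mean(losses))
        history.train_loss.append(epoch_loss)
        history.train_accuracy.append(correct / total)
        history.learning_rate.append(lr)
        if val_set:
            v_correct = v_total = 0
            for cloud in val_set:
                pred = model.predict_proba(cloud).argmax(axis=1)
                if cloud.labels is not None:
                    v_correct += int(np.sum(pred == cloud.labels))
                    v_total += len(pred)
            history.val_accuracy.append(v_correct / max(v_total, 1))
        if epoch_loss < config.loss_threshold:
            break
    return model, history


def predict_tips(model: TipSegNet, cloud: PointCloud,
                 normals_k: int = 16) -> PointCloud:
    """Label every point 0/1 by argmax probability (ties go to class 0)."""
    cloud = _prepare(cloud, normals_k)
    proba = model.predict_proba(cloud)
    return cloud.with_(labels=proba.argmax(axis=1).astype(np.int64))
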