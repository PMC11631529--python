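"""Foreground/background semantic segmentation.

A UNet maps the raw image to a per-pixel foreground probability S, the
conditioning input of the diffusion splitting process.  Training minimizes
mean binary cross-entropy against the union-of-masks target, with Adam and
a log-linear learning-rate decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import Image, Scene, SemanticMask, semantic_target
from .nn import Adam, BackboneSpec, ConfigError, UNet, lr_schedule

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings for the semantic network."""

    lr_start: float = 1e-3
    lr_end: float = 1e-5
    batch_size: int = 16
    steps: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lr_start >= self.lr_end > 0):
            raise ConfigError("need lr_start >= lr_end > 0")
        if self.batch_size < 1 or self.steps < 0:
            raise ConfigError("batch_size must be >= 1 and steps >= 0")


def bce_value(pred: np.ndarray, target: np.ndarray, eps: float = _EPS) -> np.ndarray:
    """Elementwise binary cross-entropy with saturation clamping."""
    p = np.clip(pred, eps, 1.0 - eps)
    return -(target * np.log(p) + (1.0 - target) * np.log1p(-p))


def bce_grad_through_sigmoid(pred, target, weight):
    """d(BCE)/d(prob) scaled so that, composed with the sigmoid backward pass,
    the gradient at the logit is exactly ``weight * (pred - target)``."""
    denom = pred * (1.0 - pred) + 1e-12
    return weight * (pred - target) / denom


class SemanticModel:
    """Trained foreground predictor; thin wrapper around a UNet."""

    def __init__(self, unet: UNet):
        self.unet = unet
        self.loss_trace: list[float] = []

    @property
    def in_channels(self) -> int:
        return self.unet.spec.in_channels

    def predict(self, image: Image) -> SemanticMask:
        return predict_semantic(self, image)

    def save(self, path: str | Path) -> None:
        self.unet.save(path)

    @classmethod
    def load(cls, path: str | Path) -> "SemanticModel":
        return cls(UNet.load(path))


def train_semantic(
    scenes: list[Scene], spec: BackboneSpec, cfg: TrainConfig
) -> SemanticModel:
    """Train the foreground network on scenes; deterministic given cfg.seed.

    Batches are drawn with replacement, so any batch size works for any
    dataset size.  The per-step mean-BCE loss is recorded on
    ``model.loss_trace``.
    """
    if not scenes:
        raise ConfigError("no training scenes")
    c = scenes[0].image.n_channels
    if spec.in_channels != c:
        raise ConfigError(f"spec.in_channels={spec.in_channels} but images have C={c}")
    if spec.out_channels != 1:
        raise ConfigError("semantic network must have exactly 1 output channel")
    shape = scenes[0].shape
    for s in scenes:
        if s.shape != shape or s.image.n_channels != c:
            raise ConfigError("all training scenes must share shape and channels")

    rng = np.random.default_rng(cfg.seed)
    model = UNet(spec, seed=int(rng.integers(2**31)))
    images = np.stack([s.image.pixels.transpose(2, 0, 1) for s in scenes])
    targets = np.stack([semantic_target(s.labels).pixels for s in scenes])

    opt = Adam(model.parameters())
    lr_at = lr_schedule(cfg.lr_start, cfg.lr_end, cfg.steps)
    out = SemanticModel(model)
    for step in range(cfg.steps):
        idx = rng.integers(0, len(scenes), size=cfg.batch_size)
        x = images[idx]
        t = targets[idx][:, None]
        model.zero_grad()
        p = model.forward(x, training=True)
        loss = float(bce_value(p, t).mean())
        model.backward(bce_grad_through_sigmoid(p, t, 1.0 / p.size))
        opt.step(lr_at(step))
        out.loss_trace.append(loss)
    return out


def predict_semantic(model: SemanticModel, image: Image) -> SemanticMask:
    """Per-pixel foreground probability; deterministic (evaluation mode)."""
    if image.n_channels != model.in_channels:
        raise ConfigError(
            f"image has {image.n_channels} channels, model expects {model.in_channels}"
        )
    x = image.pixels.transpose(2, 0, 1)[None]
    p = model.unet.forward(x, training=False)
    return SemanticMask(np.clip(p[0, 0], 0.0, 1.0))
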