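"""Core containers for images and overlapping instance labels.

The central design constraint is that ground-truth instances may *overlap*:
two cells can legitimately share pixels.  A flat integer label image cannot
represent that, so the canonical label container is an ordered stack of
binary masks (:class:`InstanceLabelSet`).  Coordinates are row-major,
0-based ``(row, col)`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np


class ShapeError(ValueError):
    """Raised when array shapes are inconsistent with each other."""


class FormatError(ValueError):
    """Raised for unreadable or unsupported on-disk formats."""


@dataclass(frozen=True)
class Image:
    """A multi-channel 2-D intensity image.

    ``pixels`` has shape ``(H, W, C)`` with all values finite and, after
    loading through :mod:`diffsplit.io`, normalized per channel to [0, 1].
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ShapeError(f"image must be H×W or H×W×C, got shape {px.shape}")
        h, w, c = px.shape
        if h < 8 or w < 8:
            raise ShapeError(f"image must be at least 8×8, got {h}×{w}")
        if c < 1:
            raise ShapeError("image needs at least one channel")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        if self.channel_names is not None and len(self.channel_names) != c:
            raise ShapeError("channel_names length must match channel count")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]


@dataclass(frozen=True)
class InstanceMask:
    """A single instance as a dense binary field of shape ``(H, W)``."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ShapeError(f"mask must be 2-D, got shape {px.shape}")
        px = px.astype(bool)
        if not px.any():
            raise ValueError("instance mask must contain at least one pixel")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class InstanceLabelSet:
    """Ordered collection of instance masks; overlap between masks is allowed.

    The order is arbitrary and carries no semantics — it is preserved only so
    that round-trips through disk formats are bit-exact.
    """

    masks: tuple[InstanceMask, ...]

    def __post_init__(self) -> None:
        masks = tuple(
            m if isinstance(m, InstanceMask) else InstanceMask(m) for m in self.masks
        )
        if masks:
            shape = masks[0].shape
            for m in masks[1:]:
                if m.shape != shape:
                    raise ShapeError(
                        f"all masks must share a shape; got {m.shape} vs {shape}"
                    )
        object.__setattr__(self, "masks", masks)

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self) -> Iterator[InstanceMask]:
        return iter(self.masks)

    def __getitem__(self, i: int) -> InstanceMask:
        return self.masks[i]

    @property
    def shape(self) -> tuple[int, int]:
        if not self.masks:
            raise ValueError("empty label set has no shape")
        return self.masks[0].shape

    def union(self) -> np.ndarray:
        """Per-pixel OR over all masks (the semantic foreground)."""
        if not self.masks:
            raise ValueError("empty label set has no union")
        out = np.zeros(self.shape, dtype=bool)
        for m in self.masks:
            out |= m.pixels
        return out

    def as_stack(self) -> np.ndarray:
        """Masks stacked into an ``(n, H, W)`` boolean array."""
        if not self.masks:
            return np.zeros((0, 0, 0), dtype=bool)
        return np.stack([m.pixels for m in self.masks])


@dataclass(frozen=True)
class SemanticMask:
    """Foreground probability field in [0, 1], shape ``(H, W)``."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 2:
            raise ShapeError(f"semantic mask must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)) or px.min() < 0 or px.max() > 1:
            raise ValueError("semantic mask values must be finite and in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def binary(self) -> np.ndarray:
        """Binary view at threshold 0.5."""
        return self.pixels >= 0.5


@dataclass
class Scene:
    """An image together with its (possibly overlapping) instance labels."""

    image: Image
    labels: InstanceLabelSet
    semantic: SemanticMask | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) and self.labels.shape != self.image.shape:
            raise ShapeError(
                f"label shape {self.labels.shape} != image shape {self.image.shape}"
            )
        if self.semantic is None and len(self.labels):
            self.semantic = semantic_target(self.labels)
        if self.semantic is not None and self.semantic.shape != self.image.shape:
            raise ShapeError("semantic mask shape does not match image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def semantic_target(labels: InstanceLabelSet) -> SemanticMask:
    """Foreground/background target: a pixel is foreground iff it belongs to
    at least one instance mask."""
    if not isinstance(labels, InstanceLabelSet):
        labels = InstanceLabelSet(tuple(labels))
    if len(labels) == 0:
        raise ValueError("cannot derive a semantic target from an empty label set")
    return SemanticMask(labels.union().astype(np.float32))


def normalize_image(pixels: np.ndarray) -> np.ndarray:
    """Per-channel min–max normalization to [0, 1]; constant channels map to 0."""
    px = np.asarray(pixels, dtype=np.float32)
    if px.ndim == 2:
        px = px[:, :, None]
    lo = px.min(axis=(0, 1), keepdims=True)
    hi = px.max(axis=(0, 1), keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0
    return (px - lo) / span
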