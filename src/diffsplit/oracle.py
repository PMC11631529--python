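"""Test doubles standing in for trained split networks.

These are synthetic models for isolating the chain and the recursive
segmenter from training: they look at the ground-truth labels (or at
nothing) instead of learning, and expose the same ``forward`` surface as a
trained :class:`~diffsplit.diffusion.SplitModel`.
"""

from __future__ import annotations

import numpy as np

from .datamodel import InstanceLabelSet


class ConstantSplitModel:
    """Emits fixed values for the A and B fields everywhere."""

    def __init__(self, value_a: float = 1.0, value_b: float = 0.0):
        self.value_a = float(value_a)
        self.value_b = float(value_b)
        self.noise_mean = 0.5
        self.noise_sigma = 0.25

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, _, h, w = x.shape
        out = np.empty((n, 2, h, w), dtype=np.float32)
        out[:, 0] = self.value_a
        out[:, 1] = self.value_b
        return out


class OracleSplitModel:
    """Perfect splitter that reads the ground-truth labels.

    Given input channels (..., S, A, B) it assigns every ground-truth mask
    intersecting the current region to the A or B split by the pixel-sum
    rule on the incoming fields, and emits the exact binary target unions.
    When more than one instance is present but the incoming fields put all
    of them on one side, the minimum-margin instance is moved to the other
    side — a perfect splitter always bisects a multi-instance region.

    The recursive segmenter calls ``set_context`` with the current crop
    slices so the full-image labels can be aligned with the crop.
    """

    def __init__(self, labels: InstanceLabelSet):
        self.labels = labels
        self.noise_mean = 0.5
        self.noise_sigma = 0.25
        self._context: tuple[slice, slice] | None = None

    def set_context(self, slices: tuple[slice, slice]) -> None:
        self._context = slices

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        out = np.zeros((n, 2, h, w), dtype=np.float32)
        rs, cs = self._context if self._context is not None else (slice(None), slice(None))
        for k in range(n):
            s = x[k, c - 3]
            a = x[k, c - 2]
            b = x[k, c - 1]
            support = s >= 0.5
            crops, margins = [], []
            partial, partial_margins = [], []
            for m in self.labels:
                mc = m.pixels[rs, cs]
                inside = mc & support
                if not inside.any():
                    continue
                margin = float(a[inside].sum() - b[inside].sum())
                # an instance belongs to this region only if its whole mask
                # lies inside the region's support; stray overlap slivers of
                # instances emitted elsewhere must not be split off again
                whole = int(m.pixels.sum()) == int(mc.sum()) and not (mc & ~support).any()
                if whole:
                    crops.append(inside)
                    margins.append(margin)
                else:
                    partial.append(inside)
                    partial_margins.append(margin)
            if not crops:
                crops, margins = partial, partial_margins
            if not crops:
                continue
            to_a = [g >= 0 for g in margins]
            if len(crops) > 1 and len(set(to_a)) == 1:
                flip = int(np.argmin(np.abs(margins)))
                to_a[flip] = not to_a[flip]
            for inside, is_a in zip(crops, to_a):
                out[k, 0 if is_a else 1][inside] = 1.0
        return out
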