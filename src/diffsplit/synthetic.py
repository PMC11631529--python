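"""Synthetic fluorescent-cell-like scenes with controlled overlap.

Cells are filled ellipses (closed-form membership makes the ground truth
exact and the overlap fraction controllable).  A designated fraction of
cells is placed at a partner offset so that their masks intersect; the rest
are placed disjoint by rejection sampling.  Intensities emulate fluorescence:
a dim background, a bright cell interior with a smooth radial falloff,
additive intensity where cells overlap, and additive Gaussian noise.

The default parameters describe the package's reference condition: 64×64
scenes of two overlapping ellipses, the minimal setting in which the
split-from-noise mechanism can be demonstrated and evaluated end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .datamodel import Image, InstanceLabelSet, InstanceMask, Scene, semantic_target


class PlacementError(RuntimeError):
    """Raised when cells cannot be packed at the requested radii/overlap."""


@dataclass(frozen=True)
class SceneParams:
    """Generator knobs; all lengths in pixels, intensities in [0, 1] units."""

    height: int = 64
    width: int = 64
    n_cells: int = 2
    radius_range: tuple[float, float] = (7.0, 12.0)
    eccentricity_range: tuple[float, float] = (1.0, 1.8)
    overlap_fraction: float = 1.0
    intensity_contrast: float = 0.6
    noise_sigma: float = 0.05
    background_level: float = 0.08
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.radius_range[0] < 2:
            raise ValueError("minimum radius must be >= 2 pixels")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (min, max)")
        if self.eccentricity_range[0] < 1.0:
            raise ValueError("eccentricity (major/minor axis ratio) must be >= 1")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if self.height < 8 or self.width < 8:
            raise ValueError("scene must be at least 8×8")


def _ellipse_fields(h, w, cy, cx, a, b, theta):
    """Boolean membership and squared normalized radius of a rotated ellipse."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    rho2 = (u / a) ** 2 + (v / b) ** 2
    return rho2 <= 1.0, rho2


def _sample_axes(rng: np.random.Generator, params: SceneParams):
    r = rng.uniform(*params.radius_range)
    ecc = rng.uniform(*params.eccentricity_range)
    # keep sqrt(a*b) ~ r so the nominal radius is the geometric mean
    a = r * math.sqrt(ecc)
    b = r / math.sqrt(ecc)
    theta = rng.uniform(0.0, math.pi)
    return a, b, theta, r


_MAX_TRIES = 200


def generate_scene(params: SceneParams) -> Scene:
    """Render one scene; fully reproducible from ``params.seed``.

    The target number of overlap-participating cells is
    ``round(overlap_fraction * n_cells)``; cells are placed as disjoint
    singles plus offset-partner pairs to hit that count.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    n = params.n_cells

    n_overlap = int(round(params.overlap_fraction * n))
    if n_overlap == 1:  # a single cell cannot overlap anything
        n_overlap = 2 if n >= 2 else 0
    # roles[i] is None (disjoint single) or the partner index to offset from
    roles: list[int | None] = [None] * n
    i = 0
    placed_pairs = 0
    while 2 * placed_pairs + (1 if n_overlap % 2 else 0) < n_overlap and i + 1 < n:
        roles[i + 1] = i
        placed_pairs += 1
        i += 2
    if n_overlap % 2 and n_overlap >= 3 and i < n:
        roles[i] = 0  # odd leftover attaches to the first pair
        i += 1

    masks: list[np.ndarray] = []
    rho2s: list[np.ndarray] = []
    radii: list[float] = []
    centers: list[tuple[float, float]] = []

    for idx in range(n):
        partner = roles[idx]
        placed = False
        for _ in range(_MAX_TRIES):
            a, b, theta, r = _sample_axes(rng, params)
            if partner is None:
                cy = rng.uniform(r, h - r) if h > 2 * r else h / 2
                cx = rng.uniform(r, w - r) if w > 2 * r else w / 2
            else:
                pcy, pcx = centers[partner]
                d = rng.uniform(0.45, 0.8) * (r + radii[partner])
                ang = rng.uniform(0.0, 2.0 * math.pi)
                cy = pcy + d * math.sin(ang)
                cx = pcx + d * math.cos(ang)
                if not (2 <= cy <= h - 3 and 2 <= cx <= w - 3):
                    continue
            mask, rho2 = _ellipse_fields(h, w, cy, cx, a, b, theta)
            if not mask.any():
                continue
            if partner is None:
                if any(np.logical_and(mask, m).any() for m in masks):
                    continue
            else:
                inter = np.logical_and(mask, masks[partner])
                # overlap the partner, but neither swallows the other, and
                # avoid incidental contact with unrelated cells
                if not inter.any():
                    continue
                if inter.sum() >= 0.75 * min(mask.sum(), masks[partner].sum()):
                    continue
                others = [m for j, m in enumerate(masks) if j != partner]
                if any(np.logical_and(mask, m).any() for m in others):
                    continue
            masks.append(mask)
            rho2s.append(rho2)
            radii.append(r)
            centers.append((cy, cx))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {idx} after {_MAX_TRIES} attempts "
                f"(n_cells={n}, radius_range={params.radius_range})"
            )

    signal = np.full((h, w), params.background_level, dtype=np.float32)
    for mask, rho2 in zip(masks, rho2s):
        cell = params.intensity_contrast * (1.0 - 0.45 * rho2)
        signal = signal + np.where(mask, cell, 0.0).astype(np.float32)

    channels = []
    for c in range(params.n_channels):
        gain = 1.0 if c == 0 else 0.6 / c  # secondary channels: bleed-through
        noisy = gain * signal + rng.normal(0.0, params.noise_sigma, size=(h, w))
        channels.append(noisy)
    pixels = np.clip(np.stack(channels, axis=-1), 0.0, 1.0).astype(np.float32)

    labels = InstanceLabelSet(tuple(InstanceMask(m) for m in masks))
    return Scene(
        image=Image(pixels),
        labels=labels,
        semantic=semantic_target(labels),
        meta={"params": asdict(params)},
    )


def overlap_participation(labels: InstanceLabelSet) -> float:
    """Fraction of masks intersecting at least one other mask (brute force)."""
    stack = labels.as_stack()
    n = len(labels)
    if n == 0:
        return 0.0
    hits = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if np.logical_and(stack[i], stack[j]).any():
                hits[i] = hits[j] = True
    return float(hits.mean())


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Per-scene seeds derived deterministically from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def generate_dataset(params: SceneParams, n_scenes: int, seed: int) -> list[Scene]:
    """Independent scenes from per-scene derived seeds."""
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    scenes = []
    for s in derive_seeds(seed, n_scenes):
        p = SceneParams(**{**asdict(params), "seed": s})
        scenes.append(generate_scene(p))
    return scenes
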