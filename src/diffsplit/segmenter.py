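"""Recursive splitting: from one A/B split to a full instance segmentation.

The worklist algorithm decomposes the binarized semantic mask into
8-connected components, runs the denoising chain on each component's padded
crop, thresholds the final fields into two (possibly overlapping) sub-masks,
and recurses on the connected components of each side.  A branch terminates
when the chain stops splitting its region (one side keeps everything and the
other is empty — retried a few times with fresh noise, because an unlucky
initial field can put every instance on the same side) or at a depth cap.

Pixels claimed by neither side after thresholding are re-attached to the
nearest accepted side by geodesic growth inside the region, so foreground is
conserved; this can be disabled.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datamodel import Image, InstanceLabelSet, InstanceMask, SemanticMask
from .diffusion import Schedule, SplitFieldPair, run_denoising_chain
from .nn import ConfigError

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmenterConfig:
    """Recursion and post-processing knobs.

    ``fixed_recursions`` reproduces the fixed-count behaviour (every branch
    runs that many split rounds, no adaptive stop); when unset, branches stop
    adaptively as described in the module docstring, capped at ``max_depth``.
    """

    max_depth: int = 8
    binarize_threshold: float = 0.5
    min_instance_pixels: int = 8
    fixed_recursions: int | None = None
    crop_pad: int = 8
    # a chain attempt on a multi-instance region can land every instance on
    # the same side; re-noising attempts are independent, so a generous
    # budget at the root drives the merge-failure rate down.  Deeper nodes
    # are usually single instances already (each successful bisection halves
    # the residual multiplicity), so they get a small confirmation budget —
    # a large one would let rare spurious bisections of single cells through.
    trivial_retries: int = 29
    child_retries: int = 3
    # each accepted side must carry at least this fraction of the region,
    # otherwise the "split" is noise shaving off a fragment (many retries
    # would otherwise accept one eventually and shred cells)
    min_split_fraction: float = 0.05
    # two sides sharing more than this fraction of the smaller side are
    # treated as one blob seen twice, not a bisection; genuinely overlapping
    # cells stay below it (a cell buried deeper than ~3/4 inside another is
    # degenerate — the scene generator rejects such placements too)
    max_shared_fraction: float = 0.8
    reattach_unassigned: bool = True

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1")
        if not (0.0 <= self.binarize_threshold <= 1.0):
            raise ConfigError("binarize_threshold must be in [0, 1]")
        if self.fixed_recursions is not None and self.fixed_recursions < 1:
            raise ConfigError("fixed_recursions must be >= 1 when set")


def connected_components(S_binary: np.ndarray) -> InstanceLabelSet:
    """One mask per 8-connected foreground component; empty input -> empty set."""
    S_binary = np.asarray(S_binary).astype(bool)
    lab, n = ndimage.label(S_binary, structure=_EIGHT)
    return InstanceLabelSet(tuple(InstanceMask(lab == i) for i in range(1, n + 1)))


def binarize_split(
    fields: SplitFieldPair, S: SemanticMask, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold the final fields inside the foreground.  A pixel may land in
    both splits (overlap) or, transiently, in neither."""
    support = S.binary
    return (fields.A >= threshold) & support, (fields.B >= threshold) & support


def _node_seed(master: int, counter: int) -> int:
    return int(np.random.SeedSequence([master, counter]).generate_state(1)[0]) % (2**31)


def _axis_slice(lo: int, hi: int, pad: int, size: int) -> slice:
    lo, hi = max(lo - pad, 0), min(hi + pad, size)
    while hi - lo < min(8, size):  # keep crops at least 8 px where possible
        if lo > 0:
            lo -= 1
        elif hi < size:
            hi += 1
        else:
            break
    return slice(lo, hi)


def _bbox_slices(region: np.ndarray, pad: int) -> tuple[slice, slice]:
    rows = np.flatnonzero(region.any(axis=1))
    cols = np.flatnonzero(region.any(axis=0))
    h, w = region.shape
    return (
        _axis_slice(int(rows[0]), int(rows[-1]) + 1, pad, h),
        _axis_slice(int(cols[0]), int(cols[-1]) + 1, pad, w),
    )


def _reattach(region, side_a, side_b):
    """Attach region pixels in neither side to the geodesically nearer side
    (iterative dilation inside the region; ties go to both sides)."""
    unassigned = region & ~(side_a | side_b)
    a, b = side_a.copy(), side_b.copy()
    while unassigned.any():
        grow_a = ndimage.binary_dilation(a, _EIGHT) & unassigned
        grow_b = ndimage.binary_dilation(b, _EIGHT) & unassigned
        claimed = grow_a | grow_b
        if not claimed.any():
            # isolated pocket unreachable from either side: give it to A
            a |= unassigned
            break
        a |= grow_a
        b |= grow_b
        unassigned &= ~claimed
    return a, b


def segment(
    model,
    image: Image,
    S: SemanticMask,
    schedule: Schedule,
    cfg: SegmenterConfig = SegmenterConfig(),
    seed: int = 0,
) -> InstanceLabelSet:
    """Full instance segmentation of one image; deterministic given seed.

    ``model`` is a trained split network (or any object with a compatible
    ``forward``); recursion uses per-node seeds derived from ``seed``, FIFO
    order, so output masks and their order are reproducible.
    """
    noise_mean = getattr(model, "noise_mean", 0.5)
    noise_sigma = getattr(model, "noise_sigma", 0.25)
    depth_cap = cfg.fixed_recursions if cfg.fixed_recursions is not None else cfg.max_depth
    adaptive = cfg.fixed_recursions is None

    results: list[InstanceMask] = []
    counter = 0
    queue: deque[tuple[np.ndarray, int]] = deque()
    for comp in connected_components(S.binary):
        queue.append((comp.pixels, 0))

    while queue:
        region, depth = queue.popleft()
        area = int(region.sum())
        if area < cfg.min_instance_pixels:
            continue
        if depth >= depth_cap:
            results.append(InstanceMask(region))
            continue

        rs, cs = _bbox_slices(region, cfg.crop_pad)
        sub_img = Image(np.maximum(image.pixels[rs, cs], 0.0))
        region_crop = region[rs, cs]
        # the node's binary region plays the role of S: multiplying by a soft
        # probability at every chain step would decay the fields geometrically
        sub_s = SemanticMask(region_crop.astype(np.float32))

        split_found = False
        budget = cfg.trivial_retries if depth == 0 else cfg.child_retries
        for attempt in range(budget + 1):
            node_seed = _node_seed(seed, counter)
            counter += 1
            hook = getattr(model, "set_context", None)
            if hook is not None:
                hook((rs, cs))
            fields = run_denoising_chain(
                model, sub_img, sub_s, schedule, node_seed, noise_mean, noise_sigma
            )
            side_a, side_b = binarize_split(fields, sub_s, cfg.binarize_threshold)
            na, nb = int(side_a.sum()), int(side_b.sum())
            tol = max(cfg.min_instance_pixels, int(cfg.min_split_fraction * area))
            # a genuine bisection needs two substantial sides, and neither
            # side may be (almost) the whole region: "everything into A" or
            # "A plus a shard" carries no separation information and is
            # retried with fresh noise rather than recursed on
            a_is_all = int((side_a ^ region_crop).sum()) < cfg.min_instance_pixels
            b_is_all = int((side_b ^ region_crop).sum()) < cfg.min_instance_pixels
            trivial = na < tol or nb < tol or a_is_all or b_is_all
            if not trivial:
                # the sides must actually separate something: two nearly
                # coincident sides (shared pixels dominating the smaller
                # side) carry no bisection information either
                inter = int((side_a & side_b).sum())
                trivial = inter > cfg.max_shared_fraction * min(na, nb)
            if not trivial:
                split_found = True
                break
            if not adaptive:
                # fixed-count mode: no retry loop, recurse on whatever came out
                split_found = na >= cfg.min_instance_pixels or nb >= cfg.min_instance_pixels
                break

        if not split_found:
            results.append(InstanceMask(region))
            continue

        if cfg.reattach_unassigned:
            side_a, side_b = _reattach(region_crop, side_a, side_b)
        for side in (side_a, side_b):
            for comp in connected_components(side):
                full = np.zeros_like(region)
                full[rs, cs] = comp.pixels
                full &= region  # never grow beyond the parent region
                if full.any():
                    queue.append((full, depth + 1))

    deduped: list[InstanceMask] = []
    for m in results:
        if not any(np.array_equal(m.pixels, d.pixels) for d in deduped):
            deduped.append(m)
    return InstanceLabelSet(tuple(deduped))
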