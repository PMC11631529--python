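"""Overlap-aware instance matching and recall-vs-IoU-threshold curves.

Because predictions and ground truth are both stacks of binary masks,
matching works unchanged when masks overlap — a pixel shared by two cells
simply contributes to both masks' intersections.  Matching is a one-to-one
assignment maximizing total IoU among pairs with IoU ≥ threshold (Hungarian
algorithm; an order-dependent greedy variant is available for comparison).
Recall at threshold τ is the fraction of ground-truth instances matched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datamodel import InstanceLabelSet, InstanceMask, ShapeError

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching between predicted and true masks at a threshold."""

    pairs: tuple[tuple[int, int, float], ...]
    n_pred: int
    n_truth: int
    threshold: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def recall(self) -> float | None:
        if self.n_truth == 0:
            return None
        return self.n_matched / self.n_truth


def iou(a: InstanceMask, b: InstanceMask) -> float:
    """|a ∩ b| / |a ∪ b|."""
    if a.shape != b.shape:
        raise ShapeError("masks have different shapes")
    inter = np.logical_and(a.pixels, b.pixels).sum()
    union = np.logical_or(a.pixels, b.pixels).sum()
    return float(inter / union)


def iou_matrix(pred: InstanceLabelSet, truth: InstanceLabelSet) -> np.ndarray:
    if len(pred) == 0 or len(truth) == 0:
        return np.zeros((len(pred), len(truth)))
    if pred.shape != truth.shape:
        raise ShapeError("prediction and truth have different scene shapes")
    p = pred.as_stack().reshape(len(pred), -1).astype(np.float64)
    t = truth.as_stack().reshape(len(truth), -1).astype(np.float64)
    inter = p @ t.T
    areas_p = p.sum(1)[:, None]
    areas_t = t.sum(1)[None, :]
    return inter / (areas_p + areas_t - inter)


def match_instances(
    pred: InstanceLabelSet,
    truth: InstanceLabelSet,
    threshold: float = 0.5,
    method: str = "optimal",
) -> MatchResult:
    """One-to-one matching of predictions to truths with IoU ≥ threshold.

    ``optimal`` maximizes total IoU over the admissible pairs (sub-threshold
    entries contribute zero and are dropped afterwards, which preserves
    optimality).  ``greedy`` takes pairs in decreasing IoU order and is
    order-dependent only among exact IoU ties.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    m = iou_matrix(pred, truth)
    eligible = m >= threshold
    pairs: list[tuple[int, int, float]] = []
    if m.size and eligible.any():
        if method == "optimal":
            gain = np.where(eligible, m, 0.0)
            rows, cols = linear_sum_assignment(gain, maximize=True)
            for r, c in zip(rows, cols):
                if eligible[r, c]:
                    pairs.append((int(r), int(c), float(m[r, c])))
        elif method == "greedy":
            order = np.argsort(-m, axis=None, kind="stable")
            used_p, used_t = set(), set()
            for flat in order:
                r, c = np.unravel_index(flat, m.shape)
                if not eligible[r, c]:
                    break
                if r in used_p or c in used_t:
                    continue
                used_p.add(r)
                used_t.add(c)
                pairs.append((int(r), int(c), float(m[r, c])))
        else:
            raise ValueError(f"unknown matching method {method!r}")
    pairs.sort()
    return MatchResult(
        pairs=tuple(pairs), n_pred=len(pred), n_truth=len(truth), threshold=threshold
    )


def _as_pairs(pred, truth):
    if isinstance(pred, InstanceLabelSet):
        return [(pred, truth)]
    return list(zip(pred, truth))


def recall_curve(
    pred,
    truth,
    thresholds=DEFAULT_THRESHOLDS,
    aggregate: str = "pool",
    method: str = "optimal",
) -> list[tuple[float, float | None]]:
    """Recall as a function of the IoU threshold.

    ``pred``/``truth`` are a label-set pair or parallel lists of pairs.
    ``pool`` sums matched and truth counts over scenes before dividing;
    ``per_image`` averages per-scene recalls (scenes without truth skipped).
    An empty truth overall yields None, not 0.
    """
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    scene_pairs = _as_pairs(pred, truth)
    curve: list[tuple[float, float | None]] = []
    for thr in thresholds:
        results = [match_instances(p, t, thr, method) for p, t in scene_pairs]
        if aggregate == "pool":
            n_truth = sum(r.n_truth for r in results)
            n_match = sum(r.n_matched for r in results)
            curve.append((float(thr), n_match / n_truth if n_truth else None))
        elif aggregate == "per_image":
            vals = [r.recall for r in results if r.recall is not None]
            curve.append((float(thr), float(np.mean(vals)) if vals else None))
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
    return curve
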