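"""Segmentation evaluation metrics.

Detection F1 at an IoU threshold, Dice coefficient, (symmetric) best
Dice, and the skeleton-based surface Dice for membrane-like structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

__all__ = [
    "MatchResult",
    "matched_f1",
    "dice_score",
    "best_dice",
    "surface_dice",
    "aggregate_scores",
]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2.0 * self.tp / denom if denom else 1.0


def _labels_of(x) -> np.ndarray:
    return np.asarray(getattr(x, "labels", x))


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def _contingency(seg: np.ndarray, gt: np.ndarray):
    """Pairwise overlap counts between nonzero seg and gt labels."""
    sel = (seg > 0) | (gt > 0)
    pairs, counts = np.unique(
        np.stack([gt[sel].ravel(), seg[sel].ravel()]), axis=1, return_counts=True
    )
    return pairs, counts


def matched_f1(seg, gt, iou_threshold: float = 0.5):
    """Detection F1: pairs with IoU strictly above the threshold match.

    At thresholds >= 0.5 each object can match at most one partner, so
    the assignment is unambiguous. Returns ``(f1, MatchResult)``.
    """
    seg, gt = _labels_of(seg), _labels_of(gt)
    _check_shapes(seg, gt)
    seg_sizes = dict(zip(*np.unique(seg[seg > 0], return_counts=True)))
    gt_sizes = dict(zip(*np.unique(gt[gt > 0], return_counts=True)))
    pairs, counts = _contingency(seg, gt)
    candidates = []
    for (g, s), inter in zip(pairs.T, counts):
        if g == 0 or s == 0:
            continue
        union = gt_sizes[g] + seg_sizes[s] - inter
        candidates.append((inter / union, int(g), int(s)))
    # greedy by descending IoU; unique anyway for thresholds >= 0.5
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    matched = []
    matched_seg: set[int] = set()
    matched_gt: set[int] = set()
    for iou, g, s in candidates:
        if iou > iou_threshold and g not in matched_gt and s not in matched_seg:
            matched.append((int(g), int(s), float(iou)))
            matched_gt.add(int(g))
            matched_seg.add(int(s))
    tp = len(matched)
    fp = len(seg_sizes) - tp
    fn = len(gt_sizes) - tp
    result = MatchResult(tp=tp, fp=fp, fn=fn, pairs=matched)
    return result.f1, result


def dice_score(seg, gt) -> float:
    """Dice coefficient of two binary masks (1.0 when both are empty)."""
    seg = _labels_of(seg).astype(bool)
    gt = _labels_of(gt).astype(bool)
    _check_shapes(seg, gt)
    s, a = int(seg.sum()), int(gt.sum())
    if s + a == 0:
        return 1.0
    return 2.0 * int((seg & gt).sum()) / (s + a)


def best_dice(seg, gt, symmetric: bool = False) -> float:
    """Best Dice: per ground-truth object the best Dice over segmented objects,
    averaged over ground-truth objects.

    With ``symmetric=True`` the minimum of both directions is returned
    (equal to the directional value on identical inputs).
    """
    seg, gt = _labels_of(seg), _labels_of(gt)
    _check_shapes(seg, gt)
    if symmetric:
        return min(best_dice(seg, gt), best_dice(gt, seg))
    gt_ids, gt_counts = np.unique(gt[gt > 0], return_counts=True)
    if gt_ids.size == 0:
        return 1.0 if seg.max() == 0 else 0.0
    seg_sizes = dict(zip(*np.unique(seg[seg > 0], return_counts=True)))
    gt_sizes = dict(zip(gt_ids, gt_counts))
    pairs, counts = _contingency(seg, gt)
    best = {int(g): 0.0 for g in gt_ids}
    for (g, s), inter in zip(pairs.T, counts):
        if g == 0 or s == 0:
            continue
        d = 2.0 * inter / (gt_sizes[g] + seg_sizes[s])
        if d > best[int(g)]:
            best[int(g)] = d
    return float(np.mean(list(best.values())))


def _skeleton(mask: np.ndarray) -> np.ndarray:
    """Medial-axis skeleton; very thin sheets are their own skeleton."""
    if not mask.any():
        return mask
    interior = ndi.distance_transform_edt(mask)
    if interior.max() <= 1.0:  # <= 2 voxels thick: thinning would erase it
        return mask
    return skeletonize(mask).astype(bool)


def surface_dice(seg, gt, tolerance: float = 1.0) -> float:
    """Skeleton-based surface Dice.

    Both masks are skeletonized; precision is the fraction of
    segmentation-skeleton voxels within ``tolerance`` of the ground-truth
    skeleton, recall the converse, and the score their harmonic mean.
    """
    seg = _labels_of(seg).astype(bool)
    gt = _labels_of(gt).astype(bool)
    _check_shapes(seg, gt)
    if not seg.any() and not gt.any():
        return 1.0
    if not seg.any() or not gt.any():
        return 0.0
    sk_seg, sk_gt = _skeleton(seg), _skeleton(gt)
    d_to_gt = ndi.distance_transform_edt(~sk_gt)
    d_to_seg = ndi.distance_transform_edt(~sk_seg)
    precision = float((d_to_gt[sk_seg] <= tolerance).mean())
    recall = float((d_to_seg[sk_gt] <= tolerance).mean())
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def aggregate_scores(scores) -> dict:
    """Mean over items; the SD is reported when five or more items."""
    arr = np.asarray(list(scores), dtype=np.float64)
    out = {"mean": float(arr.mean()), "n": int(arr.size)}
    if arr.size >= 5:
        out["sd"] = float(arr.std(ddof=1))
    return out
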