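"""Tracking evaluation: CLEAR-MOT (MOTA, FP, FN, ID switches), IDF1, and
the per-target tracking rate.

The CLEAR protocol matches ground-truth and hypothesis boxes frame by
frame: correspondences established earlier are kept while their IoU
stays at or above the threshold, remaining pairs are resolved by a
maximum-total-IoU assignment, and a ground-truth identity whose matched
hypothesis identity changes (relative to the last frame it was matched,
gaps included) counts one ID switch.

IDF1 follows the identity-measures protocol: a single global bipartite
assignment between ground-truth and hypothesis identities maximizes the
number of per-frame box matches (IoU >= threshold); IDF1 =
2*IDTP / (2*IDTP + IDFP + IDFN).

The tracking rate is ID-agnostic: for each ground-truth identity, the
fraction of its present frames in which it is matched to *any*
hypothesis box under CLEAR matching. A fully missed animal scores 0.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import Trajectory
from .errors import EmptyGroundTruthError

__all__ = [
    "EvalReport",
    "FrameMatching",
    "boxes_by_frame",
    "evaluate",
    "idf1",
    "iou",
    "match_frames",
    "mota",
    "tracking_rate",
]

Box = tuple[float, float, float, float]  # cx, cy, w, h


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two center/size boxes."""
    ax1, ay1 = a[0] - a[2] / 2, a[1] - a[3] / 2
    ax2, ay2 = a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1 = b[0] - b[2] / 2, b[1] - b[3] / 2
    bx2, by2 = b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union


def boxes_by_frame(trajectories: Sequence[Trajectory]) -> dict[int, dict[int, Box]]:
    """Reindex trajectories as frame -> id -> (cx, cy, w, h)."""
    out: dict[int, dict[int, Box]] = defaultdict(dict)
    for traj in trajectories:
        for k, frame in enumerate(traj.frames):
            out[int(frame)][traj.track_id] = (
                float(traj.centers[k, 0]),
                float(traj.centers[k, 1]),
                float(traj.boxes[k, 0]),
                float(traj.boxes[k, 1]),
            )
    return dict(out)


@dataclass
class FrameMatching:
    """Per-frame CLEAR correspondences and the counts derived from them."""

    pairs: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    false_positives: dict[int, list[int]] = field(default_factory=dict)
    misses: dict[int, list[int]] = field(default_factory=dict)
    id_switches: int = 0
    n_gt_boxes: int = 0
    n_hyp_boxes: int = 0
    gt_presence: dict[int, int] = field(default_factory=dict)
    gt_matched_frames: dict[int, int] = field(default_factory=dict)

    @property
    def n_false_positives(self) -> int:
        return sum(len(v) for v in self.false_positives.values())

    @property
    def n_misses(self) -> int:
        return sum(len(v) for v in self.misses.values())


def match_frames(
    gt: Sequence[Trajectory],
    hyp: Sequence[Trajectory],
    iou_threshold: float = 0.5,
) -> FrameMatching:
    """Run CLEAR matching over a whole sequence."""
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie strictly between 0 and 1")
    gt_frames = boxes_by_frame(gt)
    hyp_frames = boxes_by_frame(hyp)
    result = FrameMatching()
    last_hyp_for_gt: dict[int, int] = {}  # persists across frames, gaps included

    for frame in sorted(set(gt_frames) | set(hyp_frames)):
        gt_boxes = gt_frames.get(frame, {})
        hyp_boxes = hyp_frames.get(frame, {})
        result.n_gt_boxes += len(gt_boxes)
        result.n_hyp_boxes += len(hyp_boxes)
        for g in gt_boxes:
            result.gt_presence[g] = result.gt_presence.get(g, 0) + 1

        pairs: list[tuple[int, int]] = []
        free_gt = dict(gt_boxes)
        free_hyp = dict(hyp_boxes)
        # Keep established correspondences while they still overlap.
        for g in sorted(gt_boxes):
            h = last_hyp_for_gt.get(g)
            if h is not None and h in free_hyp:
                if iou(gt_boxes[g], hyp_boxes[h]) >= iou_threshold:
                    pairs.append((g, h))
                    del free_gt[g]
                    del free_hyp[h]
        # Resolve the remainder by maximum-total-IoU assignment.
        if free_gt and free_hyp:
            g_ids = sorted(free_gt)
            h_ids = sorted(free_hyp)
            gain = np.zeros((len(g_ids), len(h_ids)))
            for i, g in enumerate(g_ids):
                for j, h in enumerate(h_ids):
                    v = iou(free_gt[g], free_hyp[h])
                    if v >= iou_threshold:
                        gain[i, j] = v
            rows, cols = linear_sum_assignment(gain, maximize=True)
            for i, j in zip(rows, cols):
                if gain[i, j] >= iou_threshold:
                    pairs.append((g_ids[i], h_ids[j]))

        matched_gt = {g for g, _ in pairs}
        matched_hyp = {h for _, h in pairs}
        for g, h in pairs:
            prev = last_hyp_for_gt.get(g)
            if prev is not None and prev != h:
                result.id_switches += 1
            last_hyp_for_gt[g] = h
            result.gt_matched_frames[g] = result.gt_matched_frames.get(g, 0) + 1
        result.pairs[frame] = sorted(pairs)
        result.false_positives[frame] = sorted(set(hyp_boxes) - matched_hyp)
        result.misses[frame] = sorted(set(gt_boxes) - matched_gt)
    return result


def mota(matching: FrameMatching) -> float:
    """Multi-object tracking accuracy: 1 - (FP + FN + IDs) / GT boxes."""
    if matching.n_gt_boxes == 0:
        raise EmptyGroundTruthError("no ground-truth boxes")
    errors = matching.n_false_positives + matching.n_misses + matching.id_switches
    return 1.0 - errors / matching.n_gt_boxes


def idf1(
    gt: Sequence[Trajectory],
    hyp: Sequence[Trajectory],
    iou_threshold: float = 0.5,
) -> float:
    """Identity F1 over the globally optimal identity correspondence."""
    gt_frames = boxes_by_frame(gt)
    hyp_frames = boxes_by_frame(hyp)
    n_gt = sum(len(v) for v in gt_frames.values())
    n_hyp = sum(len(v) for v in hyp_frames.values())
    if n_gt == 0:
        raise EmptyGroundTruthError("no ground-truth boxes")

    overlap: dict[tuple[int, int], int] = defaultdict(int)
    for frame, gt_boxes in gt_frames.items():
        hyp_boxes = hyp_frames.get(frame, {})
        for g, gb in gt_boxes.items():
            for h, hb in hyp_boxes.items():
                if iou(gb, hb) >= iou_threshold:
                    overlap[(g, h)] += 1
    g_ids = sorted({g for traj in gt_frames.values() for g in traj})
    h_ids = sorted({h for traj in hyp_frames.values() for h in traj})
    idtp = 0
    if g_ids and h_ids:
        gain = np.zeros((len(g_ids), len(h_ids)))
        for i, g in enumerate(g_ids):
            for j, h in enumerate(h_ids):
                gain[i, j] = overlap.get((g, h), 0)
        rows, cols = linear_sum_assignment(gain, maximize=True)
        idtp = int(gain[rows, cols].sum())
    idfn = n_gt - idtp
    idfp = n_hyp - idtp
    return 2 * idtp / (2 * idtp + idfp + idfn)


def tracking_rate(
    gt: Sequence[Trajectory],
    hyp: Sequence[Trajectory],
    iou_threshold: float = 0.5,
) -> dict[int, float]:
    """Per-ground-truth-identity fraction of present frames that are tracked."""
    matching = match_frames(gt, hyp, iou_threshold)
    return {
        g: matching.gt_matched_frames.get(g, 0) / present
        for g, present in sorted(matching.gt_presence.items())
        if present > 0
    }


def post_occlusion_identity_preservation(
    gt: Sequence[Trajectory],
    hyp: Sequence[Trajectory],
    windows: Sequence[tuple[int, int, int]],
    horizon: int = 24,
    iou_threshold: float = 0.5,
) -> tuple[int, int]:
    """Fraction of post-occlusion frames that keep the pre-occlusion identity.

    ``windows`` lists (gt_id, first_occluded_frame, first_clear_frame).
    For each window the hypothesis identity matched to the ground-truth
    target just before the occlusion is compared with the identity
    matched on each of the ``horizon`` frames after it clears. Returns
    (preserved_frames, total_frames).
    """
    matching = match_frames(gt, hyp, iou_threshold)
    last_frame = max(matching.pairs) if matching.pairs else -1
    ok = total = 0
    for gt_id, start, end in windows:
        pre = None
        for f in range(start - 1, -1, -1):
            pre = dict(matching.pairs.get(f, ())).get(gt_id)
            if pre is not None:
                break
        for f in range(end, min(end + horizon, last_frame + 1)):
            total += 1
            if dict(matching.pairs.get(f, ())).get(gt_id) == pre:
                ok += 1
    return ok, total


@dataclass
class EvalReport:
    """Summary of a tracking evaluation.

    Counts are also expressed as fractions of total ground-truth boxes,
    matching how MOT benchmarks print FP/FN/IDs percentages.
    """

    mota: float
    idf1: float
    ids_count: int
    fp_count: int
    fn_count: int
    ids_rate: float
    fp_rate: float
    fn_rate: float
    n_gt_boxes: int
    per_target_tracking_rate: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "mota": self.mota,
            "idf1": self.idf1,
            "ids_count": self.ids_count,
            "fp_count": self.fp_count,
            "fn_count": self.fn_count,
            "ids_rate": self.ids_rate,
            "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
            "n_gt_boxes": self.n_gt_boxes,
            "per_target_tracking_rate": {
                str(k): v for k, v in self.per_target_tracking_rate.items()
            },
        }


def evaluate(
    gt: Sequence[Trajectory],
    hyp: Sequence[Trajectory],
    iou_threshold: float = 0.5,
) -> EvalReport:
    """Compute the full metric suite for one sequence."""
    matching = match_frames(gt, hyp, iou_threshold)
    n = matching.n_gt_boxes
    if n == 0:
        raise EmptyGroundTruthError("no ground-truth boxes")
    return EvalReport(
        mota=mota(matching),
        idf1=idf1(gt, hyp, iou_threshold),
        ids_count=matching.id_switches,
        fp_count=matching.n_false_positives,
        fn_count=matching.n_misses,
        ids_rate=matching.id_switches / n,
        fp_rate=matching.n_false_positives / n,
        fn_rate=matching.n_misses / n,
        n_gt_boxes=n,
        per_target_tracking_rate=tracking_rate(gt, hyp, iou_threshold),
    )
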