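"""Independent reference implementation of the CLEAR-MOT / identity
metrics, used only as a test oracle.

Deliberately naive and structured differently from the package path:
plain dicts, recursive brute-force enumeration of assignments instead
of the Hungarian algorithm, corner-coordinate IoU. Valid for small
scenes (<= ~6 identities per side).
"""

from __future__ import annotations

from itertools import combinations, permutations


def box_iou(a, b):
    """IoU of (cx, cy, w, h) boxes via explicit corner arithmetic."""
    ax_lo, ax_hi = a[0] - a[2] / 2.0, a[0] + a[2] / 2.0
    ay_lo, ay_hi = a[1] - a[3] / 2.0, a[1] + a[3] / 2.0
    bx_lo, bx_hi = b[0] - b[2] / 2.0, b[0] + b[2] / 2.0
    by_lo, by_hi = b[1] - b[3] / 2.0, b[1] + b[3] / 2.0
    ox = max(0.0, min(ax_hi, bx_hi) - max(ax_lo, bx_lo))
    oy = max(0.0, min(ay_hi, by_hi) - max(ay_lo, by_lo))
    inter = ox * oy
    if inter == 0.0:
        return 0.0
    return inter / (a[2] * a[3] + b[2] * b[3] - inter)


def _best_assignment(gain):
    """Max-total-gain injective assignment by exhaustive enumeration.

    ``gain[(g, h)]`` holds only admissible pairs. Returns (total, pairs).
    """
    g_ids = sorted({g for g, _ in gain})
    h_ids = sorted({h for _, h in gain})
    best_total, best_pairs = 0.0, []
    for k in range(0, min(len(g_ids), len(h_ids)) + 1):
        for g_sub in combinations(g_ids, k):
            for h_perm in permutations(h_ids, k):
                pairs = list(zip(g_sub, h_perm))
                if any(p not in gain for p in pairs):
                    continue
                total = sum(gain[p] for p in pairs)
                if total > best_total:
                    best_total, best_pairs = total, pairs
    return best_total, best_pairs


def clear_metrics(gt_frames, hyp_frames, iou_threshold=0.5):
    """CLEAR protocol on frame-indexed box dicts.

    ``gt_frames`` / ``hyp_frames``: {frame: {id: (cx, cy, w, h)}}.
    Returns a dict with fp, fn, ids, mota, n_gt and per-gt-id
    (present, matched) frame counts.
    """
    corr = {}
    fp = fn = ids = n_gt = 0
    present, matched_ct = {}, {}
    for frame in sorted(set(gt_frames) | set(hyp_frames)):
        g_boxes = gt_frames.get(frame, {})
        h_boxes = hyp_frames.get(frame, {})
        n_gt += len(g_boxes)
        for g in g_boxes:
            present[g] = present.get(g, 0) + 1
        pairs = []
        used_h = set()
        for g in sorted(g_boxes):
            h = corr.get(g)
            if (
                h is not None
                and h in h_boxes
                and box_iou(g_boxes[g], h_boxes[h]) >= iou_threshold
            ):
                pairs.append((g, h))
                used_h.add(h)
        free_g = [g for g in g_boxes if g not in {p[0] for p in pairs}]
        free_h = [h for h in h_boxes if h not in used_h]
        gain = {}
        for g in free_g:
            for h in free_h:
                v = box_iou(g_boxes[g], h_boxes[h])
                if v >= iou_threshold:
                    gain[(g, h)] = v
        _, extra = _best_assignment(gain)
        pairs.extend(extra)
        for g, h in pairs:
            if g in corr and corr[g] != h:
                ids += 1
            corr[g] = h
            matched_ct[g] = matched_ct.get(g, 0) + 1
        fp += len(h_boxes) - len(pairs)
        fn += len(g_boxes) - len(pairs)
    return {
        "fp": fp,
        "fn": fn,
        "ids": ids,
        "n_gt": n_gt,
        "mota": 1.0 - (fp + fn + ids) / n_gt if n_gt else float("nan"),
        "tracking_rate": {
            g: matched_ct.get(g, 0) / present[g] for g in present
        },
    }


def idf1_metric(gt_frames, hyp_frames, iou_threshold=0.5):
    """Identity F1 with the global identity assignment found by brute force."""
    overlap = {}
    n_gt = n_hyp = 0
    for frame in sorted(set(gt_frames) | set(hyp_frames)):
        g_boxes = gt_frames.get(frame, {})
        h_boxes = hyp_frames.get(frame, {})
        n_gt += len(g_boxes)
        n_hyp += len(h_boxes)
        for g, gb in g_boxes.items():
            for h, hb in h_boxes.items():
                if box_iou(gb, hb) >= iou_threshold:
                    overlap[(g, h)] = overlap.get((g, h), 0) + 1
    idtp, _ = _best_assignment(overlap)
    idfn = n_gt - idtp
    idfp = n_hyp - idtp
    return 2 * idtp / (2 * idtp + idfp + idfn)
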