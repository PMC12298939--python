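"""Recognition of piglet-group aggregation/dispersion responses to sow
posture changes.

When a lactating sow changes posture (stands up, lies down, rolls), the
piglets inside her immediate "stress zone" — a disc centered on her
centroid with radius equal to her body length — respond by gathering
toward her (e.g., to nurse after she lies down) or scattering away
(to avoid crushing as she rises). The recognizer works on trajectories
alone:

1. For each piglet sharing frames with the sow, compute the per-frame
   sow-piglet center distance CD and its difference series D
   (negative D = approaching).
2. Mark each frame's movement direction by the angle between the
   piglet's displacement and the piglet-to-sow direction: within 75 deg
   of the sow direction -> toward (0); between 105 and 255 deg -> away
   (1); otherwise sideways/no direction (2).
3. An individual is *gathering* (B=0) iff its mean distance difference
   is negative and its modal direction mark is 0; *dispersing* (B=1)
   iff the mean difference is positive and the modal mark is 1; else
   *other* (B=2).
4. The group label is a strict-majority vote: aggregation if more than
   half the in-zone piglets gather, dispersion if more than half
   disperse, otherwise other.

Displacements are smoothed with a short moving average before the
direction test, and sub-pixel displacements carry no direction; both
damp the jitter of idle piglets (body swaying, aimless wandering).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Trajectory
from .errors import (
    InsufficientOverlapError,
    MissingSowError,
    NoPigletsInZoneError,
)

__all__ = [
    "BehaviorConfig",
    "GroupResult",
    "PigletAssessment",
    "AGGREGATION",
    "DISPERSION",
    "OTHER",
    "analyze_episode",
    "assess_piglet",
    "confusion_metrics",
    "direction_mark",
    "distance_series",
    "estimate_sow_body_length",
    "group_behavior",
    "individual_behavior",
    "stress_zone_filter",
]

AGGREGATION = "aggregation"
DISPERSION = "dispersion"
OTHER = "other"

_LABELS = {0: AGGREGATION, 1: DISPERSION, 2: OTHER}


@dataclass
class BehaviorConfig:
    """Parameters of the recognizer (angles in degrees, lengths in pixels)."""

    toward_angle_deg: float = 75.0
    away_band_deg: tuple[float, float] = (105.0, 255.0)
    majority_fraction: float = 0.5
    zone_radius_mode: str = "sow_body_length"
    sow_body_length_estimator: str = "box_major_axis"
    min_displacement: float = 0.5
    smoothing_window: int = 3

    def __post_init__(self) -> None:
        low, high = self.away_band_deg
        if not 0.0 < self.toward_angle_deg < low < high < 360.0:
            raise ValueError(
                "angle bands must satisfy 0 < toward < away_low < away_high < 360"
            )
        if self.sow_body_length_estimator not in ("box_major_axis", "box_diagonal"):
            raise ValueError(
                f"unknown body-length estimator {self.sow_body_length_estimator!r}"
            )
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")


@dataclass
class PigletAssessment:
    """Per-piglet evidence and verdict for one episode."""

    piglet_id: int
    distance_series: np.ndarray
    distance_diffs: np.ndarray
    direction_marks: np.ndarray
    mean_diff: float
    modal_mark: int
    behavior: int  # 0 aggregation, 1 dispersion, 2 other


@dataclass
class GroupResult:
    """Group-level verdict for one posture-change episode."""

    group_label: str
    n_in_zone: int
    assessments: list[PigletAssessment] = field(default_factory=list)
    episode_id: Optional[int] = None


def estimate_sow_body_length(sow: Trajectory, config: BehaviorConfig) -> float:
    """Body length from the sow's boxes: median of the larger side (or diagonal)."""
    if config.sow_body_length_estimator == "box_major_axis":
        per_frame = np.max(sow.boxes, axis=1)
    else:
        per_frame = np.hypot(sow.boxes[:, 0], sow.boxes[:, 1])
    return float(np.median(per_frame))


def stress_zone_filter(
    sow: Optional[Trajectory],
    piglets: Sequence[Trajectory],
    config: Optional[BehaviorConfig] = None,
) -> list[Trajectory]:
    """Keep piglets that enter the stress zone in at least one shared frame."""
    config = config or BehaviorConfig()
    if sow is None or len(sow) == 0:
        raise MissingSowError("a sow trajectory is required")
    radius = estimate_sow_body_length(sow, config)
    sow_at = {int(f): sow.centers[k] for k, f in enumerate(sow.frames)}
    kept = []
    for piglet in piglets:
        for k, frame in enumerate(piglet.frames):
            sc = sow_at.get(int(frame))
            if sc is None:
                continue
            if math.hypot(*(piglet.centers[k] - sc)) <= radius:
                kept.append(piglet)
                break
    return kept


def _overlap_indices(piglet: Trajectory, sow: Trajectory):
    common, pi, si = np.intersect1d(piglet.frames, sow.frames, return_indices=True)
    return common, pi, si


def distance_series(
    piglet: Trajectory, sow: Trajectory
) -> tuple[np.ndarray, np.ndarray]:
    """Sow-piglet center distances CD per shared frame and their differences D.

    D[t] = CD[t] - CD[t-1]; negative values mean the piglet is approaching.
    """
    common, pi, si = _overlap_indices(piglet, sow)
    if len(common) < 2:
        raise InsufficientOverlapError(
            f"piglet {piglet.track_id} and sow share {len(common)} frame(s)"
        )
    cd = np.linalg.norm(piglet.centers[pi] - sow.centers[si], axis=1)
    return cd, np.diff(cd)


def direction_mark(
    displacement: tuple[float, float],
    piglet_center: tuple[float, float],
    sow_center: tuple[float, float],
    config: Optional[BehaviorConfig] = None,
) -> int:
    """Classify one frame's movement direction relative to the sow.

    Computes the angle O_ps between the piglet's displacement direction
    and the piglet-to-sow direction, wrapped to [0, 360): mark 0 (toward)
    when the signed angle is within the toward cone, 1 (away) inside the
    away band, 2 otherwise. Displacements shorter than
    ``min_displacement`` carry no direction and get mark 2.
    """
    config = config or BehaviorConfig()
    dx, dy = displacement
    if math.hypot(dx, dy) < config.min_displacement:
        return 2
    o_p = math.degrees(math.atan2(dy, dx))
    o_s = math.degrees(
        math.atan2(sow_center[1] - piglet_center[1], sow_center[0] - piglet_center[0])
    )
    o_ps = (o_p - o_s) % 360.0
    t = config.toward_angle_deg
    low, high = config.away_band_deg
    if o_ps < t or o_ps > 360.0 - t:
        return 0
    if low < o_ps < high:
        return 1
    return 2


def _smooth_displacements(disp: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 (shrinking at the edges)."""
    if window <= 1 or len(disp) <= 1:
        return disp
    half = window // 2
    out = np.empty_like(disp)
    for i in range(len(disp)):
        lo, hi = max(0, i - half), min(len(disp), i + half + 1)
        out[i] = disp[lo:hi].mean(axis=0)
    return out


def _modal_mark(marks: np.ndarray) -> int:
    """Most frequent direction mark; ties are resolved conservatively to 2."""
    if len(marks) == 0:
        return 2
    counts = Counter(int(m) for m in marks)
    best = max(counts.values())
    winners = [m for m, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else 2


def individual_behavior(mean_diff: float, modal_mark: int) -> int:
    """Step-4 rule: 0 iff approaching on average with modal mark 0;
    1 iff receding on average with modal mark 1; else 2."""
    if mean_diff < 0 and modal_mark == 0:
        return 0
    if mean_diff > 0 and modal_mark == 1:
        return 1
    return 2


def assess_piglet(
    piglet: Trajectory, sow: Trajectory, config: Optional[BehaviorConfig] = None
) -> PigletAssessment:
    """Run steps 2-4 for one piglet against the sow trajectory."""
    config = config or BehaviorConfig()
    common, pi, si = _overlap_indices(piglet, sow)
    cd, diffs = distance_series(piglet, sow)
    disp_all = piglet.displacement_series()  # aligned with piglet.frames[1:]
    # restrict to shared frames (skip the piglet's first frame, which has
    # no displacement)
    marks = []
    smoothed = _smooth_displacements(disp_all, config.smoothing_window)
    disp_by_frame = {int(f): smoothed[k] for k, f in enumerate(piglet.frames[1:])}
    for k, frame in enumerate(common):
        d = disp_by_frame.get(int(frame))
        if d is None:
            continue
        marks.append(
            direction_mark(
                (float(d[0]), float(d[1])),
                tuple(piglet.centers[pi[k]]),
                tuple(sow.centers[si[k]]),
                config,
            )
        )
    marks = np.asarray(marks, dtype=int)
    mean_diff = float(diffs.mean())
    modal = _modal_mark(marks)
    return PigletAssessment(
        piglet_id=piglet.track_id,
        distance_series=cd,
        distance_diffs=diffs,
        direction_marks=marks,
        mean_diff=mean_diff,
        modal_mark=modal,
        behavior=individual_behavior(mean_diff, modal),
    )


def group_behavior(
    behaviors: Sequence[int], majority_fraction: float = 0.5
) -> str:
    """Step-5 strict-majority vote over individual behaviors."""
    n = len(behaviors)
    if n == 0:
        raise NoPigletsInZoneError("no piglets to vote")
    counts = Counter(int(b) for b in behaviors)
    if counts.get(0, 0) > majority_fraction * n:
        return AGGREGATION
    if counts.get(1, 0) > majority_fraction * n:
        return DISPERSION
    return OTHER


def analyze_episode(
    sow: Trajectory,
    piglets: Sequence[Trajectory],
    config: Optional[BehaviorConfig] = None,
    episode_id: Optional[int] = None,
) -> GroupResult:
    """Full pipeline: stress-zone filter, per-piglet assessment, group vote."""
    config = config or BehaviorConfig()
    in_zone = stress_zone_filter(sow, piglets, config)
    assessments = []
    for piglet in in_zone:
        try:
            assessments.append(assess_piglet(piglet, sow, config))
        except InsufficientOverlapError:
            continue
    if not assessments:
        raise NoPigletsInZoneError("no piglets in the stress zone")
    label = group_behavior(
        [a.behavior for a in assessments], config.majority_fraction
    )
    return GroupResult(
        group_label=label,
        n_in_zone=len(assessments),
        assessments=assessments,
        episode_id=episode_id,
    )


def confusion_metrics(matrix) -> dict:
    """Per-class and average accuracy from a confusion matrix.

    Layout: rows = predicted, columns = ground truth. Per-class accuracy
    is the diagonal count over the column total (as a percentage);
    classes with an empty column are reported as None and excluded from
    the unweighted (macro) average.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any():
        raise ValueError("confusion matrix counts must be nonnegative")
    col_totals = m.sum(axis=0)
    if not (col_totals > 0).any():
        raise ValueError("confusion matrix has no observations")
    per_class: list[Optional[float]] = []
    for k in range(m.shape[0]):
        if col_totals[k] == 0:
            per_class.append(None)
        else:
            per_class.append(100.0 * m[k, k] / col_totals[k])
    defined = [a for a in per_class if a is not None]
    return {
        "per_class_accuracy": per_class,
        "average_accuracy": float(np.mean(defined)),
        "column_totals": col_totals.astype(int).tolist(),
    }
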