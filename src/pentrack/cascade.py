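"""Score- and time-driven hierarchical association of detections to tracks.

Piglets in a farrowing pen move through three observable motion states:
continuously visible, briefly reappearing after full occlusion, and
reappearing while still partially occluded (low detection score, altered
appearance). The cascade handles one state per stage:

1. *First matching* — greedy nearest-center association of the current
   frame's detections to active tracks, gated by box scale, claiming
   candidate-detection pairs in ascending distance order. Center
   distance is insensitive to the box-size churn that occlusion and
   crowding cause, so continuously visible animals are resolved here.
2. *Second matching* — Hungarian assignment of the leftovers to lost
   tracks by a score- and time-weighted appearance similarity
   ``g(alpha) * beta * cos(track_emb, det_emb)``, where ``alpha`` is the
   frames the track has gone unmatched, ``beta`` its last matched
   confidence, and ``g`` a decay (default 1/alpha). This revives tracks
   whose owner reappears looking like itself.
3. *Third matching* — remaining detections are split on ``score_high``:
   confident ones found new tracks (newly emerged animals); the rest
   enter a save-and-iterate pool for ``reserve_frames`` frames, where
   they are offered back to the first matching by position. A pool box
   confirmed by a later detection seeds a new track containing both
   observations; unclaimed boxes expire.

All tie-breaks are deterministic (lowest track id, then lowest detection
index), so a sequence tracked twice yields identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import Detection, Track, TrackerConfig, Trajectory
from .errors import SequenceOrderError, SimilarityUnavailableError

__all__ = [
    "AssociationResult",
    "ReservedDetection",
    "Tracker",
    "appearance_similarity",
    "first_match",
    "predict_center",
    "second_match",
    "third_match",
    "track_sequence",
]


@dataclass
class ReservedDetection:
    """A low-score leftover held in the save-and-iterate pool."""

    detection: Detection
    frame_reserved: int

    def age(self, current_frame: int) -> int:
        return current_frame - self.frame_reserved


@dataclass
class AssociationResult:
    """Outcome of one frame of association.

    Every input detection index lands in exactly one of ``matches``
    (second element of a pair), ``new_track_ids`` (keys of
    ``new_track_detections``), ``reserved`` or ``discarded``; every
    candidate track lands in ``matches`` or ``unmatched_tracks``.
    """

    matches: list[tuple[int, int]] = field(default_factory=list)
    unmatched_tracks: list[int] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)
    new_track_ids: list[int] = field(default_factory=list)
    new_track_detections: dict[int, int] = field(default_factory=dict)
    reserved: list[int] = field(default_factory=list)
    discarded: list[int] = field(default_factory=list)

    def n_accounted(self) -> int:
        return (
            len(self.matches)
            + len(self.new_track_detections)
            + len(self.reserved)
            + len(self.discarded)
        )


def predict_center(track: Track) -> tuple[float, float]:
    """Constant-velocity prediction of a track's next center.

    Velocity is the detector-supplied displacement of the last matched
    detection when available, otherwise the last inter-frame finite
    difference ((0, 0) for a single-record track).
    """
    if not track.centers:
        raise ValueError("track has no recorded center")
    cx, cy = track.centers[-1]
    vx, vy = track.velocity
    if track.displacement is not None:
        vx, vy = track.displacement
    return (cx + vx, cy + vy)


def _candidate_center(cand) -> tuple[float, float]:
    if isinstance(cand, ReservedDetection):
        return cand.detection.center
    return predict_center(cand)


def _candidate_class(cand) -> str:
    if isinstance(cand, ReservedDetection):
        return cand.detection.class_label
    return cand.class_label


def first_match(
    tracks: Sequence,
    detections: Sequence[Detection],
    config: TrackerConfig,
    det_indices: Optional[Sequence[int]] = None,
) -> AssociationResult:
    """Greedy center-distance association (stage 1).

    Candidate-detection pairs within the gate — ``gate_factor *
    sqrt(w * h)`` of the detection box, same class only — are claimed in
    ascending distance order, each candidate and detection at most once,
    so every pairing is locally nearest-first. Ties break toward the
    earlier candidate (lowest track id) and then the lower detection
    index. ``tracks`` may mix `Track` objects with `ReservedDetection`
    pool entries (which sit at their stored center). Matches are
    reported as ``(candidate_position, detection_index)`` pairs, where
    candidate_position indexes ``tracks``.
    """
    if det_indices is None:
        det_indices = list(range(len(detections)))
    result = AssociationResult()
    centers = [_candidate_center(c) for c in tracks]
    pairs: list[tuple[float, int, int]] = []
    for i, det in enumerate(detections):
        gate = config.gate_factor * math.sqrt(det.size[0] * det.size[1])
        for j, (cx, cy) in enumerate(centers):
            if _candidate_class(tracks[j]) != det.class_label:
                continue
            dist = math.hypot(det.center[0] - cx, det.center[1] - cy)
            if dist <= gate:
                pairs.append((dist, j, i))
    pairs.sort()
    claimed: set[int] = set()
    taken_dets: set[int] = set()
    for _, j, i in pairs:
        if j in claimed or i in taken_dets:
            continue
        claimed.add(j)
        taken_dets.add(i)
        result.matches.append((j, det_indices[i]))
    result.unmatched_detections = [
        det_indices[i] for i in range(len(detections)) if i not in taken_dets
    ]
    result.unmatched_tracks = [j for j in range(len(tracks)) if j not in claimed]
    result.matches.sort()
    result.unmatched_detections.sort()
    return result


def _time_decay(alpha: int, config: TrackerConfig) -> float:
    if config.time_decay == "inverse":
        return 1.0 / alpha
    return math.exp(-config.time_decay_rate * alpha)


def appearance_similarity(
    track: Track, detection: Detection, current_frame: int, config: TrackerConfig
) -> float:
    """Score- and time-weighted appearance similarity ``g(alpha)*beta*cos``.

    ``alpha = current_frame - track.last_matched_frame`` is the lost
    duration, ``beta`` the track's last matched confidence, and the
    cosine is the inner product of the two unit embeddings. The weight
    ``g`` down-ranks tracks that have been lost longer, so a reappearing
    detection preferentially revives the most recently seen look-alike.

    Raises
    ------
    SimilarityUnavailableError
        If either side carries no embedding.
    """
    if track.embedding is None or detection.embedding is None:
        raise SimilarityUnavailableError(
            f"track {track.track_id} / detection at frame {detection.frame}"
        )
    alpha = current_frame - track.last_matched_frame
    if alpha <= 0:
        raise ValueError("current_frame must exceed track.last_matched_frame")
    cos = float(np.dot(track.embedding, detection.embedding))
    return _time_decay(alpha, config) * track.last_score * cos


def second_match(
    tracks: Sequence[Track],
    detections: Sequence[Detection],
    current_frame: int,
    config: TrackerConfig,
    det_indices: Optional[Sequence[int]] = None,
) -> AssociationResult:
    """Hungarian assignment on appearance similarity (stage 2).

    Builds the track x detection similarity matrix, solves the maximum
    total-similarity assignment, and drops pairs whose similarity falls
    below ``config.similarity_floor`` or that were unavailable (missing
    embedding / class mismatch). Matches are ``(track_position,
    detection_index)`` pairs; reviving the matched tracks is the
    caller's responsibility.
    """
    if det_indices is None:
        det_indices = list(range(len(detections)))
    result = AssociationResult()
    nt, nd = len(tracks), len(detections)
    if nt == 0 or nd == 0:
        result.unmatched_tracks = list(range(nt))
        result.unmatched_detections = sorted(det_indices)
        return result
    UNAVAILABLE = -1e9
    sim = np.full((nt, nd), UNAVAILABLE)
    for ti, track in enumerate(tracks):
        for di, det in enumerate(detections):
            if track.class_label != det.class_label:
                continue
            try:
                sim[ti, di] = appearance_similarity(track, det, current_frame, config)
            except SimilarityUnavailableError:
                continue
    rows, cols = linear_sum_assignment(sim, maximize=True)
    matched_t: set[int] = set()
    matched_d: set[int] = set()
    for ti, di in zip(rows, cols):
        if sim[ti, di] <= UNAVAILABLE / 2 or sim[ti, di] < config.similarity_floor:
            continue
        result.matches.append((ti, det_indices[di]))
        matched_t.add(ti)
        matched_d.add(di)
    result.unmatched_tracks = [t for t in range(nt) if t not in matched_t]
    result.unmatched_detections = sorted(
        det_indices[d] for d in range(nd) if d not in matched_d
    )
    result.matches.sort()
    return result


def third_match(
    detections: Sequence[Detection],
    config: TrackerConfig,
    det_indices: Optional[Sequence[int]] = None,
) -> tuple[list[int], list[int]]:
    """Split stage-2 leftovers on the high-score threshold (stage 3).

    Returns ``(new_track_indices, reserved_indices)``: confident
    detections (score >= ``score_high``) found new tracks, the rest go
    to the save-and-iterate pool. With ``use_third_match`` disabled the
    pool is bypassed and low-score leftovers are discarded by the caller.
    """
    if det_indices is None:
        det_indices = list(range(len(detections)))
    new_ids = [det_indices[i] for i, d in enumerate(detections) if d.score >= config.score_high]
    reserved = [det_indices[i] for i, d in enumerate(detections) if d.score < config.score_high]
    return sorted(new_ids), sorted(reserved)


class Tracker:
    """Online tracker state machine running the cascade frame by frame.

    Feed frames in strictly increasing order through :meth:`step`, then
    collect :meth:`trajectories`. All tracks ever created (active, lost,
    terminated) are reported.
    """

    def __init__(self, config: Optional[TrackerConfig] = None):
        self.config = config or TrackerConfig()
        self.tracks: dict[int, Track] = {}
        self.finished: dict[int, Track] = {}
        self.reserved_pool: list[ReservedDetection] = []
        self._next_id = 1
        self._last_frame: Optional[int] = None

    # -- helpers ---------------------------------------------------------
    def _new_track(self, det: Detection, frame: int) -> Track:
        track = Track(track_id=self._next_id, class_label=det.class_label)
        self._next_id += 1
        track.add_observation(det, self.config.embedding_momentum)
        track.velocity = (0.0, 0.0) if det.displacement is None else det.displacement
        self.tracks[track.track_id] = track
        return track

    def _active(self) -> list[Track]:
        return [t for t in self.tracks.values() if t.status == "active"]

    def _lost(self, frame: int) -> list[Track]:
        return [
            t
            for t in self.tracks.values()
            if t.status == "lost" and t.lost_age(frame) <= self.config.max_lost_age
        ]

    # -- main entry ------------------------------------------------------
    def step(self, frame: int, detections: Sequence[Detection]) -> AssociationResult:
        """Associate one frame of detections and update the tracker state."""
        cfg = self.config
        if self._last_frame is not None and frame <= self._last_frame:
            raise SequenceOrderError(
                f"frame {frame} not after previous frame {self._last_frame}"
            )
        for det in detections:
            if det.frame != frame:
                raise SequenceOrderError(
                    f"detection frame {det.frame} does not match step frame {frame}"
                )
        result = AssociationResult()

        admitted = [i for i, d in enumerate(detections) if d.score >= cfg.score_low]
        result.discarded = [
            i for i, d in enumerate(detections) if d.score < cfg.score_low
        ]

        # Stage 1: active tracks plus the save-and-iterate pool, by position.
        active = sorted(self._active(), key=lambda t: t.track_id)
        candidates: list = list(active) + list(self.reserved_pool)
        stage1 = first_match(
            candidates,
            [detections[i] for i in admitted],
            cfg,
            det_indices=admitted,
        )
        consumed_pool: set[int] = set()
        for cand_pos, det_idx in stage1.matches:
            det = detections[det_idx]
            if cand_pos < len(active):
                track = active[cand_pos]
                track.add_observation(det, cfg.embedding_momentum)
                result.matches.append((track.track_id, det_idx))
            else:
                # A pool box confirmed by a nearby later detection: the pair
                # becomes a new track seeded at the reserved observation.
                pool_pos = cand_pos - len(active)
                res = self.reserved_pool[pool_pos]
                consumed_pool.add(pool_pos)
                track = self._new_track(res.detection, res.frame_reserved)
                track.add_observation(det, cfg.embedding_momentum)
                result.matches.append((track.track_id, det_idx))
        leftover_dets = list(stage1.unmatched_detections)

        # Stage 2: appearance revival of lost tracks (and stage-1 leftovers).
        stage1_unmatched_tracks = [
            active[p] for p in stage1.unmatched_tracks if p < len(active)
        ]
        if cfg.use_second_match and leftover_dets:
            by_id = {t.track_id: t for t in stage1_unmatched_tracks}
            by_id.update({t.track_id: t for t in self._lost(frame)})
            candidates2 = [by_id[tid] for tid in sorted(by_id)]
            stage2 = second_match(
                candidates2,
                [detections[i] for i in leftover_dets],
                frame,
                cfg,
                det_indices=leftover_dets,
            )
            for t_pos, det_idx in stage2.matches:
                track = candidates2[t_pos]
                track.add_observation(detections[det_idx], cfg.embedding_momentum)
                result.matches.append((track.track_id, det_idx))
            leftover_dets = list(stage2.unmatched_detections)

        # Stage 3: spawn confident newcomers, reserve the rest.
        new_idx, low_idx = third_match(
            [detections[i] for i in leftover_dets], cfg, det_indices=leftover_dets
        )
        for det_idx in new_idx:
            track = self._new_track(detections[det_idx], frame)
            result.new_track_ids.append(track.track_id)
            result.new_track_detections[track.track_id] = det_idx
        if cfg.use_third_match:
            for det_idx in low_idx:
                self.reserved_pool.append(
                    ReservedDetection(detections[det_idx], frame_reserved=frame)
                )
                result.reserved.append(det_idx)
        else:
            result.discarded.extend(low_idx)

        # Lifecycle upkeep.
        matched_ids = {tid for tid, _ in result.matches}
        for track in list(self.tracks.values()):
            if track.track_id in matched_ids or track.track_id in set(
                result.new_track_ids
            ):
                continue
            track.status = "lost"
            if track.lost_age(frame) > cfg.max_lost_age:
                self.finished[track.track_id] = self.tracks.pop(track.track_id)
        self.reserved_pool = [
            r
            for p, r in enumerate(self.reserved_pool)
            if p not in consumed_pool and r.age(frame) < self.config.reserve_frames
        ]

        result.unmatched_tracks = sorted(
            t.track_id for t in self.tracks.values() if t.status == "lost"
        )
        result.matches.sort()
        result.new_track_ids.sort()
        result.reserved.sort()
        result.discarded.sort()
        assert result.n_accounted() == len(detections), "partition invariant violated"
        self._last_frame = frame
        return result

    def trajectories(self) -> list[Trajectory]:
        """Finalized trajectories of every track ever created."""
        all_tracks = {**self.finished, **self.tracks}
        return [all_tracks[tid].to_trajectory() for tid in sorted(all_tracks)]


def track_sequence(
    detection_stream: Iterable[Detection] | Mapping[int, Sequence[Detection]],
    config: Optional[TrackerConfig] = None,
) -> list[Trajectory]:
    """Run the cascade over a whole sequence and return its trajectories.

    ``detection_stream`` is either a flat iterable of detections (grouped
    by their ``frame`` attribute) or a mapping frame -> detections.
    Deterministic: identical input and config give identical output.
    """
    if isinstance(detection_stream, Mapping):
        by_frame = {f: list(dets) for f, dets in detection_stream.items()}
    else:
        by_frame = {}
        for det in detection_stream:
            by_frame.setdefault(det.frame, []).append(det)
    tracker = Tracker(config)
    for frame in sorted(by_frame):
        tracker.step(frame, by_frame[frame])
    return tracker.trajectories()
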