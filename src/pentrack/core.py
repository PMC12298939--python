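"""Domain types and conventions shared by every module.

Coordinate convention: image pixels, origin at the top-left corner, x
rightward, y downward. Frame indices are 0-based internally (the
MOTChallenge text dialect is 1-based on disk; the io module converts).
All angles are degrees.

Two classes of objects live in a pen scene: one lactating sow and her
piglets. Detections carry an optional unit-norm appearance embedding
(default 64-dim) produced by an external re-identification head, and an
optional inter-frame displacement produced by an external motion head;
the tracker consumes both but learns neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidEmbeddingError

SOW = "sow"
PIGLET = "piglet"

DEFAULT_EMBEDDING_DIM = 64

_UNIT_NORM_TOL = 1e-6


def normalize_embedding(v: Sequence[float] | np.ndarray) -> np.ndarray:
    """Scale ``v`` to unit Euclidean norm, preserving direction.

    Raises
    ------
    InvalidEmbeddingError
        If ``v`` is empty or has zero norm.
    """
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size == 0:
        raise InvalidEmbeddingError("embedding is empty")
    norm = float(np.linalg.norm(arr))
    if norm == 0.0 or not np.isfinite(norm):
        raise InvalidEmbeddingError("embedding has zero or non-finite norm")
    return arr / norm


def smooth_embedding(
    track_emb: np.ndarray, det_emb: np.ndarray, momentum: float
) -> np.ndarray:
    """Exponentially smooth a track's appearance embedding with a new observation.

    Returns ``normalize(momentum * track_emb + (1 - momentum) * det_emb)``.
    If the blend cancels exactly (opposite vectors at momentum 0.5) the
    detection embedding is returned unchanged.
    """
    if not 0.0 <= momentum <= 1.0:
        raise ValueError(f"momentum must be in [0, 1], got {momentum}")
    blend = momentum * np.asarray(track_emb, float) + (1.0 - momentum) * np.asarray(
        det_emb, float
    )
    try:
        return normalize_embedding(blend)
    except InvalidEmbeddingError:
        return np.asarray(det_emb, dtype=float).copy()


@dataclass
class Detection:
    """One frame-level observation from an external detector.

    ``center`` is the box center in pixels; ``size`` is (width, height).
    ``displacement`` is the detector's estimate of the object's motion
    from the previous frame, in pixels/frame.
    """

    frame: int
    center: tuple[float, float]
    size: tuple[float, float]
    score: float
    class_label: str = PIGLET
    embedding: Optional[np.ndarray] = None
    displacement: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        w, h = self.size
        if w <= 0 or h <= 0:
            raise ValueError(f"box size must be positive, got {self.size}")
        if self.class_label not in (SOW, PIGLET):
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.embedding is not None:
            emb = np.asarray(self.embedding, dtype=float).ravel()
            norm = float(np.linalg.norm(emb))
            if abs(norm - 1.0) > _UNIT_NORM_TOL:
                raise InvalidEmbeddingError(
                    f"embedding norm {norm:.8f} deviates from 1 by more than "
                    f"{_UNIT_NORM_TOL}"
                )
            self.embedding = emb


@dataclass
class TrackerConfig:
    """Tunable parameters of the association cascade.

    score_high / score_low
        Detection-confidence thresholds: detections below ``score_low``
        are discarded before any matching; leftovers at or above
        ``score_high`` may found new tracks in the third matching stage.
    reserve_frames
        How many frames an unclaimed low-score leftover stays in the
        save-and-iterate pool.
    gate_factor
        First-stage distance gate as a multiple of sqrt(w*h) of the
        detection box.
    embedding_momentum
        Exponential-smoothing weight on the track side when folding a
        matched detection's embedding into the track embedding.
    time_decay / time_decay_rate
        Shape of the time weight g(alpha) in the appearance-similarity
        score for a track unmatched for alpha frames: ``inverse`` gives
        1/alpha, ``exponential`` gives exp(-rate * alpha).
    similarity_floor
        Second-stage assignments with similarity below this are dropped.
    max_lost_age
        Frames a lost track remains revivable before termination.
    use_second_match / use_third_match
        Ablation switches for the cascade stages (both on by default).
    """

    score_high: float = 0.6
    score_low: float = 0.2
    reserve_frames: int = 3
    gate_factor: float = 1.0
    embedding_momentum: float = 0.9
    time_decay: str = "inverse"
    time_decay_rate: float = 0.5
    similarity_floor: float = 0.0
    max_lost_age: int = 30
    use_second_match: bool = True
    use_third_match: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_low < self.score_high <= 1.0:
            raise ValueError(
                "thresholds must satisfy 0 <= score_low < score_high <= 1, got "
                f"score_low={self.score_low}, score_high={self.score_high}"
            )
        if self.reserve_frames < 1:
            raise ValueError("reserve_frames must be >= 1")
        if not 0.0 <= self.embedding_momentum <= 1.0:
            raise ValueError("embedding_momentum must be in [0, 1]")
        if self.time_decay not in ("inverse", "exponential"):
            raise ValueError(f"unknown time_decay {self.time_decay!r}")
        if self.max_lost_age < 0:
            raise ValueError("max_lost_age must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "TrackerConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown tracker config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class Track:
    """A persistent identity maintained by the tracker.

    A track is ``active`` while it matched in the current frame and
    ``lost`` otherwise; lost tracks older than ``max_lost_age`` frames
    are terminated. ``last_score`` is the confidence of the most recent
    matched detection (the beta weight of the appearance-similarity
    score); ``last_matched_frame`` supplies the alpha = t - n_i lost
    duration.
    """

    track_id: int
    class_label: str = PIGLET
    status: str = "active"
    last_matched_frame: int = -1
    last_score: float = 0.0
    embedding: Optional[np.ndarray] = None
    velocity: tuple[float, float] = (0.0, 0.0)
    displacement: Optional[tuple[float, float]] = None
    frames: list[int] = field(default_factory=list)
    centers: list[tuple[float, float]] = field(default_factory=list)
    boxes: list[tuple[float, float]] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)

    def add_observation(self, det: Detection, momentum: float = 0.9) -> None:
        """Record a matched detection and refresh the track state."""
        if self.frames and det.frame <= self.frames[-1]:
            raise ValueError(
                f"track {self.track_id}: frame {det.frame} not after {self.frames[-1]}"
            )
        if self.frames:
            prev_c, prev_f = self.centers[-1], self.frames[-1]
            span = det.frame - prev_f
            self.velocity = (
                (det.center[0] - prev_c[0]) / span,
                (det.center[1] - prev_c[1]) / span,
            )
        self.displacement = det.displacement
        if det.displacement is not None:
            self.velocity = det.displacement
        self.frames.append(det.frame)
        self.centers.append(det.center)
        self.boxes.append(det.size)
        self.scores.append(det.score)
        if det.embedding is not None:
            if self.embedding is None:
                self.embedding = det.embedding.copy()
            else:
                self.embedding = smooth_embedding(
                    self.embedding, det.embedding, momentum
                )
        self.last_matched_frame = det.frame
        self.last_score = det.score
        self.status = "active"

    def lost_age(self, current_frame: int) -> int:
        return current_frame - self.last_matched_frame

    def to_trajectory(self) -> "Trajectory":
        return Trajectory(
            track_id=self.track_id,
            frames=np.asarray(self.frames, dtype=int),
            centers=np.asarray(self.centers, dtype=float).reshape(-1, 2),
            boxes=np.asarray(self.boxes, dtype=float).reshape(-1, 2),
            scores=np.asarray(self.scores, dtype=float),
            class_label=self.class_label,
        )


@dataclass
class Trajectory:
    """Finalized per-identity time series consumed by metrics and behavior analysis."""

    track_id: int
    frames: np.ndarray
    centers: np.ndarray
    boxes: np.ndarray
    scores: np.ndarray
    class_label: str = PIGLET
    displacements: Optional[np.ndarray] = None
    """Detector-supplied motion, aligned with ``frames``; row 0 is undefined
    and ignored (there is no previous frame). When absent, finite
    differences of ``centers`` are used."""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 2)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.frames)
        if not (len(self.centers) == len(self.boxes) == len(self.scores) == n):
            raise ValueError("trajectory field lengths disagree")
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("trajectory frames must be strictly increasing")
        if self.displacements is not None:
            self.displacements = np.asarray(self.displacements, float).reshape(-1, 2)
            if len(self.displacements) != n:
                raise ValueError("displacements must align with frames")

    def __len__(self) -> int:
        return len(self.frames)

    def displacement_series(self) -> np.ndarray:
        """Per-frame motion aligned with ``frames[1:]`` (length n-1).

        Detector-supplied displacements take precedence; otherwise finite
        differences of the centers (per frame of gap, so units stay
        pixels/frame across dropped frames).
        """
        if len(self.frames) < 2:
            return np.empty((0, 2))
        if self.displacements is not None:
            return self.displacements[1:]
        gaps = np.diff(self.frames).astype(float)[:, None]
        return np.diff(self.centers, axis=0) / gaps
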