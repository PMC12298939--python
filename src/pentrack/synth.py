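"""Synthetic farrowing-pen scene generator.

Emulates the observable structure of overhead pen video at the
trajectory/detection level (no rendering): one sow and a litter of
piglets in a 1920x1080 arena, 30-second clips at 10 fps (300 frames).
A scripted posture-change event makes the sow's box aspect change; from
the event onward each piglet plays one of three roles: *aggregating*
(moves radially toward the sow, with heading jitter, for the rest of
the clip), *dispersing* (radially away), or *other* (rests with tiny
jitter — sleeping or indifferent piglets). Before the event all piglets
rest.

The detection stream is derived from the ground truth by a declared
noise model only: Gaussian center/box jitter, per-identity fixed unit
embeddings plus spherical noise, uniform false positives, Bernoulli
misses, and scripted occlusion episodes in which the detection score
ramps linearly from 0.55 down to a floor (the characteristic score
collapse of a piglet sliding under the sow or litter-mates) with extra
center jitter. Frames whose ramped score falls below the tracker's
admission threshold become effective detection gaps. With all noise
zero and no occlusions the stream equals the ground truth with score
1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import Detection, PIGLET, SOW, Trajectory, normalize_embedding

__all__ = [
    "NoiseConfig",
    "OcclusionEvent",
    "SceneConfig",
    "SceneOutput",
    "generate_behavior_dataset",
    "generate_scene",
    "largest_remainder_counts",
]

OCCLUSION_RAMP_START = 0.55  # score at the onset of an occlusion episode

_EVENT_LABEL = {"downward": "aggregation", "upward": "dispersion", "rolling": "other"}
_LABEL_EVENT = {v: k for k, v in _EVENT_LABEL.items()}


@dataclass
class NoiseConfig:
    """Detector-noise model (all sigmas in pixels except embeddings)."""

    center_sigma: float = 2.0
    box_sigma: float = 1.0
    embedding_sigma: float = 0.05
    fp_rate: float = 0.02  # per-frame probability of one spurious detection
    miss_rate: float = 0.01  # per-detection probability of a dropout

    def __post_init__(self) -> None:
        for name in ("center_sigma", "box_sigma", "embedding_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fp_rate", "miss_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class OcclusionEvent:
    """Scripted occlusion: scores ramp from 0.55 down to ``score_floor``
    across ``duration`` frames, then recover."""

    piglet: int  # ground-truth piglet id
    start_frame: int
    duration: int
    score_floor: float = 0.25

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("occlusion duration must be >= 1")
        if not 0.0 <= self.score_floor <= 1.0:
            raise ValueError("score_floor must lie in [0, 1]")

    def score_at(self, frame: int) -> Optional[float]:
        k = frame - self.start_frame
        if not 0 <= k < self.duration:
            return None
        frac = 1.0 - (k + 1) / self.duration
        return self.score_floor + (OCCLUSION_RAMP_START - self.score_floor) * frac


@dataclass
class SceneConfig:
    """Generative parameters for one pen scene / posture-change episode."""

    n_piglets: int = 12
    n_frames: int = 300  # 30 s at 10 fps
    arena: tuple[int, int] = (1920, 1080)
    sow_event: str = "none"  # upward | downward | rolling | none
    event_frame: Optional[int] = None  # default: n_frames // 10
    response_mix: tuple[float, float, float] = (0.0, 0.0, 1.0)
    occlusion_script: tuple[OcclusionEvent, ...] = ()
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    embedding_dim: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sow_event not in ("upward", "downward", "rolling", "none"):
            raise ValueError(f"unknown sow_event {self.sow_event!r}")
        if abs(sum(self.response_mix) - 1.0) > 1e-9:
            raise ValueError("response_mix fractions must sum to 1")
        if self.event_frame is None:
            self.event_frame = self.n_frames // 10
        if not 0 <= self.event_frame < self.n_frames:
            raise ValueError("event_frame must lie inside the clip")
        self.occlusion_script = tuple(
            o if isinstance(o, OcclusionEvent) else OcclusionEvent(*o)
            for o in self.occlusion_script
        )


@dataclass
class SceneOutput:
    """Ground truth plus the derived detection stream for one scene."""

    gt_trajectories: list[Trajectory]
    sow_id: int
    detections: list[Detection]  # flat, sorted by frame then row order
    episode_label: str
    roles: dict[int, str]  # piglet id -> aggregating | dispersing | other
    config: SceneConfig


def largest_remainder_counts(fractions: Sequence[float], n: int) -> list[int]:
    """Apportion ``n`` into integer counts proportional to ``fractions``."""
    exact = [f * n for f in fractions]
    counts = [int(math.floor(e)) for e in exact]
    short = n - sum(counts)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(exact[i] - counts[i]), i)
    )
    for i in order[:short]:
        counts[i] += 1
    return counts


def _sow_path(config: SceneConfig, rng: np.random.Generator):
    w, h = config.arena
    center = np.array([w / 2.0, h / 2.0])
    start = center + rng.normal(0.0, 20.0, size=2)
    steps = rng.normal(0.0, 0.5, size=(config.n_frames, 2))
    steps[0] = 0.0
    path = start + np.cumsum(steps, axis=0)
    boxes = np.empty((config.n_frames, 2))
    pre, post = (300.0, 130.0), (300.0, 130.0)
    if config.sow_event == "upward":
        post = (280.0, 180.0)
    elif config.sow_event == "downward":
        post = (310.0, 110.0)
    elif config.sow_event == "rolling":
        post = (260.0, 200.0)
    boxes[: config.event_frame] = pre
    boxes[config.event_frame :] = post
    return path, boxes


def _piglet_paths(
    config: SceneConfig,
    sow_path: np.ndarray,
    roles: list[str],
    rng: np.random.Generator,
):
    """Simulate each piglet's center path given its scripted role."""
    n, T = config.n_piglets, config.n_frames
    w, h = config.arena
    body_r = 300.0  # nominal sow body length, zone radius scale
    paths = np.empty((n, T, 2))
    rest_sigma = 0.3
    for i in range(n):
        angle = 2 * math.pi * i / max(n, 1) + rng.uniform(-0.15, 0.15)
        # Role-consistent staging: piglets that will gather start in the
        # outer zone (they have somewhere to go), piglets that will flee
        # start near the sow; indifferent piglets rest anywhere.
        if roles[i] == "aggregating":
            radius = rng.uniform(0.70, 0.95) * body_r
        elif roles[i] == "dispersing":
            radius = rng.uniform(0.45, 0.75) * body_r
        else:
            radius = rng.uniform(0.45, 0.95) * body_r
        pos = sow_path[0] + radius * np.array([math.cos(angle), math.sin(angle)])
        ev = config.event_frame
        remaining = max(T - ev, 1)
        d0 = float(np.linalg.norm(pos - sow_path[min(ev, T - 1)]))
        if roles[i] == "aggregating":
            # approach paced to arrive at the udder around clip end, so the
            # directed phase spans the episode
            speed = min(4.0, (d0 - 30.0) / remaining)
        elif roles[i] == "dispersing":
            speed = rng.uniform(0.8, 1.5)
        else:
            speed = 0.0
        for t in range(T):
            if t > 0:
                pos = paths[i, t - 1].copy()
                if t < ev or roles[i] == "other" or config.sow_event == "none":
                    pos = pos + rng.normal(0.0, rest_sigma, size=2)
                else:
                    to_sow = sow_path[t] - pos
                    dist = float(np.linalg.norm(to_sow))
                    if dist < 1e-9:
                        direction = np.array([1.0, 0.0])
                    else:
                        direction = to_sow / dist
                    if roles[i] == "dispersing":
                        direction = -direction
                    theta = math.radians(rng.normal(0.0, 15.0))
                    c, s = math.cos(theta), math.sin(theta)
                    direction = np.array(
                        [
                            c * direction[0] - s * direction[1],
                            s * direction[0] + c * direction[1],
                        ]
                    )
                    step = speed
                    if roles[i] == "aggregating" and dist - speed < 40.0:
                        step = max(0.0, dist - 40.0)  # settled at the udder
                    pos = pos + step * direction + rng.normal(0.0, 0.1, size=2)
                pos[0] = min(max(pos[0], 50.0), w - 50.0)
                pos[1] = min(max(pos[1], 50.0), h - 50.0)
            paths[i, t] = pos
    return paths


def generate_scene(config: Optional[SceneConfig] = None) -> SceneOutput:
    """Generate one scene: ground-truth trajectories and a detection stream.

    Fully deterministic given ``config.seed``.
    """
    config = config or SceneConfig()
    rng = np.random.default_rng(config.seed)
    T = config.n_frames
    noise = config.noise

    counts = largest_remainder_counts(config.response_mix, config.n_piglets)
    roles_flat = (
        ["aggregating"] * counts[0]
        + ["dispersing"] * counts[1]
        + ["other"] * counts[2]
    )
    perm = rng.permutation(config.n_piglets)
    roles = [roles_flat[int(k)] for k in perm]
    if config.sow_event == "none":
        episode_label = "other"
    elif counts[0] > config.n_piglets / 2:
        episode_label = "aggregation"
    elif counts[1] > config.n_piglets / 2:
        episode_label = "dispersion"
    else:
        episode_label = "other"

    sow_centers, sow_boxes = _sow_path(config, rng)
    piglet_paths = _piglet_paths(config, sow_centers, roles, rng)
    piglet_boxes = np.empty((config.n_piglets, 2))
    for i in range(config.n_piglets):
        piglet_boxes[i] = (80.0 + rng.uniform(-8, 8), 60.0 + rng.uniform(-6, 6))

    sow_id = 1
    frames = np.arange(T)
    gt = [
        Trajectory(
            track_id=sow_id,
            frames=frames,
            centers=sow_centers,
            boxes=sow_boxes,
            scores=np.ones(T),
            class_label=SOW,
        )
    ]
    piglet_ids = list(range(2, 2 + config.n_piglets))
    for i, pid in enumerate(piglet_ids):
        gt.append(
            Trajectory(
                track_id=pid,
                frames=frames,
                centers=piglet_paths[i],
                boxes=np.tile(piglet_boxes[i], (T, 1)),
                scores=np.ones(T),
                class_label=PIGLET,
            )
        )

    # fixed per-identity appearance embeddings
    identities = {traj.track_id: traj for traj in gt}
    base_emb = {
        tid: normalize_embedding(rng.normal(size=config.embedding_dim))
        for tid in identities
    }
    occl_by_target = {}
    for ev in config.occlusion_script:
        occl_by_target.setdefault(ev.piglet, []).append(ev)

    detections: list[Detection] = []
    w, h = config.arena
    for t in range(T):
        for tid, traj in identities.items():
            if noise.miss_rate > 0 and rng.random() < noise.miss_rate:
                continue
            score = 1.0
            extra_jitter = 0.0
            for ev in occl_by_target.get(tid, ()):
                s = ev.score_at(t)
                if s is not None:
                    score = min(score, s)
                    extra_jitter = 3.0
            center = traj.centers[t] + rng.normal(
                0.0, noise.center_sigma + extra_jitter, size=2
            )
            box = np.maximum(
                traj.boxes[t] + rng.normal(0.0, noise.box_sigma, size=2), 4.0
            )
            emb = base_emb[tid]
            if noise.embedding_sigma > 0:
                emb = normalize_embedding(
                    emb + rng.normal(0.0, noise.embedding_sigma, size=emb.shape)
                )
            disp = None
            if t > 0:
                d = traj.centers[t] - traj.centers[t - 1]
                disp = (float(d[0]), float(d[1]))
            detections.append(
                Detection(
                    frame=t,
                    center=(float(center[0]), float(center[1])),
                    size=(float(box[0]), float(box[1])),
                    score=float(score),
                    class_label=traj.class_label,
                    embedding=emb,
                    displacement=disp,
                )
            )
        if noise.fp_rate > 0 and rng.random() < noise.fp_rate:
            detections.append(
                Detection(
                    frame=t,
                    center=(float(rng.uniform(60, w - 60)), float(rng.uniform(60, h - 60))),
                    size=(80.0, 60.0),
                    score=float(rng.uniform(0.2, 0.9)),
                    class_label=PIGLET,
                    embedding=normalize_embedding(
                        rng.normal(size=config.embedding_dim)
                    ),
                    displacement=None,
                )
            )
    return SceneOutput(
        gt_trajectories=gt,
        sow_id=sow_id,
        detections=detections,
        episode_label=episode_label,
        roles={pid: roles[i] for i, pid in enumerate(piglet_ids)},
        config=config,
    )


def occlusion_benchmark_scene(seed: int, n_frames: int = 200) -> SceneOutput:
    """A quiescent pen scene with four scripted occlusion episodes.

    Each episode ramps a piglet's score over 6 frames down to 0.01; the
    last 3 ramp frames fall below the 0.2 admission threshold, giving a
    3-frame detection gap. Embedding noise is 0.05, center jitter 1 px.
    Used by the occlusion-recovery and stage-ablation checks.
    """
    occ = tuple(
        OcclusionEvent(piglet=2 + 2 * i, start_frame=50 + 30 * i, duration=6,
                       score_floor=0.01)
        for i in range(4)
    )
    return generate_scene(
        SceneConfig(
            n_piglets=12,
            n_frames=n_frames,
            sow_event="none",
            occlusion_script=occ,
            noise=NoiseConfig(
                center_sigma=1.0, box_sigma=0.5, embedding_sigma=0.05,
                fp_rate=0.0, miss_rate=0.0,
            ),
            seed=seed,
        )
    )


_LABEL_MIX_DEFAULT = (0.41, 0.36, 0.23)  # aggregation, dispersion, other
_LABEL_RESPONSE_MIX = {
    "aggregation": (0.75, 0.0, 0.25),
    "dispersion": (0.0, 0.75, 0.25),
    "other": (0.25, 0.25, 0.5),
}


def generate_behavior_dataset(
    n_episodes: int = 100,
    label_mix: Sequence[float] = _LABEL_MIX_DEFAULT,
    config_template: Optional[SceneConfig] = None,
    seed: int = 0,
) -> list[SceneOutput]:
    """Generate a dataset of scripted posture-change episodes.

    Labels follow ``label_mix`` (aggregation, dispersion, other) via
    largest-remainder apportionment; each episode gets an independent
    seed derived from ``seed``. Aggregation episodes pair with a
    downward sow event, dispersion with upward, other with rolling.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    template = config_template or SceneConfig()
    counts = largest_remainder_counts(label_mix, n_episodes)
    labels = (
        ["aggregation"] * counts[0]
        + ["dispersion"] * counts[1]
        + ["other"] * counts[2]
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_episodes)
    episodes = []
    child_seeds = rng.integers(0, 2**31 - 1, size=n_episodes)
    for k in range(n_episodes):
        label = labels[int(order[k])]
        cfg = replace(
            template,
            sow_event=_LABEL_EVENT[label],
            response_mix=_LABEL_RESPONSE_MIX[label],
            seed=int(child_seeds[k]),
        )
        episodes.append(generate_scene(cfg))
    return episodes
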