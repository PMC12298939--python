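import numpy as np
import pytest
from hypothesis import settings

from pentrack.core import Trajectory

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_trajectory(track_id, frame_boxes, class_label="piglet"):
    """Build a Trajectory from {frame: (cx, cy, w, h)}."""
    frames = sorted(frame_boxes)
    boxes = [frame_boxes[f] for f in frames]
    return Trajectory(
        track_id=track_id,
        frames=np.array(frames),
        centers=np.array([[b[0], b[1]] for b in boxes], dtype=float),
        boxes=np.array([[b[2], b[3]] for b in boxes], dtype=float),
        scores=np.ones(len(frames)),
        class_label=class_label,
    )


def to_frame_dicts(trajectories):
    """Reindex trajectories as {frame: {id: (cx, cy, w, h)}} for the reference."""
    out = {}
    for traj in trajectories:
        for k, frame in enumerate(traj.frames):
            out.setdefault(int(frame), {})[traj.track_id] = (
                float(traj.centers[k, 0]),
                float(traj.centers[k, 1]),
                float(traj.boxes[k, 0]),
                float(traj.boxes[k, 1]),
            )
    return out


def random_small_scene(rng, n_ids=None, n_frames=None):
    """Random gt + hyp trajectory pair for metric cross-checks.

    Hypotheses are jittered copies of the ground truth with random
    dropouts, identity splits and spurious boxes, so all metric branches
    (FP, FN, switches, partial coverage) are exercised.
    """
    n_ids = n_ids or int(rng.integers(1, 6))
    n_frames = n_frames or int(rng.integers(5, 31))
    gt, hyp = [], []
    hyp_id = 100
    for gid in range(1, n_ids + 1):
        start = int(rng.integers(0, max(1, n_frames - 3)))
        stop = int(rng.integers(start + 2, n_frames + 1))
        frames = range(start, stop)
        pos = rng.uniform(100, 900, size=2)
        steps = rng.normal(0, 5, size=(len(frames), 2))
        centers = pos + np.cumsum(steps, axis=0)
        size = rng.uniform(30, 60, size=2)
        gt.append(
            {f: (centers[k, 0], centers[k, 1], size[0], size[1])
             for k, f in enumerate(frames)}
        )
        # hypothesis: same path, jittered, possibly split into two ids
        split = int(rng.integers(start, stop)) if rng.random() < 0.4 else stop
        segs = [(start, split), (split, stop)]
        for lo, hi in segs:
            if hi <= lo:
                continue
            hyp_id += 1
            seg = {}
            for k, f in enumerate(frames):
                if not lo <= f < hi or rng.random() < 0.1:
                    continue
                jitter = rng.normal(0, 3, size=2)
                seg[f] = (
                    centers[k, 0] + jitter[0],
                    centers[k, 1] + jitter[1],
                    size[0] * rng.uniform(0.9, 1.1),
                    size[1] * rng.uniform(0.9, 1.1),
                )
            if seg:
                hyp.append(seg)
    # spurious short track
    if rng.random() < 0.5:
        f0 = int(rng.integers(0, n_frames))
        hyp.append({f0: (rng.uniform(0, 1000), rng.uniform(0, 1000), 40.0, 30.0)})
    gt_trajs = [make_trajectory(i + 1, d) for i, d in enumerate(gt)]
    hyp_trajs = [make_trajectory(101 + i, d) for i, d in enumerate(hyp)]
    return gt_trajs, hyp_trajs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
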