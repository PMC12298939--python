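"""Readers and writers for the MOTChallenge text dialect, embedding
sidecars, and YAML configuration files.

File conventions:

* MOT lines are ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,class,
  visibility``. Frames are 1-based on disk and 0-based in memory; boxes
  are top-left/size on disk and center/size in memory. ``id`` is -1 for
  raw detections. Class codes: 1 = piglet, 2 = sow.
* The embedding sidecar is a comma-separated table, one row per
  detection, ``frame,row,v0,...,v{D-1}`` keyed by the 1-based frame and
  the 0-based detection row index within that frame. Vectors are
  normalized on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .behavior import BehaviorConfig
from .core import Detection, PIGLET, SOW, Trajectory, TrackerConfig, normalize_embedding
from .errors import InvalidEmbeddingError, MotFormatError
from .synth import NoiseConfig, SceneConfig

logger = logging.getLogger("pentrack")

CLASS_CODES = {PIGLET: 1, SOW: 2}
CLASS_LABELS = {v: k for k, v in CLASS_CODES.items()}

_MOT_COLUMNS = [
    "frame", "id", "bb_left", "bb_top", "bb_width", "bb_height",
    "conf", "class", "visibility",
]


def _fmt(x: float) -> str:
    """Canonical numeric formatting: integers bare, floats trimmed."""
    if float(x) == int(x):
        return str(int(x))
    return f"{x:.10g}"


def read_mot(path) -> pd.DataFrame:
    """Read a MOT text file into a DataFrame (frames converted to 0-based,
    boxes to center representation), sorted by (frame, id)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise MotFormatError(
                    f"{path}:{lineno}: expected >=7 comma-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts[:9]]
            except ValueError as exc:
                raise MotFormatError(f"{path}:{lineno}: {exc}") from exc
            while len(vals) < 9:
                vals.append(-1.0)
            rows.append(vals)
    if not rows:
        logger.warning("%s: empty MOT file", path)
        return pd.DataFrame(columns=_MOT_COLUMNS)
    df = pd.DataFrame(rows, columns=_MOT_COLUMNS)
    if (df["bb_width"] <= 0).any() or (df["bb_height"] <= 0).any():
        raise MotFormatError(f"{path}: nonpositive box size")
    df["frame"] = df["frame"].astype(int) - 1
    df["id"] = df["id"].astype(int)
    df["class"] = df["class"].astype(int)
    df["cx"] = df["bb_left"] + df["bb_width"] / 2.0
    df["cy"] = df["bb_top"] + df["bb_height"] / 2.0
    return df.sort_values(["frame", "id"], kind="stable").reset_index(drop=True)


def write_mot(path, df_or_trajectories, default_conf: float = 1.0) -> None:
    """Write trajectories (or a read_mot-style DataFrame) as MOT text."""
    if isinstance(df_or_trajectories, pd.DataFrame):
        df = df_or_trajectories
        cols = _MOT_COLUMNS
        lines = [
            ",".join(
                [_fmt(row[0] + 1)] + [_fmt(v) for v in row[1:]]
            )
            for row in df[cols].itertuples(index=False, name=None)
        ]
    else:
        records = []
        for traj in df_or_trajectories:
            code = CLASS_CODES.get(traj.class_label, 1)
            for k, frame in enumerate(traj.frames):
                cx, cy = traj.centers[k]
                w, h = traj.boxes[k]
                records.append(
                    (
                        int(frame) + 1,
                        traj.track_id,
                        cx - w / 2.0,
                        cy - h / 2.0,
                        w,
                        h,
                        float(traj.scores[k]) if traj.scores is not None else default_conf,
                        code,
                        -1,
                    )
                )
        records.sort(key=lambda r: (r[0], r[1]))
        lines = [",".join(_fmt(v) for v in rec) for rec in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def detections_to_mot_df(detections: Sequence[Detection]) -> pd.DataFrame:
    """Raw detections (id = -1) as a read_mot-style DataFrame."""
    rows = []
    for det in sorted(detections, key=lambda d: d.frame):
        cx, cy = det.center
        w, h = det.size
        rows.append(
            {
                "frame": det.frame,
                "id": -1,
                "bb_left": cx - w / 2.0,
                "bb_top": cy - h / 2.0,
                "bb_width": w,
                "bb_height": h,
                "conf": det.score,
                "class": CLASS_CODES.get(det.class_label, 1),
                "visibility": -1,
                "cx": cx,
                "cy": cy,
            }
        )
    return pd.DataFrame(rows)


def detections_from_mot(
    df: pd.DataFrame,
    embeddings: Optional[dict[tuple[int, int], np.ndarray]] = None,
) -> list[Detection]:
    """Turn a read_mot DataFrame of raw detections into Detection objects.

    ``embeddings`` is keyed by (0-based frame, row index within frame).
    Missing rows leave the embedding absent (appearance matching is then
    skipped for that detection); warned once.
    """
    detections = []
    warned = False
    for frame, group in df.groupby("frame", sort=True):
        for row, (_, rec) in enumerate(group.iterrows()):
            emb = None
            if embeddings is not None:
                emb = embeddings.get((int(frame), row))
                if emb is None and not warned:
                    logger.warning(
                        "no embedding for frame %d row %d (warned once)", frame, row
                    )
                    warned = True
            detections.append(
                Detection(
                    frame=int(frame),
                    center=(float(rec["cx"]), float(rec["cy"])),
                    size=(float(rec["bb_width"]), float(rec["bb_height"])),
                    score=float(np.clip(rec["conf"], 0.0, 1.0)),
                    class_label=CLASS_LABELS.get(int(rec["class"]), PIGLET),
                    embedding=emb,
                )
            )
    return detections


def trajectories_from_mot(df: pd.DataFrame) -> list[Trajectory]:
    """Group a read_mot DataFrame by identity into Trajectory objects."""
    trajectories = []
    for tid, group in df.groupby("id", sort=True):
        if tid < 0:
            continue
        group = group.sort_values("frame", kind="stable")
        trajectories.append(
            Trajectory(
                track_id=int(tid),
                frames=group["frame"].to_numpy(),
                centers=group[["cx", "cy"]].to_numpy(),
                boxes=group[["bb_width", "bb_height"]].to_numpy(),
                scores=group["conf"].to_numpy(),
                class_label=CLASS_LABELS.get(int(group["class"].iloc[0]), PIGLET),
            )
        )
    return trajectories


def write_embeddings(path, detections: Sequence[Detection]) -> None:
    """Write the embedding sidecar for a detection stream (rows follow the
    within-frame order of the stream)."""
    lines = []
    by_frame: dict[int, int] = {}
    for det in sorted(detections, key=lambda d: d.frame):
        row = by_frame.get(det.frame, 0)
        by_frame[det.frame] = row + 1
        if det.embedding is None:
            continue
        vec = ",".join(f"{v:.8g}" for v in det.embedding)
        lines.append(f"{det.frame + 1},{row},{vec}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_embeddings(
    path, expected_dim: Optional[int] = None
) -> dict[tuple[int, int], np.ndarray]:
    """Read an embedding sidecar; vectors are normalized, frames 0-based."""
    out: dict[tuple[int, int], np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 3:
                raise MotFormatError(f"{path}:{lineno}: too few fields")
            try:
                frame = int(float(parts[0])) - 1
                row = int(float(parts[1]))
                vec = np.array([float(p) for p in parts[2:]])
            except ValueError as exc:
                raise MotFormatError(f"{path}:{lineno}: {exc}") from exc
            if expected_dim is not None and vec.size != expected_dim:
                raise InvalidEmbeddingError(
                    f"{path}:{lineno}: embedding dimension {vec.size}, "
                    f"expected {expected_dim}"
                )
            out[(frame, row)] = normalize_embedding(vec)
    return out


def load_tracker_config(path) -> TrackerConfig:
    """Load a TrackerConfig from a flat YAML key-value file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return TrackerConfig.from_dict(data)


def load_behavior_config(path) -> BehaviorConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "away_band_deg" in data:
        data["away_band_deg"] = tuple(data["away_band_deg"])
    return BehaviorConfig(**data)


def load_scene_config(path) -> SceneConfig:
    """Load a SceneConfig from YAML (nested ``noise`` and ``occlusion_script``)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "noise" in data:
        data["noise"] = NoiseConfig(**data["noise"])
    if "arena" in data:
        data["arena"] = tuple(data["arena"])
    if "response_mix" in data:
        data["response_mix"] = tuple(data["response_mix"])
    if "occlusion_script" in data:
        data["occlusion_script"] = tuple(
            tuple(entry) for entry in data["occlusion_script"]
        )
    return SceneConfig(**data)
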