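"""Reading, repairing and standardizing 2D pose sequences.

A clip is a sequence of per-frame poses, each an 18-keypoint array of
``(x, y, confidence)`` triplets in pixel units, as produced by AlphaPose-style
pose estimators on video frames.  Before feature encoding every clip is
standardized to a fixed number of frames (300 by default): short clips are
loop-padded (repeated cyclically, which preserves motion statistics better
than zero-padding), long clips are sampled at evenly spaced indices.

Confidence scores are used only here — to pick the most confident person in
multi-person frames and to repair low-confidence joints by temporal linear
interpolation.  The features downstream use coordinates only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .topology import N_JOINTS

NECK = 1
DEFAULT_LENGTH = 300
DEFAULT_C_MIN = 0.05


class PoseFormatError(ValueError):
    """Raised for malformed keypoint records."""


class MissingPersonError(ValueError):
    """Raised when a frame offers no pose candidate."""


@dataclass(frozen=True)
class PoseFrame:
    """One person's pose in one frame: ``joints`` is (18, 3) = x, y, c."""

    joints: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        j = np.asarray(self.joints, dtype=float)
        if j.shape != (N_JOINTS, 3):
            raise PoseFormatError(f"expected ({N_JOINTS}, 3) joints, got {j.shape}")
        if not np.all(np.isfinite(j[:, :2])):
            raise PoseFormatError("non-finite joint coordinates")
        object.__setattr__(self, "joints", j)

    @property
    def mean_confidence(self) -> float:
        return float(self.joints[:, 2].mean())


@dataclass(frozen=True)
class SkeletonSequence:
    """A clip of pose frames with an optional action label and split ids."""

    frames: tuple[PoseFrame, ...]
    label: int | None = None
    clip_id: str = ""
    subject_id: str | None = None
    camera_id: str | None = None
    repair_log: tuple[int, ...] = ()  # joints that had to fall back to the neck

    def __len__(self) -> int:
        return len(self.frames)

    def coords(self) -> np.ndarray:
        """(T, 18, 3) array of x, y, confidence."""
        return np.stack([f.joints for f in self.frames])

    @classmethod
    def from_coords(
        cls, coords: np.ndarray, **kwargs
    ) -> "SkeletonSequence":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:  # (T, 54) flat
            coords = coords.reshape(len(coords), N_JOINTS, 3)
        frames = tuple(
            PoseFrame(coords[t], frame_index=t) for t in range(len(coords))
        )
        return cls(frames, **kwargs)


def _frame_from_flat(values: Sequence[float], frame_index: int, where: str) -> PoseFrame:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (3 * N_JOINTS,):
        raise PoseFormatError(
            f"{where}: keypoint array has length {arr.size}, need {3 * N_JOINTS}"
        )
    return PoseFrame(arr.reshape(N_JOINTS, 3), frame_index=frame_index)


def select_person(frame_candidates: Sequence[PoseFrame]) -> PoseFrame:
    """The candidate with the highest mean confidence; ties keep list order."""
    if not frame_candidates:
        raise MissingPersonError("no pose candidates in frame")
    best = frame_candidates[0]
    for cand in frame_candidates[1:]:
        if cand.mean_confidence > best.mean_confidence:
            best = cand
    return best


def _clip_and_frame(record: dict, position: int) -> tuple[str, int]:
    if "clip_id" in record:
        clip = str(record["clip_id"])
    elif "image_id" in record and "/" in str(record["image_id"]):
        clip = str(record["image_id"]).rsplit("/", 1)[0]
    else:
        clip = "clip0"
    if "frame_index" in record:
        idx = int(record["frame_index"])
    elif "image_id" in record:
        stem = Path(str(record["image_id"])).stem
        digits = "".join(ch for ch in stem if ch.isdigit())
        idx = int(digits) if digits else position
    else:
        idx = position
    return clip, idx


def load_pose_json(path: str | Path) -> list[SkeletonSequence]:
    """Load an AlphaPose-style keypoint JSON file into one sequence per clip.

    Each record needs a ``keypoints`` array of 54 floats (x, y, c per joint);
    clip and frame identity come from ``clip_id``/``frame_index`` fields or
    are parsed from ``image_id`` paths.  Multiple records for one frame are
    resolved with :func:`select_person`.
    """
    path = Path(path)
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PoseFormatError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(records, list):
        raise PoseFormatError(f"{path}: expected a top-level JSON list")

    by_clip: dict[str, dict[int, list[PoseFrame]]] = {}
    meta: dict[str, dict] = {}
    for pos, rec in enumerate(records):
        if "keypoints" not in rec:
            raise PoseFormatError(f"{path}: record {pos} lacks 'keypoints'")
        clip, idx = _clip_and_frame(rec, pos)
        frame = _frame_from_flat(rec["keypoints"], idx, f"{path}: record {pos}")
        by_clip.setdefault(clip, {}).setdefault(idx, []).append(frame)
        m = meta.setdefault(clip, {})
        for key in ("label", "subject_id", "camera_id"):
            if key in rec:
                m[key] = rec[key]

    sequences = []
    for clip in sorted(by_clip):
        frames = tuple(
            select_person(by_clip[clip][idx]) for idx in sorted(by_clip[clip])
        )
        m = meta[clip]
        sequences.append(
            SkeletonSequence(
                frames,
                label=None if m.get("label") is None else int(m["label"]),
                clip_id=clip,
                subject_id=None if m.get("subject_id") is None else str(m["subject_id"]),
                camera_id=None if m.get("camera_id") is None else str(m["camera_id"]),
            )
        )
    return sequences


def standardize_length(seq: SkeletonSequence, L: int = DEFAULT_LENGTH) -> SkeletonSequence:
    """Return a clip with exactly ``L`` frames.

    Short clips repeat cyclically (frame ``n`` of the output is input frame
    ``n mod T``); long clips keep frames at ``floor(i * T / L)``.
    """
    T = len(seq)
    if T == 0:
        raise ValueError("cannot standardize an empty sequence")
    if T == L:
        return seq
    if T < L:
        idx = np.arange(L) % T
    else:
        idx = (np.arange(L) * T) // L
    frames = tuple(
        replace(seq.frames[i], frame_index=n) for n, i in enumerate(idx)
    )
    return replace(seq, frames=frames)


def repair_missing_joints(
    seq: SkeletonSequence, c_min: float = DEFAULT_C_MIN
) -> SkeletonSequence:
    """Fill in joints whose confidence falls below ``c_min``.

    Low-confidence coordinates are linearly interpolated over time from the
    nearest confident frames of the same joint; gaps at the clip boundaries
    hold the nearest confident value.  A joint that is never confident falls
    back to the neck position frame-by-frame and is recorded in the repair
    log.  Confident joints are returned untouched.
    """
    coords = seq.coords()
    T = len(seq)
    valid = coords[:, :, 2] >= c_min
    out = coords.copy()
    flagged: list[int] = []

    neck = coords[:, NECK, :2].copy()
    if valid[:, NECK].any() and not valid[:, NECK].all():
        t = np.arange(T, dtype=float)
        tv = t[valid[:, NECK]]
        for axis in range(2):
            neck[:, axis] = np.interp(t, tv, coords[valid[:, NECK], NECK, axis])

    t = np.arange(T, dtype=float)
    for j in range(N_JOINTS):
        vj = valid[:, j]
        if vj.all():
            continue
        if not vj.any():
            out[:, j, :2] = neck
            flagged.append(j)
            continue
        tv = t[vj]
        for axis in range(2):
            out[~vj, j, axis] = np.interp(t[~vj], tv, coords[vj, j, axis])

    frames = tuple(
        PoseFrame(out[n], frame_index=seq.frames[n].frame_index) for n in range(T)
    )
    return replace(seq, frames=frames, repair_log=tuple(flagged))


# -- dataset cache and manifest -----------------------------------------


def sequences_to_manifest(sequences: Iterable[SkeletonSequence]) -> pd.DataFrame:
    rows = [
        {
            "clip_id": s.clip_id,
            "label": s.label,
            "subject_id": s.subject_id,
            "camera_id": s.camera_id,
        }
        for s in sequences
    ]
    return pd.DataFrame(rows, columns=["clip_id", "label", "subject_id", "camera_id"])


def save_sequences_h5(
    path: str | Path, sequences: Sequence[SkeletonSequence]
) -> None:
    """Cache standardized clips as (N, T, 18, 3) plus label/split fields."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"clips have mixed lengths {sorted(lengths)}; standardize first")
    coords = np.stack([s.coords() for s in sequences]).astype(np.float32)
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=coords, compression="gzip")
        f.create_dataset(
            "label",
            data=np.array([-1 if s.label is None else s.label for s in sequences]),
        )
        for name in ("clip_id", "subject_id", "camera_id"):
            f.create_dataset(
                name,
                data=np.array(
                    [getattr(s, name) or "" for s in sequences], dtype=object
                ),
                dtype=str_dt,
            )


def load_sequences_h5(path: str | Path) -> list[SkeletonSequence]:
    with h5py.File(path, "r") as f:
        coords = f["coords"][...]
        labels = f["label"][...]
        ids = {k: [v.decode() for v in f[k][...]] for k in ("clip_id", "subject_id", "camera_id")}
    return [
        SkeletonSequence.from_coords(
            coords[i],
            label=None if labels[i] < 0 else int(labels[i]),
            clip_id=ids["clip_id"][i],
            subject_id=ids["subject_id"][i] or None,
            camera_id=ids["camera_id"][i] or None,
        )
        for i in range(len(coords))
    ]
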