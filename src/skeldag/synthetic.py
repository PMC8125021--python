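"""Synthetic labeled skeleton clips with class-distinct kinematics.

Each action class is a sinusoidal "motion program": a set of joints that
oscillate around an upright base pose with class-specific amplitude,
frequency and phase.  Sinusoids (rather than random walks) make the motion
statistics analytically predictable — the variance of a finite-difference of
``A sin(2 pi f t / T)`` scales as ``(A f)^2`` — so encoder and classifier
behaviour can be checked against closed forms.  Gaussian pixel noise and
random joint dropout (confidence collapsing to ~0 with the detection
snapping to the origin, as failed pose estimates do) emulate pose-estimator
imperfections.  Everything is deterministic under the spec's seed.

Clips carry round-robin subject and camera ids so both cross-subject and
cross-view splits can be exercised.  The default geometry places the figure
in a 1920x1080 frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SkeletonSequence, sequences_to_manifest
from .topology import N_JOINTS

FRAME_W, FRAME_H = 1920, 1080

# Upright base pose (pixels), figure centred in the frame.
_CX, _CY, _U = FRAME_W / 2, FRAME_H / 2, 55.0  # _U ~ one "limb unit"
BASE_POSE: np.ndarray = np.array(
    [
        (_CX, _CY - 4.4 * _U),        # 0 nose
        (_CX, _CY - 3.6 * _U),        # 1 neck
        (_CX - 1.0 * _U, _CY - 3.4 * _U),   # 2 right shoulder
        (_CX - 1.3 * _U, _CY - 2.4 * _U),   # 3 right elbow
        (_CX - 1.5 * _U, _CY - 1.4 * _U),   # 4 right wrist
        (_CX + 1.0 * _U, _CY - 3.4 * _U),   # 5 left shoulder
        (_CX + 1.3 * _U, _CY - 2.4 * _U),   # 6 left elbow
        (_CX + 1.5 * _U, _CY - 1.4 * _U),   # 7 left wrist
        (_CX - 0.6 * _U, _CY - 1.2 * _U),   # 8 right femur
        (_CX - 0.7 * _U, _CY + 0.2 * _U),   # 9 right knee
        (_CX - 0.7 * _U, _CY + 1.6 * _U),   # 10 right ankle
        (_CX + 0.6 * _U, _CY - 1.2 * _U),   # 11 left femur
        (_CX + 0.7 * _U, _CY + 0.2 * _U),   # 12 left knee
        (_CX + 0.7 * _U, _CY + 1.6 * _U),   # 13 left ankle
        (_CX - 0.25 * _U, _CY - 4.55 * _U),  # 14 right eye
        (_CX + 0.25 * _U, _CY - 4.55 * _U),  # 15 left eye
        (_CX - 0.5 * _U, _CY - 4.45 * _U),   # 16 right ear
        (_CX + 0.5 * _U, _CY - 4.45 * _U),   # 17 left ear
    ],
    dtype=float,
)

# Limb groups cycled through when auto-building class programs.
_LIMB_GROUPS: tuple[tuple[int, ...], ...] = (
    (3, 4),       # right elbow + wrist
    (6, 7),       # left elbow + wrist
    (9, 10),      # right knee + ankle
    (12, 13),     # left knee + ankle
    (0, 14, 15, 16, 17),  # head
    (4, 7),       # both wrists
    (10, 13),     # both ankles
)


@dataclass(frozen=True)
class LimbOscillation:
    """One oscillating joint: displacement A sin(2 pi f t / T + phase)."""

    joint: int
    amplitude_xy: tuple[float, float]  # pixels
    frequency: float                   # cycles per clip
    phase: float = 0.0                 # radians


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic dataset; the seed fully determines it."""

    n_classes: int
    clips_per_class: int
    frames_per_clip: int = 300
    base_pose: np.ndarray = field(default_factory=lambda: BASE_POSE.copy())
    motion_programs: tuple[tuple[LimbOscillation, ...], ...] | None = None
    noise_sd: float = 2.0              # pixels
    confidence_mean: float = 0.9
    dropout_prob: float = 0.02         # per joint per frame
    n_subjects: int = 4
    n_cameras: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.clips_per_class < 1 or self.frames_per_clip < 1:
            raise ValueError("n_classes, clips_per_class, frames_per_clip must be >= 1")
        if self.noise_sd < 0 or not 0 <= self.dropout_prob <= 1:
            raise ValueError("invalid noise_sd or dropout_prob")
        pose = np.asarray(self.base_pose, dtype=float)
        if pose.shape != (N_JOINTS, 2):
            raise ValueError(f"base_pose must be ({N_JOINTS}, 2)")
        object.__setattr__(self, "base_pose", pose)
        programs = self.motion_programs
        if programs is None:
            programs = tuple(
                default_motion_program(c) for c in range(self.n_classes)
            )
        if len(programs) != self.n_classes:
            raise ValueError("one motion program per class required")
        for prog in programs:
            for osc in prog:
                if not 0 <= osc.joint < N_JOINTS:
                    raise ValueError(f"oscillation joint out of range: {osc.joint}")
                if min(osc.amplitude_xy) < 0:
                    raise ValueError("amplitudes must be >= 0")
        freqs = {tuple(sorted(o.frequency for o in p)) for p in programs}
        if len(freqs) != len(programs):
            raise ValueError("class frequency signatures must be distinct")
        object.__setattr__(self, "motion_programs", tuple(programs))


def default_motion_program(class_index: int) -> tuple[LimbOscillation, ...]:
    """Class-distinct program: one limb group, amplitude and frequency both
    growing with the class index so classes separate in position and speed."""
    group = _LIMB_GROUPS[class_index % len(_LIMB_GROUPS)]
    amp = 35.0 + 12.0 * class_index
    freq = 1.0 + 0.75 * class_index
    return tuple(
        LimbOscillation(j, (amp, 0.6 * amp), freq, phase=0.4 * k)
        for k, j in enumerate(group)
    )


def _render_clip(
    spec: SyntheticSpec, program: Sequence[LimbOscillation], rng: np.random.Generator
) -> np.ndarray:
    """(T, 18, 3) coordinates + confidence for one clip."""
    T = spec.frames_per_clip
    t = np.arange(T, dtype=float)
    xy = np.broadcast_to(spec.base_pose, (T, N_JOINTS, 2)).copy()
    clip_phase = rng.uniform(0, 2 * np.pi)
    for osc in program:
        wave = np.sin(2 * np.pi * osc.frequency * t / T + osc.phase + clip_phase)
        xy[:, osc.joint, 0] += osc.amplitude_xy[0] * wave
        xy[:, osc.joint, 1] += osc.amplitude_xy[1] * wave
    if spec.noise_sd > 0:
        xy += rng.normal(0.0, spec.noise_sd, size=xy.shape)
    conf = np.clip(
        rng.normal(spec.confidence_mean, 0.05, size=(T, N_JOINTS)), 0.06, 1.0
    )
    if spec.dropout_prob > 0:
        drop = rng.random((T, N_JOINTS)) < spec.dropout_prob
        conf[drop] = rng.uniform(0.0, 0.04, size=int(drop.sum()))
        xy[drop] = 0.0  # failed detections collapse to the origin
    return np.concatenate([xy, conf[..., None]], axis=2)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[SkeletonSequence], pd.DataFrame]:
    """Labeled synthetic clips plus their manifest (clip/label/subject/camera)."""
    rng = np.random.default_rng(spec.seed)
    sequences: list[SkeletonSequence] = []
    i = 0
    for label in range(spec.n_classes):
        for _ in range(spec.clips_per_class):
            coords = _render_clip(spec, spec.motion_programs[label], rng)
            sequences.append(
                SkeletonSequence.from_coords(
                    coords,
                    label=label,
                    clip_id=f"clip{i:05d}",
                    subject_id=f"S{i % spec.n_subjects}",
                    camera_id=f"C{(i // spec.n_subjects) % spec.n_cameras}",
                )
            )
            i += 1
    return sequences, sequences_to_manifest(sequences)


def toy_fixture() -> tuple[list[SkeletonSequence], pd.DataFrame]:
    """A tiny fixed dataset: 3 classes x 6 clips x 300 frames, seed 12345."""
    spec = SyntheticSpec(
        n_classes=3, clips_per_class=6, frames_per_clip=300, seed=12345
    )
    return generate_dataset(spec)


def write_pose_json(
    sequences: Sequence[SkeletonSequence], path: str | Path
) -> None:
    """Serialize clips in the keypoint-JSON dialect the pose reader accepts."""
    records = []
    for seq in sequences:
        for frame in seq.frames:
            records.append(
                {
                    "clip_id": seq.clip_id,
                    "frame_index": int(frame.frame_index),
                    "keypoints": [round(v, 4) for v in frame.joints.ravel()],
                    "label": seq.label,
                    "subject_id": seq.subject_id,
                    "camera_id": seq.camera_id,
                }
            )
    Path(path).write_text(json.dumps(records))
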