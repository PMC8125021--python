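"""Encoding skeleton clips into two-stream feature tensors.

Four base features summarise a standardized clip of T frames, each as a
``2T x 18`` matrix holding x and y rows:

* joint feature ``F_v``      — raw joint coordinates, column = joint;
* skeleton feature ``F_s``   — limb vectors (child minus parent joint),
  column = edge, with the virtual self-loop column identically zero;
* joint motion ``F_mv``      — frame-to-frame differences of ``F_v``;
* skeleton motion ``F_ms``   — frame-to-frame differences of ``F_s``.

Each base feature is expanded through the DAG incidence matrices into an
"in" (source-side) and "out" (target-side) companion, and triplets of
matching index space are stacked as channels:

* spatial stream  = [joint part (F_v, F_sin, F_sout); skeleton part
  (F_s, F_vin, F_vout)], a ``4T x 18 x 3`` tensor;
* motion stream   = the same construction on F_mv / F_ms.

Joint-indexed features multiply by the transposed matrices (columns become
edges); edge-indexed features multiply by the matrices directly (columns
become joint aggregates), so that the three channels of every sub-feature
share one column index space.

Rows may interleave x and y per frame (default: rows 2n, 2n+1 belong to
frame n) or block them (all x rows, then all y rows).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import SkeletonSequence, DEFAULT_LENGTH
from .topology import DagMatrices, SkeletonTopology, N_JOINTS

Layout = Literal["interleaved", "block"]
Kind = Literal["v", "s", "m_v", "m_s"]

_JOINT_KINDS = {"v": "joint", "m_v": "joint", "s": "edge", "m_s": "edge"}


@dataclass(frozen=True)
class BaseFeature:
    """A ``2T x 18`` base feature matrix with its row-layout descriptor."""

    values: np.ndarray  # (2T, 18)
    kind: Kind
    layout: Layout = "interleaved"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != N_JOINTS or v.shape[0] % 2:
            raise ValueError(f"base feature must be (2T, {N_JOINTS}), got {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0] // 2

    @property
    def index_space(self) -> str:
        """Whether columns index joints (v, m_v) or edges (s, m_s)."""
        return _JOINT_KINDS[self.kind]

    def to_frames(self) -> np.ndarray:
        """(T, 2, 18) view-like array: per frame, the x row then the y row."""
        T = self.n_frames
        if self.layout == "interleaved":
            return self.values.reshape(T, 2, N_JOINTS)
        return np.stack([self.values[:T], self.values[T:]], axis=1)

    @classmethod
    def from_frames(
        cls, frames: np.ndarray, kind: Kind, layout: Layout
    ) -> "BaseFeature":
        T = frames.shape[0]
        if layout == "interleaved":
            values = frames.reshape(2 * T, N_JOINTS)
        else:
            values = np.concatenate([frames[:, 0], frames[:, 1]], axis=0)
        return cls(values, kind, layout)


@dataclass(frozen=True)
class StreamFeature:
    """A ``4T x 18 x 3`` two-part stream tensor.

    Rows 0..2T-1 are the joint part, rows 2T..4T-1 the skeleton part; the
    channel names record the Table-style composition of each part.
    """

    tensor: np.ndarray
    stream: Literal["spatial", "motion"]
    joint_channels: tuple[str, str, str]
    skeleton_channels: tuple[str, str, str]
    layout: Layout = "interleaved"

    @property
    def joint_part(self) -> np.ndarray:
        return self.tensor[: self.tensor.shape[0] // 2]

    @property
    def skeleton_part(self) -> np.ndarray:
        return self.tensor[self.tensor.shape[0] // 2 :]


def _xy(seq: SkeletonSequence) -> np.ndarray:
    return seq.coords()[:, :, :2]  # (T, 18, 2)


def _require_standardized(seq: SkeletonSequence, expected_frames: int) -> None:
    if len(seq) != expected_frames:
        raise ValueError(
            f"sequence has {len(seq)} frames; standardize to {expected_frames} first"
        )


def compute_joint_feature(
    seq: SkeletonSequence,
    layout: Layout = "interleaved",
    expected_frames: int = DEFAULT_LENGTH,
) -> BaseFeature:
    """Joint coordinates as a (2T, 18) matrix, columns indexed by joint."""
    _require_standardized(seq, expected_frames)
    xy = _xy(seq)  # (T, 18, 2)
    frames = np.moveaxis(xy, 2, 1)  # (T, 2, 18)
    return BaseFeature.from_frames(frames, "v", layout)


def compute_skeleton_feature(
    seq: SkeletonSequence,
    topo: SkeletonTopology,
    layout: Layout = "interleaved",
    expected_frames: int = DEFAULT_LENGTH,
) -> BaseFeature:
    """Limb vectors (edge target joint minus source joint), columns = edges.

    The virtual self-loop (edge 0) gives an identically zero column.
    """
    _require_standardized(seq, expected_frames)
    xy = _xy(seq)
    src = np.array([e[0] for e in topo.edges])
    tgt = np.array([e[1] for e in topo.edges])
    limb = xy[:, tgt, :] - xy[:, src, :]  # (T, 18, 2)
    return BaseFeature.from_frames(np.moveaxis(limb, 2, 1), "s", layout)


def compute_motion_feature(base: BaseFeature) -> BaseFeature:
    """Frame-to-frame differences; the final frame's rows are zero-filled."""
    if base.kind not in ("v", "s"):
        raise ValueError(f"motion is computed from a spatial base, not {base.kind}")
    frames = base.to_frames()
    motion = np.zeros_like(frames)
    motion[:-1] = frames[1:] - frames[:-1]
    kind = "m_v" if base.kind == "v" else "m_s"
    return BaseFeature.from_frames(motion, kind, base.layout)


def dag_expand(
    F: BaseFeature | np.ndarray,
    dag: DagMatrices,
    index_space: str | None = None,
    transpose_all: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand a feature matrix through the DAG source/target matrices.

    Joint-indexed features map columns to edges via ``F @ S.T`` / ``F @ T.T``;
    edge-indexed features map columns back to joints via ``F @ S`` / ``F @ T``
    (``transpose_all=True`` forces the transposed form everywhere).
    """
    if isinstance(F, BaseFeature):
        values, space = F.values, F.index_space
    else:
        values = np.asarray(F, dtype=float)
        space = index_space or "joint"
    if values.shape[-1] != N_JOINTS:
        raise ValueError(f"expected {N_JOINTS} columns, got {values.shape[-1]}")
    if space == "joint" or transpose_all:
        return values @ dag.source.T, values @ dag.target.T
    return values @ dag.source, values @ dag.target


def assemble_stream(
    seq: SkeletonSequence,
    topo: SkeletonTopology,
    dag: DagMatrices,
    stream: Literal["spatial", "motion"],
    layout: Layout = "interleaved",
    expected_frames: int = DEFAULT_LENGTH,
    transpose_all: bool = False,
) -> StreamFeature:
    """Assemble the ``4T x 18 x 3`` spatial or motion stream tensor."""
    fv = compute_joint_feature(seq, layout, expected_frames)
    fs = compute_skeleton_feature(seq, topo, layout, expected_frames)
    if stream == "motion":
        fv = compute_motion_feature(fv)
        fs = compute_motion_feature(fs)
        names = ("F_mv", "F_msin", "F_msout"), ("F_ms", "F_mvin", "F_mvout")
    elif stream == "spatial":
        names = ("F_v", "F_sin", "F_sout"), ("F_s", "F_vin", "F_vout")
    else:
        raise ValueError(f"unknown stream {stream!r}")

    v_in, v_out = dag_expand(fv, dag, transpose_all=transpose_all)
    s_in, s_out = dag_expand(fs, dag, transpose_all=transpose_all)

    joint_part = np.stack([fv.values, s_in, s_out], axis=-1)
    skeleton_part = np.stack([fs.values, v_in, v_out], axis=-1)
    tensor = np.concatenate([joint_part, skeleton_part], axis=0)
    return StreamFeature(tensor, stream, names[0], names[1], layout)


def encode_clip(
    seq: SkeletonSequence,
    topo: SkeletonTopology,
    dag: DagMatrices,
    layout: Layout = "interleaved",
    expected_frames: int = DEFAULT_LENGTH,
) -> dict[str, StreamFeature]:
    """Both stream tensors for one standardized clip."""
    return {
        s: assemble_stream(seq, topo, dag, s, layout, expected_frames)
        for s in ("spatial", "motion")
    }
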