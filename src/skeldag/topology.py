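"""Skeleton graph topology and its directed-acyclic-graph incidence matrices.

The 18-keypoint (COCO-18 / AlphaPose) skeleton is modelled as a directed tree
rooted at the nose: every anatomical edge points from a parent joint towards
the periphery (shoulder -> elbow -> wrist, and so on).  Edge ``e_i`` is, by
convention, the edge whose *target* is joint ``i``; a virtual self-loop
``e_0 = (0, 0)`` at the root pads the 17 anatomical edges to 18 so the
edge-by-joint incidence matrices are square.

Two incidence matrices describe the graph.  The *source* matrix ``S`` has
``S[j, i] = 1`` when joint ``i`` is the source of edge ``j``; the *target*
matrix ``T`` marks target joints the same way.  Each nonzero of ``S`` is
divided by the out-degree of its joint and each nonzero of ``T`` by the
in-degree, so a joint distributes unit total weight over the edges it feeds.
For this skeleton the nose and neck each source four edges, giving the
characteristic entry value of 0.25; every joint is the target of exactly one
edge, so the normalized target matrix stays binary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

N_JOINTS = 18

#: COCO-18 joint labels in index order.
JOINT_NAMES: tuple[str, ...] = (
    "Nose",
    "Neck",
    "Right shoulder",
    "Right elbow",
    "Right wrist",
    "Left shoulder",
    "Left elbow",
    "Left wrist",
    "Right femur",
    "Right knee",
    "Right ankle",
    "Left femur",
    "Left knee",
    "Left ankle",
    "Right eye",
    "Left eye",
    "Right ear",
    "Left ear",
)

#: Parent of each joint in the rooted tree (root: Nose, its own parent).
_PARENTS: tuple[int, ...] = (0, 0, 1, 2, 3, 1, 5, 6, 1, 8, 9, 1, 11, 12, 0, 0, 14, 15)


class TopologyError(ValueError):
    """Raised when a skeleton description violates the tree/edge contract."""


@dataclass(frozen=True)
class SkeletonTopology:
    """A rooted directed skeleton tree with a virtual root self-loop.

    ``edges[i]`` is the ``(source, target)`` pair of edge ``e_i``; index 0 is
    the virtual self-loop at the root, and for ``i >= 1`` the target of
    ``edges[i]`` is joint ``i``.
    """

    joint_names: tuple[str, ...]
    parent_of: tuple[int, ...]
    edges: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.joint_names)
        if len(self.parent_of) != n:
            raise TopologyError(
                f"{n} joint names but {len(self.parent_of)} parent entries"
            )
        root = [i for i, p in enumerate(self.parent_of) if p == i]
        if root != [0]:
            raise TopologyError(f"expected joint 0 as the unique root, got {root}")
        for i, p in enumerate(self.parent_of):
            if not 0 <= p < n:
                raise TopologyError(f"parent of joint {i} out of range: {p}")
        # Edge e_i targets joint i; e_0 is the virtual self-loop at the root.
        edges = tuple((self.parent_of[i], i) for i in range(n))
        if len(set(edges)) != len(edges):
            raise TopologyError("duplicated edge in topology")
        self._check_acyclic()
        object.__setattr__(self, "edges", edges)

    def _check_acyclic(self) -> None:
        for start in range(len(self.parent_of)):
            seen = set()
            j = start
            while j != 0:
                if j in seen:
                    raise TopologyError(f"cycle through joint {j}")
                seen.add(j)
                j = self.parent_of[j]

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    def out_degree(self) -> np.ndarray:
        """Edges sourced at each joint, counting the virtual self-loop."""
        deg = np.zeros(self.n_joints, dtype=np.int64)
        for src, _tgt in self.edges:
            deg[src] += 1
        return deg

    def in_degree(self) -> np.ndarray:
        """Edges targeting each joint; identically 1 for a rooted tree."""
        deg = np.zeros(self.n_joints, dtype=np.int64)
        for _src, tgt in self.edges:
            deg[tgt] += 1
        return deg

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "joint_names": list(self.joint_names),
            "parent_of": list(self.parent_of),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SkeletonTopology":
        return cls(tuple(d["joint_names"]), tuple(int(p) for p in d["parent_of"]))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SkeletonTopology":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


@dataclass(frozen=True)
class DagMatrices:
    """Degree-normalized source/target incidence matrices of a skeleton DAG.

    ``source`` and ``target`` are the normalized edge-by-joint matrices;
    the unnormalized binary versions are kept alongside.
    """

    source: np.ndarray
    target: np.ndarray
    source_binary: np.ndarray
    target_binary: np.ndarray

    def row_normalized(self) -> tuple[np.ndarray, np.ndarray]:
        """Literal per-row normalization (each edge has one source, so this
        is the identity on the binary matrices; provided for comparison)."""
        s = self.source_binary / self.source_binary.sum(axis=1, keepdims=True)
        t = self.target_binary / self.target_binary.sum(axis=1, keepdims=True)
        return s, t


def build_topology() -> SkeletonTopology:
    """The fixed COCO-18 skeleton rooted at the nose."""
    return SkeletonTopology(JOINT_NAMES, _PARENTS)


def build_dag_matrices(topology: SkeletonTopology) -> DagMatrices:
    """Build binary incidence matrices from the edge list and normalize them
    by joint degree (out-degree for the source matrix, in-degree for the
    target matrix)."""
    n = topology.n_joints
    s_bin = np.zeros((n, n))
    t_bin = np.zeros((n, n))
    for j, (src, tgt) in enumerate(topology.edges):
        s_bin[j, src] = 1.0
        t_bin[j, tgt] = 1.0
    out_deg = topology.out_degree().astype(float)
    in_deg = topology.in_degree().astype(float)
    if np.any(in_deg == 0):
        missing = [topology.joint_names[i] for i in np.flatnonzero(in_deg == 0)]
        raise TopologyError(f"joints never referenced as edge targets: {missing}")
    source = s_bin / np.where(out_deg > 0, out_deg, 1.0)[np.newaxis, :]
    target = t_bin / in_deg[np.newaxis, :]
    return DagMatrices(source, target, s_bin, t_bin)


def identity_dag_matrices(n: int = N_JOINTS) -> DagMatrices:
    """Identity source/target matrices: the no-DAG ablation, where expansion
    replicates features instead of mixing neighbouring joints."""
    eye = np.eye(n)
    return DagMatrices(eye.copy(), eye.copy(), eye.copy(), eye.copy())
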