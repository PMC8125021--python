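import numpy as np
import pytest

from skeldag import (
    SkeletonSequence,
    SyntheticSpec,
    build_dag_matrices,
    build_topology,
    generate_dataset,
)


@pytest.fixture(scope="session")
def topo():
    return build_topology()


@pytest.fixture(scope="session")
def dag(topo):
    return build_dag_matrices(topo)


@pytest.fixture(scope="session")
def small_dataset():
    """3 separable classes, 4 clips each, short clips — enough to exercise
    the full pipeline quickly."""
    spec = SyntheticSpec(
        n_classes=3, clips_per_class=4, frames_per_clip=40, seed=7
    )
    return generate_dataset(spec)


def make_sequence(coords_xy, confidence=1.0, **kwargs):
    """Build a SkeletonSequence from a (T, 18, 2) coordinate array."""
    coords_xy = np.asarray(coords_xy, dtype=float)
    conf = np.full(coords_xy.shape[:2] + (1,), confidence)
    return SkeletonSequence.from_coords(
        np.concatenate([coords_xy, conf], axis=2), **kwargs
    )


@pytest.fixture
def constant_pose_seq():
    """300 frames of a fixed pose: all joints at (5, 7)."""
    xy = np.full((300, 18, 2), 0.0)
    xy[..., 0] = 5.0
    xy[..., 1] = 7.0
    return make_sequence(xy)
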