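"""Base feature matrices, DAG expansion and stream assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from skeldag.features import (
    BaseFeature,
    assemble_stream,
    compute_joint_feature,
    compute_motion_feature,
    compute_skeleton_feature,
    dag_expand,
)

from conftest import make_sequence


def random_sequence(seed=0, t=300):
    rng = np.random.default_rng(seed)
    return make_sequence(rng.uniform(0, 1000, size=(t, 18, 2))), rng


def brute_force_expand(values, topo, joint_indexed=True):
    """Per-edge loop oracle for the incidence-matrix products."""
    out_deg = topo.out_degree()
    f_in = np.zeros_like(values)
    f_out = np.zeros_like(values)
    if joint_indexed:
        # column j of the result = source/target joint's column, degree-weighted
        for j, (src, tgt) in enumerate(topo.edges):
            f_in[:, j] = values[:, src] / out_deg[src]
            f_out[:, j] = values[:, tgt]  # in-degree is 1 everywhere
    else:
        for j, (src, tgt) in enumerate(topo.edges):
            f_in[:, src] += values[:, j] / out_deg[src]
            f_out[:, tgt] += values[:, j]
    return f_in, f_out


class TestJointFeature:
    def test_shape_is_600_by_18(self, constant_pose_seq):
        f = compute_joint_feature(constant_pose_seq)
        assert f.values.shape == (600, 18)

    def test_constant_pose_interleaves_x_and_y(self, constant_pose_seq):
        f = compute_joint_feature(constant_pose_seq)
        assert (f.values[0::2] == 5.0).all()  # x rows
        assert (f.values[1::2] == 7.0).all()  # y rows

    def test_entry_indexing_against_raw_coordinates(self):
        seq, _ = random_sequence(3)
        f = compute_joint_feature(seq)
        xy = seq.coords()[..., :2]
        for n in (0, 7, 299):
            for i in (0, 4, 17):
                assert f.values[2 * n, i] == xy[n, i, 0]
                assert f.values[2 * n + 1, i] == xy[n, i, 1]

    def test_block_layout(self):
        seq, _ = random_sequence(4)
        f = compute_joint_feature(seq, layout="block")
        xy = seq.coords()[..., :2]
        assert f.values[5, 2] == xy[5, 2, 0]      # x block first
        assert f.values[305, 2] == xy[5, 2, 1]    # then y block

    def test_non_standardized_length_rejected(self):
        seq, _ = random_sequence(5, t=120)
        with pytest.raises(ValueError, match="standardize"):
            compute_joint_feature(seq)


class TestSkeletonFeature:
    def test_virtual_edge_column_is_zero(self, topo):
        seq, _ = random_sequence(6)
        f = compute_skeleton_feature(seq, topo)
        assert (f.values[:, 0] == 0).all()

    def test_translation_invariance(self, topo):
        seq, _ = random_sequence(7)
        shifted = make_sequence(seq.coords()[..., :2] + np.array([13.0, -4.5]))
        a = compute_skeleton_feature(seq, topo)
        b = compute_skeleton_feature(shifted, topo)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_edge_4_is_wrist_minus_elbow(self, topo):
        seq, _ = random_sequence(8)
        f = compute_skeleton_feature(seq, topo)
        xy = seq.coords()[..., :2]
        np.testing.assert_allclose(f.values[0::2, 4], xy[:, 4, 0] - xy[:, 3, 0])
        np.testing.assert_allclose(f.values[1::2, 4], xy[:, 4, 1] - xy[:, 3, 1])


class TestMotionFeature:
    def test_static_sequence_gives_zero(self, constant_pose_seq):
        f = compute_motion_feature(compute_joint_feature(constant_pose_seq))
        assert (f.values == 0).all()
        assert f.values.shape == (600, 18)

    def test_uniform_velocity(self):
        xy = np.zeros((300, 18, 2))
        xy[..., 0] = 2.0 * np.arange(300)[:, None]
        f = compute_motion_feature(compute_joint_feature(make_sequence(xy)))
        assert (f.values[0:598:2] == 2.0).all()  # x-motion rows
        assert (f.values[1:599:2] == 0.0).all()  # y-motion rows
        assert (f.values[598:] == 0.0).all()     # final frame zero-filled

    def test_finite_difference_oracle(self):
        seq, _ = random_sequence(9)
        base = compute_joint_feature(seq)
        f = compute_motion_feature(base)
        frames = base.values.reshape(300, 2, 18)
        expected = frames[1:] - frames[:-1]
        np.testing.assert_array_equal(
            f.values.reshape(300, 2, 18)[:-1], expected
        )


class TestDagExpand:
    def test_zeros_map_to_zeros(self, dag):
        f_in, f_out = dag_expand(np.zeros((600, 18)), dag)
        assert (f_in == 0).all() and (f_out == 0).all()

    def test_neck_impulse_spreads_quarter_weight(self, topo, dag):
        f = np.zeros((4, 18))
        f[:, 1] = 1.0  # unit signal on the neck
        f_in, _ = dag_expand(f, dag, index_space="joint")
        neck_edges = [j for j, (s, _) in enumerate(topo.edges) if s == 1]
        assert (f_in[:, neck_edges] == 0.25).all()
        others = [j for j in range(18) if j not in neck_edges]
        assert (f_in[:, others] == 0).all()

    @pytest.mark.parametrize("joint_indexed", [True, False])
    def test_matches_brute_force_loop_on_random_inputs(
        self, topo, dag, joint_indexed
    ):
        rng = np.random.default_rng(11)
        for _ in range(100):
            f = rng.standard_normal((6, 18))
            got_in, got_out = dag_expand(
                f, dag, index_space="joint" if joint_indexed else "edge"
            )
            exp_in, exp_out = brute_force_expand(f, topo, joint_indexed)
            np.testing.assert_allclose(got_in, exp_in, atol=1e-12)
            np.testing.assert_allclose(got_out, exp_out, atol=1e-12)

    @given(
        f1=arrays(np.float64, (4, 18), elements=st.floats(-100, 100)),
        f2=arrays(np.float64, (4, 18), elements=st.floats(-100, 100)),
    )
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, dag, f1, f2):
        a_in, a_out = dag_expand(f1, dag)
        b_in, b_out = dag_expand(f2, dag)
        s_in, s_out = dag_expand(f1 + f2, dag)
        np.testing.assert_allclose(s_in, a_in + b_in, atol=1e-9)
        np.testing.assert_allclose(s_out, a_out + b_out, atol=1e-9)


class TestAssembleStream:
    def test_spatial_tensor_shape(self, topo, dag):
        seq, _ = random_sequence(12)
        sf = assemble_stream(seq, topo, dag, "spatial")
        assert sf.tensor.shape == (1200, 18, 3)
        assert sf.joint_part.shape == (600, 18, 3)
        assert sf.skeleton_part.shape == (600, 18, 3)

    def test_static_clip_motion_stream_is_zero_spatial_is_not(
        self, topo, dag, constant_pose_seq
    ):
        motion = assemble_stream(constant_pose_seq, topo, dag, "motion")
        spatial = assemble_stream(constant_pose_seq, topo, dag, "spatial")
        assert (motion.tensor == 0).all()
        assert (spatial.tensor != 0).any()

    def test_channel_0_of_joint_part_is_the_joint_feature(self, topo, dag):
        seq, _ = random_sequence(13)
        sf = assemble_stream(seq, topo, dag, "spatial")
        fv = compute_joint_feature(seq)
        np.testing.assert_array_equal(sf.joint_part[..., 0], fv.values)

    def test_channel_compositions(self, topo, dag):
        seq, _ = random_sequence(14)
        sf = assemble_stream(seq, topo, dag, "spatial")
        fv = compute_joint_feature(seq)
        fs = compute_skeleton_feature(seq, topo)
        s_in, s_out = dag_expand(fs, dag)
        v_in, v_out = dag_expand(fv, dag)
        np.testing.assert_array_equal(sf.joint_part[..., 1], s_in)
        np.testing.assert_array_equal(sf.joint_part[..., 2], s_out)
        np.testing.assert_array_equal(sf.skeleton_part[..., 0], fs.values)
        np.testing.assert_array_equal(sf.skeleton_part[..., 1], v_in)
        np.testing.assert_array_equal(sf.skeleton_part[..., 2], v_out)
        assert sf.joint_channels == ("F_v", "F_sin", "F_sout")
        assert sf.skeleton_channels == ("F_s", "F_vin", "F_vout")

    def test_translation_moves_only_joint_coordinates(self, topo, dag):
        seq, _ = random_sequence(15)
        shifted = make_sequence(seq.coords()[..., :2] + np.array([10.0, 20.0]))
        a = assemble_stream(seq, topo, dag, "motion")
        b = assemble_stream(shifted, topo, dag, "motion")
        np.testing.assert_allclose(a.tensor, b.tensor, atol=1e-9)

    def test_round_trip_determinism(self, topo, dag):
        seq, _ = random_sequence(16)
        a = assemble_stream(seq, topo, dag, "spatial")
        b = assemble_stream(seq, topo, dag, "spatial")
        assert np.array_equal(a.tensor, b.tensor)
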