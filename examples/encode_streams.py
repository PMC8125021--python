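"""Encode one synthetic clip into its spatial and motion stream tensors.

A standardized 300-frame clip becomes four 600x18 base feature matrices
(joint coordinates, limb vectors, and their frame differences); the DAG
matrices expand each into source/target companions, and matching triplets
stack into two 1200x18x3 stream tensors.
"""

from skeldag import (
    SyntheticSpec,
    assemble_stream,
    build_dag_matrices,
    build_topology,
    generate_dataset,
    standardize_length,
)

topo = build_topology()
dag = build_dag_matrices(topo)

spec = SyntheticSpec(n_classes=1, clips_per_class=1, frames_per_clip=240, seed=0)
(clip,), _ = generate_dataset(spec)
clip = standardize_length(clip, 300)  # loop-pad the 240 frames to 300

spatial = assemble_stream(clip, topo, dag, "spatial")
motion = assemble_stream(clip, topo, dag, "motion")
print("spatial tensor:", spatial.tensor.shape,
      "channels", spatial.joint_channels, "+", spatial.skeleton_channels)
print("motion tensor: ", motion.tensor.shape,
      "channels", motion.joint_channels, "+", motion.skeleton_channels)
print("virtual-edge column of the skeleton part is zero:",
      bool((spatial.skeleton_part[:, 0, 0] == 0).all()))
print("mean |motion| is much smaller than mean |position|: "
      f"{abs(motion.tensor).mean():.3f} vs {abs(spatial.tensor).mean():.1f} px")
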