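"""Build the 18-joint skeleton graph and its normalized incidence matrices.

The source matrix spreads each joint's influence over the edges it feeds:
the nose and neck each source four edges (counting the virtual self-loop at
the nose), so their entries are 1/4; every other sourcing joint feeds one
edge and keeps weight 1.  The target matrix stays binary because every
joint is the target of exactly one edge.
"""

import numpy as np

from skeldag import build_dag_matrices, build_topology

topo = build_topology()
dag = build_dag_matrices(topo)

print("joints:", ", ".join(topo.joint_names[:6]), "...")
print("edge 0 (virtual):", topo.edges[0])
print("edge 4 (elbow->wrist):", topo.edges[4])
print("out-degrees:", topo.out_degree().tolist())
print("distinct nonzero source-matrix values:",
      sorted(set(np.round(dag.source[dag.source > 0], 6))))
print("target matrix is binary:",
      bool(np.array_equal(dag.target, dag.target_binary)))
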