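"""Dihedral PCA: finding the dominant conformer of a mixed ensemble.

Frames are drawn from two wrapped-Gaussian clusters (70% near all-trans,
30% with gauche defects); PCA on the (cos, sin)-embedded dihedrals
separates them and the probability mode identifies the majority state.
"""

import numpy as np

import chainfel as cf
from chainfel.dpca import (
    DihedralTrajectory, circular_embed, classify_motif, dominant_conformation,
    top2_pca,
)
from chainfel.oracles import two_cluster_dihedral_fixture

m = 8
centers = np.array([
    [180.0] * m,                                # extended
    [180, 60, 60, 180, 180, -60, 60, 180.0],    # gauche-rich
])
angles, labels = two_cluster_dihedral_fixture(
    m, centers, spreads=10.0, weights=(0.7, 0.3), n=2_000, seed=0,
)
traj = DihedralTrajectory(angles)
pca = top2_pca(circular_embed(traj))
dom = dominant_conformation(traj, pca)

print(f"top-2 variance fraction: {pca.variance_fraction:.3f}")
print(f"dominant frame: {dom.frame_index} "
      f"(drawn from cluster {labels[dom.frame_index]})")
conf = cf.Conformation(cf.ChainTopology(m + 3), dom.dihedrals)
print(f"its motif: {classify_motif(conf)}, r_ee = {conf.r_ee:.2f} A")
print("\nWith >90% of the variance in two components, the 2D projection is")
print("a faithful map of the ensemble, and its mode sits in the 70% cluster.")
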