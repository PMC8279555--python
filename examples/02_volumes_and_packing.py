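"""Van der Waals volumes and packing fractions inside the cavitand dimer.

The sealed octa-acid dimer encloses about 740 A^3.  A guest's packing
fraction — its union-of-spheres van der Waals volume over that interior —
signals packing frustration: hard spheres freeze near 0.49.
"""

import numpy as np

import chainfel as cf

CAVITY = 740.0  # A^3

for n in (20, 21, 22):
    topo = cf.ChainTopology(n, with_hydrogens=True)
    conf = cf.Conformation(topo, np.full(topo.n_dihedrals, 180.0))
    elements, coords = cf.with_hydrogens(topo, conf.coords)
    est = cf.vdw_volume(coords, cf.BONDI.for_elements(elements),
                        n_points=500_000, seed=1)
    phi = cf.packing_fraction(est.value, CAVITY)
    print(f"C{n}H{2 * n + 2}: V = {est.value:5.1f} +/- {est.stderr:.1f} A^3  "
          f"packing fraction = {phi:.3f}")

print("\nBeyond C20 the packing fraction passes the hard-sphere freezing")
print("point (~0.49): longer guests are predicted to be packing-frustrated.")
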