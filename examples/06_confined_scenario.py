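"""Free vs confined chains: the full pipeline on two scenarios.

Umbrella-sample the end-to-end distance of C15 in vacuum and inside the
soft prolate-ellipsoid cavity (8 A wide, 13 A long), reconstruct both
PMFs with WHAM, and classify the dominant conformer at each minimum via
dihedral PCA.
"""

import chainfel as cf
from chainfel.oracles import confined_chain_scenario
from chainfel.pipeline import run_scenario
from chainfel.wham import find_minima

for label, cavity in (("free", None), ("confined", cf.CavityWall())):
    config = confined_chain_scenario(15, cavity=cavity, seed=4, n_steps=20_000)
    result = run_scenario(config)
    r_min, _ = result.pmf.minimum()
    minima = find_minima(result.pmf, prominence=1.0)
    print(f"C15 {label}:")
    print(f"  primary minimum at r_ee = {r_min:.2f} A "
          f"(all-trans length {cf.all_trans_length(cf.ChainTopology(15)):.2f} A)")
    for r, g in minima[1:3]:
        print(f"  secondary minimum at r_ee = {r:.2f} A, +{g:.1f} kJ/mol")
    print(f"  dominant conformer motif: {result.motif}")

print("\nThe free chain extends; inside the 13 A cavity a C15 chain cannot,")
print("so short-r_ee (folded) basins gain weight — the onset of the")
print("extended -> hairpin progression seen with growing guest length.")
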