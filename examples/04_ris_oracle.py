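"""The rotational-isomeric-state oracle: exact landscapes by enumeration.

A chain whose dihedrals take only {t, g+, g-} has 3^m states; for m <= 12
the full partition function is summed exactly, giving ground-truth
G(T, r_ee), trans fractions and chain dimensions that validate the
Monte Carlo sampler.
"""

import numpy as np

import chainfel as cf
from chainfel.oracles import RISModel, ris_enumerate, ris_sample

model = RISModel(cf.ChainTopology(9))  # 6 dihedrals, 729 states
exact = ris_enumerate(model, [298.15, 400.0, 500.0])

for t, frac, rms in zip(exact.temperatures, exact.trans_fraction, exact.rms_ree):
    print(f"T = {t:6.1f} K: trans fraction = {frac:.3f},  "
          f"<r_ee^2>^1/2 = {rms:.2f} A")

r_samp, _, acc = ris_sample(model, temperature=298.15, n_steps=500_000, seed=3)
print(f"\nMC sampling of the same model (acceptance {acc:.2f}):")
print(f"  sampled <r_ee^2>^1/2 = {np.sqrt(np.mean(r_samp**2)):.2f} A "
      f"(exact {exact.rms_ree[0]:.2f} A)")
print("\nHeating melts trans order: the trans fraction and the chain's")
print("extension both drop, exactly as the enumerated weights dictate.")
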