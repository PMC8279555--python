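"""Enthalpy/entropy decomposition of a multi-temperature free-energy surface.

Exact G(T, r_ee) from the RIS oracle over the ten-temperature replica
ladder is fit per bin to G = A + B(T - T0) + C*T*ln(T/T0); temperature
derivatives split the 298.15 K landscape into H and -TS.
"""

import numpy as np

import chainfel as cf
from chainfel.oracles import RISModel, ris_enumerate
from chainfel.sampling import REFERENCE_LADDER
from chainfel.thermo import MultiTemperaturePMF, enthalpy_entropy, fit_gibbs_helmholtz

model = RISModel(cf.ChainTopology(9))
ladder = np.array(REFERENCE_LADDER)
exact = ris_enumerate(model, ladder)

fit = fit_gibbs_helmholtz(
    MultiTemperaturePMF(ladder, exact.r, exact.G), T0=298.15,
)
h, minus_ts = enthalpy_entropy(fit, 298.15)

well = exact.P[0] >= 0.01
print("  r / A     G        H       -TS   (kJ/mol at 298.15 K)")
for r, g, hh, ts in zip(exact.r[well], fit.G0[well], h[well], minus_ts[well]):
    print(f"{r:7.2f} {g:7.2f} {hh:8.2f} {ts:8.2f}")

i_max = np.nanargmax(np.where(well, exact.r, np.nan))
print(f"\nAt maximal extension (r = {exact.r[i_max]:.2f} A) the enthalpy is "
      f"most favorable\n(H = {h[i_max]:.2f}) while the entropy term is most "
      f"unfavorable (-TS = {minus_ts[i_max]:.2f}):\nthe all-trans state is "
      "energetically ideal but uniquely ordered, so the free-\nenergy "
      "minimum sits at slightly shorter r_ee — the central competition of "
      "the model.")
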