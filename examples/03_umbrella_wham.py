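"""Umbrella sampling + WHAM on a fixture with an exactly known answer.

Biased histograms are drawn from the closed-form Gaussians implied by a
quadratic free-energy surface U(r) = 0.5*kappa*r^2 under harmonic windows
(force constant 50 kJ/mol/A^2, 0.5 A spacing — the reference protocol);
WHAM must reconstruct the quadratic.
"""

import numpy as np

from chainfel.oracles import harmonic_umbrella_fixture
from chainfel.wham import KB, wham_solve

KT = KB * 298.15

hist, true_g = harmonic_umbrella_fixture(
    kappa=2.0, centers=np.arange(-4.0, 4.01, 0.5),
    bias_k=50.0, n_per_window=20_000, seed=11,
)
pmf = wham_solve(hist)

ok = np.isfinite(pmf.G) & (hist.counts.sum(axis=0) >= 100)
diff = pmf.G[ok] - true_g[ok]
diff -= diff.mean()
rmse = np.sqrt(np.mean(diff**2))

print(f"{hist.n_windows} windows, {hist.totals.sum()} samples total")
print(f"WHAM converged in {pmf.iterations} iterations "
      f"(residual {pmf.residual:.2e} kJ/mol)")
print(f"RMSE vs the exact quadratic: {rmse / KT:.4f} kT over {ok.sum()} bins")
print("\nValues well below 0.05 kT mean the estimator reproduces the")
print("underlying free-energy surface to within sampling noise.")
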