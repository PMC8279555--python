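# Methods

## The coarse-grained chain model

The guest is a united-atom chain of n carbon sites with fixed bond length
l = 1.53 Å and backbone angle θ = 112.7° (typical alkane values; both
configurable). A conformation is the vector of its m = n − 3 backbone
dihedrals, IUPAC sign convention with *trans* = 180°; Cartesian
coordinates are rebuilt deterministically by natural-extension reference
frames, so internal coordinates are the only degrees of freedom.

The Hamiltonian has four switchable terms (kJ/mol, Å):

* **Torsion** — U(φ) = Σₖ cₖ cosᵏ(φ − 180°). Defaults are
  Ryckaert–Bellemans butane coefficients rescaled so the gauche–trans gap
  is exactly 2.9 kJ/mol; the trans→gauche barrier then sits at
  ≈ 12.2 kJ/mol, inside the 12–15 kJ/mol range typical of alkane force
  fields. The all-*trans* torsional energy is zero by construction.
* **Intramolecular Lennard-Jones** — 4ε[(σ/r)¹² − (σ/r)⁶] with
  TraPPE-like CH₂ parameters (ε = 0.39 kJ/mol, σ = 3.95 Å) between carbon
  pairs separated by more than three bonds; no 1-4 scaling. This supplies
  the ring-closure attraction that stabilizes compact states of long
  chains.
* **Confinement** — a soft prolate-ellipsoidal wall with semi-axes
  a = 4.0 Å (equatorial) and c = 6.5 Å (axial), i.e. an 8 Å-wide,
  13 Å-long interior matching the inferred dimer cavity, charging
  stiffness·max(0, s − 1)² per site with s the scaled ellipsoidal radius
  (stiffness 100 kJ/mol per unit²). The interior shape function of the
  real dimer is not known; the soft ellipsoid is a modeling choice.
  Because the sampler works in torsion space, the wall energy is
  evaluated with the chain centered and principal-axis-aligned in the
  cavity frame — rigid-body placement is relaxed rather than sampled,
  which assumes the guest always sits optimally aligned in the prolate
  cavity.
* **Umbrella bias** — ½k(r_ee − r₀)² on the end-to-end distance, with
  the reference force constant k = 50 kJ mol⁻¹ Å⁻² and centers every
  0.5 Å (0.32 Å for replica-ladder runs) as defaults.

## Sampling

All observables are canonical equilibrium averages, so Metropolis Monte
Carlo in torsion space replaces molecular dynamics: any ergodic sampler
obeying detailed balance yields the same histograms. Moves mix small
single-dihedral perturbations (±30° default, 80%) with pivot moves (full
uniform resample of one dihedral, 20%), the latter decorrelating long
chains. Inner loops are numba-compiled; a full five-chain confined PMF
sweep runs in about a minute on one core. Step counts are
acceptance-driven choices with no MD-time equivalent: umbrella production
defaults to 2×10⁴–4×10⁴ steps per window after 2×10³–5×10³ equilibration
steps, sizes at which the WHAM statistical error is well below the
features of interest for these chain lengths.

Replica exchange propagates one replica per ladder temperature within
each umbrella window (default ladder: the ten temperatures
298.15–500 K); after every exchange interval a random adjacent pair
attempts a configuration swap with acceptance
min(1, exp((β_i − β_j)(E_i − E_j))) on the total biased potential energy.
A single-temperature ladder degenerates bit-identically to plain umbrella
sampling. All streams derive from one integer seed through
`SeedSequence(seed, spawn_key=…)`, making every histogram reproducible.

## WHAM

The unbiased distribution solves the standard self-consistent equations
on a shared uniform grid (0.1 Å bins by default), with bias energies
evaluated at bin centers, direct fixed-point iteration, and a convergence
tolerance of 10⁻⁶ kJ/mol on max|ΔF_i| (10⁵ iteration cap). Windows must
form a single overlap component; bins with zero aggregate counts are
reported as missing (NaN), never interpolated; profiles are anchored so
the minimum is exactly zero. Uncertainties, when requested, come from a
Bayesian bootstrap over windows (Dirichlet(1,…,1) weights, 50 resamples
default). Note that this bootstrap measures window-to-window
consistency: rescaling all counts by a common factor leaves it unchanged,
so it does not shrink like 1/√N with per-window sample size. The test
suite cross-checks the fixed point against an independent minimization of
the convex WHAM log-likelihood and against analytic fixtures.

## Thermodynamic decomposition

Multi-temperature PMFs are fit per bin by least squares to
G(T, r) = A(r) + B(r)(T − T₀) + C(r)·T·ln(T/T₀), T₀ = 298.15 K. This
is the unique three-coefficient form with a temperature-independent heat
capacity (dH/dT = −C) satisfying G(T₀) = A, H(T₀) = A − (B + C)T₀ and
−T₀S(T₀) = (B + C)T₀ exactly; the identity G = H − TS holds at every
temperature by construction. Each temperature's PMF is min-anchored
before fitting (only free-energy shapes are available from WHAM), so the
absolute scale of A inherits that per-temperature anchor. Weighted fits
are used when bootstrap uncertainties are attached.

Two caveats the tests quantify rather than hide:

* H(T₀) is a derivative at the ladder's endpoint; error propagation
  through the design matrix amplifies per-point G noise by a factor of
  ≈ 6.6 for the default ladder. The parameter-recovery test asserts the
  exact sampling-theory prediction of this amplification.
* The model class is deliberately minimal. On exact RIS surfaces, whose
  heat capacity does vary with temperature, the fitted H(T₀) deviates
  from the exact finite-difference −T²∂(G/T)/∂T by up to ≈ 0.2 kJ/mol on
  sparsely populated bins; agreement is therefore judged as an RMS over
  well-populated bins (≥ 0.1% of the population), where it is
  < 0.1 kJ/mol.

## Dihedral PCA and motifs

Dihedrals are embedded as (cos φ, sin φ) pairs to remove the ±180°
wrap, and the covariance of the embedded matrix is diagonalized; the two
leading eigenvectors define the projection plane. The probability mode is
located with a 50×50 2D histogram (simplest reading of "maximum in
probability"; KDE would be a smooth alternative) and the dominant
conformer is the sampled frame nearest the mode, ties broken to the
lowest frame index.

Motif rules are intentionally coarse, standing in for visual inspection:
the backbone is principal-axis aligned, successive 3-bond segments give
direction vectors, and a turn is a sign reversal of the axial component
persisting at least 2 segments — 0 turns → *linear*, 1 → *hairpin*,
≥ 2 → *chicane*. Extended and helical conformers are deliberately merged
into one *linear* family, since they do not form thermodynamically
distinct basins. The r_ee consistency thresholds (linear expects
r_ee > 0.75 of the all-trans length, hairpin < 0.5) are advisory
diagnostics, config-exposed, validated only on constructed fixtures. A
geometric note: a run of three same-signed gauche dihedrals does *not*
reverse an alkane's direction; the canonical tight fold used in the
fixtures is g⁺g⁺tg⁺g⁺, which folds an 18-carbon chain to r_ee ≈ 5.8 Å.

## Oracles and the synthetic-data conditions

* **RIS enumeration** — dihedrals restricted to {180°, ±60°} with a
  gauche penalty ε_g = 2.9 kJ/mol (matching the continuous torsion gap)
  and a syn-pentane penalty ε_pent = 8 kJ/mol for adjacent g⁺g⁻ pairs
  (literature-typical; an exclusion flag makes it infinite). All 3^m
  states (m ≤ 12) are summed exactly, yielding ground-truth G(T, r),
  trans fractions and ⟨r_ee²⟩^½. A discrete-state Metropolis sampler on
  the same model validates sampling against enumeration.
* **Analytic umbrella fixture** — windows on U(r) = ½κr² sample exact
  Gaussians (mean k·r₀/(κ+k), variance kT/(κ+k)). Defaults κ = 2
  kJ mol⁻¹ Å⁻², 17 windows at 0.5 Å spacing with the reference k = 50,
  and 2×10⁴ draws per window — per-window statistics at the scale of
  long MD windows, placing statistical error below the estimator's
  binning floor so the WHAM check measures the estimator, not the noise.
* **Two-cluster dihedral fixture** — wrapped-Gaussian mixture with
  retained labels for validating mode finding and variance capture.

What the generators do *not* emulate: solvent (free-chain landscapes in
water closely track vacuum for these lengths), host flexibility,
electrostatics, and the all-atom torsion surface. Passing tests therefore
demonstrate correctness of the estimators and the qualitative confinement
physics (entropic shortening of free chains, compression and fold
stabilization in the cavity, enthalpy–entropy competition at full
extension), not force-field-accurate free energies for the experimental
system. In the same spirit, the confinement acceptance check spans chain
lengths C13–C21, which bracket and exceed the 13 Å cavity: chains shorter
than the cavity (C11–C12) are essentially unfrustrated and show
free-chain behavior, so the monotonic stabilization of the folded basin
with length is a statement about guests at least commensurate with the
interior.

## Numerical choices and degenerate inputs

* Histogram bin width 0.1 Å; WHAM tolerance 10⁻⁶ kJ/mol; 10⁵ iteration cap.
* A dihedral of exactly 0° classifies as g⁺ (documented tie-break);
  measured torsions of exactly −180° report as +180°.
* Monte Carlo volume integration requires ≥ 10⁵ points and reports the
  binomial standard error; fixed seeds give bit-identical estimates.
* Chains with fewer than three 3-bond segments cannot be motif-classified
  and raise; the pipeline records `None` for such chains.
* Duplicate ladder temperatures make the thermo fit rank-deficient and
  raise; fewer than three temperatures is a usage error.
* Zero-strength terms (k_w → 0, k → 0) reduce exactly to the unconfined /
  unbiased model.

## Known limitations

* The wall's principal-axis alignment is a surrogate for sampling
  rigid-body placement; for near-spherical intermediates the principal
  axis is weakly determined, though the chains studied here are always
  elongated enough for it to be stable.
* WHAM evaluates bias energies at bin centers; with k = 50 and 0.1 Å bins
  this contributes well under 0.01 kT for continuously distributed
  samples, but can bias discrete-state (RIS) umbrella runs, which is why
  RIS validation uses unbiased sampling plus Boltzmann inversion.
* The Bayesian window bootstrap quantifies inter-window consistency, not
  total sampling error.
* Replica-exchange swap scheduling (random adjacent pair per interval) is
  a choice; the original study does not describe its scheme.
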