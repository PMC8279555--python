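"""Synthetic inputs with exactly known ground truth.

Every pipeline stage is testable without external data through three
generators:

* :func:`ris_enumerate` — a rotational-isomeric-state (RIS) chain whose
  dihedrals take only the three states {t = 180°, g+ = 60°, g− = −60°}.
  With m ≤ 12 dihedrals all 3^m states are enumerable, giving the *exact*
  multi-temperature free-energy surface G(T, r_ee), trans fractions and
  ⟨r_ee²⟩^(1/2) — the oracle for WHAM and for the enthalpy/entropy fit.
* :func:`harmonic_umbrella_fixture` — biased histograms drawn from the
  closed-form Gaussians of a quadratic PMF under harmonic windows, the
  analytic oracle for WHAM.
* :func:`two_cluster_dihedral_fixture` — a wrapped-Gaussian mixture of
  dihedral frames with retained labels, the oracle for DPCA.

:func:`confined_chain_scenario` assembles a complete, seeded run
configuration for the full sampler → WHAM → thermo → DPCA pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .config import RunConfig
from .energy import CavityWall
from .geometry import ChainTopology, all_trans_length
from .wham import KB, BiasedHistogramSet

__all__ = [
    "RISModel",
    "ExactLandscape",
    "RIS_ANGLES",
    "ris_states",
    "ris_enumerate",
    "ris_sample",
    "ris_histograms",
    "harmonic_umbrella_fixture",
    "two_cluster_dihedral_fixture",
    "confined_chain_scenario",
]

#: Dihedral angle (degrees) of each RIS state index: 0 = t, 1 = g+, 2 = g−.
RIS_ANGLES = np.array([180.0, 60.0, -60.0])

_MAX_STATES = 531_441  # 3^12


@dataclass(frozen=True)
class RISModel:
    """Discrete trans/gauche chain with gauche and pentane-effect penalties.

    ``eps_g`` (kJ/mol) is charged per gauche dihedral; ``eps_pent`` per
    adjacent g+g− or g−g+ pair (the syn-pentane clash).  Setting
    ``exclude_pentane`` removes those states outright (infinite penalty).
    """

    topology: ChainTopology
    eps_g: float = 2.9
    eps_pent: float = 8.0
    exclude_pentane: bool = False

    def __post_init__(self) -> None:
        m = self.topology.n_dihedrals
        if m < 1:
            raise ValueError("RIS model needs at least one dihedral")
        if 3**m > _MAX_STATES:
            raise ValueError(
                f"3^{m} states exceed the enumeration budget (m <= 12)"
            )

    @property
    def n_dihedrals(self) -> int:
        return self.topology.n_dihedrals


@dataclass(frozen=True)
class ExactLandscape:
    """Exact multi-temperature observables of an enumerated RIS chain.

    ``G`` is −kT·ln P(T, r) per bin, min-anchored per temperature, NaN on
    empty bins; ``P`` sums to one per temperature.
    """

    temperatures: np.ndarray
    bin_edges: np.ndarray
    P: np.ndarray
    G: np.ndarray
    trans_fraction: np.ndarray
    rms_ree: np.ndarray

    @property
    def r(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def free_energy(self, temperature: float) -> np.ndarray:
        """G(T, r) for one of the enumerated temperatures."""
        idx = np.flatnonzero(np.isclose(self.temperatures, temperature))
        if idx.size == 0:
            raise KeyError(f"temperature {temperature} K not enumerated")
        return self.G[idx[0]]


def ris_states(model: RISModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Enumerate all states: (state digits (S, m), energies (S,), r_ee (S,)).

    State ``s`` has index ``Σ_k s_k·3^k`` (digit k is dihedral k); energies
    are in kJ/mol, with +inf for pentane-excluded states when the model
    excludes them.
    """
    m = model.n_dihedrals
    n_states = 3**m
    idx = np.arange(n_states)
    digits = (idx[:, None] // 3 ** np.arange(m)[None, :]) % 3

    energies = model.eps_g * np.count_nonzero(digits, axis=1).astype(float)
    a = digits[:, :-1]
    b = digits[:, 1:]
    pent = np.sum(((a == 1) & (b == 2)) | ((a == 2) & (b == 1)), axis=1)
    if model.exclude_pentane:
        energies = np.where(pent > 0, np.inf, energies)
    else:
        energies = energies + model.eps_pent * pent

    angles = np.deg2rad(RIS_ANGLES[digits])
    ree = _kernels.batch_ree(
        angles, model.topology.bond_length,
        np.deg2rad(model.topology.bond_angle),
    )
    return digits, energies, ree


def _default_edges(topology: ChainTopology, bin_width: float) -> np.ndarray:
    r_max = all_trans_length(topology) + 2.0 * bin_width
    n_bins = int(np.ceil(r_max / bin_width))
    return np.linspace(0.0, n_bins * bin_width, n_bins + 1)


def ris_enumerate(model: RISModel,
                  temperatures: float | np.ndarray,
                  bin_edges: np.ndarray | None = None,
                  bin_width: float = 0.1) -> ExactLandscape:
    """Exact Boltzmann landscape of the RIS chain at one or many temperatures.

    All 3^m states are enumerated; for each temperature the states are
    Boltzmann-weighted into r_ee bins, giving G(T, r) = −kT·ln P(T, r)
    (min-anchored), the exact trans fraction and ⟨r_ee²⟩^(1/2).
    """
    temps = np.atleast_1d(np.asarray(temperatures, dtype=float))
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive")
    digits, energies, ree = ris_states(model)
    if bin_edges is None:
        bin_edges = _default_edges(model.topology, bin_width)
    bin_edges = np.asarray(bin_edges, dtype=float)
    m = model.n_dihedrals

    n_t = temps.size
    n_b = bin_edges.size - 1
    P = np.zeros((n_t, n_b))
    G = np.full((n_t, n_b), np.nan)
    trans_frac = np.zeros(n_t)
    rms = np.zeros(n_t)
    trans_count = (digits == 0).sum(axis=1)

    for i, t in enumerate(temps):
        beta = 1.0 / (KB * t)
        finite = np.isfinite(energies)
        w = np.zeros_like(energies)
        w[finite] = np.exp(-beta * (energies[finite] - energies[finite].min()))
        w /= w.sum()
        P[i], _ = np.histogram(ree, bins=bin_edges, weights=w)
        occ = P[i] > 0
        G[i, occ] = -KB * t * np.log(P[i, occ])
        G[i, occ] -= G[i, occ].min()
        trans_frac[i] = float(w @ trans_count) / m
        rms[i] = float(np.sqrt(w @ ree**2))

    return ExactLandscape(
        temperatures=temps,
        bin_edges=bin_edges,
        P=P,
        G=G,
        trans_fraction=trans_frac,
        rms_ree=rms,
    )


def ris_sample(model: RISModel,
               temperature: float = 298.15,
               n_steps: int = 1_000_000,
               equilibration: int = 10_000,
               stride: int = 1,
               bias_k: float = 0.0,
               bias_r0: float = 0.0,
               seed: int = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """Metropolis MC over the discrete RIS states, optionally umbrella-biased.

    Moves flip one dihedral to one of its two alternative states; the
    chain's r_ee comes from a precomputed per-state lookup.  Returns
    (r_ee samples, state digit samples, acceptance rate).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    m = model.n_dihedrals
    _, energies, ree = ris_states(model)
    if model.exclude_pentane:
        # the kernel works with finite penalties; emulate exclusion
        eps_pent = 1e6
    else:
        eps_pent = model.eps_pent
    beta = 1.0 / (KB * temperature)
    state = np.zeros(m, dtype=np.int64)  # all trans
    if equilibration > 0:
        _kernels.ris_mc_chunk(
            state, equilibration, equilibration + 1, beta, model.eps_g,
            eps_pent, ree, bias_k, bias_r0, (seed * 2_654_435 + 1) % (2**31),
        )
    r_samp, s_samp, n_acc = _kernels.ris_mc_chunk(
        state, n_steps, stride, beta, model.eps_g, eps_pent, ree,
        bias_k, bias_r0, seed % (2**31),
    )
    return r_samp, s_samp, n_acc / n_steps


def ris_histograms(model: RISModel,
                   temperature: float = 298.15,
                   n_steps: int = 1_000_000,
                   bin_edges: np.ndarray | None = None,
                   bin_width: float = 0.1,
                   seed: int = 0) -> BiasedHistogramSet:
    """A single unbiased RIS sampling run packaged as a one-window histogram set.

    WHAM on this degenerate set collapses to Boltzmann inversion, so the
    resulting PMF can be compared directly against :func:`ris_enumerate`.
    """
    if bin_edges is None:
        bin_edges = _default_edges(model.topology, bin_width)
    r_samp, _, _ = ris_sample(
        model, temperature=temperature, n_steps=n_steps, seed=seed,
    )
    counts, _ = np.histogram(r_samp, bins=bin_edges)
    return BiasedHistogramSet(
        bin_edges=np.asarray(bin_edges, dtype=float),
        counts=counts[None, :],
        bias_k=np.zeros(1),
        bias_r0=np.zeros(1),
        temperature=temperature,
        metadata={"seed": seed, "n_steps": n_steps, "sampler": "RIS-MC"},
    )


def harmonic_umbrella_fixture(kappa: float,
                              centers: np.ndarray,
                              temperature: float = 298.15,
                              bias_k: float = 50.0,
                              n_per_window: int = 20_000,
                              seed: int = 0,
                              bin_edges: np.ndarray | None = None,
                              bin_width: float = 0.1,
                              ) -> tuple[BiasedHistogramSet, np.ndarray]:
    """Analytic umbrella fixture on the quadratic PMF U(r) = ½·κ·r².

    Window i samples the exact Gaussian implied by ½κr² + ½k(r − r0_i)²:
    mean k·r0_i/(κ + k), variance kT/(κ + k).  Returns the histogram set
    together with the true min-anchored PMF evaluated at the bin centers.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    kt = KB * temperature
    var = kt / (kappa + bias_k)
    means = bias_k * centers / (kappa + bias_k)
    if bin_edges is None:
        lo = means.min() - 6.0 * np.sqrt(var)
        hi = means.max() + 6.0 * np.sqrt(var)
        n_bins = int(np.ceil((hi - lo) / bin_width))
        bin_edges = lo + bin_width * np.arange(n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    rng = np.random.default_rng(seed)
    counts = np.zeros((centers.size, bin_edges.size - 1), dtype=np.int64)
    for i, mu in enumerate(means):
        samples = rng.normal(mu, np.sqrt(var), size=n_per_window)
        counts[i], _ = np.histogram(samples, bins=bin_edges)
    hist = BiasedHistogramSet(
        bin_edges=bin_edges,
        counts=counts,
        bias_k=np.full(centers.size, bias_k),
        bias_r0=centers,
        temperature=temperature,
        metadata={"seed": seed, "kappa": kappa, "n_per_window": n_per_window,
                  "sampler": "analytic-gaussian"},
    )
    r = hist.bin_centers
    true_g = 0.5 * kappa * r**2
    true_g -= true_g.min()
    return hist, true_g


def two_cluster_dihedral_fixture(m: int,
                                 centers: np.ndarray,
                                 spreads: float | np.ndarray = 10.0,
                                 weights: tuple[float, float] = (0.7, 0.3),
                                 n: int = 2_000,
                                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Wrapped-Gaussian dihedral frames around two cluster centers.

    ``centers`` is (2, m) in degrees; ``spreads`` a scalar or per-cluster
    pair of circular standard deviations.  Returns (angles (n, m), labels
    (n,)) with labels 0/1 identifying the generating cluster.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (2, m):
        raise ValueError(f"centers must be (2, {m})")
    w = np.asarray(weights, dtype=float)
    if w.min() < 0 or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    spreads = np.broadcast_to(np.asarray(spreads, dtype=float), (2,))
    rng = np.random.default_rng(seed)
    labels = rng.choice(2, size=n, p=w)
    noise = rng.normal(0.0, 1.0, size=(n, m)) * spreads[labels][:, None]
    angles = centers[labels] + noise
    angles = np.mod(angles + 180.0, 360.0) - 180.0
    angles[angles == -180.0] = 180.0
    return angles, labels


def confined_chain_scenario(n_carbons: int,
                            cavity: CavityWall | None = None,
                            seed: int = 0,
                            spacing: float = 0.5,
                            n_steps: int = 30_000,
                            temperature: float = 298.15) -> RunConfig:
    """A ready-to-run configuration for one chain length in (or out of) the cavity.

    Umbrella windows span methyl contact (~3.5 Å) to just past the
    all-*trans* extension (capped near the cavity length when confined,
    plus wall give); all stages share the single global seed.
    """
    if not 4 <= n_carbons <= 30:
        raise ValueError("n_carbons must lie in 4..30")
    topo = ChainTopology(n_carbons=n_carbons)
    r_top = all_trans_length(topo) + spacing
    config = RunConfig(seed=seed)
    config.chain.n_carbons = n_carbons
    config.mc.temperature = temperature
    config.mc.n_steps = n_steps
    config.umbrella.r_min = 3.5
    config.umbrella.r_max = float(r_top)
    config.umbrella.spacing = spacing
    if cavity is not None:
        config.cavity.enabled = True
        config.cavity.a = cavity.a
        config.cavity.c = cavity.c
        config.cavity.stiffness = cavity.stiffness
    return config
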