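"""Canonical Monte Carlo sampling of the chain model.

Monte Carlo in torsion space replaces the molecular-dynamics integration
of the original study: every target observable is an equilibrium average
over the canonical ensemble, so any ergodic sampler obeying detailed
balance produces the same histograms.  The move set mixes small
single-dihedral perturbations with pivot moves (a dihedral resampled
uniformly), which rotate the downstream chain segment and decorrelate
long chains quickly.

Three layers are provided:

* :func:`metropolis_step` — a single textbook accept/reject decision;
* :func:`run_umbrella_windows` — one biased simulation per umbrella window
  along the end-to-end distance, returning a :class:`~chainfel.wham.BiasedHistogramSet`;
* :func:`run_remd_umbrella` — the same umbrella schedule replicated over a
  temperature ladder with Metropolis-accepted configuration swaps between
  adjacent temperatures (replica exchange), returning one histogram set
  per temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from . import _kernels
from .energy import CavityWall, PotentialParams, UmbrellaBias
from .errors import ChainfelError
from .geometry import ChainTopology, all_trans_length
from .wham import BiasedHistogramSet

__all__ = [
    "KB",
    "MCConfig",
    "WindowSchedule",
    "REMDConfig",
    "MCState",
    "metropolis_step",
    "remd_exchange_decision",
    "run_umbrella_windows",
    "run_remd_umbrella",
    "REMDResult",
    "REFERENCE_LADDER",
]

#: Gas constant in kJ/(mol K); energies are molar throughout.
KB = 0.008314462618

#: The ten-temperature replica-exchange ladder used in the reference study, K.
REFERENCE_LADDER: tuple[float, ...] = (
    298.15, 317.79, 338.46, 360.20, 383.13,
    407.22, 432.55, 459.21, 487.29, 500.0,
)


@dataclass(frozen=True)
class MCConfig:
    """Settings for a single canonical Monte Carlo run.

    ``max_step`` is the half-width (degrees) of the uniform single-dihedral
    perturbation; ``pivot_prob`` is the probability of a pivot move (full
    uniform resample of one dihedral) instead.
    """

    temperature: float = 298.15
    n_steps: int = 20_000
    equilibration: int = 2_000
    max_step: float = 30.0
    pivot_prob: float = 0.2
    sample_stride: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if not 0.0 <= self.pivot_prob <= 1.0:
            raise ValueError("pivot_prob must lie in [0, 1]")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)


@dataclass(frozen=True)
class WindowSchedule:
    """Umbrella window layout along the end-to-end distance.

    ``centers`` must be strictly increasing; the reference protocol spaces
    them evenly every 0.5 Å (0.32 Å for the replica-exchange runs) with a
    force constant of 50 kJ/(mol Å²).
    """

    centers: tuple[float, ...]
    k: float = 50.0

    def __post_init__(self) -> None:
        centers = tuple(float(c) for c in self.centers)
        object.__setattr__(self, "centers", centers)
        if len(centers) < 1:
            raise ValueError("schedule needs at least one window")
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("window centers must be strictly increasing")
        if self.k < 0:
            raise ValueError("force constant must be nonnegative")

    @classmethod
    def from_range(cls, r_min: float, r_max: float, spacing: float = 0.5,
                   k: float = 50.0) -> "WindowSchedule":
        """Evenly spaced centers from ``r_min`` up to (at least) ``r_max``."""
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        n = int(np.ceil((r_max - r_min) / spacing)) + 1
        return cls(tuple(r_min + spacing * i for i in range(n)), k=k)

    @property
    def spacing(self) -> float:
        if len(self.centers) < 2:
            return 0.0
        return self.centers[1] - self.centers[0]

    def biases(self) -> list[UmbrellaBias]:
        return [UmbrellaBias(k=self.k, r0=c) for c in self.centers]

    def check_overlap(self, temperature: float) -> bool:
        """Heuristic: spacing should not exceed 2·sqrt(kT/k) for overlap."""
        if len(self.centers) < 2 or self.k == 0:
            return True
        sigma = np.sqrt(KB * temperature / self.k)
        return self.spacing <= 2.0 * sigma


@dataclass(frozen=True)
class REMDConfig:
    """Replica-exchange setup over a temperature ladder."""

    ladder: tuple[float, ...] = REFERENCE_LADDER
    exchange_interval: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        ladder = tuple(float(t) for t in self.ladder)
        object.__setattr__(self, "ladder", ladder)
        if len(ladder) < 1:
            raise ValueError("ladder must not be empty")
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("temperature ladder must be strictly increasing")
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval must be >= 1")


class MCState(NamedTuple):
    """A sampler state with its energy (kJ/mol)."""

    value: object
    energy: float


def metropolis_step(state: MCState, proposal: MCState, beta: float,
                    u: float) -> MCState:
    """One Metropolis decision: accept iff u < min(1, exp(−β·ΔE)).

    Returns the proposal on acceptance, the prior state otherwise.
    """
    if not 0.0 <= u < 1.0:
        raise ValueError("u must be uniform on [0, 1)")
    de = proposal.energy - state.energy
    if de <= 0.0 or u < np.exp(-beta * de):
        return proposal
    return state


def remd_exchange_decision(e_i: float, e_j: float, beta_i: float,
                           beta_j: float, u: float) -> bool:
    """Replica-exchange swap criterion: u < min(1, exp((β_i − β_j)(E_i − E_j)))."""
    if not 0.0 <= u < 1.0:
        raise ValueError("u must be uniform on [0, 1)")
    arg = (beta_i - beta_j) * (e_i - e_j)
    return arg >= 0.0 or u < np.exp(arg)


# ---------------------------------------------------------------------------
# umbrella orchestration
# ---------------------------------------------------------------------------

def _kernel_args(topology: ChainTopology, params: PotentialParams,
                 wall: CavityWall | None):
    tors = np.asarray(params.torsion_coeffs, dtype=float)
    use_wall = wall is not None
    a = wall.a if wall else 1.0
    c = wall.c if wall else 1.0
    kw = wall.stiffness if wall else 0.0
    return (topology.bond_length, np.deg2rad(topology.bond_angle), tors,
            params.lj_epsilon, params.lj_sigma, params.exclusion_depth,
            use_wall, a, c, kw)


def _subseed(seed: int, *key: int) -> int:
    """A stable 31-bit stream seed derived from (seed, key)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _default_bins(topology: ChainTopology, bin_width: float) -> np.ndarray:
    r_max = all_trans_length(topology) + 2.0 * bin_width
    n_bins = int(np.ceil(r_max / bin_width))
    return np.linspace(0.0, n_bins * bin_width, n_bins + 1)


def run_umbrella_windows(topology: ChainTopology,
                         params: PotentialParams,
                         wall: CavityWall | None,
                         schedule: WindowSchedule,
                         mc: MCConfig,
                         bin_edges: np.ndarray | None = None,
                         bin_width: float = 0.1,
                         keep_dihedrals: bool = False) -> BiasedHistogramSet:
    """Run one biased MC simulation per umbrella window.

    Each window starts from the all-*trans* chain, equilibrates, then
    histograms the end-to-end distance onto the shared bin grid.  Raises
    :class:`~chainfel.errors.ChainfelError` if a window collects no
    samples; warns if adjacent windows fail to share occupied bins.
    """
    if bin_edges is None:
        bin_edges = _default_bins(topology, bin_width)
    bin_edges = np.asarray(bin_edges, dtype=float)
    m = topology.n_dihedrals
    args = _kernel_args(topology, params, wall)
    counts = np.zeros((len(schedule.centers), len(bin_edges) - 1), dtype=np.int64)
    dihedrals: list[np.ndarray] = []
    acceptance = np.zeros(len(schedule.centers))

    for w, r0 in enumerate(schedule.centers):
        phi = np.full(m, np.pi)
        seed_w = _subseed(mc.seed, w)
        # equilibration: discard, keep final state
        if mc.equilibration > 0:
            _kernels.mc_chunk(
                phi, mc.equilibration, mc.equilibration + 1, mc.beta, *args,
                schedule.k, r0, np.deg2rad(mc.max_step), mc.pivot_prob,
                _subseed(mc.seed, w, 1),
            )
        r_samp, dih_samp, n_acc, _ = _kernels.mc_chunk(
            phi, mc.n_steps, mc.sample_stride, mc.beta, *args,
            schedule.k, r0, np.deg2rad(mc.max_step), mc.pivot_prob, seed_w,
        )
        if r_samp.size == 0:
            raise ChainfelError(
                f"window {w} (center {r0:.3f} Å) produced zero samples"
            )
        counts[w], _ = np.histogram(r_samp, bins=bin_edges)
        acceptance[w] = n_acc / mc.n_steps
        if keep_dihedrals:
            dihedrals.append(np.rad2deg(dih_samp))

    hist = BiasedHistogramSet(
        bin_edges=bin_edges,
        counts=counts,
        bias_k=np.full(len(schedule.centers), schedule.k),
        bias_r0=np.array(schedule.centers),
        temperature=mc.temperature,
        metadata={
            "seed": mc.seed,
            "n_steps": mc.n_steps,
            "equilibration": mc.equilibration,
            "sampler": "torsion-MC",
            "mean_acceptance": float(acceptance.mean()),
        },
        dihedrals=dihedrals if keep_dihedrals else None,
    )
    gaps = hist.overlap_gaps()
    if gaps:
        warnings.warn(
            f"adjacent windows without shared occupied bins: {gaps}",
            stacklevel=2,
        )
    return hist


@dataclass
class REMDResult:
    """Per-temperature histogram sets plus exchange diagnostics."""

    histograms: dict[float, BiasedHistogramSet]
    swap_attempts: int
    swap_accepts: int
    replica_trace: np.ndarray  # (n_windows, n_cycles) replica id at ladder rung 0

    @property
    def swap_acceptance(self) -> float:
        if self.swap_attempts == 0:
            return float("nan")
        return self.swap_accepts / self.swap_attempts


def run_remd_umbrella(topology: ChainTopology,
                      params: PotentialParams,
                      wall: CavityWall | None,
                      schedule: WindowSchedule,
                      remd: REMDConfig,
                      mc: MCConfig,
                      bin_edges: np.ndarray | None = None,
                      bin_width: float = 0.1,
                      keep_dihedrals: bool = False) -> REMDResult:
    """Umbrella sampling replicated over a temperature ladder with exchanges.

    For every umbrella window a ladder of replicas is propagated; after
    each ``remd.exchange_interval`` production steps a random adjacent
    temperature pair attempts a configuration swap with the standard
    replica-exchange criterion on the total (biased) potential energy.
    Samples are accumulated per temperature rung.
    """
    if bin_edges is None:
        bin_edges = _default_bins(topology, bin_width)
    bin_edges = np.asarray(bin_edges, dtype=float)
    ladder = remd.ladder
    n_t = len(ladder)
    if n_t == 1:
        # degenerate ladder: no exchanges possible, identical to plain
        # umbrella sampling at that temperature with the same seed
        single = replace(mc, temperature=ladder[0], seed=remd.seed)
        hist = run_umbrella_windows(
            topology, params, wall, schedule, single,
            bin_edges=bin_edges, keep_dihedrals=keep_dihedrals,
        )
        return REMDResult(
            histograms={ladder[0]: hist},
            swap_attempts=0,
            swap_accepts=0,
            replica_trace=np.zeros((len(schedule.centers), 0), dtype=np.int64),
        )
    betas = 1.0 / (KB * np.asarray(ladder))
    m = topology.n_dihedrals
    args = _kernel_args(topology, params, wall)
    n_w = len(schedule.centers)
    n_cycles = max(1, mc.n_steps // remd.exchange_interval)

    counts = {t: np.zeros((n_w, len(bin_edges) - 1), dtype=np.int64) for t in ladder}
    dihedrals = {t: [np.empty((0, m))] * n_w for t in ladder} if keep_dihedrals else None
    swap_attempts = 0
    swap_accepts = 0
    trace = np.zeros((n_w, n_cycles), dtype=np.int64)
    exchange_rng = np.random.default_rng(_subseed(remd.seed, 0xE))

    for w, r0 in enumerate(schedule.centers):
        phis = [np.full(m, np.pi) for _ in range(n_t)]
        replica_id = np.arange(n_t)
        energies = np.zeros(n_t)
        # per-rung equilibration
        for t in range(n_t):
            _, _, _, energies[t] = _kernels.mc_chunk(
                phis[t], mc.equilibration, mc.equilibration + 1, betas[t],
                *args, schedule.k, r0, np.deg2rad(mc.max_step),
                mc.pivot_prob, _subseed(remd.seed, w, t, 999),
            )
        window_dih: list[list[np.ndarray]] = [[] for _ in range(n_t)]
        for cycle in range(n_cycles):
            for t in range(n_t):
                r_samp, dih_samp, _, energies[t] = _kernels.mc_chunk(
                    phis[t], remd.exchange_interval, mc.sample_stride,
                    betas[t], *args, schedule.k, r0,
                    np.deg2rad(mc.max_step), mc.pivot_prob,
                    _subseed(remd.seed, w, t, cycle),
                )
                counts[ladder[t]][w] += np.histogram(r_samp, bins=bin_edges)[0]
                if keep_dihedrals:
                    window_dih[t].append(np.rad2deg(dih_samp))
            if n_t >= 2:
                i = int(exchange_rng.integers(0, n_t - 1))
                j = i + 1
                swap_attempts += 1
                if remd_exchange_decision(
                    energies[i], energies[j], betas[i], betas[j],
                    float(exchange_rng.random()),
                ):
                    phis[i], phis[j] = phis[j], phis[i]
                    energies[i], energies[j] = energies[j], energies[i]
                    replica_id[i], replica_id[j] = replica_id[j], replica_id[i]
                    swap_accepts += 1
            trace[w, cycle] = replica_id[0]
        if keep_dihedrals:
            for t, temp in enumerate(ladder):
                dihedrals[temp][w] = (
                    np.vstack(window_dih[t]) if window_dih[t] else np.empty((0, m))
                )

    out: dict[float, BiasedHistogramSet] = {}
    for t, temp in enumerate(ladder):
        zero_cells = np.where(counts[temp].sum(axis=1) == 0)[0]
        if zero_cells.size:
            raise ChainfelError(
                f"temperature {temp} K: windows {zero_cells.tolist()} unsampled"
            )
        out[temp] = BiasedHistogramSet(
            bin_edges=bin_edges,
            counts=counts[temp],
            bias_k=np.full(n_w, schedule.k),
            bias_r0=np.array(schedule.centers),
            temperature=temp,
            metadata={"seed": remd.seed, "n_steps": mc.n_steps,
                      "sampler": "torsion-MC/REMD"},
            dihedrals=list(dihedrals[temp]) if keep_dihedrals else None,
        )
    return REMDResult(
        histograms=out,
        swap_attempts=swap_attempts,
        swap_accepts=swap_accepts,
        replica_trace=trace,
    )
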