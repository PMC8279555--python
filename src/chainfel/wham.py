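"""Weighted histogram analysis method (WHAM).

Umbrella sampling leaves each window's end-to-end histogram biased by its
harmonic restraint.  WHAM recovers the single unbiased distribution
``P(r)`` — and hence the potential of mean force ``G(r) = −kT ln P(r)`` —
as the self-consistent solution of

    P(r)         = Σ_i n_i(r) / Σ_i N_i · exp(β(F_i − U_i(r)))
    exp(−β F_i)  = Σ_r P(r) · exp(−β U_i(r))

where ``n_i(r)`` are window counts, ``N_i`` window totals, ``U_i`` the
bias potentials evaluated at bin centers, and ``F_i`` the window free
energies.  The fixed point is found by direct iteration with a tolerance
on ``max_i |ΔF_i|``; the profile is anchored so its minimum is zero.

Bins with zero aggregate counts are reported as missing (NaN), never
interpolated.  Optional uncertainties come from a Bayesian bootstrap over
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.sparse.csgraph import connected_components

from .errors import ConvergenceError, DisconnectedWindowsError

__all__ = [
    "BiasedHistogramSet",
    "PMFProfile",
    "wham_solve",
    "align_pmf",
    "find_minima",
    "wham_bootstrap",
]

KB = 0.008314462618  # kJ/(mol K)


@dataclass(frozen=True)
class BiasedHistogramSet:
    """Per-window biased histograms of the end-to-end distance.

    All windows share one uniform bin grid.  ``counts`` has shape
    (n_windows, n_bins); ``bias_k``/``bias_r0`` hold each window's harmonic
    restraint parameters in kJ/(mol Å²) and Å.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    bias_k: np.ndarray
    bias_r0: np.ndarray
    temperature: float
    metadata: Mapping[str, object] = field(default_factory=dict)
    dihedrals: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        k = np.atleast_1d(np.asarray(self.bias_k, dtype=float))
        r0 = np.atleast_1d(np.asarray(self.bias_r0, dtype=float))
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "bias_k", k)
        object.__setattr__(self, "bias_r0", r0)
        if counts.ndim != 2 or counts.shape[1] != edges.size - 1:
            raise ValueError("counts must be (n_windows, n_bins)")
        if k.shape != (counts.shape[0],) or r0.shape != (counts.shape[0],):
            raise ValueError("bias parameter arrays must match window count")
        if np.any(counts < 0):
            raise ValueError("histogram counts must be nonnegative")
        widths = np.diff(edges)
        if not np.allclose(widths, widths[0], rtol=1e-8):
            raise ValueError("bin grid must be uniform")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def bias_matrix(self) -> np.ndarray:
        """Bias energies U_i(r) at bin centers, shape (n_windows, n_bins)."""
        r = self.bin_centers[None, :]
        return 0.5 * self.bias_k[:, None] * (r - self.bias_r0[:, None]) ** 2

    def overlap_gaps(self) -> list[tuple[int, int]]:
        """Adjacent window pairs (by bias center order) without shared occupied bins."""
        order = np.argsort(self.bias_r0)
        gaps = []
        for a, b in zip(order, order[1:]):
            if not np.any((self.counts[a] > 0) & (self.counts[b] > 0)):
                gaps.append((int(a), int(b)))
        return gaps

    def overlap_components(self) -> list[list[int]]:
        """Connected components of the window-overlap graph."""
        occ = self.counts > 0
        adj = (occ.astype(np.int64) @ occ.T.astype(np.int64)) > 0
        n, labels = connected_components(adj, directed=False)
        return [np.where(labels == i)[0].tolist() for i in range(n)]


@dataclass(frozen=True)
class PMFProfile:
    """A potential of mean force G(r) on a distance grid, minimum-anchored."""

    r: np.ndarray
    G: np.ndarray
    temperature: float
    window_free_energies: np.ndarray = field(default_factory=lambda: np.zeros(0))
    iterations: int = 0
    residual: float = 0.0
    stderr: np.ndarray | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        object.__setattr__(self, "G", np.asarray(self.G, dtype=float))
        if self.r.shape != self.G.shape:
            raise ValueError("r and G must have the same shape")

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.G)

    def minimum(self) -> tuple[float, float]:
        """(r, G) at the global minimum over the supported bins."""
        mask = self.finite_mask
        if not mask.any():
            raise ValueError("profile has no finite values")
        idx = np.flatnonzero(mask)[np.argmin(self.G[mask])]
        return float(self.r[idx]), float(self.G[idx])


def _solve_fixed_point(counts: np.ndarray, totals: np.ndarray,
                       boltz: np.ndarray, kt: float, tolerance: float,
                       max_iterations: int) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Iterate the WHAM equations.

    ``boltz`` is exp(−βU_i(r)).  Returns (P, f, iterations, residual) with
    ``f = exp(−βF_i)`` normalized to window 0; the residual is the change
    in the window free energies, max_i |ΔF_i|, in kJ/mol.
    """
    agg = counts.sum(axis=0).astype(float)
    f = np.ones(counts.shape[0])
    sampled = agg > 0
    residual = np.inf
    for it in range(1, max_iterations + 1):
        denom = (totals / f) @ boltz  # Σ_i N_i exp(βF_i) exp(−βU_i(r))
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(sampled & (denom > 0), agg / denom, 0.0)
        f_new = boltz @ p
        f_new = f_new / f_new[0]
        with np.errstate(divide="ignore"):
            # ln f = −βF, so ΔF in kJ/mol is kt·|Δ ln f|
            residual = kt * float(np.max(np.abs(np.log(f_new) - np.log(f))))
        f = f_new
        if residual < tolerance:
            norm = p.sum()
            return p / norm, f, it, residual
    raise ConvergenceError(
        f"WHAM did not converge in {max_iterations} iterations "
        f"(residual {residual:.3e})", residual=residual,
    )


def wham_solve(histograms: BiasedHistogramSet,
               tolerance: float = 1e-6,
               max_iterations: int = 100_000,
               n_bootstrap: int = 0,
               bootstrap_seed: int = 0) -> PMFProfile:
    """Reconstruct the unbiased PMF from a set of biased histograms.

    Parameters
    ----------
    histograms:
        Windows on a shared uniform grid; their occupied bins must form a
        single connected overlap component.
    tolerance:
        Convergence threshold on max |ΔF_i| in kJ/mol.
    n_bootstrap:
        If positive, attach per-bin standard errors from a Bayesian
        bootstrap over windows with this many resamples.

    Raises
    ------
    DisconnectedWindowsError
        If the window overlap graph has more than one component.
    ConvergenceError
        If the fixed-point iteration exhausts ``max_iterations``.
    """
    comps = histograms.overlap_components()
    if len(comps) > 1:
        raise DisconnectedWindowsError(comps)
    kt = KB * histograms.temperature
    boltz = np.exp(-histograms.bias_matrix() / kt)
    p, f, iterations, residual = _solve_fixed_point(
        histograms.counts.astype(float), histograms.totals.astype(float),
        boltz, kt, tolerance, max_iterations,
    )
    with np.errstate(divide="ignore"):
        g = np.where(p > 0, -kt * np.log(np.where(p > 0, p, 1.0)), np.nan)
    profile = PMFProfile(
        r=histograms.bin_centers,
        G=g,
        temperature=histograms.temperature,
        window_free_energies=-kt * np.log(f),
        iterations=iterations,
        residual=residual,
        metadata={"tolerance": tolerance, "n_windows": histograms.n_windows},
    )
    profile = align_pmf(profile)
    if n_bootstrap > 0:
        stderr = wham_bootstrap(
            histograms, n_resamples=n_bootstrap, seed=bootstrap_seed,
            tolerance=tolerance, max_iterations=max_iterations,
        )
        profile = replace(profile, stderr=stderr)
    return profile


def align_pmf(profile: PMFProfile) -> PMFProfile:
    """Shift a PMF so its global minimum is exactly zero (shape unchanged)."""
    mask = np.isfinite(profile.G)
    if not mask.any():
        raise ValueError("cannot align an all-empty profile")
    return replace(profile, G=profile.G - profile.G[mask].min())


def find_minima(profile: PMFProfile,
                prominence: float = 0.5) -> list[tuple[float, float]]:
    """Interior local minima of the PMF, ordered by depth (lowest G first).

    ``prominence`` (kJ/mol) is the minimum barrier separating a reported
    minimum from lower terrain, as measured by ``scipy.signal.find_peaks``
    on the negated profile.  Missing bins cannot host minima.
    """
    g = np.where(np.isfinite(profile.G), profile.G, np.inf)
    idx, _ = find_peaks(-g, prominence=prominence)
    minima = [(float(profile.r[i]), float(profile.G[i])) for i in idx]
    return sorted(minima, key=lambda t: t[1])


def wham_bootstrap(histograms: BiasedHistogramSet,
                   n_resamples: int = 50,
                   seed: int = 0,
                   tolerance: float = 1e-6,
                   max_iterations: int = 100_000) -> np.ndarray:
    """Bayesian-bootstrap standard error of G(r) over windows.

    Window contributions are reweighted with Dirichlet(1, …, 1) weights;
    each resample is solved with the same fixed-point iteration and
    min-anchored before the per-bin standard deviation is taken.
    """
    rng = np.random.default_rng(seed)
    kt = KB * histograms.temperature
    boltz = np.exp(-histograms.bias_matrix() / kt)
    counts = histograms.counts.astype(float)
    totals = histograms.totals.astype(float)
    n_w = histograms.n_windows
    profiles = []
    for _ in range(n_resamples):
        w = rng.dirichlet(np.ones(n_w)) * n_w
        try:
            p, _, _, _ = _solve_fixed_point(
                counts * w[:, None], totals * w, boltz, kt, tolerance,
                max_iterations,
            )
        except ConvergenceError:
            continue
        with np.errstate(divide="ignore"):
            g = np.where(p > 0, -kt * np.log(np.where(p > 0, p, 1.0)), np.nan)
        g = g - np.nanmin(g)
        profiles.append(g)
    stacked = np.array(profiles)
    return np.nanstd(stacked, axis=0, ddof=1)
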