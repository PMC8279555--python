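"""Enthalpy/entropy decomposition of multi-temperature PMFs.

PMFs measured over a temperature ladder are fit, bin by bin, to the
constant-heat-capacity form

    G(T, r) = A(r) + B(r)·(T − T0) + C(r)·T·ln(T/T0)

with A, B, C temperature-independent functions of the end-to-end
distance and T0 a reference temperature (298.15 K).  Temperature
derivatives give

    S(T, r)  = −∂G/∂T = −B − C·(1 + ln(T/T0))
    H(T, r)  = G + T·S = A − B·T0 − C·T

so that at T0 the printed identities hold exactly: G(T0) = A,
H(T0) = A − (B + C)·T0, −T0·S(T0) = (B + C)·T0, and the interaction heat
capacity dH/dT = −C is constant.  Including higher-order terms was found
not to improve such fits statistically, so the three-coefficient form is
the only model class offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import NumericalError
from .wham import KB, BiasedHistogramSet, PMFProfile, align_pmf, wham_solve

__all__ = [
    "MultiTemperaturePMF",
    "ThermoProfile",
    "fit_gibbs_helmholtz",
    "enthalpy_entropy",
    "decompose_pmf_pipeline",
]

T0_DEFAULT = 298.15


@dataclass(frozen=True)
class MultiTemperaturePMF:
    """G(T, r) on a common distance grid at several temperatures.

    ``G`` has shape (n_temperatures, n_bins); NaN marks unsampled bins.
    ``sigma``, if given, carries per-point standard errors for weighted
    fitting.
    """

    temperatures: np.ndarray
    r: np.ndarray
    G: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        r = np.asarray(self.r, dtype=float)
        g = np.asarray(self.G, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "G", g)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("need at least 3 temperatures (3 free coefficients)")
        if np.any(t <= 0):
            raise ValueError("temperatures must be positive")
        if np.unique(t).size != t.size:
            raise NumericalError("duplicate temperatures make the fit rank-deficient")
        if g.shape != (t.size, r.size):
            raise ValueError("G must be (n_temperatures, n_bins)")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != g.shape:
                raise ValueError("sigma must match G's shape")
            object.__setattr__(self, "sigma", s)

    @classmethod
    def from_profiles(cls, profiles: Sequence[PMFProfile]) -> "MultiTemperaturePMF":
        """Stack aligned single-temperature PMFs sharing one grid."""
        if not profiles:
            raise ValueError("no profiles given")
        r = profiles[0].r
        for p in profiles[1:]:
            if p.r.shape != r.shape or not np.allclose(p.r, r):
                raise ValueError("profiles must share one distance grid")
        temps = np.array([p.temperature for p in profiles])
        g = np.vstack([align_pmf(p).G for p in profiles])
        sig = None
        if all(p.stderr is not None for p in profiles):
            sig = np.vstack([p.stderr for p in profiles])
        return cls(temperatures=temps, r=r, G=g, sigma=sig)


@dataclass(frozen=True)
class ThermoProfile:
    """Fitted A(r), B(r), C(r) with the derived profiles at T0.

    NaN coefficients mark bins with fewer than three temperatures of data.
    """

    r: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    T0: float
    residual_rms: np.ndarray

    def __post_init__(self) -> None:
        for name in ("r", "A", "B", "C", "residual_rms"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")

    @property
    def G0(self) -> np.ndarray:
        """Free energy at T0: G(T0, r) = A(r)."""
        return self.A.copy()

    @property
    def H0(self) -> np.ndarray:
        """Enthalpy at T0: H(T0, r) = A − (B + C)·T0."""
        return self.A - (self.B + self.C) * self.T0

    @property
    def minus_TS0(self) -> np.ndarray:
        """Entropic term at T0: −T0·S(T0, r) = (B + C)·T0."""
        return (self.B + self.C) * self.T0

    @property
    def heat_capacity(self) -> np.ndarray:
        """Interaction heat capacity dH/dT = −C, independent of T."""
        return -self.C

    def gibbs(self, T: float) -> np.ndarray:
        """G(T, r) from the fitted coefficients."""
        if T <= 0:
            raise ValueError("T must be positive")
        return self.A + self.B * (T - self.T0) + self.C * T * np.log(T / self.T0)


def fit_gibbs_helmholtz(multi: MultiTemperaturePMF,
                        T0: float = T0_DEFAULT) -> ThermoProfile:
    """Per-bin least squares of G(T) = A + B·(T − T0) + C·T·ln(T/T0).

    Bins are fit independently over the temperatures where they carry a
    finite G; bins with fewer than three finite values get NaN
    coefficients.  When ``multi.sigma`` is present the fit is
    inverse-variance weighted.
    """
    t = multi.temperatures
    design = np.column_stack([
        np.ones_like(t),
        t - T0,
        t * np.log(t / T0),
    ])
    n_bins = multi.r.size
    A = np.full(n_bins, np.nan)
    B = np.full(n_bins, np.nan)
    C = np.full(n_bins, np.nan)
    rms = np.full(n_bins, np.nan)
    for b in range(n_bins):
        g = multi.G[:, b]
        ok = np.isfinite(g)
        if multi.sigma is not None:
            ok &= np.isfinite(multi.sigma[:, b]) & (multi.sigma[:, b] > 0)
        if ok.sum() < 3:
            continue
        x = design[ok]
        y = g[ok]
        if multi.sigma is not None:
            w = 1.0 / multi.sigma[ok, b]
            x = x * w[:, None]
            y = y * w
        coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
        if rank < 3:
            raise NumericalError(
                f"rank-deficient design at bin {b}: duplicate or degenerate "
                "temperatures"
            )
        A[b], B[b], C[b] = coef
        resid = design[ok] @ coef - g[ok]
        rms[b] = float(np.sqrt(np.mean(resid**2)))
    return ThermoProfile(r=multi.r, A=A, B=B, C=C, T0=T0, residual_rms=rms)


def enthalpy_entropy(profile: ThermoProfile,
                     T: float) -> tuple[np.ndarray, np.ndarray]:
    """(H(T, r), −T·S(T, r)) from the fitted coefficients, kJ/mol.

    H(T) = A − B·T0 − C·T and −T·S(T) = T·[B + C·(1 + ln(T/T0))]; the sum
    H − T·S reproduces the fitted G(T) identically.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    h = profile.A - profile.B * profile.T0 - profile.C * T
    minus_ts = T * (profile.B + profile.C * (1.0 + np.log(T / profile.T0)))
    return h, minus_ts


def decompose_pmf_pipeline(histogram_sets: Sequence[BiasedHistogramSet],
                           T0: float = T0_DEFAULT,
                           tolerance: float = 1e-6,
                           max_iterations: int = 100_000,
                           ) -> tuple[ThermoProfile, list[PMFProfile]]:
    """WHAM every temperature's histograms, align, and fit the decomposition.

    Returns the fitted :class:`ThermoProfile` together with the per-
    temperature PMFs.  Each stage failure is re-raised with the stage and
    temperature named.
    """
    if len(histogram_sets) < 3:
        raise ValueError(
            f">= 3 temperatures required for the decomposition, got "
            f"{len(histogram_sets)}"
        )
    profiles = []
    for hs in histogram_sets:
        try:
            profiles.append(wham_solve(hs, tolerance=tolerance,
                                       max_iterations=max_iterations))
        except Exception as exc:
            raise NumericalError(f"[wham @ {hs.temperature} K] {exc}") from exc
    try:
        multi = MultiTemperaturePMF.from_profiles(profiles)
        thermo = fit_gibbs_helmholtz(multi, T0=T0)
    except Exception as exc:
        raise NumericalError(f"[thermo fit] {exc}") from exc
    return thermo, profiles
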