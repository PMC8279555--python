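"""Coarse-grained single-chain potential.

The chain Hamiltonian has four terms, each switchable:

* a cosine-polynomial torsion potential per backbone dihedral, anchored so
  the all-*trans* state has zero torsional energy;
* intramolecular Lennard-Jones between united-atom carbon sites separated
  by more than the bonded-exclusion depth;
* a soft prolate-ellipsoid confinement wall standing in for the sealed
  cavitand dimer interior (quadratic penalty outside the surface);
* a harmonic umbrella bias on the end-to-end distance.

Units: kJ/mol, Å, degrees.  The torsion defaults are Ryckaert-Bellemans
butane coefficients rescaled so the gauche-trans gap is exactly 2.9 kJ/mol
(the trans-to-gauche barrier then sits near 12.2 kJ/mol, in the range
typical of alkane force fields).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import ChainTopology, Conformation, end_to_end

__all__ = [
    "PotentialParams",
    "CavityWall",
    "UmbrellaBias",
    "torsion_energy",
    "intramolecular_lj",
    "confinement_energy",
    "bias_energy",
    "total_energy",
    "DEFAULT_TORSION_COEFFS",
]

# Ryckaert-Bellemans butane torsion coefficients (kJ/mol), rescaled so
# U(gauche) - U(trans) = 2.9 kJ/mol exactly; U(trans) = 0 by construction
# (coefficients sum to zero).
_RB = np.array([9.28, 12.16, -13.12, -3.06, 26.24, -31.5])
_RB_GAUCHE = float(_RB @ np.power(-0.5, np.arange(6)))  # U at phi = 60 deg
DEFAULT_TORSION_COEFFS: tuple[float, ...] = tuple(
    float(c) for c in _RB * (2.9 / _RB_GAUCHE)
)


@dataclass(frozen=True)
class PotentialParams:
    """Parameters of the intramolecular potential.

    ``torsion_coeffs`` are the c0..c5 of U(φ) = Σ_k c_k cos^k(φ − 180°).
    ``lj_epsilon``/``lj_sigma`` are per-site united-atom Lennard-Jones
    parameters (TraPPE-like CH2 values by default); carbon pairs separated
    by ``exclusion_depth`` bonds or fewer are excluded, with no 1-4 scaling.
    """

    torsion_coeffs: tuple[float, ...] = DEFAULT_TORSION_COEFFS
    lj_epsilon: float = 0.39
    lj_sigma: float = 3.95
    exclusion_depth: int = 3

    def __post_init__(self) -> None:
        if self.lj_sigma <= 0:
            raise ValueError("lj_sigma must be positive")
        if self.exclusion_depth < 3:
            raise ValueError("exclusion_depth must be at least 3")
        object.__setattr__(
            self, "torsion_coeffs", tuple(float(c) for c in self.torsion_coeffs)
        )

    @property
    def gauche_penalty(self) -> float:
        """U(60°) − U(180°) of the torsion term, kJ/mol."""
        return float(torsion_energy(60.0, self) - torsion_energy(180.0, self))


@dataclass(frozen=True)
class CavityWall:
    """Soft prolate-ellipsoid confinement, axis along z, centered at origin.

    Defaults give a cavity 8 Å wide at the equator (a = 4 Å) and 13 Å long
    pole-to-pole (c = 6.5 Å), matching the inferred interior of the sealed
    cavitand dimer.  ``stiffness`` is the quadratic penalty per unit of
    overshoot of the scaled ellipsoidal coordinate.
    """

    a: float = 4.0
    c: float = 6.5
    stiffness: float = 100.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0 or self.stiffness <= 0:
            raise ValueError("cavity semi-axes and stiffness must be positive")


@dataclass(frozen=True)
class UmbrellaBias:
    """Harmonic umbrella restraint ½·k·(r_ee − r0)² on the end-to-end distance."""

    k: float = 50.0
    r0: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("umbrella force constant must be nonnegative")


# ---------------------------------------------------------------------------
# energy terms
# ---------------------------------------------------------------------------

def torsion_energy(phi: float | np.ndarray,
                   params: PotentialParams | None = None) -> float | np.ndarray:
    """Torsional energy U(φ) = Σ_k c_k cos^k(φ − 180°), kJ/mol.

    Periodic with period 360°; the default coefficients put the global
    minimum (zero) at φ = 180° and gauche minima near ±60°.
    """
    params = params or PotentialParams()
    x = np.cos(np.deg2rad(np.asarray(phi, dtype=float) - 180.0))
    c = params.torsion_coeffs
    out = np.zeros_like(x)
    for ck in reversed(c):
        out = out * x + ck
    return float(out) if np.isscalar(phi) else out


def intramolecular_lj(coords: np.ndarray, params: PotentialParams | None = None) -> float:
    """Σ 4ε[(σ/r)¹² − (σ/r)⁶] over carbon pairs beyond the exclusion depth."""
    params = params or PotentialParams()
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    depth = params.exclusion_depth
    e = 0.0
    for i in range(n):
        for j in range(i + depth + 1, n):
            d2 = float(np.sum((coords[i] - coords[j]) ** 2))
            if d2 == 0.0:
                raise ValueError(f"coincident interacting sites {i} and {j}")
            s2 = params.lj_sigma**2 / d2
            s6 = s2**3
            e += 4.0 * params.lj_epsilon * (s6 * s6 - s6)
    return e


def confinement_energy(coords: np.ndarray, wall: CavityWall) -> float:
    """Quadratic penalty for sites outside the ellipsoid, kJ/mol.

    Per site, s = sqrt((x² + y²)/a² + z²/c²); the energy is
    stiffness·max(0, s − 1)² summed over sites, exactly zero inside.
    """
    coords = np.asarray(coords, dtype=float)
    s = np.sqrt(
        (coords[:, 0] ** 2 + coords[:, 1] ** 2) / wall.a**2
        + coords[:, 2] ** 2 / wall.c**2
    )
    over = np.maximum(0.0, s - 1.0)
    return float(wall.stiffness * np.sum(over**2))


def bias_energy(r_ee: float, bias: UmbrellaBias) -> float:
    """Harmonic umbrella energy ½·k·(r_ee − r0)², kJ/mol."""
    if r_ee < 0:
        raise ValueError("r_ee must be nonnegative")
    return 0.5 * bias.k * (r_ee - bias.r0) ** 2


def total_energy(conformation: Conformation,
                 params: PotentialParams | None = None,
                 wall: CavityWall | None = None,
                 bias: UmbrellaBias | None = None) -> float:
    """Sum of the active energy terms for a conformation, kJ/mol.

    Omitting ``wall`` or ``bias`` is identical to passing a zero-strength
    version of the term.
    """
    params = params or PotentialParams()
    e = float(np.sum(torsion_energy(conformation.dihedrals, params))) if (
        conformation.dihedrals.size
    ) else 0.0
    e += intramolecular_lj(conformation.coords, params)
    if wall is not None:
        e += confinement_energy(conformation.coords, wall)
    if bias is not None:
        e += bias_energy(end_to_end(conformation), bias)
    return e
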