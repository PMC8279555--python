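"""Chain geometry: building alkane conformations and measuring their observables.

An *n*-carbon alkane backbone is modeled as a chain of carbon sites with
fixed bond length and bond angle; a conformation is fully specified by its
``n - 3`` backbone dihedral angles.  This module builds Cartesian
coordinates from those internal coordinates, measures the observables used
throughout the analysis (end-to-end distance, all-*trans* length, gauche
content, root-mean-square extension), and estimates van der Waals volumes
and host-guest packing fractions.

Conventions
-----------
* Distances in Å, angles in degrees at the API surface.
* Dihedrals follow the IUPAC sign convention: *trans* (anti-periplanar) is
  180°, values lie on (−180, 180], positive = right-handed rotation.
* The end-to-end distance ``r_ee`` is measured between the first and last
  backbone *carbon* centers (the terminal methyl carbons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ChainTopology",
    "Conformation",
    "RadiiSet",
    "BONDI",
    "VolumeEstimate",
    "build_cartesian",
    "measure_dihedrals",
    "end_to_end",
    "all_trans_length",
    "classify_dihedrals",
    "gauche_fraction",
    "rms_end_to_end",
    "with_hydrogens",
    "vdw_volume",
    "packing_fraction",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainTopology:
    """Fixed internal-coordinate description of an n-alkane backbone.

    Parameters
    ----------
    n_carbons:
        Number of backbone carbons (C11-C22 in the host-guest study;
        anything >= 2 is accepted).
    bond_length:
        C-C bond length in Å.
    bond_angle:
        Backbone C-C-C angle in degrees.
    with_hydrogens:
        Whether all-atom construction (tetrahedral hydrogens) is intended
        for this chain; only the volume calculations need it.
    ch_bond:
        C-H bond length in Å for all-atom construction.
    """

    n_carbons: int
    bond_length: float = 1.53
    bond_angle: float = 112.7
    with_hydrogens: bool = False
    ch_bond: float = 1.09

    def __post_init__(self) -> None:
        if self.n_carbons < 2:
            raise ValueError(f"n_carbons must be >= 2, got {self.n_carbons}")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if not 0.0 < self.bond_angle < 180.0:
            raise ValueError("bond_angle must lie strictly between 0 and 180 degrees")
        if self.ch_bond <= 0:
            raise ValueError("ch_bond must be positive")

    @property
    def n_dihedrals(self) -> int:
        """Number of backbone dihedrals, m = n_carbons - 3 (0 for n < 4)."""
        return max(self.n_carbons - 3, 0)

    @property
    def n_bonds(self) -> int:
        return self.n_carbons - 1


@dataclass(frozen=True)
class Conformation:
    """A chain conformation: dihedral vector plus derived site coordinates."""

    topology: ChainTopology
    dihedrals: np.ndarray
    coords: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        dih = np.asarray(self.dihedrals, dtype=float)
        object.__setattr__(self, "dihedrals", dih)
        if dih.shape != (self.topology.n_dihedrals,):
            raise ValueError(
                f"expected {self.topology.n_dihedrals} dihedrals for "
                f"C{self.topology.n_carbons}, got shape {dih.shape}"
            )
        if self.coords is None:
            object.__setattr__(
                self, "coords", build_cartesian(self.topology, dih)
            )
        else:
            object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))

    @property
    def r_ee(self) -> float:
        return end_to_end(self)


@dataclass(frozen=True)
class RadiiSet:
    """Van der Waals radii by element, in Å."""

    radii: Mapping[str, float]

    def __post_init__(self) -> None:
        for elem, r in self.radii.items():
            if r <= 0:
                raise ValueError(f"radius for {elem!r} must be positive, got {r}")

    def __getitem__(self, element: str) -> float:
        return self.radii[element]

    def for_elements(self, elements: Sequence[str]) -> np.ndarray:
        return np.array([self.radii[e] for e in elements], dtype=float)


#: Bondi radii for the elements the chain model uses.
BONDI = RadiiSet({"C": 1.70, "H": 1.20})


class VolumeEstimate(NamedTuple):
    """Monte Carlo union-of-spheres volume with its standard error."""

    value: float
    stderr: float
    n_points: int


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _nerf_extend(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                 r: float, theta: float, phi: float) -> np.ndarray:
    """Place atom d given atoms a-b-c, bond r=|cd|, angle b-c-d, torsion a-b-c-d.

    Natural extension reference frame; angles in radians.
    """
    bc = c - b
    bc_u = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_u)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc_u)
    d_local = np.array([
        -r * np.cos(theta),
        r * np.sin(theta) * np.cos(phi),
        r * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc_u + d_local[1] * m + d_local[2] * n


def build_cartesian(topology: ChainTopology,
                    dihedrals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Build backbone carbon coordinates from dihedral angles.

    The first carbon sits at the origin, the second along +x, the third in
    the xy-plane.  Every backbone bond has length ``bond_length`` and every
    backbone angle equals ``bond_angle``; dihedral ``k`` is the torsion of
    carbons (k, k+1, k+2, k+3).

    Returns an ``(n_carbons, 3)`` array in Å.
    """
    dih = np.atleast_1d(np.asarray(dihedrals, dtype=float))
    if dih.size == 0:
        dih = dih.reshape(0)
    m = topology.n_dihedrals
    if dih.shape != (m,):
        raise ValueError(
            f"C{topology.n_carbons} needs {m} dihedrals, got shape {dih.shape}"
        )
    n = topology.n_carbons
    l = topology.bond_length
    theta = np.deg2rad(topology.bond_angle)
    phi = np.deg2rad(dih)

    coords = np.zeros((n, 3))
    coords[0] = (0.0, 0.0, 0.0)
    if n >= 2:
        coords[1] = (l, 0.0, 0.0)
    if n >= 3:
        coords[2] = coords[1] + l * np.array(
            [-np.cos(theta), np.sin(theta), 0.0]
        )
    for i in range(3, n):
        coords[i] = _nerf_extend(
            coords[i - 3], coords[i - 2], coords[i - 1], l, theta, phi[i - 3]
        )
    return coords


def measure_dihedrals(coords: np.ndarray) -> np.ndarray:
    """Measure backbone torsions of a coordinate chain (IUPAC sign, degrees).

    Output angles lie on (−180, 180]; exact anti-periplanar geometry reports
    +180.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 4:
        return np.zeros(0)
    b0 = coords[1:-2] - coords[:-3]
    b1 = coords[2:-1] - coords[1:-2]
    b2 = coords[3:] - coords[2:-1]
    c01 = np.cross(b0, b1)
    c12 = np.cross(b1, b2)
    b1_u = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    x = np.einsum("ij,ij->i", c01, c12)
    y = np.einsum("ij,ij->i", np.cross(c01, c12), b1_u)
    phi = np.rad2deg(np.arctan2(y, x))
    # fold -180 onto +180 so trans is reported as exactly 180
    phi[np.isclose(phi, -180.0)] = 180.0
    return phi


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def end_to_end(conformation: Conformation | np.ndarray) -> float:
    """Euclidean distance between the first and last backbone carbons, Å."""
    coords = (
        conformation.coords
        if isinstance(conformation, Conformation)
        else np.asarray(conformation, dtype=float)
    )
    if coords.shape[0] < 2:
        raise ValueError("end_to_end needs at least 2 backbone sites")
    return float(np.linalg.norm(coords[-1] - coords[0]))


def all_trans_length(topology: ChainTopology) -> float:
    """End-to-end length of the all-*trans* (planar zigzag) chain, Å.

    With m bonds of length l and backbone angle θ the zigzag advances
    ``p = l·sin(θ/2)`` per bond along the chain axis and alternates
    ``q = l·cos(θ/2)`` transverse to it, so the terminal separation is
    ``m·p`` for even m and ``sqrt((m·p)² + q²)`` for odd m.
    """
    m = topology.n_bonds
    half = np.deg2rad(topology.bond_angle) / 2.0
    p = topology.bond_length * np.sin(half)
    q = topology.bond_length * np.cos(half)
    if m % 2 == 0:
        return float(m * p)
    return float(np.hypot(m * p, q))


def classify_dihedrals(dihedrals: Sequence[float] | np.ndarray) -> list[str]:
    """Label each dihedral as trans ('t'), gauche+ ('g+') or gauche− ('g−').

    ``t`` for \\|φ\\| >= 120°, ``g+`` for 0 < φ < 120°, ``g−`` for
    −120 < φ < 0.  φ exactly 0 is labeled ``g+`` (tie-break).
    """
    dih = np.atleast_1d(np.asarray(dihedrals, dtype=float))
    labels = []
    for phi in dih:
        if abs(phi) >= 120.0:
            labels.append("t")
        elif phi >= 0.0:
            labels.append("g+")
        else:
            labels.append("g-")
    return labels


def gauche_fraction(dihedrals: Sequence[float] | np.ndarray) -> float:
    """Fraction of backbone dihedrals in either gauche state."""
    labels = classify_dihedrals(dihedrals)
    if not labels:
        return 0.0
    return sum(lab != "t" for lab in labels) / len(labels)


def rms_end_to_end(r_values: Sequence[float] | np.ndarray,
                   weights: Sequence[float] | np.ndarray | None = None) -> float:
    """Root-mean-square end-to-end separation ⟨r_ee²⟩^(1/2) of an ensemble.

    ``r_values`` may be end-to-end distances or :class:`Conformation`
    objects; ``weights`` default to uniform.
    """
    r = np.array(
        [c.r_ee if isinstance(c, Conformation) else float(c) for c in r_values]
    )
    if r.size == 0:
        raise ValueError("empty ensemble")
    if weights is None:
        w = np.ones_like(r)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != r.shape:
            raise ValueError("weights must match ensemble length")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights must not all be zero")
    return float(np.sqrt(np.dot(w, r**2) / wsum))


def principal_frame(coords: np.ndarray) -> np.ndarray:
    """Center coordinates and rotate their principal axis onto z.

    The gyration tensor is diagonalized and the eigenvector of largest
    eigenvalue (the long axis of the site cloud) is mapped to the z axis —
    the axis of the prolate confinement ellipsoid.  Internal observables
    are unchanged; only the rigid-body frame is fixed.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    gyr = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(gyr)
    # eigh returns ascending eigenvalues; map (small, mid, large) -> (x, y, z)
    rot = evecs  # columns are axes; want largest as z
    aligned = centered @ rot
    if np.linalg.det(rot) < 0:
        aligned[:, 0] *= -1.0
    return aligned


# ---------------------------------------------------------------------------
# all-atom construction (volumes only)
# ---------------------------------------------------------------------------

_TET_HALF = np.deg2rad(109.471) / 2.0  # half the H-C-H tetrahedral angle


def _perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to v."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(v[0]) > 0.9 * np.linalg.norm(v):
        ref = np.array([0.0, 1.0, 0.0])
    w = np.cross(v, ref)
    return w / np.linalg.norm(w)


def with_hydrogens(topology: ChainTopology,
                   coords: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Add tetrahedral hydrogens to a backbone, returning (elements, coords).

    Interior carbons receive two hydrogens in the plane bisecting the two
    backbone bonds; terminal carbons receive three methyl hydrogens at the
    tetrahedral angle about the terminal C-C bond.  Positions are exact for
    volume purposes; no attempt is made to relax them.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least an ethane-like two-carbon backbone")
    lch = topology.ch_bond
    elements: list[str] = ["C"] * n
    sites = [coords]
    h_list: list[np.ndarray] = []

    for i in range(n):
        c = coords[i]
        if i == 0 or i == n - 1:
            # terminal methyl: three H at 109.47 degrees from the C-C bond
            nb = coords[1] if i == 0 else coords[n - 2]
            axis = c - nb
            axis /= np.linalg.norm(axis)
            perp1 = _perpendicular(axis)
            perp2 = np.cross(axis, perp1)
            tilt = np.deg2rad(180.0 - 109.471)
            for azim in (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0):
                direction = (
                    np.cos(tilt) * axis
                    + np.sin(tilt) * (np.cos(azim) * perp1 + np.sin(azim) * perp2)
                )
                h_list.append(c + lch * direction)
        else:
            b1 = coords[i - 1] - c
            b2 = coords[i + 1] - c
            b1 /= np.linalg.norm(b1)
            b2 /= np.linalg.norm(b2)
            bisector = b1 + b2
            bisector /= np.linalg.norm(bisector)
            normal = np.cross(b1, b2)
            normal /= np.linalg.norm(normal)
            for sign in (+1.0, -1.0):
                direction = -np.cos(_TET_HALF) * bisector + sign * np.sin(_TET_HALF) * normal
                h_list.append(c + lch * direction)

    elements.extend(["H"] * len(h_list))
    sites.append(np.array(h_list))
    return elements, np.vstack(sites)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def vdw_volume(coords: np.ndarray,
               radii: np.ndarray | Sequence[float],
               n_points: int = 1_000_000,
               seed: int | np.random.Generator = 0,
               chunk: int = 200_000) -> VolumeEstimate:
    """Monte Carlo estimate of the union-of-spheres van der Waals volume, Å³.

    Uniform points are thrown in the axis-aligned bounding box of the
    spheres; the hit fraction times the box volume estimates the union
    volume, with the binomial standard error attached.

    Parameters
    ----------
    coords:
        ``(n_atoms, 3)`` sphere centers in Å.
    radii:
        Per-atom radii in Å (same length as ``coords``).
    n_points:
        Total sample count; at least 1e5 for a meaningful standard error.
    seed:
        Integer seed or a ``numpy.random.Generator``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.size == 0:
        raise ValueError("vdw_volume requires at least one atom")
    if coords.ndim != 2 or coords.shape[1] != 3 or radii.shape != (coords.shape[0],):
        raise ValueError("coords must be (n, 3) with matching radii")
    if n_points < 100_000:
        raise ValueError("n_points must be at least 1e5")

    lo = (coords - radii[:, None]).min(axis=0)
    hi = (coords + radii[:, None]).max(axis=0)
    box_volume = float(np.prod(hi - lo))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r2 = radii**2

    hits = 0
    remaining = n_points
    while remaining > 0:
        take = min(chunk, remaining)
        pts = rng.uniform(lo, hi, size=(take, 3))
        inside = np.zeros(take, dtype=bool)
        for center, rsq in zip(coords, r2):
            not_yet = ~inside
            if not not_yet.any():
                break
            d2 = np.sum((pts[not_yet] - center) ** 2, axis=1)
            inside[not_yet] = d2 <= rsq
        hits += int(inside.sum())
        remaining -= take

    p = hits / n_points
    volume = box_volume * p
    stderr = box_volume * np.sqrt(p * (1.0 - p) / n_points)
    return VolumeEstimate(volume, stderr, n_points)


def packing_fraction(guest_volume: float, cavity_volume: float) -> float:
    """Guest van der Waals volume over cavity interior volume."""
    if guest_volume <= 0 or cavity_volume <= 0:
        raise ValueError("volumes must be positive")
    return guest_volume / cavity_volume
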