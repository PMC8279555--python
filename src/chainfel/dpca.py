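"""Dihedral principal component analysis and conformational motifs.

Backbone dihedrals are periodic, so PCA is performed on the circular
embedding (cos φ, sin φ) of every angle, which removes the ±180° wrap
artifact.  The two eigenvectors of the embedded covariance matrix with
the greatest variance define a 2D projection plane; the densest region of
the projected ensemble (a 2D histogram mode) locates the dominant
conformation, reported as the actual sampled frame closest to the mode.

Motif classification (linear / hairpin / chicane) counts persistent
reversals of the chain's direction along its principal axis.  The rules
are coarse, deliberately so: the original assignments were made by visual
inspection, and extended and helical chains are treated as one *linear*
family because they are not thermodynamically distinct basins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import CavityWall
from .geometry import (
    ChainTopology,
    Conformation,
    all_trans_length,
    end_to_end,
    principal_frame,
)

__all__ = [
    "DihedralTrajectory",
    "PCAResult",
    "DominantConformation",
    "circular_embed",
    "top2_pca",
    "dominant_conformation",
    "classify_motif",
    "MotifThresholds",
]


@dataclass(frozen=True)
class DihedralTrajectory:
    """Time-ordered frames of backbone dihedrals (degrees), with weights."""

    angles: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        ang = np.atleast_2d(np.asarray(self.angles, dtype=float))
        object.__setattr__(self, "angles", ang)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (ang.shape[0],):
                raise ValueError("weights must have one entry per frame")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            object.__setattr__(self, "weights", w)

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return self.angles.shape[1]

    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.n_frames, 1.0 / self.n_frames)
        return self.weights / self.weights.sum()


@dataclass(frozen=True)
class PCAResult:
    """Mean, eigenvalues and the top-2 eigenvectors of the embedded covariance."""

    mean: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray  # (2, 2m) rows are PC1, PC2
    projections: np.ndarray  # (n_frames, 2)
    total_variance: float

    @property
    def variance_fraction(self) -> float:
        """Fraction of total variance captured by the top two components."""
        return float(self.eigenvalues[:2].sum() / self.total_variance)


@dataclass(frozen=True)
class DominantConformation:
    """The sampled frame closest to the probability mode in the PC plane."""

    frame_index: int
    dihedrals: np.ndarray
    mode_location: tuple[float, float]
    motif: str | None = None


def circular_embed(trajectory: DihedralTrajectory | np.ndarray) -> np.ndarray:
    """Map each dihedral φ_k to (cos φ_k, sin φ_k); shape (frames, 2m).

    Columns alternate cos/sin per dihedral; values lie in [−1, 1] and are
    invariant under φ → φ ± 360°.
    """
    ang = (
        trajectory.angles
        if isinstance(trajectory, DihedralTrajectory)
        else np.atleast_2d(np.asarray(trajectory, dtype=float))
    )
    rad = np.deg2rad(ang)
    out = np.empty((rad.shape[0], 2 * rad.shape[1]))
    out[:, 0::2] = np.cos(rad)
    out[:, 1::2] = np.sin(rad)
    return out


def top2_pca(embedded: np.ndarray,
             weights: np.ndarray | None = None) -> PCAResult:
    """Eigendecomposition of the (weighted) covariance of embedded angles.

    Components are sorted by descending eigenvalue with a deterministic
    sign convention: the largest-magnitude loading of each component is
    positive.
    """
    x = np.atleast_2d(np.asarray(embedded, dtype=float))
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 frames and 2 columns")
    if weights is None:
        w = np.full(x.shape[0], 1.0 / x.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mean = w @ x
    centered = x - mean
    cov = (centered * w[:, None]).T @ centered
    total = float(np.trace(cov))
    if total <= 0.0:
        raise ValueError("zero total variance: all frames identical")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    comps = evecs[:, :2].T.copy()
    for i in range(2):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] *= -1.0
    projections = centered @ comps.T
    return PCAResult(
        mean=mean,
        eigenvalues=evals,
        components=comps,
        projections=projections,
        total_variance=total,
    )


def dominant_conformation(trajectory: DihedralTrajectory,
                          pca: PCAResult | None = None,
                          bins: int = 50) -> DominantConformation:
    """Locate the probability mode in the PC plane and return its nearest frame.

    A ``bins × bins`` 2D histogram of the projections (weighted) is built;
    the center of the fullest bin is the mode, and the returned frame
    minimizes the Euclidean distance to it (ties break to the lowest frame
    index, which ``argmin`` guarantees).
    """
    if trajectory.n_frames < 1:
        raise ValueError("empty trajectory")
    if trajectory.n_frames == 1:
        return DominantConformation(0, trajectory.angles[0].copy(), (0.0, 0.0))
    pca = pca or top2_pca(circular_embed(trajectory), trajectory.weights)
    proj = pca.projections
    hist, xe, ye = np.histogram2d(
        proj[:, 0], proj[:, 1], bins=bins,
        weights=trajectory.effective_weights(),
    )
    i, j = np.unravel_index(np.argmax(hist), hist.shape)
    mode = (0.5 * (xe[i] + xe[i + 1]), 0.5 * (ye[j] + ye[j + 1]))
    d2 = (proj[:, 0] - mode[0]) ** 2 + (proj[:, 1] - mode[1]) ** 2
    idx = int(np.argmin(d2))
    return DominantConformation(idx, trajectory.angles[idx].copy(), mode)


@dataclass(frozen=True)
class MotifThresholds:
    """Tunable knobs of the motif classifier.

    ``segment_bonds`` bonds per coarse direction segment; a turn requires
    the axial-component sign to persist ``persistence`` segments;
    ``linear_ree``/``hairpin_ree`` are the r_ee consistency thresholds as
    fractions of the all-*trans* length.
    """

    segment_bonds: int = 3
    persistence: int = 2
    linear_ree: float = 0.75
    hairpin_ree: float = 0.5


def _count_turns(axial: np.ndarray, persistence: int) -> int:
    """Count persistent sign reversals in a sequence of axial components.

    Runs of identical sign shorter than ``persistence`` are treated as
    transient wobbles and dropped before counting transitions.
    """
    signs = np.sign(axial)
    signs = signs[signs != 0]
    if signs.size == 0:
        return 0
    runs: list[tuple[float, int]] = []
    for s in signs:
        if runs and runs[-1][0] == s:
            runs[-1] = (s, runs[-1][1] + 1)
        else:
            runs.append((s, 1))
    persistent = [s for s, length in runs if length >= persistence]
    # merge neighbours that became equal after dropping transients
    merged: list[float] = []
    for s in persistent:
        if not merged or merged[-1] != s:
            merged.append(s)
    return max(len(merged) - 1, 0)


def classify_motif(conformation: Conformation,
                   cavity: CavityWall | None = None,
                   thresholds: MotifThresholds | None = None) -> str:
    """Classify a conformation as ``linear``, ``hairpin`` or ``chicane``.

    The backbone is centered and principal-axis aligned (the cavity axis,
    when confined); successive ``segment_bonds``-bond segments give coarse
    direction vectors whose axial components are scanned for persistent
    sign reversals: 0 turns → linear, 1 → hairpin, ≥ 2 → chicane.

    The r_ee consistency expectation (linear: r_ee > 0.75·all-trans;
    hairpin: r_ee < 0.5·all-trans) is advisory; disagreement does not
    change the label but is available via :func:`motif_report`.
    """
    label, _ = motif_report(conformation, cavity, thresholds)
    return label


def motif_report(conformation: Conformation,
                 cavity: CavityWall | None = None,
                 thresholds: MotifThresholds | None = None,
                 ) -> tuple[str, dict[str, object]]:
    """Motif label plus diagnostics (turn count, r_ee consistency flag)."""
    th = thresholds or MotifThresholds()
    coords = np.asarray(conformation.coords, dtype=float)
    n_bonds = coords.shape[0] - 1
    n_segments = n_bonds // th.segment_bonds
    if n_segments < 3:
        raise ValueError(
            f"chain too short to classify: {n_segments} segments "
            f"(need >= 3 of {th.segment_bonds} bonds)"
        )
    aligned = principal_frame(coords)
    idx = np.arange(n_segments + 1) * th.segment_bonds
    idx[-1] = coords.shape[0] - 1  # absorb leftover bonds into the last segment
    seg_vec = aligned[idx[1:]] - aligned[idx[:-1]]
    turns = _count_turns(seg_vec[:, 2], th.persistence)
    if turns == 0:
        label = "linear"
    elif turns == 1:
        label = "hairpin"
    else:
        label = "chicane"

    ree = end_to_end(coords)
    lmax = all_trans_length(conformation.topology)
    consistent = True
    if label == "linear" and ree <= th.linear_ree * lmax:
        consistent = False
    if label == "hairpin" and ree >= th.hairpin_ree * lmax:
        consistent = False
    return label, {
        "turns": turns,
        "r_ee": ree,
        "all_trans_length": lmax,
        "ree_consistent": consistent,
    }
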