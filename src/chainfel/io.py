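"""Plain-text file formats.

Every tabular artifact is a TSV/CSV with a self-describing metadata
header of ``# key: value`` lines; trajectories use the XYZ dialect
(element, x, y, z per site, frame-concatenated).  Floats survive a
write/read round trip to 1e−12 relative precision.

Dialects
--------
* histogram TSV — columns ``window_index, bias_center_A, bias_k,
  bin_left_A, bin_right_A, count`` (long format, one row per window×bin).
* PMF TSV — ``r_A, G_kJmol[, stderr_kJmol]``.
* thermo TSV — ``r_A, G_kJmol, H_kJmol, minus_TS_kJmol, A, B, C,
  residual_rms``.
* dihedral CSV — ``frame, phi1..phim`` in degrees.
"""

from __future__ import annotations

import ast
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .dpca import DihedralTrajectory
from .thermo import ThermoProfile, enthalpy_entropy
from .wham import BiasedHistogramSet, PMFProfile

__all__ = [
    "write_histograms", "read_histograms",
    "write_pmf", "read_pmf",
    "write_thermo", "read_thermo",
    "write_dihedrals", "read_dihedrals",
    "write_xyz", "read_xyz",
]

_FLOAT_FMT = "%.17g"


def _write_header(fh, metadata: dict[str, Any]) -> None:
    for key, value in metadata.items():
        fh.write(f"# {key}: {value!r}\n")


def _read_header(path: Path) -> tuple[dict[str, Any], int]:
    """Parse leading '# key: value' lines; returns (metadata, n_header_lines)."""
    meta: dict[str, Any] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" not in body:
                raise ValueError(
                    f"{path}: malformed metadata header at line {lineno}: {line!r}"
                )
            key, _, value = body.partition(":")
            try:
                meta[key.strip()] = ast.literal_eval(value.strip())
            except (ValueError, SyntaxError):
                meta[key.strip()] = value.strip()
            n += 1
    return meta, n


# ---------------------------------------------------------------------------
# biased histograms
# ---------------------------------------------------------------------------

def write_histograms(hist: BiasedHistogramSet, path: str | Path) -> None:
    path = Path(path)
    n_w, n_b = hist.counts.shape
    rows = {
        "window_index": np.repeat(np.arange(n_w), n_b),
        "bias_center_A": np.repeat(hist.bias_r0, n_b),
        "bias_k": np.repeat(hist.bias_k, n_b),
        "bin_left_A": np.tile(hist.bin_edges[:-1], n_w),
        "bin_right_A": np.tile(hist.bin_edges[1:], n_w),
        "count": hist.counts.ravel(),
    }
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        _write_header(fh, {
            "format": "chainfel-histograms",
            "temperature_K": hist.temperature,
            **{k: v for k, v in hist.metadata.items()},
        })
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_histograms(path: str | Path) -> BiasedHistogramSet:
    path = Path(path)
    meta, skip = _read_header(path)
    if meta.get("format") != "chainfel-histograms":
        raise ValueError(f"{path}: not a chainfel histogram TSV (header line 1)")
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    windows = sorted(df["window_index"].unique())
    first = df[df["window_index"] == windows[0]].sort_values("bin_left_A")
    edges = np.append(first["bin_left_A"].to_numpy(), first["bin_right_A"].iloc[-1])
    counts = np.zeros((len(windows), edges.size - 1), dtype=np.int64)
    bias_k = np.zeros(len(windows))
    bias_r0 = np.zeros(len(windows))
    for i, w in enumerate(windows):
        sub = df[df["window_index"] == w].sort_values("bin_left_A")
        if len(sub) != edges.size - 1:
            raise ValueError(f"{path}: window {w} has an inconsistent bin grid")
        counts[i] = sub["count"].to_numpy()
        bias_k[i] = sub["bias_k"].iloc[0]
        bias_r0[i] = sub["bias_center_A"].iloc[0]
    temperature = float(meta.pop("temperature_K"))
    meta.pop("format", None)
    return BiasedHistogramSet(
        bin_edges=edges, counts=counts, bias_k=bias_k, bias_r0=bias_r0,
        temperature=temperature, metadata=meta,
    )


# ---------------------------------------------------------------------------
# PMF profiles
# ---------------------------------------------------------------------------

def write_pmf(profile: PMFProfile, path: str | Path) -> None:
    data = {"r_A": profile.r, "G_kJmol": profile.G}
    if profile.stderr is not None:
        data["stderr_kJmol"] = profile.stderr
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        _write_header(fh, {
            "format": "chainfel-pmf",
            "temperature_K": profile.temperature,
            "n_windows": len(profile.window_free_energies),
            "iterations": profile.iterations,
            "residual_kJmol": profile.residual,
            "window_free_energies": list(map(float, profile.window_free_energies)),
        })
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_pmf(path: str | Path) -> PMFProfile:
    path = Path(path)
    meta, skip = _read_header(path)
    if meta.get("format") != "chainfel-pmf":
        raise ValueError(f"{path}: not a chainfel PMF TSV (header line 1)")
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    stderr = df["stderr_kJmol"].to_numpy() if "stderr_kJmol" in df else None
    return PMFProfile(
        r=df["r_A"].to_numpy(),
        G=df["G_kJmol"].to_numpy(),
        temperature=float(meta["temperature_K"]),
        window_free_energies=np.asarray(meta.get("window_free_energies", []), dtype=float),
        iterations=int(meta.get("iterations", 0)),
        residual=float(meta.get("residual_kJmol", 0.0)),
        stderr=stderr,
    )


# ---------------------------------------------------------------------------
# thermo profiles
# ---------------------------------------------------------------------------

def write_thermo(profile: ThermoProfile, path: str | Path) -> None:
    h, minus_ts = enthalpy_entropy(profile, profile.T0)
    df = pd.DataFrame({
        "r_A": profile.r,
        "G_kJmol": profile.G0,
        "H_kJmol": h,
        "minus_TS_kJmol": minus_ts,
        "A": profile.A,
        "B": profile.B,
        "C": profile.C,
        "residual_rms": profile.residual_rms,
    })
    with open(path, "w") as fh:
        _write_header(fh, {"format": "chainfel-thermo", "T0_K": profile.T0})
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_thermo(path: str | Path) -> ThermoProfile:
    path = Path(path)
    meta, skip = _read_header(path)
    if meta.get("format") != "chainfel-thermo":
        raise ValueError(f"{path}: not a chainfel thermo TSV (header line 1)")
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return ThermoProfile(
        r=df["r_A"].to_numpy(),
        A=df["A"].to_numpy(),
        B=df["B"].to_numpy(),
        C=df["C"].to_numpy(),
        T0=float(meta["T0_K"]),
        residual_rms=df["residual_rms"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# dihedral trajectories
# ---------------------------------------------------------------------------

def write_dihedrals(trajectory: DihedralTrajectory, path: str | Path) -> None:
    m = trajectory.n_dihedrals
    df = pd.DataFrame(
        trajectory.angles, columns=[f"phi{k + 1}" for k in range(m)]
    )
    df.insert(0, "frame", np.arange(trajectory.n_frames))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_dihedrals(path: str | Path) -> DihedralTrajectory:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("phi")]
    if not cols:
        raise ValueError(f"{path}: no phi columns found in dihedral CSV")
    return DihedralTrajectory(angles=df[cols].to_numpy())


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def write_xyz(path: str | Path,
              elements: list[str],
              frames: np.ndarray,
              comment: str = "chainfel") -> None:
    """Write frame-concatenated XYZ; ``frames`` is (n_frames, n_atoms, 3)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            fh.write(f"{len(elements)}\n{comment} frame {f}\n")
            for elem, (x, y, z) in zip(elements, frame):
                fh.write(f"{elem} {x:.12f} {y:.12f} {z:.12f}\n")


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read frame-concatenated XYZ; returns (elements, (n_frames, n_atoms, 3))."""
    import MDAnalysis as mda

    u = mda.Universe(str(path), format="XYZ")
    elements = [str(name) for name in u.atoms.names]
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
    return elements, coords.astype(float)
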