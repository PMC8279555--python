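"""End-to-end scenario runner: sampler → WHAM → thermo → DPCA.

A :class:`~chainfel.config.RunConfig` fully determines a run; with the
same configuration and seed every output file is bit-identical.  When an
output directory is configured, the resolved configuration, histogram
sets, PMFs, thermo profile and the dominant conformation (as XYZ) are
written beside each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as cfio
from .config import RunConfig, dump_config
from .dpca import DihedralTrajectory, DominantConformation, \
    classify_motif, dominant_conformation
from .energy import CavityWall, PotentialParams
from .geometry import ChainTopology, Conformation
from .sampling import MCConfig, REMDConfig, WindowSchedule, \
    run_remd_umbrella, run_umbrella_windows
from .thermo import ThermoProfile, decompose_pmf_pipeline
from .wham import BiasedHistogramSet, PMFProfile, wham_solve

__all__ = ["ScenarioResult", "run_scenario"]


@dataclass
class ScenarioResult:
    """Everything a scenario run produces."""

    config: RunConfig
    histograms: BiasedHistogramSet
    pmf: PMFProfile
    thermo: ThermoProfile | None
    pmfs_by_temperature: dict[float, PMFProfile]
    dominant: DominantConformation | None
    motif: str | None


def _components(config: RunConfig):
    topo = ChainTopology(
        n_carbons=config.chain.n_carbons,
        bond_length=config.chain.bond_length,
        bond_angle=config.chain.bond_angle,
    )
    params = PotentialParams(
        torsion_coeffs=tuple(config.potential.torsion_coeffs),
        lj_epsilon=config.potential.lj_epsilon,
        lj_sigma=config.potential.lj_sigma,
        exclusion_depth=config.potential.exclusion_depth,
    )
    wall = None
    if config.cavity.enabled:
        wall = CavityWall(
            a=config.cavity.a, c=config.cavity.c,
            stiffness=config.cavity.stiffness,
        )
    schedule = WindowSchedule.from_range(
        config.umbrella.r_min, config.umbrella.r_max,
        spacing=config.umbrella.spacing, k=config.umbrella.k,
    )
    mc = MCConfig(
        temperature=config.mc.temperature,
        n_steps=config.mc.n_steps,
        equilibration=config.mc.equilibration,
        max_step=config.mc.max_step,
        pivot_prob=config.mc.pivot_prob,
        sample_stride=config.mc.sample_stride,
        seed=config.seed,
    )
    return topo, params, wall, schedule, mc


def run_scenario(config: RunConfig) -> ScenarioResult:
    """Execute the configured pipeline and optionally write its artifacts."""
    topo, params, wall, schedule, mc = _components(config)
    thermo: ThermoProfile | None = None
    pmfs_by_t: dict[float, PMFProfile] = {}

    if config.remd.enabled:
        remd = REMDConfig(
            ladder=tuple(config.remd.ladder),
            exchange_interval=config.remd.exchange_interval,
            seed=config.seed,
        )
        result = run_remd_umbrella(
            topo, params, wall, schedule, remd, mc,
            bin_width=config.wham.bin_width, keep_dihedrals=True,
        )
        thermo, profiles = decompose_pmf_pipeline(
            [result.histograms[t] for t in remd.ladder],
            T0=config.thermo.t0,
            tolerance=config.wham.tolerance,
            max_iterations=config.wham.max_iterations,
        )
        pmfs_by_t = {p.temperature: p for p in profiles}
        hist = result.histograms[min(remd.ladder, key=lambda t: abs(t - config.thermo.t0))]
        pmf = pmfs_by_t[hist.temperature]
    else:
        hist = run_umbrella_windows(
            topo, params, wall, schedule, mc,
            bin_width=config.wham.bin_width, keep_dihedrals=True,
        )
        pmf = wham_solve(
            hist, tolerance=config.wham.tolerance,
            max_iterations=config.wham.max_iterations,
            n_bootstrap=config.wham.bootstrap, bootstrap_seed=config.seed,
        )
        pmfs_by_t = {pmf.temperature: pmf}

    dominant = None
    motif = None
    if hist.dihedrals is not None and topo.n_dihedrals >= 1:
        # DPCA over the window whose bias center is closest to the PMF minimum
        r_min, _ = pmf.minimum()
        w = int(np.argmin(np.abs(hist.bias_r0 - r_min)))
        frames = hist.dihedrals[w]
        if frames.shape[0] >= 2:
            traj = DihedralTrajectory(angles=frames)
            dominant = dominant_conformation(traj, bins=config.dpca.bins)
            conf = Conformation(topo, dominant.dihedrals)
            try:
                motif = classify_motif(conf, cavity=wall)
            except ValueError:
                motif = None  # chain too short for the segment rules

    result_obj = ScenarioResult(
        config=config,
        histograms=hist,
        pmf=pmf,
        thermo=thermo,
        pmfs_by_temperature=pmfs_by_t,
        dominant=dominant,
        motif=motif,
    )
    if config.output.directory:
        _write_outputs(result_obj, topo)
    return result_obj


def _write_outputs(result: ScenarioResult, topo: ChainTopology) -> None:
    outdir = Path(result.config.output.directory)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(result.config, outdir / "config.yaml")
    cfio.write_histograms(result.histograms, outdir / "histograms.tsv")
    cfio.write_pmf(result.pmf, outdir / "pmf.tsv")
    if result.thermo is not None:
        cfio.write_thermo(result.thermo, outdir / "thermo.tsv")
    for t, profile in result.pmfs_by_temperature.items():
        if len(result.pmfs_by_temperature) > 1:
            cfio.write_pmf(profile, outdir / f"pmf_{t:.2f}K.tsv")
    if result.dominant is not None:
        conf = Conformation(topo, result.dominant.dihedrals)
        cfio.write_xyz(
            outdir / "dominant.xyz", ["C"] * topo.n_carbons, conf.coords,
            comment=f"dominant conformation ({result.motif})",
        )
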