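"""Run configuration: one YAML document describing a full pipeline run.

Sections mirror the pipeline stages (chain, potential, cavity, umbrella,
remd, mc, wham, thermo, dpca, output).  Unknown keys are rejected so a
typo cannot silently fall back to a default, and every run writes its
resolved configuration beside its outputs.  Units are Å, kJ/mol and K
throughout; there is no unit autodetection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .energy import DEFAULT_TORSION_COEFFS

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class ChainSection:
    n_carbons: int = 11
    bond_length: float = 1.53
    bond_angle: float = 112.7


@dataclass
class PotentialSection:
    torsion_coeffs: list[float] = field(
        default_factory=lambda: list(DEFAULT_TORSION_COEFFS)
    )
    lj_epsilon: float = 0.39
    lj_sigma: float = 3.95
    exclusion_depth: int = 3


@dataclass
class CavitySection:
    enabled: bool = False
    a: float = 4.0
    c: float = 6.5
    stiffness: float = 100.0


@dataclass
class UmbrellaSection:
    r_min: float = 2.0
    r_max: float = 13.0
    spacing: float = 0.5
    k: float = 50.0


@dataclass
class REMDSection:
    enabled: bool = False
    ladder: list[float] = field(default_factory=lambda: [
        298.15, 317.79, 338.46, 360.20, 383.13,
        407.22, 432.55, 459.21, 487.29, 500.0,
    ])
    exchange_interval: int = 500


@dataclass
class MCSection:
    temperature: float = 298.15
    n_steps: int = 20_000
    equilibration: int = 2_000
    max_step: float = 30.0
    pivot_prob: float = 0.2
    sample_stride: int = 2


@dataclass
class WHAMSection:
    bin_width: float = 0.1
    tolerance: float = 1e-6
    max_iterations: int = 100_000
    bootstrap: int = 0


@dataclass
class ThermoSection:
    t0: float = 298.15


@dataclass
class DPCASection:
    bins: int = 50


@dataclass
class OutputSection:
    directory: str | None = None


@dataclass
class RunConfig:
    """The resolved configuration of a pipeline run."""

    chain: ChainSection = field(default_factory=ChainSection)
    potential: PotentialSection = field(default_factory=PotentialSection)
    cavity: CavitySection = field(default_factory=CavitySection)
    umbrella: UmbrellaSection = field(default_factory=UmbrellaSection)
    remd: REMDSection = field(default_factory=REMDSection)
    mc: MCSection = field(default_factory=MCSection)
    wham: WHAMSection = field(default_factory=WHAMSection)
    thermo: ThermoSection = field(default_factory=ThermoSection)
    dpca: DPCASection = field(default_factory=DPCASection)
    output: OutputSection = field(default_factory=OutputSection)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        return _build(cls, data, path="")


def _build(dc_type: type, data: dict[str, Any], path: str):
    """Construct a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"section {path or '<root>'} must be a mapping")
    known = {f.name: f for f in dataclasses.fields(dc_type)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in section {path or '<root>'}"
        )
    kwargs: dict[str, Any] = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type.endswith("Section")
        ):
            sub_type = f.type if dataclasses.is_dataclass(f.type) else _SECTION_TYPES[f.type]
            kwargs[name] = _build(sub_type, value, path=f"{path}{name}.")
        else:
            kwargs[name] = value
    return dc_type(**kwargs)


_SECTION_TYPES = {
    "ChainSection": ChainSection,
    "PotentialSection": PotentialSection,
    "CavitySection": CavitySection,
    "UmbrellaSection": UmbrellaSection,
    "REMDSection": REMDSection,
    "MCSection": MCSection,
    "WHAMSection": WHAMSection,
    "ThermoSection": ThermoSection,
    "DPCASection": DPCASection,
    "OutputSection": OutputSection,
}


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
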