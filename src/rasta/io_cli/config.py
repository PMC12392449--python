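"""Run configuration: schema-validated YAML with every numeric default.

Unknown keys are rejected so typos cannot silently fall back to defaults.
The full (resolved) configuration is echoed into output provenance by the
CLI so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from rasta.prior import PriorParams

__all__ = ["BeamConfig", "GridConfig", "ModelConfig", "ScheduleConfig",
           "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


@dataclass
class BeamConfig:
    wavelength: float = 2.5  # Å
    kmax: float = 3.0  # Å^-1
    i0_eff: float | None = None  # direct effective intensity, overrides below
    photons_per_pulse: float = 1.0e12
    beam_diameter_um: float = 1.0


@dataclass
class GridConfig:
    n_r: int = 64  # radial likelihood-grid cells
    n_s: int = 64  # angular likelihood-grid cells
    n_rotations: int = 72  # orientation quadrature nodes (1 or 2*t**2)
    sim_n_r: int = 64  # simulator tabulation grid
    sim_n_s: int = 64


@dataclass
class ModelConfig:
    height: float = 7.0  # electrons per bead
    bead_fwhm: float = 2.0  # Å


@dataclass
class ScheduleConfig:
    total_steps: int = 2000
    sigma0: float = 3.0
    anneal_fraction: float = 0.8
    eta0: float = 1.0e-3
    eta1: float = 1.0e-4
    beta: float = 0.9
    batch_size: int = 1000
    init_radius_of_gyration: float = 5.0
    checkpoint_sigmas: list[float] = field(default_factory=list)


@dataclass
class RunConfig:
    beam: BeamConfig = field(default_factory=BeamConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    prior: PriorParams = field(default_factory=PriorParams)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(
            f"{context}: unknown keys {sorted(unknown)}; "
            f"valid keys: {sorted(fields)}"
        )
    return cls(**data)


def load_config(source: "str | Path | dict | None") -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file or dict (None: defaults)."""
    if source is None:
        return RunConfig()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    sections = {
        "beam": BeamConfig,
        "grid": GridConfig,
        "model": ModelConfig,
        "prior": PriorParams,
        "schedule": ScheduleConfig,
    }
    unknown = set(data) - set(sections) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        if name in data:
            kwargs[name] = _build(cls, data[name], name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    return RunConfig(**kwargs)
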