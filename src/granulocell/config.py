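"""Declarative run configuration: YAML with one section per module.

An empty file (or ``{}``) yields the full default parameter set — the
model constants of the simulation (time step 5e-5, contact stiffnesses
5e4·d / 5e3·d, kinetic-energy threshold 2e-3, structural springs 6.25·L_i²,
4% detachment, (20d)³ box, 16×10 replicates).  Unknown keys and
out-of-range values raise :class:`~granulocell.errors.ConfigError` listing
the offending entries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .experiment import ScenarioConfig

__all__ = ["FullConfig", "load_config", "save_config", "default_config"]


@dataclass(frozen=True)
class UnitsSection:
    length_unit_um: float = 32.0
    particle_density_g_cm3: float = 1.07
    fluid_density_g_cm3: float = 1.00
    gravity_m_s2: float = 9.81


@dataclass(frozen=True)
class BedSection:
    box_size: float = 20.0
    d_mean: float = 1.0
    dispersion: float = 0.05
    y_u: float = 5e4
    y_l: float = 5e3
    dt: float = 5e-5
    ke_threshold: float = 2e-3
    target_layers: int = 3
    seed: int = 0
    max_steps: int = 3_000_000


@dataclass(frozen=True)
class CellSection:
    aspect_ratio: float = 1.0
    k_s_coefficient: float = 6.25
    c_s_coefficient: float = 6.25e-2
    contraction_steps: int = 50_000
    relax_speed_tol: float = 1e-3


@dataclass(frozen=True)
class AdhesionSection:
    detachment_fraction: float = 0.04
    binding_stretch_fraction: float = 2.5e-5
    binding_damping_fraction: float = 1.25e-2


@dataclass(frozen=True)
class SweepSection:
    aspect_ratios: tuple = (1.0,)
    relative_densities: tuple = (1.0,)
    bed_layers: tuple = (3,)
    n_drop_positions: int = 16
    n_bed_configs: int = 10
    master_seed: int = 0


@dataclass(frozen=True)
class FullConfig:
    units: UnitsSection = field(default_factory=UnitsSection)
    bed: BedSection = field(default_factory=BedSection)
    cell: CellSection = field(default_factory=CellSection)
    adhesion: AdhesionSection = field(default_factory=AdhesionSection)
    sweep: SweepSection = field(default_factory=SweepSection)

    def scenario_config(self, **overrides) -> ScenarioConfig:
        """Collapse the sections into one ScenarioConfig."""
        cfg = ScenarioConfig(
            aspect_ratio=self.cell.aspect_ratio,
            bed_layers=self.bed.target_layers,
            box_size=self.bed.box_size,
            dispersion=self.bed.dispersion,
            n_drop_positions=self.sweep.n_drop_positions,
            n_bed_configs=self.sweep.n_bed_configs,
            master_seed=self.sweep.master_seed,
            dt=self.bed.dt,
            ke_threshold=self.bed.ke_threshold,
            settle_max_steps=self.bed.max_steps,
            contraction_steps=self.cell.contraction_steps,
            relax_speed_tol=self.cell.relax_speed_tol,
        )
        return cfg.replace(**overrides) if overrides else cfg


_SECTIONS = {
    "units": UnitsSection,
    "bed": BedSection,
    "cell": CellSection,
    "adhesion": AdhesionSection,
    "sweep": SweepSection,
}

_RANGES = {
    ("bed", "dispersion"): (0.0, 0.2),
    ("bed", "dt"): (1e-9, 1e-2),
    ("bed", "ke_threshold"): (0.0, 1.0),
    ("bed", "box_size"): (2.0, 1e4),
    ("bed", "target_layers"): (1, 10),
    ("cell", "aspect_ratio"): (1e-3, 1e3),
    ("adhesion", "detachment_fraction"): (0.0, 1.0),
    ("sweep", "n_drop_positions"): (1, 4096),
    ("sweep", "n_bed_configs"): (1, 4096),
}


def default_config() -> FullConfig:
    return FullConfig()


def load_config(path) -> FullConfig:
    """Load and validate a YAML configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    bad = [k for k in data if k not in _SECTIONS]
    if bad:
        raise ConfigError(f"unknown config sections: {bad}")
    sections = {}
    problems = []
    for name, cls in _SECTIONS.items():
        raw = data.get(name, {}) or {}
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = [k for k in raw if k not in known]
        if unknown:
            problems.extend(f"{name}.{k}: unknown key" for k in unknown)
            raw = {k: v for k, v in raw.items() if k in known}
        for key, value in raw.items():
            rng = _RANGES.get((name, key))
            if rng is not None and not (rng[0] <= value <= rng[1]):
                problems.append(
                    f"{name}.{key}: {value} outside [{rng[0]}, {rng[1]}]"
                )
        if name == "sweep":
            raw = {
                k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
            }
        sections[name] = cls(**raw)
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    return FullConfig(**sections)


def save_config(path, config: FullConfig) -> None:
    data = {
        name: dataclasses.asdict(getattr(config, name)) for name in _SECTIONS
    }
    for key, value in data["sweep"].items():
        if isinstance(value, tuple):
            data["sweep"][key] = list(value)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
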