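"""Run configuration: one human-readable YAML file drives every stage.

The shipped default file (``spinefem/data/default_config.yaml``) documents
every tunable parameter; :func:`load_config` validates against the dataclass
schemas (unknown keys are rejected, bound violations name the offending
key).  Configurations round-trip exactly through write -> read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .elastic import Material
from .errors import ConfigurationError
from .geometry import COMPARTMENTS, GeometryParams
from .morphogenesis import ProcessSchedule
from .synth import GeneratorConfig


@dataclass(frozen=True)
class SimulationSettings:
    mesh_size: float = 3.5  # um; target triangle edge length
    bc: str = "fixed_outer"

    def __post_init__(self):
        if self.mesh_size <= 0:
            raise ConfigurationError("simulation.mesh_size must be > 0")
        if self.bc not in ("fixed_outer", "pinned"):
            raise ConfigurationError(
                f"simulation.bc must be 'fixed_outer' or 'pinned', got '{self.bc}'"
            )


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to re-derive any output: parameters + seed."""

    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "runs/default"
    geometry: GeometryParams = field(default_factory=GeometryParams)
    materials: dict = field(
        default_factory=lambda: {
            "medulla": Material(E=1.0, nu=0.3),
            "cortex_posterior": Material(E=1.0, nu=0.3),
            "cortex_anterior": Material(E=1.0, nu=0.3),
            "irs_posterior": Material(E=0.5, nu=0.3),
            "irs_anterior": Material(E=0.5, nu=0.3),
            "outer_ring": Material(E=20.0, nu=0.3),
        }
    )
    schedule: ProcessSchedule = field(default_factory=ProcessSchedule)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self):
        missing = set(COMPARTMENTS) - set(self.materials)
        if missing:
            raise ConfigurationError(f"materials missing for: {sorted(missing)}")


def _build(cls, data: dict, context: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"{context}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{context}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{context}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    known = {"seed", "log_level", "output_dir", "geometry", "materials",
             "schedule", "simulation", "generator"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"config: unknown top-level keys {sorted(unknown)}")

    kwargs: dict = {}
    for key in ("seed", "log_level", "output_dir"):
        if key in data:
            kwargs[key] = data[key]
    if "geometry" in data:
        kwargs["geometry"] = _build(GeometryParams, data["geometry"], "geometry")
    if "materials" in data:
        mats = {}
        for name, md in (data["materials"] or {}).items():
            mats[name] = _build(Material, md, f"materials.{name}")
        kwargs["materials"] = mats
    if "schedule" in data:
        kwargs["schedule"] = _build(ProcessSchedule, data["schedule"], "schedule")
    if "simulation" in data:
        kwargs["simulation"] = _build(
            SimulationSettings, data["simulation"], "simulation"
        )
    if "generator" in data:
        gen = dict(data["generator"])
        if "geometry" in gen:
            gen["geometry"] = _build(
                GeometryParams, gen["geometry"], "generator.geometry"
            )
        if "brdu_fade" in gen:
            gen["brdu_fade"] = tuple(gen["brdu_fade"])
        if "tunel_rise" in gen:
            gen["tunel_rise"] = tuple(gen["tunel_rise"])
        kwargs["generator"] = _build(GeneratorConfig, gen, "generator")
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    def as_dict(obj):
        d = dataclasses.asdict(obj)
        return d

    out = {
        "seed": cfg.seed,
        "log_level": cfg.log_level,
        "output_dir": cfg.output_dir,
        "geometry": as_dict(cfg.geometry),
        "materials": {k: as_dict(v) for k, v in cfg.materials.items()},
        "schedule": as_dict(cfg.schedule),
        "simulation": as_dict(cfg.simulation),
        "generator": as_dict(cfg.generator),
    }
    out["generator"]["brdu_fade"] = list(cfg.generator.brdu_fade)
    out["generator"]["tunel_rise"] = list(cfg.generator.tunel_rise)
    return out


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; ``None`` loads the shipped default."""
    if path is None:
        text = (
            resources.files("spinefem").joinpath("data/default_config.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"config parse error: {exc}") from exc
    return config_from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    """Stable content hash of a configuration (for run manifests)."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
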