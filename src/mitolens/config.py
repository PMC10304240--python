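"""Run configuration: schema-validated YAML/JSON, manifest writing.

All lengths are nanometres, all angles degrees at the interface (the
library works in radians internally).  Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .bilayer import reference_wall
from .geometry import MitochondrionModel, build_mitochondrion
from .stratified import Layer, StratifiedStack

__all__ = ["RunConfig", "load_config", "model_from_config", "write_manifest"]

SCHEMA_VERSION = 1


class GeometrySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    radius_nm: float = 1000.0
    lattice_nm: float = 400.0
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)  # ZYX Euler
    phase_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_A: float = 1.33
    n_B: float = 1.48
    n_exterior: float = 1.33


class WallSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: str | None = "standard"          # the 12-bilayer/11-gap wall
    layers: list[tuple[float, float]] | None = None   # explicit [n, d_nm] pairs
    enabled: bool = True


class IlluminationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    wavelength_nm: float = 550.0
    spacing_nm: float = Field(28.0, ge=2.0, le=50.0)
    polarization: tuple[float, float] = (1.0, 0.0)


class TransportSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    strategy: str = Field("ii", pattern="^(i|ii|iii)$")
    epsilon: float = 1e-9
    max_depth: int = 60


class IntegrationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    planes_um: tuple[float, float, float] = (0.5, 6.0, 0.1)  # start, stop, step
    pixel_nm: float | None = None            # default lambda/4
    model: str = Field("first_order", pattern="^(first_order|patch)$")


class OutputSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    directory: str = "out"
    write_tiff: bool = True
    write_tsv: bool = True


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    geometry: GeometrySection = GeometrySection()
    wall: WallSection = WallSection()
    illumination: IlluminationSection = IlluminationSection()
    transport: TransportSection = TransportSection()
    integration: IntegrationSection = IntegrationSection()
    output: OutputSection = OutputSection()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def wall_from_config(cfg: RunConfig) -> StratifiedStack | None:
    if not cfg.wall.enabled:
        return None
    if cfg.wall.layers is not None:
        return StratifiedStack(
            cfg.geometry.n_A,
            tuple(Layer(n, d) for n, d in cfg.wall.layers),
            cfg.geometry.n_B,
        )
    if cfg.wall.preset == "standard":
        return reference_wall()
    raise ValueError(f"unknown wall preset {cfg.wall.preset!r}")


def model_from_config(cfg: RunConfig) -> MitochondrionModel:
    g = cfg.geometry
    return build_mitochondrion(
        radius_nm=g.radius_nm,
        lattice_nm=g.lattice_nm,
        rotation_deg=g.rotation_deg,
        phase_offset=g.phase_offset,
        n_A=g.n_A,
        n_B=g.n_B,
        n_exterior=g.n_exterior,
        wall_stack=wall_from_config(cfg),
    )


def write_manifest(path: str | Path, cfg: RunConfig, extra: dict | None = None) -> dict:
    """Write a JSON manifest capturing config, hash and versions."""
    cfg_json = cfg.model_dump()
    digest = hashlib.sha256(json.dumps(cfg_json, sort_keys=True).encode()).hexdigest()
    manifest = {
        "config": cfg_json,
        "config_sha256": digest,
        "seed": cfg.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
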