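"""Run configuration, report serialization and provenance.

Configurations are YAML files validated against a versioned pydantic schema
(unknown keys are rejected, every default is made explicit in the serialized
provenance block).  Reports are written as JSON (full structure, including
provenance sufficient to re-run the producing command) plus a CSV summary
table with one row per phase and target region.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .phantom import PhantomConfig
from .solver import DEFAULT_CONDUCTIVITY, ConductivityMap

__all__ = ["ConfigError", "PhantomSettings", "RunConfig", "load_config",
           "save_config", "config_hash", "write_report", "read_report"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


class PhantomSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    head_radius: float = Field(80.0, gt=0)
    skin_thickness: float = Field(5.0, gt=0)
    bone_thickness: float = Field(6.0, gt=0)
    eye_radius: float = Field(12.0, gt=0)
    eye_azimuth_deg: float = 24.0
    eye_protrusion: float = Field(2.0, ge=0)
    lid_offset: float = Field(1.4, gt=0)
    aperture_half_angle_deg: float = Field(20.0, gt=0)
    socket_thickness: float = Field(4.0, gt=0)
    socket_aperture_deg: float = Field(60.0, gt=0)
    fine_size: float = Field(3.0, gt=0)
    coarse_size: float = Field(8.0, gt=0)
    fine_radius: float = Field(40.0, gt=0)
    eye_surface_size: float = Field(1.7, gt=0)
    skin_surface_size: float = Field(5.0, gt=0)
    periocular_skin_size: float = Field(1.7, gt=0)
    periocular_angle_deg: float = Field(32.0, gt=0)
    jitter: float = Field(0.35, ge=0, le=0.49)

    def to_phantom_config(self, seed: int) -> PhantomConfig:
        return PhantomConfig(seed=seed, **self.model_dump())


class RunConfig(BaseModel):
    """Validated experiment configuration with explicit defaults."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    phantom: PhantomSettings = Field(default_factory=PhantomSettings)
    montage: str = "electrode_5"
    currents_ma: list[float] | None = None
    conductivity: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITY))
    frequency_hz: float = 10.0
    phases: list[str] = Field(default_factory=lambda: ["same", "anti"])
    grid_resolution_deg: float = Field(1.0, gt=0)
    edge_length_mm: float = Field(42.0, gt=0)
    seed: int = 0
    output_dir: str = "out"

    @field_validator("conductivity")
    @classmethod
    def _positive_sigma(cls, v):
        bad = {t: s for t, s in v.items() if not s > 0}
        if bad:
            raise ValueError(f"non-positive conductivities: {bad}")
        return v

    @field_validator("phases")
    @classmethod
    def _known_phases(cls, v):
        unknown = set(v) - {"same", "anti"}
        if unknown:
            raise ValueError(f"unknown phases: {sorted(unknown)}")
        return v

    @field_validator("currents_ma")
    @classmethod
    def _positive_currents(cls, v):
        if v is not None and any(c <= 0 for c in v):
            raise ValueError("currents must be positive")
        return v

    def conductivity_map(self) -> ConductivityMap:
        values = dict(DEFAULT_CONDUCTIVITY)
        values.update(self.conductivity)
        return ConductivityMap(values=values, frequency_hz=self.frequency_hz)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Raises :class:`ConfigError` listing the offending keys on schema
    violations.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"invalid configuration {path}: {exc}") from exc


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(comparison, out_dir, config: RunConfig | None = None,
                 include_timestamp: bool = False) -> dict:
    """Write a phase comparison as ``report.json`` + ``report.csv``.

    Without ``include_timestamp`` the JSON is byte-identical across runs
    with the same seed and configuration.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = comparison.to_dict()
    doc["provenance"] = dict(doc.get("provenance", {}))
    doc["provenance"]["package_version"] = __version__
    if config is not None:
        doc["provenance"]["config"] = config.model_dump()
        doc["provenance"]["config_hash"] = config_hash(config)
        doc["provenance"]["seed"] = config.seed
    if include_timestamp:
        doc["provenance"]["timestamp"] = datetime.now(
            timezone.utc).isoformat()
    json_path = out / "report.json"
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    rows = []
    for phase, reports in comparison.phase_reports.items():
        for (eye, region), rep in reports.items():
            rows.append({
                "phase": phase, "eye": eye, "region": region,
                "max_in": rep.max_in.value,
                "max_in_lon": rep.max_in.lon, "max_in_lat": rep.max_in.lat,
                "max_upper": rep.max_upper.value,
                "max_adjacent": max(p.value
                                    for p in rep.max_adjacent.values()),
                "delta_upper": rep.delta_upper,
                "delta_adjacent": rep.delta_adjacent,
            })
    csv_path = out / "report.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return {"json": json_path, "csv": csv_path}


def read_report(path) -> dict:
    with open(Path(path)) as fh:
        return json.load(fh)
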