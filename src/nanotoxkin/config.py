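"""Run configuration: a flat, validated YAML key/value block.

Defaults reproduce the standard assay parameter set (35 nm particle radius,
350 kg/m^3 effective bulk density, 5 um cell radius, 5e5 cells/mL, water
viscosity law).  Unknown keys are rejected so typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .physchem import (
    CellSpec,
    ParticleSpec,
    VISCOSITY_A,
    VISCOSITY_B,
    VISCOSITY_C,
)

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    particle_radius_m: float = 35e-9
    particle_bulk_density_kg_m3: float = 350.0
    cell_radius_m: float = 5e-6
    cell_concentration_per_ml: float = 5e5
    viscosity_A: float = VISCOSITY_A
    viscosity_B: float = VISCOSITY_B
    viscosity_C: float = VISCOSITY_C
    convention: str = "corrected"
    transient_k1: bool = False
    time_window_min: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.convention not in ("corrected", "printed"):
            raise ValueError(f"unknown convention {self.convention!r}")
        for name in (
            "particle_radius_m",
            "particle_bulk_density_kg_m3",
            "cell_radius_m",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.cell_concentration_per_ml < 0:
            raise ValueError("cell_concentration_per_ml must be >= 0")
        if self.time_window_min is not None:
            lo, hi = self.time_window_min
            if not (0 <= lo < hi):
                raise ValueError("time_window_min must be an increasing pair")
            object.__setattr__(self, "time_window_min", (float(lo), float(hi)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key/value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "time_window_min" in raw and raw["time_window_min"] is not None:
            raw["time_window_min"] = tuple(raw["time_window_min"])
        return cls(**raw)

    def particle(self) -> ParticleSpec:
        return ParticleSpec(
            radius=self.particle_radius_m,
            bulk_density=self.particle_bulk_density_kg_m3,
        )

    def cell(self) -> CellSpec:
        return CellSpec.from_per_ml(
            self.cell_concentration_per_ml, radius=self.cell_radius_m
        )

    def digest(self) -> str:
        """Short stable hash of the configuration (for run logs)."""
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
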