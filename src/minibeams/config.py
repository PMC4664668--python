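"""Run configuration: strict YAML schema, defaults, hashing.

A run config has a ``beam`` section (always), a ``phantom`` section
(depth extent and grids), an optional ``plan`` section for interleaved
arrays, and a ``model`` section for the knobs that are genuinely open
(merge rule, sparing factor, width limit, incident-profile shape).
Unknown keys are rejected; every default is explicit, so a round-trip
through YAML is the identity.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import ConfigError
from .interleave_planner import Direction, InterleavePlan, TargetBox
from .ion_physics import EnergySpec, energy_for_range, get_species
from .mcs_transport import BeamShape, BeamSpec, IncidentProfile


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class BeamConfig(_Strict):
    species: str = "proton"
    energy_mev_u: Optional[float] = None
    range_cm: Optional[float] = None
    energy_spread_fwhm_mev_u: float = 0.0
    shape: Literal["planar", "pencil"] = "planar"
    incident_width_fwhm_mm: float = 0.3
    spacing_on_center_mm: float = 0.0
    angular_divergence_mrad: float = 0.0
    incident_profile: Literal["gaussian", "tophat"] = "gaussian"

    @model_validator(mode="after")
    def _one_energy(self):
        if (self.energy_mev_u is None) == (self.range_cm is None):
            raise ValueError("specify exactly one of energy_mev_u or range_cm")
        return self

    def to_beam(self) -> BeamSpec:
        species = get_species(self.species)
        if self.energy_mev_u is not None:
            e0 = self.energy_mev_u
        else:
            e0 = energy_for_range(species, self.range_cm)
        return BeamSpec(
            species=species,
            energy=EnergySpec(e0, self.energy_spread_fwhm_mev_u),
            shape=BeamShape(self.shape),
            incident_width_fwhm=self.incident_width_fwhm_mm,
            angular_divergence_rms=self.angular_divergence_mrad,
            spacing_on_center=self.spacing_on_center_mm,
            incident_profile=IncidentProfile(self.incident_profile),
        )


class PhantomConfig(_Strict):
    material: Literal["water"] = "water"
    depth_mm: float = 100.0
    depth_step_mm: float = 0.1
    lateral_resolution_mm: float = 0.01


class PlanConfig(_Strict):
    target_x_min_mm: float = 36.0
    target_x_max_mm: float = 42.5
    target_v_min_mm: float = -3.25
    target_v_max_mm: float = 3.25
    phantom_extent_mm: float = 0.0  # 0 => symmetric
    directions: list[str] = ["+x", "+y", "-x", "-y"]
    pedestal_dose_gy: float = 14.0
    pedestal_to_sobp_ratio: float = 20.0 / 14.0
    rbe: float = 3.0

    def to_plan(self, beam: BeamConfig, model: "ModelConfig") -> InterleavePlan:
        return InterleavePlan(
            species=get_species(beam.species),
            target=TargetBox(
                x_min=self.target_x_min_mm,
                x_max=self.target_x_max_mm,
                v_min=self.target_v_min_mm,
                v_max=self.target_v_max_mm,
                phantom_extent=self.phantom_extent_mm,
            ),
            incident_width_fwhm=beam.incident_width_fwhm_mm,
            spacing_on_center=beam.spacing_on_center_mm,
            directions=tuple(Direction(d) for d in self.directions),
            pedestal_dose=self.pedestal_dose_gy,
            pedestal_to_sobp_ratio=self.pedestal_to_sobp_ratio,
            rbe=self.rbe,
            width_limit=model.width_limit_mm,
        )


class ModelConfig(_Strict):
    merge_rule: Literal["valley_peak_threshold", "fwhm_equals_spacing"] = "valley_peak_threshold"
    valley_peak_threshold: float = 0.95
    sparing_factor: float = 7.0
    width_limit_mm: float = 0.7


class RunConfig(_Strict):
    beam: BeamConfig = BeamConfig(range_cm=10.0)
    phantom: PhantomConfig = PhantomConfig()
    plan: Optional[PlanConfig] = None
    model: ModelConfig = ModelConfig()
    seed: int = 12345
    output_dir: str = "."

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form (stable key order)."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config.

    Raises
    ------
    ConfigError
        Listing the offending keys on any schema violation.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"not valid YAML: {exc}") from exc
    return parse_config(raw)


def parse_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors())
        raise ConfigError(f"invalid config ({keys}): {exc}") from exc


def save_config(cfg: RunConfig, path, header: str | None = None) -> None:
    text = cfg.to_yaml()
    if header:
        text = "".join(f"# {line}\n" for line in header.splitlines()) + text
    Path(path).write_text(text)
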