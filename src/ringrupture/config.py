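"""Run-configuration schema (YAML/JSON) with explicit units in every key.

The published protocol mixes µm, nm and pN; configuration keys therefore
always carry a unit suffix and are converted to the internal pN/nm/s
system when the domain objects are built.  Validation is strict: unknown
keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .polymer import WLCParams
from .simulate import BondModel, PullingProtocol

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WLCConfig(_Strict):
    persistence_length_nm: float = 50.0
    contour_length_um: float = 16.32

    def build(self) -> WLCParams:
        return WLCParams(
            persistence_length_nm=self.persistence_length_nm,
            contour_length_nm=self.contour_length_um * 1000.0,
        )


class BondConfig(_Strict):
    k0_per_s: float = Field(gt=0)
    delta_nm: float = Field(ge=0)

    def build(self) -> BondModel:
        return BondModel(k0_per_s=self.k0_per_s, delta_nm=self.delta_nm)


class ProtocolConfig(_Strict):
    velocity_um_per_s: float = 0.16
    dt_s: float = 0.01
    anchor_distance_mean_um: float = 8.8
    anchor_distance_sd_um: float = 0.5
    thermal_energy_pn_nm: float = 4.114
    initial_displacement_um: float = 0.0

    def build(self, seed: int | None = None) -> PullingProtocol:
        return PullingProtocol(
            velocity_nm_per_s=self.velocity_um_per_s * 1000.0,
            dt_s=self.dt_s,
            anchor_distance_mean_nm=self.anchor_distance_mean_um * 1000.0,
            anchor_distance_sd_nm=self.anchor_distance_sd_um * 1000.0,
            thermal_energy_pn_nm=self.thermal_energy_pn_nm,
            initial_displacement_nm=self.initial_displacement_um * 1000.0,
            seed=seed,
        )


class SimulateConfig(_Strict):
    mode: Literal["single", "two_dna"] = "single"
    n_events: int = Field(default=10_000, ge=1)
    k0_per_s: float | None = Field(default=None, gt=0)  # two_dna mode
    delta_choices_nm: dict[float, float] | None = None  # two_dna mode
    bead_side_contour_um: float = 2.45
    bead_side_persistence_nm: float = 50.0

    @model_validator(mode="after")
    def _check_two_dna(self) -> "SimulateConfig":
        if self.mode == "two_dna":
            if self.k0_per_s is None or not self.delta_choices_nm:
                raise ValueError(
                    "two_dna mode requires k0_per_s and delta_choices_nm"
                )
        return self


class FitConfig(_Strict):
    bounds_k0_per_s: tuple[float, float] = (1e-6, 1.0)
    bounds_delta_nm: tuple[float, float] = (0.1, 3.0)
    n_sim: int = Field(default=2000, ge=100)
    scaling: Literal["likelihood", "raw"] = "likelihood"
    compute_ci: bool = False
    ci_n_samples: int = Field(default=500, ge=50)
    ci_n_sim: int = Field(default=500, ge=10)
    bootstrap_subsamples: int = Field(default=0, ge=0)
    bootstrap_fraction: float = Field(default=0.8, gt=0, le=1)


class BeadsConfig(_Strict):
    lambda_efficiency: float | None = Field(default=None, ge=0, le=1)
    calibrate_to_beads_per_dna: float | None = Field(default=None, ge=0)
    proximity_threshold_um: float = Field(default=1.0, gt=0)
    n_steps: int = Field(default=10_000, ge=1)
    occupancy_csv: str | None = None
    synthetic_n_dna: int = Field(default=1000, ge=1)
    synthetic_mean_cohesins: float = Field(default=1.5, ge=0)
    synthetic_dna_length_um: float = Field(default=16.32, gt=0)

    @model_validator(mode="after")
    def _check_mode(self) -> "BeadsConfig":
        if self.lambda_efficiency is None and self.calibrate_to_beads_per_dna is None:
            raise ValueError(
                "set either lambda_efficiency or calibrate_to_beads_per_dna"
            )
        return self


class ScenarioConfig(_Strict):
    name: str = "head"
    n_events: int | None = None
    noise_sd_pn: float = Field(default=0.0, ge=0)


class RunConfig(_Strict):
    """Top-level configuration for all CLI commands."""

    seed: int = 0
    log_level: str = "INFO"
    wlc: WLCConfig = Field(default_factory=WLCConfig)
    bond: BondConfig | None = None
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    beads: BeadsConfig | None = None
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)


def load_config(path: str | Path | None, **overrides: Any) -> RunConfig:
    """Load and validate a YAML or JSON configuration file."""
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: top level must be a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.model_validate(data)
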