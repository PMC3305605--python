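"""Scenario configuration: schema, validation, defaults.

A scenario is a YAML file with unit-suffixed keys (all SI) describing the
blood and drug properties, the example network, the REV upscaling of the
capillary bed, the two alveolus-model parameter sets (healthy/tumor), the
transfer functions and run control.  Unknown keys are rejected; every value
has a validated default reproducing the example simulation set-up (1064 /
199.5 Pa root pressures, 21 alveoli of which 3 tumorous).
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ScenarioConfig", "load_config", "dump_config", "default_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class BloodConfig(_Section):
    mass_density_kg_per_m3: float = 1050.0
    molar_density_mol_per_m3: float = 284.0
    plasma_viscosity_pa_s: float = 1.2e-3
    #: (diameter [um], discharge hematocrit) lookup pairs
    hematocrit_table: list[tuple[float, float]] = Field(
        default_factory=lambda: [
            (8.0, 0.12), (10.0, 0.15), (15.0, 0.22), (20.0, 0.28),
            (30.0, 0.35), (40.0, 0.40), (60.0, 0.43), (100.0, 0.45),
        ])


class DrugConfig(_Section):
    half_life_s: float = 21600.0
    molecular_radius_m: float = 3.7e-9
    inlet_mole_fraction: float = 1e-6
    bolus_duration_s: float | None = None  # None: continuous injection
    temperature_k: float = 310.15

    @property
    def bolus_duration(self) -> float:
        return math.inf if self.bolus_duration_s is None else self.bolus_duration_s


class GraphConfig(_Section):
    n_alveoli: int = 21
    tumor_ids: list[int] = Field(default_factory=lambda: [4, 10, 16])
    arterial_root_order: int = 4
    venous_root_order: int = 4
    graph_file: str | None = None  # read instead of generating


class RevConfig(_Section):
    n_segments: int = 1800
    diameter_m: float = 8e-6
    seg_length_m: float = 1e-5
    cuboid_m: tuple[float, float, float] = (364e-6, 364e-6, 112e-6)
    orientation: Literal["rows_x", "rows_y"] = "rows_x"
    probe_pressure_pa: float = 100.0


class MeshConfig(_Section):
    n_r: int = 3
    n_theta: int = 4
    n_phi: int = 8
    cap_half_angle_deg: float = 30.0


class TissueConfig(_Section):
    porosity: float = 0.13
    tissue_volume_fraction: float = 0.9
    permeability_m2: float = 5e-18
    tortuosity: float = 0.28
    viscosity_pa_s: float = 1.2e-3
    mass_density_kg_per_m3: float = 1030.0
    molar_density_mol_per_m3: float = 303.5
    lymph_conductivity_m_per_pa_s: float = 2.6e-9
    lymph_surface_density_per_m: float = 3.0
    lymph_pressure_pa: float = -1200.0
    lymph_clamped: bool = True
    receptor_concentration_mol_per_m3: float = 1e-5
    k_on_m3_per_mol_s: float = 100.0
    k_off_per_s: float = 1e-4
    boundary_pressure_pa: float = -1064.0


class CapillaryConfig(_Section):
    volume_fraction: float = 0.1
    viscosity_pa_s: float = 2.1e-3
    mass_density_kg_per_m3: float = 1050.0
    molar_density_mol_per_m3: float = 284.0
    #: None: healthy from REV upscaling / tumor from r^2/8
    permeability_m2: tuple[float, float, float] | None = None
    tumor_capillary_radius_m: float = 10e-6


class TransferConfig(_Section):
    hydraulic_conductivity_m_per_pa_s: float = 2.7e-12
    surface_density_per_m: float | None = None  # None: shell closed form
    osmotic_reflection_coefficient: float = 0.8
    solvent_drag_reflection_coefficient: float = 0.91
    diffusive_permeability_m_per_s: float = 5e-9
    capillary_oncotic_pressure_pa: float = 3724.0
    interstitial_oncotic_pressure_pa: float = 1862.0


class DcmConfig(_Section):
    shell_inner_radius_m: float = 70e-6
    shell_outer_radius_m: float = 182e-6
    mesh: MeshConfig = Field(default_factory=MeshConfig)
    tissue: TissueConfig = Field(default_factory=TissueConfig)
    capillary: CapillaryConfig = Field(default_factory=CapillaryConfig)
    newton_tolerance: float = 1e-8


def _tumor_dcm_defaults() -> "DcmConfig":
    return DcmConfig(
        shell_inner_radius_m=0.0,
        tissue=TissueConfig(
            porosity=0.27,
            tissue_volume_fraction=0.8,
            permeability_m2=4e-17,
            tortuosity=0.71,
            boundary_pressure_pa=133.0,
        ),
        capillary=CapillaryConfig(volume_fraction=0.2),
    )


def _tumor_transfer_defaults() -> "TransferConfig":
    return TransferConfig(
        hydraulic_conductivity_m_per_pa_s=2.1e-11,
        surface_density_per_m=2.0e4,
        solvent_drag_reflection_coefficient=0.82,
        diffusive_permeability_m_per_s=5e-8,
        capillary_oncotic_pressure_pa=2660.0,
        interstitial_oncotic_pressure_pa=1995.0,
    )


class CouplingConfig(_Section):
    n_substeps: int = 1  # DCM steps per graph step
    recompute_effective_resistance: bool = False  # cached-static per run


class RunConfig(_Section):
    t_end_s: float = 11.0
    courant: float = 0.9
    output_interval_s: float = 1.0
    output_dir: str | None = None
    arterial_pressure_pa: float = 1064.0
    venous_pressure_pa: float = 199.5
    gravity_enabled: bool = False
    compliance_enabled: bool = False
    seed: int | None = None  # recorded in the manifest; the model is
    # deterministic, the seed only matters for future stochastic extensions
    log_level: str = "INFO"


class ScenarioConfig(_Section):
    blood: BloodConfig = Field(default_factory=BloodConfig)
    drug: DrugConfig = Field(default_factory=DrugConfig)
    graph: GraphConfig = Field(default_factory=GraphConfig)
    rev: RevConfig = Field(default_factory=RevConfig)
    dcm_healthy: DcmConfig = Field(default_factory=DcmConfig)
    dcm_tumor: DcmConfig = Field(default_factory=_tumor_dcm_defaults)
    transfer_healthy: TransferConfig = Field(default_factory=TransferConfig)
    transfer_tumor: TransferConfig = Field(default_factory=_tumor_transfer_defaults)
    coupling: CouplingConfig = Field(default_factory=CouplingConfig)
    run: RunConfig = Field(default_factory=RunConfig)

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.drug.half_life_s <= 0:
            raise ValueError("drug.half_life_s must be > 0")
        if not 0.0 < self.run.courant <= 1.0:
            raise ValueError("run.courant must lie in (0, 1]")
        if self.dcm_tumor.shell_inner_radius_m != 0.0:
            raise ValueError("dcm_tumor.shell_inner_radius_m must be 0 (sphere)")
        n = self.graph.n_alveoli
        bad = [t for t in self.graph.tumor_ids if not 0 <= t < n]
        if bad:
            raise ValueError(f"graph.tumor_ids out of range: {bad}")
        return self

    def config_hash(self) -> str:
        doc = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def default_config() -> ScenarioConfig:
    return ScenarioConfig()


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario file must be a YAML mapping")
    return ScenarioConfig.model_validate(raw)


def dump_config(config: ScenarioConfig, path: str | Path | None = None) -> str:
    doc = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    if path is not None:
        Path(path).write_text(doc)
    return doc
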