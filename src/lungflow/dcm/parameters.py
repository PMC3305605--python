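"""Parameter sets of the alveolus double-continuum model.

Healthy and tumor parameter registries: tissue continuum (interstitium),
capillary continuum (alveolar capillary bed as a porous medium) and the
transfer functions coupling them (Starling fluid exchange,
Stavermann-Kedem-Katchalsky solute exchange, lymphatic drainage, tumor-cell
receptor binding).  Values marked "literature default" are mid-range choices
for a macromolecular (protein) therapeutic where the printed registry gives
only ranges; all are plain fields and can be overridden via the scenario
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ..upscaling import (
    PermeabilityTensor,
    capillary_surface_density,
    stokes_einstein_diffusivity,
    tumor_permeability,
)

__all__ = [
    "TissueParameters",
    "CapillaryParameters",
    "TransferParameters",
    "AlveolusParameters",
    "healthy_parameters",
    "tumor_parameters",
]

BODY_TEMPERATURE = 310.15  # K


@dataclass
class TissueParameters:
    """Interstitium (tissue continuum)."""

    porosity: float = 0.13  # phi, fluid-accessible fraction of tissue
    tissue_fraction: float = 0.9  # eps_t, tissue share of the model domain
    permeability: float = 5e-18  # K_t [m^2], isotropic; literature default
    tortuosity: float = 0.28  # tau <= 1, multiplies the diffusivity
    viscosity: float = 1.2e-3  # Pa*s, interstitial fluid
    mass_density: float = 1030.0  # kg/m^3
    molar_density: float = 303.5  # mol/m^3
    # lymphatic drainage (healthy tissue only)
    lymph_conductivity: float = 2.6e-9  # L_p,ly [m/(Pa*s)], literature default
    lymph_surface_density: float = 3.0  # S_ly/V [1/m]
    lymph_pressure: float = -1200.0  # p_ly [Pa]
    lymph_clamped: bool = True  # no reverse lymph flow below p_ly
    # receptor binding (tumor tissue only)
    receptor_concentration: float = 1e-5  # C_R0 [mol/m^3], literature default
    k_on: float = 100.0  # [m^3/(mol*s)], literature default
    k_off: float = 1e-4  # [1/s], literature default
    boundary_pressure: float = -1064.0  # Dirichlet p_t at the outer boundary

    def __post_init__(self) -> None:
        for name in ("porosity", "tissue_fraction", "tortuosity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class CapillaryParameters:
    """Capillary bed continuum (porosity and tortuosity are one)."""

    volume_fraction: float = 0.1  # eps_c
    permeability: PermeabilityTensor = field(
        default_factory=lambda: PermeabilityTensor.diagonal(
            3.6e-14, 3.6e-14, 0.0))
    viscosity: float = 2.1e-3  # Pa*s, constant capillary blood viscosity
    mass_density: float = 1050.0
    molar_density: float = 284.0
    porosity: float = 1.0
    tortuosity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.volume_fraction <= 1.0:
            raise ValueError("volume_fraction must lie in (0, 1]")
        if self.porosity != 1.0 or self.tortuosity != 1.0:
            raise ValueError("capillary continuum has porosity = tortuosity = 1")

    @property
    def k_radial(self) -> float:
        """Face-normal permeability across radial (shell-normal) faces.

        The cuboid z-axis maps to the local shell normal, so this is K_zz
        (zero for the planar bed).
        """
        return float(self.permeability.K[2, 2])

    @property
    def k_tangential(self) -> float:
        """Tangential face-normal permeability (in-surface mean of Kxx, Kyy).

        The azimuthal orientation of the bed on the sphere is undefined, so
        the two in-plane principal values are averaged.
        """
        K = self.permeability.K
        return float(0.5 * (K[0, 0] + K[1, 1]))


@dataclass
class TransferParameters:
    """Capillary-wall transfer functions (Starling / Kedem-Katchalsky)."""

    hydraulic_conductivity: float = 2.7e-12  # L_p [m/(Pa*s)], literature default
    surface_density: float = 1.9e4  # S/V [1/m]
    sigma: float = 0.8  # osmotic reflection coefficient
    sigma_f: float = 0.91  # solvent-drag reflection coefficient
    diffusive_permeability: float = 5e-9  # P [m/s], literature default
    pi_c: float = 3724.0  # capillary oncotic pressure [Pa]
    pi_t: float = 1862.0  # interstitial oncotic pressure [Pa]
    molar_density: float = 293.75  # mean of the two fluids' molar densities
    mass_density: float = 1040.0  # mean of the two fluids' mass densities

    def __post_init__(self) -> None:
        for name in ("sigma", "sigma_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class AlveolusParameters:
    """Complete parameter set of one upscaled node's alveolus model."""

    kind: str  # "healthy" or "tumor"
    tissue: TissueParameters
    capillary: CapillaryParameters
    transfer: TransferParameters
    decay_rate: float = math.log(2.0) / 21600.0  # 1/s, drug degradation
    diffusivity_tissue: float = field(default=None)  # m^2/s
    diffusivity_capillary: float = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("healthy", "tumor"):
            raise ValueError(f"kind must be healthy or tumor, got {self.kind!r}")
        r_mol = 3.7e-9
        if self.diffusivity_tissue is None:
            self.diffusivity_tissue = stokes_einstein_diffusivity(
                BODY_TEMPERATURE, self.tissue.viscosity, r_mol)
        if self.diffusivity_capillary is None:
            self.diffusivity_capillary = stokes_einstein_diffusivity(
                BODY_TEMPERATURE, self.capillary.viscosity, r_mol)
        if not math.isclose(
            self.transfer.molar_density,
            0.5 * (self.tissue.molar_density + self.capillary.molar_density),
            rel_tol=1e-6,
        ):
            raise ValueError(
                "transfer molar density must be the arithmetic mean of the "
                "tissue and capillary molar densities")

    @property
    def has_lymphatics(self) -> bool:
        return self.kind == "healthy"

    @property
    def has_receptors(self) -> bool:
        return self.kind == "tumor"


def healthy_parameters(
    capillary_tensor: PermeabilityTensor | None = None,
    n_capillaries: int = 1800,
    capillary_radius: float = 4e-6,
    capillary_length: float = 1e-5,
    R_in: float = 70e-6,
    R_out: float = 182e-6,
    **overrides,
) -> AlveolusParameters:
    """Healthy parameter set; S/V from the shell geometry closed form."""
    sv = capillary_surface_density(
        n_capillaries, capillary_radius, capillary_length, R_out, R_in)
    capillary = CapillaryParameters()
    if capillary_tensor is not None:
        capillary = replace(capillary, permeability=capillary_tensor)
    transfer = TransferParameters(surface_density=sv)
    params = AlveolusParameters(
        kind="healthy",
        tissue=TissueParameters(),
        capillary=capillary,
        transfer=transfer,
    )
    return _apply_overrides(params, overrides)


def tumor_parameters(
    mean_capillary_radius: float = 10e-6,
    **overrides,
) -> AlveolusParameters:
    """Tumor parameter set: no lymphatics, receptor binding, leakier wall."""
    tissue = TissueParameters(
        porosity=0.27,
        tissue_fraction=0.8,
        permeability=4e-17,  # literature default (tumor interstitium leakier)
        tortuosity=0.71,
        boundary_pressure=133.0,
    )
    capillary = CapillaryParameters(
        volume_fraction=0.2,
        permeability=tumor_permeability(mean_capillary_radius),
    )
    transfer = TransferParameters(
        hydraulic_conductivity=2.1e-11,  # literature default (tumor vessels)
        surface_density=2.0e4,
        sigma_f=0.82,
        diffusive_permeability=5e-8,  # literature default (tumor vessels)
        pi_c=2660.0,
        pi_t=1995.0,
    )
    params = AlveolusParameters(
        kind="tumor", tissue=tissue, capillary=capillary, transfer=transfer)
    return _apply_overrides(params, overrides)


def _apply_overrides(params: AlveolusParameters, overrides: dict) -> AlveolusParameters:
    for key, value in overrides.items():
        target = params
        name = key
        for section in ("tissue", "capillary", "transfer"):
            prefix = section + "__"
            if key.startswith(prefix):
                target = getattr(params, section)
                name = key[len(prefix):]
                break
        if not hasattr(target, name):
            raise ValueError(f"unknown parameter override {key!r}")
        setattr(target, name, value)
    return params
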