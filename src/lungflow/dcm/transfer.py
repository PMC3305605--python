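"""Transfer functions coupling the tissue and capillary continua.

Fluid crosses the capillary wall according to Starling's law (hydrostatic
minus reflection-weighted oncotic pressure difference); the dissolved drug
follows the Stavermann-Kedem-Katchalsky equation (diffusive term plus
solvent drag).  Healthy tissue additionally drains to the lymphatic system;
tumor tissue instead binds drug to cell-surface receptors with first-order
on/off kinetics.  All rates are per unit volume of the model domain
[mol/(m^3 s)], positive from capillary to tissue.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "effective_filtration_pressure",
    "starling_flux",
    "kedem_katchalsky_flux",
    "lymphatic_sinks",
    "receptor_binding_update",
]


def effective_filtration_pressure(p_c, p_t, sigma, pi_c, pi_t):
    """Starling effective filtration pressure [Pa].

    ``p_eff = (p_c - p_t) - sigma (pi_c - pi_t)``; positive drives
    filtration (capillary to tissue), negative reabsorption.
    """
    return (p_c - p_t) - sigma * (pi_c - pi_t)


def starling_flux(p_eff, L_p, surface_density, molar_density):
    """Net transvascular fluid exchange.

    Returns ``(q_v, J_v)``: the molar rate ``q_v = L_p (S/V) p_eff rho_mol``
    [mol/(m^3 s)] and the volumetric rate ``J_v = L_p (S/V) p_eff`` [1/s]
    that also drives the solvent-drag term of the solute exchange.
    """
    J_v = L_p * surface_density * p_eff
    return J_v * molar_density, J_v


def kedem_katchalsky_flux(x_c, x_t, J_v, P, sigma_f, surface_density,
                          molar_density):
    """Transvascular solute exchange [mol/(m^3 s)], capillary to tissue.

    Diffusive term ``P (S/V) rho_mol (x_c - x_t)`` plus solvent drag
    ``(1 - sigma_f) J_v rho_mol x_bar`` with the wall-pore mole fraction
    approximated by the arithmetic mean ``x_bar = (x_c + x_t)/2``.
    """
    x_bar = 0.5 * (x_c + x_t)
    return (P * surface_density * molar_density * (x_c - x_t)
            + (1.0 - sigma_f) * J_v * molar_density * x_bar)


def lymphatic_sinks(p_t, x_t, L_p_ly, surface_density_ly, p_ly,
                    molar_density, clamped=True):
    """Lymphatic drainage of fluid and dissolved drug [mol/(m^3 s)].

    Drainage is proportional to ``p_t - p_ly``; with ``clamped`` (default)
    it only acts while the interstitial pressure exceeds the lymphatic
    pressure (no reverse lymph flow).  Returns ``(fluid_sink, drug_sink)``;
    both are zero in tumor tissue (no functional lymphatics), which callers
    enforce by not invoking this on tumor cells.
    """
    dp = p_t - p_ly
    if clamped:
        dp = np.maximum(dp, 0.0)
    fluid = L_p_ly * surface_density_ly * dp * molar_density
    return fluid, fluid * x_t


def receptor_binding_update(x_t, C_RL, molar_density, k_on, k_off, C_R0, dt):
    """Implicit one-step update of the receptor-ligand complex.

    With free-drug concentration ``c = x_t rho_mol`` held at its (implicit)
    end-of-step value, ``dC_RL/dt = k_on c (C_R0 - C_RL) - k_off C_RL`` is
    linear in ``C_RL`` and solved exactly over ``dt``.  Returns
    ``(drug_sink, C_RL_new)`` where the sink [mol/(m^3 s)] equals the
    binding rate (negative when net unbinding releases drug).  Receptor
    conservation ``C_R + C_RL = C_R0`` holds by construction.
    """
    c = np.asarray(x_t) * molar_density
    a = k_on * c + k_off
    C_new = (np.asarray(C_RL) + dt * k_on * c * C_R0) / (1.0 + dt * a)
    rate = (C_new - C_RL) / dt
    return rate, C_new
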