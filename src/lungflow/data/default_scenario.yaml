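# Default scenario: the coupled 21-alveolus example simulation.
# All values SI; keys carry unit suffixes.  Keys marked "literature default"
# are mid-range choices for a macromolecular (protein) therapeutic where the
# parameter registry gives only a range or no usable value; see
# docs/methods.md section 5.
blood:
  mass_density_kg_per_m3: 1050.0
  molar_density_mol_per_m3: 284.0
  plasma_viscosity_pa_s: 0.0012
  # synthetic representative in-vivo microvessel hematocrit lookup
  # (diameter um, discharge hematocrit); overridable
  hematocrit_table:
  - [8.0, 0.12]
  - [10.0, 0.15]
  - [15.0, 0.22]
  - [20.0, 0.28]
  - [30.0, 0.35]
  - [40.0, 0.40]
  - [60.0, 0.43]
  - [100.0, 0.45]
drug:
  half_life_s: 21600.0
  molecular_radius_m: 3.7e-9
  inlet_mole_fraction: 1.0e-6     # literature default (registry illegible)
  bolus_duration_s: null          # null = continuous injection
  temperature_k: 310.15
graph:
  n_alveoli: 21
  tumor_ids: [4, 10, 16]
  arterial_root_order: 4
  venous_root_order: 4
  graph_file: null
rev:
  n_segments: 1800
  diameter_m: 8.0e-6
  seg_length_m: 1.0e-5
  cuboid_m: [3.64e-4, 3.64e-4, 1.12e-4]
  orientation: rows_x
  probe_pressure_pa: 100.0
dcm_healthy:
  shell_inner_radius_m: 7.0e-5
  shell_outer_radius_m: 1.82e-4
  mesh: {n_r: 3, n_theta: 4, n_phi: 8, cap_half_angle_deg: 30.0}
  tissue:
    porosity: 0.13
    tissue_volume_fraction: 0.9
    permeability_m2: 5.0e-18      # literature default
    tortuosity: 0.28
    viscosity_pa_s: 0.0012
    mass_density_kg_per_m3: 1030.0
    molar_density_mol_per_m3: 303.5
    lymph_conductivity_m_per_pa_s: 2.6e-9   # literature default
    lymph_surface_density_per_m: 3.0
    lymph_pressure_pa: -1200.0
    lymph_clamped: true
    receptor_concentration_mol_per_m3: 1.0e-5  # unused in healthy tissue
    k_on_m3_per_mol_s: 100.0
    k_off_per_s: 1.0e-4
    boundary_pressure_pa: -1064.0
  capillary:
    volume_fraction: 0.1
    viscosity_pa_s: 0.0021
    mass_density_kg_per_m3: 1050.0
    molar_density_mol_per_m3: 284.0
    permeability_m2: null         # null = from REV upscaling of the bed
    tumor_capillary_radius_m: 1.0e-5
  newton_tolerance: 1.0e-8
dcm_tumor:
  shell_inner_radius_m: 0.0       # full sphere
  shell_outer_radius_m: 1.82e-4
  mesh: {n_r: 3, n_theta: 4, n_phi: 8, cap_half_angle_deg: 30.0}
  tissue:
    porosity: 0.27
    tissue_volume_fraction: 0.8
    permeability_m2: 4.0e-17      # literature default
    tortuosity: 0.71
    viscosity_pa_s: 0.0012
    mass_density_kg_per_m3: 1030.0
    molar_density_mol_per_m3: 303.5
    lymph_conductivity_m_per_pa_s: 2.6e-9   # unused: no tumor lymphatics
    lymph_surface_density_per_m: 3.0
    lymph_pressure_pa: -1200.0
    lymph_clamped: true
    receptor_concentration_mol_per_m3: 1.0e-5  # literature default
    k_on_m3_per_mol_s: 100.0      # literature default
    k_off_per_s: 1.0e-4           # literature default
    boundary_pressure_pa: 133.0
  capillary:
    volume_fraction: 0.2
    viscosity_pa_s: 0.0021
    mass_density_kg_per_m3: 1050.0
    molar_density_mol_per_m3: 284.0
    permeability_m2: null         # null = isotropic r^2/8
    tumor_capillary_radius_m: 1.0e-5
  newton_tolerance: 1.0e-8
transfer_healthy:
  hydraulic_conductivity_m_per_pa_s: 2.7e-12  # literature default
  surface_density_per_m: null     # null = shell-geometry closed form
  osmotic_reflection_coefficient: 0.8
  solvent_drag_reflection_coefficient: 0.91
  diffusive_permeability_m_per_s: 5.0e-9      # literature default
  capillary_oncotic_pressure_pa: 3724.0
  interstitial_oncotic_pressure_pa: 1862.0
transfer_tumor:
  hydraulic_conductivity_m_per_pa_s: 2.1e-11  # literature default
  surface_density_per_m: 2.0e4
  osmotic_reflection_coefficient: 0.8
  solvent_drag_reflection_coefficient: 0.82
  diffusive_permeability_m_per_s: 5.0e-8      # literature default
  capillary_oncotic_pressure_pa: 2660.0
  interstitial_oncotic_pressure_pa: 1995.0
coupling:
  n_substeps: 1
  recompute_effective_resistance: false
run:
  t_end_s: 11.0
  courant: 0.9
  output_interval_s: 1.0
  output_dir: null
  arterial_pressure_pa: 1064.0
  venous_pressure_pa: 199.5
  gravity_enabled: false
  compliance_enabled: false
  seed: null
  log_level: INFO
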