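"""Coupling of the vascular graph to the alveolus double-continuum models.

Per graph time step the pressure/flow field and the drug distribution on
the vascular graph are solved first; each upscaled node's double-continuum
model is then driven with boundary conditions taken from its two adjacent
graph nodes (arterial and venous side) and advanced over the same step;
the volume-integrated transvascular exchange (fluid and drug leaving the
blood) is fed back to the graph as sink terms in the *next* step
(sequential, lagged coupling, which keeps the graph system linear).  The
upscaled node's hydraulic footprint in the graph is a static effective
resistance obtained from the capillary continuum alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .config import (
    CapillaryConfig,
    DcmConfig,
    ScenarioConfig,
    TissueConfig,
    TransferConfig,
)
from .dcm import (
    AlveolusModel,
    AlveolusParameters,
    CapillaryParameters,
    DCMState,
    TissueParameters,
    TransferParameters,
    build_dcm_mesh,
)
from .hemodynamics import BloodProperties, FlowSolution, GravityModel, PressureSystem
from .network import NodeKind, VascularGraph, VesselClass, build_coupled_example, read_graph
from .transport import TransportState, advance_transport, cfl_timestep, decay_rate
from .upscaling import (
    PermeabilityTensor,
    build_hexagonal_capillary_bed,
    capillary_surface_density,
    rev_permeability_tensor,
    tumor_permeability,
)

__all__ = [
    "UpscaledNode",
    "CoupledResults",
    "identify_upscaled_nodes",
    "capillary_bcs_from_vgm",
    "build_alveolus_parameters",
    "run_coupled",
]

log = logging.getLogger(__name__)


@dataclass
class UpscaledNode:
    """One upscaled node: graph bookkeeping plus its alveolus model."""

    vgm_node_id: int
    kind: str  # "healthy" | "tumor"
    arterial_neighbor: int
    venous_neighbor: int
    model: AlveolusModel
    state: DCMState | None = None
    R_eff: float = 0.0
    #: cumulative ledgers [mol] / [kg] over the run
    ledger: dict[str, float] = field(default_factory=lambda: {
        "q_x_moles": 0.0, "q_mass_kg": 0.0, "lymph_drug_moles": 0.0,
        "lymph_fluid_kg": 0.0, "boundary_drug_moles": 0.0,
        "applied_q_x_moles": 0.0})


def identify_upscaled_nodes(graph: VascularGraph) -> list[dict]:
    """Locate upscaled nodes and classify their two neighbors by side."""
    out = []
    for node in graph.upscaled_nodes:
        edges = graph.incident_edges(node.id)
        if len(edges) != 2:
            raise ValueError(f"upscaled node {node.id} must have degree 2")
        art = ven = None
        for e in edges:
            nb = graph.other_end(e, node.id)
            classes = {
                other.vessel_class for other in graph.incident_edges(nb)
                if other.id != e.id
            }
            if classes & {VesselClass.ARTERY, VesselClass.ARTERIOLE}:
                art = nb
            elif classes & {VesselClass.VEIN, VesselClass.VENULE}:
                ven = nb
        if art is None or ven is None:
            raise ValueError(
                f"upscaled node {node.id}: could not classify an arterial "
                "and a venous neighbor")
        out.append({
            "vgm_node_id": node.id,
            "kind": "tumor" if node.kind is NodeKind.UPSCALED_TUMOR else "healthy",
            "arterial_neighbor": art,
            "venous_neighbor": ven,
        })
    return out


def capillary_bcs_from_vgm(
    flow: FlowSolution, state: TransportState, node: UpscaledNode
) -> tuple[float, float, float, float]:
    """Dirichlet (p_art, p_ven, x_art, x_ven) copied from adjacent nodes."""
    try:
        return (
            flow.pressures[node.arterial_neighbor],
            flow.pressures[node.venous_neighbor],
            state.mole_fraction[node.arterial_neighbor],
            state.mole_fraction[node.venous_neighbor],
        )
    except KeyError as exc:
        raise ValueError(
            f"upscaled node {node.vgm_node_id}: neighbor {exc} missing from "
            "the graph solution") from exc


# ---------------------------------------------------------------------------
# Parameter assembly from configuration
# ---------------------------------------------------------------------------

def _tissue_from(cfg: TissueConfig) -> TissueParameters:
    return TissueParameters(
        porosity=cfg.porosity,
        tissue_fraction=cfg.tissue_volume_fraction,
        permeability=cfg.permeability_m2,
        tortuosity=cfg.tortuosity,
        viscosity=cfg.viscosity_pa_s,
        mass_density=cfg.mass_density_kg_per_m3,
        molar_density=cfg.molar_density_mol_per_m3,
        lymph_conductivity=cfg.lymph_conductivity_m_per_pa_s,
        lymph_surface_density=cfg.lymph_surface_density_per_m,
        lymph_pressure=cfg.lymph_pressure_pa,
        lymph_clamped=cfg.lymph_clamped,
        receptor_concentration=cfg.receptor_concentration_mol_per_m3,
        k_on=cfg.k_on_m3_per_mol_s,
        k_off=cfg.k_off_per_s,
        boundary_pressure=cfg.boundary_pressure_pa,
    )


def _capillary_from(cfg: CapillaryConfig, kind: str,
                    rev_tensor: PermeabilityTensor | None) -> CapillaryParameters:
    if cfg.permeability_m2 is not None:
        K = PermeabilityTensor.diagonal(*cfg.permeability_m2)
    elif kind == "healthy":
        if rev_tensor is None:
            raise ValueError("healthy capillary permeability requires the "
                             "REV tensor or an explicit config value")
        K = rev_tensor
    else:
        K = tumor_permeability(cfg.tumor_capillary_radius_m)
    return CapillaryParameters(
        volume_fraction=cfg.volume_fraction,
        permeability=K,
        viscosity=cfg.viscosity_pa_s,
        mass_density=cfg.mass_density_kg_per_m3,
        molar_density=cfg.molar_density_mol_per_m3,
    )


def build_alveolus_parameters(
    config: ScenarioConfig, kind: str,
    rev_tensor: PermeabilityTensor | None = None,
) -> AlveolusParameters:
    """Assemble one kind's full parameter set from the scenario config."""
    dcm_cfg: DcmConfig = (config.dcm_healthy if kind == "healthy"
                          else config.dcm_tumor)
    tr_cfg: TransferConfig = (config.transfer_healthy if kind == "healthy"
                              else config.transfer_tumor)
    tissue = _tissue_from(dcm_cfg.tissue)
    capillary = _capillary_from(dcm_cfg.capillary, kind, rev_tensor)
    sv = tr_cfg.surface_density_per_m
    if sv is None:
        sv = capillary_surface_density(
            config.rev.n_segments, config.rev.diameter_m / 2.0,
            config.rev.seg_length_m, dcm_cfg.shell_outer_radius_m,
            dcm_cfg.shell_inner_radius_m)
    transfer = TransferParameters(
        hydraulic_conductivity=tr_cfg.hydraulic_conductivity_m_per_pa_s,
        surface_density=sv,
        sigma=tr_cfg.osmotic_reflection_coefficient,
        sigma_f=tr_cfg.solvent_drag_reflection_coefficient,
        diffusive_permeability=tr_cfg.diffusive_permeability_m_per_s,
        pi_c=tr_cfg.capillary_oncotic_pressure_pa,
        pi_t=tr_cfg.interstitial_oncotic_pressure_pa,
        molar_density=0.5 * (tissue.molar_density + capillary.molar_density),
        mass_density=0.5 * (tissue.mass_density + capillary.mass_density),
    )
    from .upscaling import stokes_einstein_diffusivity
    return AlveolusParameters(
        kind=kind, tissue=tissue, capillary=capillary, transfer=transfer,
        decay_rate=decay_rate(config.drug.half_life_s),
        diffusivity_tissue=stokes_einstein_diffusivity(
            config.drug.temperature_k, tissue.viscosity,
            config.drug.molecular_radius_m),
        diffusivity_capillary=stokes_einstein_diffusivity(
            config.drug.temperature_k, capillary.viscosity,
            config.drug.molecular_radius_m),
    )


def _build_model(config: ScenarioConfig, kind: str,
                 rev_tensor: PermeabilityTensor | None) -> AlveolusModel:
    dcm_cfg = config.dcm_healthy if kind == "healthy" else config.dcm_tumor
    mesh = build_dcm_mesh(
        "shell" if kind == "healthy" else "sphere",
        dcm_cfg.shell_inner_radius_m, dcm_cfg.shell_outer_radius_m,
        (dcm_cfg.mesh.n_r, dcm_cfg.mesh.n_theta, dcm_cfg.mesh.n_phi),
        dcm_cfg.mesh.cap_half_angle_deg)
    params = build_alveolus_parameters(config, kind, rev_tensor)
    return AlveolusModel(mesh, params, newton_tol=dcm_cfg.newton_tolerance)


# ---------------------------------------------------------------------------
# Coupled run
# ---------------------------------------------------------------------------

@dataclass
class CoupledResults:
    """Results bundle of a coupled simulation."""

    config: ScenarioConfig
    graph: VascularGraph
    flow: FlowSolution
    transport: TransportState
    nodes: dict[int, UpscaledNode]
    times: list[float]
    graph_series: list[dict]  # time, node_id, x records at output intervals
    node_series: list[dict]  # per-upscaled-node records at output intervals
    rev_tensor: PermeabilityTensor | None
    n_steps: int

    def audit(self) -> dict[str, float]:
        """Global drug bookkeeping [mol].

        Injected drug must equal what remains in the graph plus what was
        degraded, extracted into the alveolus models (tissue + bound +
        lymph-cleared + tissue-boundary effluent) and the one-step lag of
        the sequential coupling (``in_flight``).
        """
        blood = self.config.blood
        volumes = self.flow.node_volumes
        graph_inv = self.transport.total_moles(
            volumes, blood.molar_density_mol_per_m3)
        tissue = bound = lymph = boundary = applied = gained = 0.0
        for un in self.nodes.values():
            inv = un.model.inventories(un.state)
            tissue += inv["tissue"]
            bound += inv["bound"]
            lymph += un.ledger["lymph_drug_moles"]
            boundary += un.ledger["boundary_drug_moles"]
            applied += un.ledger["applied_q_x_moles"]
            gained += un.ledger["q_x_moles"]
        injected = self.transport.injected_moles + self.transport.clipped_moles
        in_flight = gained - applied
        accounted = (graph_inv + self.transport.degraded_moles
                     + self.transport.effluent_moles + tissue
                     + bound + lymph + boundary + in_flight)
        return {
            "injected_moles": injected,
            "graph_moles": graph_inv,
            "degraded_moles": self.transport.degraded_moles,
            "effluent_moles": self.transport.effluent_moles,
            "tissue_moles": tissue,
            "bound_moles": bound,
            "lymph_moles": lymph,
            "boundary_outflow_moles": boundary,
            "in_flight_moles": in_flight,
            "accounted_moles": accounted,
            "closure_error": abs(injected - accounted) / max(injected, 1e-300),
        }


def run_coupled(
    config: ScenarioConfig | None = None,
    graph: VascularGraph | None = None,
    t_end: float | None = None,
) -> CoupledResults:
    """Run the coupled discrete/continuum simulation.

    Sequence per step: (1) graph pressure/flow with the previous step's
    fluid sinks; (2) CFL time step; (3) explicit drug advection with the
    previous step's drug sinks; (4) per upscaled node, boundary conditions
    from the adjacent graph nodes, one (or ``coupling.n_substeps``) implicit
    DCM step(s), exchange integration; (5) the new exchange rates become
    next step's sinks.
    """
    config = config or ScenarioConfig()
    t_end = config.run.t_end_s if t_end is None else t_end
    if graph is None:
        if config.graph.graph_file:
            graph = read_graph(config.graph.graph_file)
        else:
            graph = build_coupled_example(
                config.graph.n_alveoli, set(config.graph.tumor_ids),
                arterial_root_order=config.graph.arterial_root_order,
                venous_root_order=config.graph.venous_root_order)
    graph.validate()
    infos = identify_upscaled_nodes(graph)
    if not infos:
        raise ValueError("coupled run requires at least one upscaled node")

    blood = BloodProperties(
        mass_density=config.blood.mass_density_kg_per_m3,
        molar_density=config.blood.molar_density_mol_per_m3,
        plasma_viscosity=config.blood.plasma_viscosity_pa_s,
        hematocrit_table=tuple(map(tuple, config.blood.hematocrit_table)))

    # REV upscaling for the healthy capillary continuum
    kinds = {info["kind"] for info in infos}
    rev_tensor = None
    if "healthy" in kinds and config.dcm_healthy.capillary.permeability_m2 is None:
        bed = build_hexagonal_capillary_bed(
            config.rev.n_segments, config.rev.diameter_m,
            config.rev.seg_length_m, tuple(config.rev.cuboid_m),
            config.rev.orientation)
        rev_tensor = rev_permeability_tensor(
            bed, p_hi=config.rev.probe_pressure_pa, p_lo=0.0,
            mu=config.dcm_healthy.capillary.viscosity_pa_s)
        log.info("REV tensor diag: %s", rev_tensor.K.diagonal())

    models = {k: _build_model(config, k, rev_tensor) for k in kinds}
    R_eff = {k: m.effective_resistance() for k, m in models.items()}
    log.info("effective upscaled-node resistances: %s", R_eff)

    nodes: dict[int, UpscaledNode] = {}
    edge_override: dict[int, float] = {}
    for info in infos:
        un = UpscaledNode(model=models[info["kind"]],
                          R_eff=R_eff[info["kind"]], **info)
        nodes[un.vgm_node_id] = un
        for e in graph.incident_edges(un.vgm_node_id):
            edge_override[e.id] = un.R_eff / 2.0

    art_root = graph.metadata.get("arterial_root")
    ven_root = graph.metadata.get("venous_root")
    if art_root is None or ven_root is None:
        arts = [n.id for n in graph.nodes_of_kind(NodeKind.BOUNDARY_ARTERIAL)]
        vens = [n.id for n in graph.nodes_of_kind(NodeKind.BOUNDARY_VENOUS)]
        if len(arts) != 1 or len(vens) != 1:
            raise ValueError("graph must declare one arterial and one venous root")
        art_root, ven_root = arts[0], vens[0]
    bcs = {art_root: config.run.arterial_pressure_pa,
           ven_root: config.run.venous_pressure_pa}

    psys = PressureSystem(
        graph, blood, bcs,
        gravity=GravityModel(enabled=config.run.gravity_enabled),
        upscaled_edge_resistance=edge_override)

    k_decay = decay_rate(config.drug.half_life_s)
    x_in = config.drug.inlet_mole_fraction
    tstate = TransportState({nid: 0.0 for nid in graph.nodes})

    q_mass: dict[int, float] = {}
    q_x: dict[int, float] = {}
    times: list[float] = []
    graph_series: list[dict] = []
    node_series: list[dict] = []
    next_output = 0.0
    t = 0.0
    n_steps = 0
    flow = psys.solve(q_mass)

    def record(flow, tstate):
        for nid in sorted(graph.nodes):
            graph_series.append({
                "time": tstate.time, "node_id": nid,
                "pressure_pa": flow.pressures[nid],
                "mole_fraction": tstate.mole_fraction[nid]})
        for un in nodes.values():
            inv = (un.model.inventories(un.state) if un.state is not None
                   else {"tissue": 0.0, "capillary": 0.0, "bound": 0.0})
            node_series.append({
                "time": tstate.time, "node_id": un.vgm_node_id,
                "kind": un.kind,
                "q_x_mol_per_s": q_x.get(un.vgm_node_id, 0.0),
                "q_mass_kg_per_s": q_mass.get(un.vgm_node_id, 0.0),
                "tissue_moles": inv["tissue"],
                "bound_moles": inv["bound"],
                "extracted_moles": un.ledger["q_x_moles"]})
        times.append(tstate.time)

    while t < t_end - 1e-12:
        flow = psys.solve(q_mass)
        dt_cfl = cfl_timestep(graph, flow, config.run.courant)
        if math.isinf(dt_cfl):
            raise RuntimeError("no flow in the graph; cannot advance transport")
        dt = min(dt_cfl, t_end - t)
        inlet = ({art_root: x_in}
                 if t < config.drug.bolus_duration else {})
        for un in nodes.values():
            un.ledger["applied_q_x_moles"] += q_x.get(un.vgm_node_id, 0.0) * dt
        tstate = advance_transport(
            graph, flow, tstate, dt, q_x, k_decay, inlet,
            molar_density=blood.molar_density)
        for un in nodes.values():
            p_art, p_ven, xa, xv = capillary_bcs_from_vgm(flow, tstate, un)
            un.model.set_capillary_bcs(p_art, p_ven, xa, xv)
            if un.state is None:
                un.state = un.model.initial_state()
            try:
                un.state, ledger = un.model.step_accounted(
                    un.state, dt, config.coupling.n_substeps)
            except Exception as exc:
                raise RuntimeError(
                    f"DCM solve failed at upscaled node {un.vgm_node_id} "
                    f"(t = {t:.6g} s): {exc}") from exc
            q_x[un.vgm_node_id] = ledger["q_x"]
            q_mass[un.vgm_node_id] = ledger["q_mass"]
            for key in ("q_x_moles", "q_mass_kg", "lymph_drug_moles",
                        "lymph_fluid_kg", "boundary_drug_moles"):
                un.ledger[key] += ledger[key]
        t += dt
        n_steps += 1
        if t >= next_output - 1e-12 or t >= t_end - 1e-12:
            record(flow, tstate)
            while next_output <= t + 1e-12:
                next_output += config.run.output_interval_s

    return CoupledResults(
        config=config, graph=graph, flow=flow, transport=tstate,
        nodes=nodes, times=times, graph_series=graph_series,
        node_series=node_series, rev_tensor=rev_tensor, n_steps=n_steps)
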