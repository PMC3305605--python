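"""Drug transport on the vascular graph.

The dissolved therapeutic agent is advected with the blood stream between
the node volumes of the graph: an explicit-Euler, first-order-upwind update
of the nodal mole fractions, stabilized by a CFL restriction on the time
step.  First-order degradation (bolus-injection kinetics, rate ln2 / t_half)
and the coupling sinks at upscaled nodes (drug leaving the blood compartment
into the alveolar tissue) enter as additive sink terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hemodynamics import FlowSolution
from .network import NodeKind, VascularGraph

__all__ = [
    "DrugProperties",
    "TransportState",
    "decay_rate",
    "cfl_timestep",
    "advance_transport",
]


@dataclass
class DrugProperties:
    """Therapeutic-agent parameters."""

    half_life: float = 21600.0  # s
    molecular_radius: float = 3.7e-9  # m
    inlet_mole_fraction: float = 1e-6  # dimensionless, held at arterial root
    bolus_duration: float = math.inf  # s; continuous injection by default
    diffusivity_blood: float | None = None  # m^2/s; None -> Stokes-Einstein
    diffusivity_interstitial: float | None = None

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")
        if self.molecular_radius <= 0:
            raise ValueError("molecular_radius must be > 0")
        if not 0.0 <= self.inlet_mole_fraction <= 1.0:
            raise ValueError("inlet_mole_fraction must lie in [0, 1]")

    @property
    def decay_rate(self) -> float:
        return decay_rate(self.half_life)


def decay_rate(half_life: float) -> float:
    """First-order degradation rate constant ``k = ln 2 / t_half`` [1/s]."""
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    if math.isinf(half_life):
        return 0.0
    return math.log(2.0) / half_life


@dataclass
class TransportState:
    """Nodal mole fractions of the dissolved agent at a given time."""

    mole_fraction: dict[int, float]
    time: float = 0.0
    dt: float = 0.0
    #: cumulative moles removed by flooring negative values at zero
    clipped_moles: float = 0.0
    #: cumulative moles added at Dirichlet inlet nodes (bolus bookkeeping)
    injected_moles: float = 0.0
    #: cumulative moles removed by first-order degradation
    degraded_moles: float = 0.0
    #: cumulative moles carried out of the graph with fluid leaving at
    #: boundary (Dirichlet pressure) nodes
    effluent_moles: float = 0.0
    metadata: dict = field(default_factory=dict)

    def total_moles(self, volumes: dict[int, float],
                    molar_density: float) -> float:
        """Drug inventory of the graph [mol]."""
        return molar_density * sum(
            x * volumes[nid] for nid, x in self.mole_fraction.items())


def _boundary_efflux(graph: VascularGraph, flow: FlowSolution,
                     node_id: int) -> float:
    """Fluid leaving the system at a boundary node [m^3/s].

    A Dirichlet pressure node with net inflow passes that excess out of the
    graph (e.g. the venous root draining towards the heart); drug is carried
    along with it.
    """
    node = graph.nodes[node_id]
    if node.kind not in (NodeKind.BOUNDARY_ARTERIAL, NodeKind.BOUNDARY_VENOUS):
        return 0.0
    net_in = 0.0
    for e in graph.incident_edges(node_id):
        q = flow.edge_flows[e.id]
        net_in += q if e.node_b == node_id else -q
    return max(net_in, 0.0)


def cfl_timestep(
    graph: VascularGraph, flow: FlowSolution, courant: float = 1.0
) -> float:
    """Largest stable explicit step: ``courant * min_i V_i / outflow_i``.

    The outflow of a boundary node includes the fluid leaving the system
    there.  Infinite if nothing flows.  ``courant`` must lie in (0, 1].
    """
    if not 0.0 < courant <= 1.0:
        raise ValueError("courant number must lie in (0, 1]")
    dt = math.inf
    for nid in graph.nodes:
        V = flow.node_volumes[nid]
        if V <= 0:
            raise ValueError(f"non-positive volume at node {nid}")
        out = flow.outflow(graph, nid) + _boundary_efflux(graph, flow, nid)
        if out > 0:
            dt = min(dt, V / out)
    return courant * dt


def advance_transport(
    graph: VascularGraph,
    flow: FlowSolution,
    state: TransportState,
    dt: float,
    q_x: dict[int, float] | None = None,
    k: float = 0.0,
    inlet: dict[int, float] | None = None,
    molar_density: float = 284.0,
    cfl_tolerance: float = 1e-9,
) -> TransportState:
    """One explicit-Euler first-order-upwind step of the nodal mole fractions.

    ``q_x`` [mol/s] removes drug at upscaled nodes (coupling to the alveolar
    continua); ``k`` [1/s] is the degradation rate; ``inlet`` holds Dirichlet
    mole fractions (the arterial root during the bolus).  Values are floored
    at zero with the clipped moles accounted in ``clipped_moles``.
    """
    q_x = q_x or {}
    inlet = inlet or {}
    upscaled = {n.id for n in graph.upscaled_nodes}
    for nid, q in q_x.items():
        if q != 0.0 and nid not in upscaled:
            raise ValueError(f"drug sink at node {nid} which is not upscaled")

    node_ids = sorted(graph.nodes)
    idx = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)
    x = np.array([state.mole_fraction[nid] for nid in node_ids])
    V = np.array([flow.node_volumes[nid] for nid in node_ids])

    # CFL guard; boundary nodes shed their excess inflow out of the system
    outflow = np.zeros(n)
    for e in graph.edges.values():
        q = flow.edge_flows[e.id]
        if q > 0:
            outflow[idx[e.node_a]] += q
        elif q < 0:
            outflow[idx[e.node_b]] -= q
    efflux = np.zeros(n)
    for nid in node_ids:
        efflux[idx[nid]] = _boundary_efflux(graph, flow, nid)
    outflow += efflux
    with np.errstate(divide="ignore"):
        limits = np.where(outflow > 0, V / np.maximum(outflow, 1e-300), np.inf)
    dt_max = limits.min() if n else math.inf
    if dt > dt_max * (1.0 + cfl_tolerance):
        raise ValueError(
            f"dt = {dt:.6e} s exceeds the CFL limit {dt_max:.6e} s")

    influx = np.zeros(n)  # sum of Q_in * x_upstream
    for e in graph.edges.values():
        q = flow.edge_flows[e.id]
        if q > 0:
            influx[idx[e.node_b]] += q * x[idx[e.node_a]]
        elif q < 0:
            influx[idx[e.node_a]] -= q * x[idx[e.node_b]]

    x_new = x + dt / V * (influx - outflow * x) - dt * k * x
    for nid, q in q_x.items():
        x_new[idx[nid]] -= dt * q / (molar_density * V[idx[nid]])

    degraded = float(dt * k * (x * V).sum() * molar_density)
    effluent = float(dt * (efflux * x).sum() * molar_density)

    clipped = 0.0
    neg = x_new < 0.0
    if neg.any():
        clipped = float(-(x_new[neg] * V[neg]).sum() * molar_density)
        x_new[neg] = 0.0

    injected = 0.0
    for nid, xi in inlet.items():
        i = idx[nid]
        injected += (xi - x_new[i]) * V[i] * molar_density
        x_new[i] = xi

    return TransportState(
        mole_fraction={nid: float(x_new[i]) for nid, i in idx.items()},
        time=state.time + dt,
        dt=dt,
        clipped_moles=state.clipped_moles + clipped,
        injected_moles=state.injected_moles + injected,
        degraded_moles=state.degraded_moles + degraded,
        effluent_moles=state.effluent_moles + effluent,
        metadata=dict(state.metadata),
    )
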