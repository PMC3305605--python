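"""Blood flow on the vascular graph.

Pressures at the graph nodes follow from a continuity equation per node:
signed volumetric flows over the incident vessel segments balance any
coupling sink (nonzero only at upscaled nodes).  Segment flow obeys
Hagen-Poiseuille with an apparent blood viscosity that depends on vessel
diameter and hematocrit: the hematocrit is read from a monotone
diameter-hematocrit lookup (in-vivo microvessel data), the relative
viscosity from the published in-vitro diameter/hematocrit relation of
Pries and coworkers.  Gravity optionally corrects each node's pressure by
rho*g*z along the gravity axis; cross-sectional compliance optionally makes
vessel areas pressure dependent (fixed-point iteration).  Both options are
off in the example scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import NodeKind, VascularGraph, VesselClass, VesselSegment

__all__ = [
    "BloodProperties",
    "GravityModel",
    "FlowSolution",
    "DEFAULT_HEMATOCRIT_TABLE",
    "hematocrit_from_diameter",
    "relative_viscosity",
    "viscosity_from_hematocrit_diameter",
    "segment_resistance",
    "node_volume",
    "compliant_area",
    "PressureSystem",
    "solve_pressure",
]

#: Default diameter [um] -> discharge hematocrit [-] lookup.  Synthetic
#: representative table emulating the in-vivo microvessel hematocrit
#: reduction at small diameters (Fahraeus effect), approaching the systemic
#: value ~0.45 in large vessels.  Overridable via the `blood:` config section.
DEFAULT_HEMATOCRIT_TABLE: tuple[tuple[float, float], ...] = (
    (8.0, 0.12),
    (10.0, 0.15),
    (15.0, 0.22),
    (20.0, 0.28),
    (30.0, 0.35),
    (40.0, 0.40),
    (60.0, 0.43),
    (100.0, 0.45),
)


def hematocrit_from_diameter(
    d: float, table: tuple[tuple[float, float], ...] = DEFAULT_HEMATOCRIT_TABLE
) -> float:
    """Discharge hematocrit for a vessel of diameter ``d`` [m].

    Piecewise-linear interpolation of the (diameter [um], hematocrit) table,
    constant extrapolation beyond the tabulated range.
    """
    if d <= 0:
        raise ValueError("diameter must be > 0")
    if not table:
        raise ValueError("empty hematocrit table")
    d_um = d * 1e6
    ds = [row[0] for row in table]
    hs = [row[1] for row in table]
    h = float(np.interp(d_um, ds, hs))
    return min(max(h, 0.0), 1.0)


def relative_viscosity(H: float, d: float) -> float:
    """Relative apparent blood viscosity (in-vitro law) at hematocrit ``H``,
    diameter ``d`` [m].

    Closed form of the in-vitro diameter/hematocrit relation (Pries et al.):
    ``eta_rel = 1 + (eta45 - 1) * ((1-H)^C - 1) / ((1-0.45)^C - 1)`` with the
    published diameter dependences of ``eta45`` (relative viscosity at
    H = 0.45) and of the shape exponent ``C``.
    """
    if not 0.0 <= H <= 1.0:
        raise ValueError("hematocrit must lie in [0, 1]")
    if d <= 0:
        raise ValueError("diameter must be > 0")
    d_um = d * 1e6
    eta45 = 220.0 * math.exp(-1.3 * d_um) + 3.2 - 2.44 * math.exp(
        -0.06 * d_um**0.645)
    f = 1e11 / (1e11 + d_um**12)  # = 1/(1 + 10^-11 d^12)
    C = (0.8 + math.exp(-0.075 * d_um)) * (-1.0 + f) + f
    if H == 0.0:
        return 1.0
    num = (1.0 - H) ** C - 1.0
    den = (1.0 - 0.45) ** C - 1.0
    return 1.0 + (eta45 - 1.0) * num / den


@dataclass
class BloodProperties:
    """Bulk and rheological blood parameters."""

    mass_density: float = 1050.0  # kg/m^3
    molar_density: float = 284.0  # mol/m^3
    plasma_viscosity: float = 1.2e-3  # Pa*s
    hematocrit_table: tuple[tuple[float, float], ...] = DEFAULT_HEMATOCRIT_TABLE

    def __post_init__(self) -> None:
        if self.mass_density <= 0 or self.molar_density <= 0:
            raise ValueError("densities must be > 0")
        for _, h in self.hematocrit_table:
            if not 0.0 <= h <= 1.0:
                raise ValueError("hematocrit table values must lie in [0, 1]")

    def hematocrit(self, d: float) -> float:
        return hematocrit_from_diameter(d, self.hematocrit_table)

    def viscosity(self, H: float, d: float) -> float:
        return viscosity_from_hematocrit_diameter(H, d, self.plasma_viscosity)


def viscosity_from_hematocrit_diameter(
    H: float, d: float, plasma_viscosity: float = 1.2e-3
) -> float:
    """Apparent viscosity [Pa*s]; never below the plasma viscosity."""
    return plasma_viscosity * max(relative_viscosity(H, d), 1.0)


def segment_resistance(d: float, l: float, mu: float) -> float:
    """Hagen-Poiseuille flow resistance ``R = 8 mu l / (pi r^4)`` [Pa*s/m^3]."""
    if d <= 0 or l <= 0 or mu <= 0:
        raise ValueError("diameter, length and viscosity must be > 0")
    return 8.0 * mu * l / (math.pi * (d / 2.0) ** 4)


def node_volume(graph: VascularGraph, node_id: int) -> float:
    """Blood volume attributed to a node: half the volume of incident edges."""
    edges = graph.incident_edges(node_id)
    if not edges:
        raise ValueError(f"node {node_id} is isolated; volume undefined")
    return sum(e.area * e.length / 2.0 for e in edges)


def compliant_area(
    A_ref: float, C: float, p: float, p_ref: float, min_fraction: float = 0.1
) -> float:
    """Pressure-dependent cross-sectional area ``A = A_ref + C (p - p_ref)``.

    Floored at ``min_fraction * A_ref`` to keep the lumen open; ``C = 0``
    returns the reference area (compliance disabled).
    """
    if A_ref <= 0:
        raise ValueError("A_ref must be > 0")
    return max(A_ref + C * (p - p_ref), min_fraction * A_ref)


@dataclass
class GravityModel:
    enabled: bool = False
    g: float = 9.81  # m/s^2
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)

    def __post_init__(self) -> None:
        n = math.sqrt(sum(c * c for c in self.direction))
        if not math.isclose(n, 1.0, rel_tol=1e-9):
            raise ValueError("gravity direction must be a unit vector")


@dataclass
class FlowSolution:
    """Solved pressure/flow state of the vascular graph."""

    pressures: dict[int, float]
    edge_flows: dict[int, float]  # m^3/s, positive node_a -> node_b
    edge_viscosity: dict[int, float]
    edge_hematocrit: dict[int, float]
    node_volumes: dict[int, float]
    residual: float = 0.0  # max relative nodal imbalance
    metadata: dict = field(default_factory=dict)

    def outflow(self, graph: VascularGraph, node_id: int) -> float:
        """Total volumetric outflow [m^3/s] leaving ``node_id``."""
        out = 0.0
        for e in graph.incident_edges(node_id):
            q = self.edge_flows[e.id]
            if e.node_a == node_id and q > 0:
                out += q
            elif e.node_b == node_id and q < 0:
                out -= q
        return out

    def inflows(self, graph: VascularGraph, node_id: int) -> list[tuple[int, float]]:
        """(upstream node, volumetric inflow) pairs for ``node_id``."""
        res = []
        for e in graph.incident_edges(node_id):
            q = self.edge_flows[e.id]
            if e.node_a == node_id and q < 0:
                res.append((e.node_b, -q))
            elif e.node_b == node_id and q > 0:
                res.append((e.node_a, q))
        return res


class PressureSystem:
    """Reusable sparse linear system for the nodal pressure solve.

    The conductance matrix depends only on geometry, blood properties and the
    (static) effective resistances of upscaled edges, so it is factorized
    once; repeated solves with changing coupling sinks ``q_mass`` only touch
    the right-hand side.
    """

    def __init__(
        self,
        graph: VascularGraph,
        blood: BloodProperties,
        bcs: dict[int, float],
        gravity: GravityModel | None = None,
        upscaled_edge_resistance: dict[int, float] | None = None,
        conservation_tol: float = 1e-10,
    ) -> None:
        if not bcs:
            raise ValueError("at least one Dirichlet pressure node is required")
        for nid, p in bcs.items():
            if nid not in graph.nodes:
                raise ValueError(f"Dirichlet node {nid} not in graph")
            if not math.isfinite(p):
                raise ValueError(f"non-finite Dirichlet pressure at node {nid}")
        self.graph = graph
        self.blood = blood
        self.bcs = dict(bcs)
        self.gravity = gravity or GravityModel()
        self.conservation_tol = conservation_tol
        self._index = {nid: k for k, nid in enumerate(sorted(graph.nodes))}

        self.edge_hematocrit: dict[int, float] = {}
        self.edge_viscosity: dict[int, float] = {}
        self.edge_resistance: dict[int, float] = {}
        override = upscaled_edge_resistance or {}
        for e in graph.edges.values():
            H = blood.hematocrit(e.diameter)
            mu = blood.viscosity(H, e.diameter)
            self.edge_hematocrit[e.id] = H
            self.edge_viscosity[e.id] = mu
            if e.id in override:
                self.edge_resistance[e.id] = override[e.id]
            else:
                self.edge_resistance[e.id] = segment_resistance(
                    e.diameter, e.length, mu)
            if not math.isfinite(self.edge_resistance[e.id]):
                raise ValueError(f"non-finite resistance on edge {e.id}")

        self._assemble()

    def _head_offset(self, node_id: int) -> float:
        """Gravity head rho*g*z of a node [Pa]."""
        if not self.gravity.enabled:
            return 0.0
        return (self.blood.mass_density * self.gravity.g
                * self.graph.nodes[node_id].z_offset)

    def _assemble(self) -> None:
        n = len(self._index)
        rows, cols, vals = [], [], []
        self._grav_rhs = np.zeros(n)
        dirichlet = set(self.bcs)
        for e in self.graph.edges.values():
            gij = 1.0 / self.edge_resistance[e.id]
            ia, ib = self._index[e.node_a], self._index[e.node_b]
            dz_head = self._head_offset(e.node_a) - self._head_offset(e.node_b)
            for i, j, sgn in ((ia, ib, 1.0), (ib, ia, -1.0)):
                nid = e.node_a if sgn > 0 else e.node_b
                if nid in dirichlet:
                    continue
                rows += [i, i]
                cols += [i, j]
                vals += [gij, -gij]
                self._grav_rhs[i] -= sgn * gij * dz_head
        for nid in dirichlet:
            i = self._index[nid]
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
        A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        try:
            self._lu = spla.splu(A)
        except RuntimeError as exc:  # singular
            raise ValueError(f"singular pressure system: {exc}") from exc

    def solve(self, q_mass: dict[int, float] | None = None) -> FlowSolution:
        """Solve for nodal pressures given coupling mass sinks [kg/s].

        ``q_mass`` is positive where fluid leaves the graph (upscaled nodes).
        """
        q_mass = q_mass or {}
        upscaled = {n.id for n in self.graph.upscaled_nodes}
        for nid, q in q_mass.items():
            if q != 0.0 and nid not in upscaled:
                raise ValueError(
                    f"mass sink at node {nid} which is not an upscaled node")
            if not math.isfinite(q):
                raise ValueError(f"non-finite q_mass at node {nid}")
        n = len(self._index)
        b = self._grav_rhs.copy()
        for nid, q in q_mass.items():
            b[self._index[nid]] -= q / self.blood.mass_density
        for nid, p in self.bcs.items():
            b[self._index[nid]] = p
        p = self._lu.solve(b)

        pressures = {nid: float(p[i]) for nid, i in self._index.items()}
        edge_flows = {}
        for e in self.graph.edges.values():
            ha = pressures[e.node_a] + self._head_offset(e.node_a)
            hb = pressures[e.node_b] + self._head_offset(e.node_b)
            edge_flows[e.id] = (ha - hb) / self.edge_resistance[e.id]

        # nodal balance check on free, non-upscaled nodes
        scale = max(abs(q) for q in edge_flows.values()) or 1.0
        residual = 0.0
        for nid in self.graph.nodes:
            if nid in self.bcs:
                continue
            net = sum(
                (edge_flows[e.id] if e.node_b == nid else -edge_flows[e.id])
                for e in self.graph.incident_edges(nid)
            )
            net -= q_mass.get(nid, 0.0) / self.blood.mass_density
            residual = max(residual, abs(net) / scale)
        if residual > self.conservation_tol:
            raise ValueError(
                f"nodal balance residual {residual:.3e} exceeds tolerance "
                f"{self.conservation_tol:.3e}")

        volumes = {nid: node_volume(self.graph, nid) for nid in self.graph.nodes}
        return FlowSolution(
            pressures=pressures,
            edge_flows=edge_flows,
            edge_viscosity=dict(self.edge_viscosity),
            edge_hematocrit=dict(self.edge_hematocrit),
            node_volumes=volumes,
            residual=residual,
        )


def solve_pressure(
    graph: VascularGraph,
    blood: BloodProperties | None = None,
    bcs: dict[int, float] | None = None,
    q_mass: dict[int, float] | None = None,
    gravity: GravityModel | None = None,
    upscaled_edge_resistance: dict[int, float] | None = None,
    compliance_enabled: bool = False,
    compliance_p_ref: float = 0.0,
    compliance_rtol: float = 1e-8,
    compliance_max_iter: int = 50,
) -> FlowSolution:
    """Solve the nodal continuity equations of the vascular graph.

    With ``compliance_enabled`` the solve iterates area -> resistance ->
    pressure -> area until the pressures are stationary to
    ``compliance_rtol`` (only edges with nonzero compliance change).
    """
    blood = blood or BloodProperties()
    if bcs is None:
        raise ValueError("Dirichlet boundary conditions are required")
    system = PressureSystem(graph, blood, bcs, gravity, upscaled_edge_resistance)
    sol = system.solve(q_mass)
    if not compliance_enabled:
        return sol
    has_compliance = any(e.compliance != 0.0 for e in graph.edges.values())
    if not has_compliance:
        return sol
    for _ in range(compliance_max_iter):
        override = dict(upscaled_edge_resistance or {})
        for e in graph.edges.values():
            if e.compliance == 0.0 or e.vessel_class is VesselClass.UPSCALED_EDGE:
                continue
            p_edge = 0.5 * (sol.pressures[e.node_a] + sol.pressures[e.node_b])
            A = compliant_area(e.area, e.compliance, p_edge, compliance_p_ref)
            d_eff = 2.0 * math.sqrt(A / math.pi)
            override[e.id] = segment_resistance(
                d_eff, e.length, system.edge_viscosity[e.id])
        system = PressureSystem(graph, blood, bcs, gravity, override)
        new = system.solve(q_mass)
        delta = max(
            abs(new.pressures[n] - sol.pressures[n]) for n in graph.nodes
        )
        scale = max(abs(p) for p in new.pressures.values()) or 1.0
        sol = new
        if delta / scale <= compliance_rtol:
            break
    return sol
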