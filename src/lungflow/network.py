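"""Vascular graph data model and generators.

The pulmonary vasculature outside the capillary bed is represented as a graph:
nodes are bifurcation points or vessel ends, edges are vessel segments with a
mean diameter, a length and a Strahler order.  Generators build
Strahler-ordered dichotomous trees from printed morphometry tables of the
human pulmonary arterial and venous trees (diameters/lengths per order), and
the coupled example scenario in which an arterial tree and a venous tree are
joined through "upscaled" nodes, each standing in for the capillary bed of a
single alveolus.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "NodeKind",
    "VesselClass",
    "GraphNode",
    "VesselSegment",
    "VascularGraph",
    "GraphError",
    "ARTERIAL_MORPHOMETRY",
    "VENOUS_MORPHOMETRY",
    "assign_strahler_orders",
    "build_strahler_tree",
    "build_coupled_example",
    "side_subgraph",
    "read_graph",
    "write_graph",
]

GRAPH_SCHEMA = "lungflow-graph"
GRAPH_SCHEMA_VERSION = 1


class GraphError(ValueError):
    """Raised for structurally invalid vascular graphs or graph files."""


class NodeKind(str, Enum):
    REGULAR = "regular"
    BOUNDARY_ARTERIAL = "boundary_arterial"
    BOUNDARY_VENOUS = "boundary_venous"
    UPSCALED_HEALTHY = "upscaled_healthy"
    UPSCALED_TUMOR = "upscaled_tumor"


class VesselClass(str, Enum):
    ARTERY = "artery"
    ARTERIOLE = "arteriole"
    VENULE = "venule"
    VEIN = "vein"
    UPSCALED_EDGE = "upscaled_edge"


@dataclass
class GraphNode:
    id: int
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: NodeKind = NodeKind.REGULAR
    #: signed distance [m] to the pulmonary-artery entry along the gravity
    #: axis; used by the optional gravity correction of the pressure solve.
    z_offset: float = 0.0


@dataclass
class VesselSegment:
    id: int
    node_a: int
    node_b: int
    diameter: float  # m
    length: float  # m
    strahler_order: int = 1
    vessel_class: VesselClass = VesselClass.ARTERY
    compliance: float = 0.0  # m^2/Pa, cross-sectional; 0 disables

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GraphError(f"edge {self.id}: diameter must be > 0")
        if self.length <= 0:
            raise GraphError(f"edge {self.id}: length must be > 0")
        if self.node_a == self.node_b:
            raise GraphError(f"edge {self.id}: self-loop not allowed")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def area(self) -> float:
        """Reference cross-sectional area [m^2]."""
        return math.pi * self.radius**2


class VascularGraph:
    """Container for nodes and vessel segments with adjacency bookkeeping."""

    def __init__(self, metadata: dict | None = None) -> None:
        self.nodes: dict[int, GraphNode] = {}
        self.edges: dict[int, VesselSegment] = {}
        self.metadata: dict = dict(metadata or {})
        self._adj: dict[int, list[int]] = {}  # node id -> incident edge ids

    # -- construction -------------------------------------------------
    def add_node(self, node: GraphNode) -> GraphNode:
        if node.id in self.nodes:
            raise GraphError(f"duplicate node id {node.id}")
        self.nodes[node.id] = node
        self._adj[node.id] = []
        return node

    def add_edge(self, edge: VesselSegment) -> VesselSegment:
        if edge.id in self.edges:
            raise GraphError(f"duplicate edge id {edge.id}")
        for n in (edge.node_a, edge.node_b):
            if n not in self.nodes:
                raise GraphError(f"edge {edge.id}: unknown node {n}")
        pair = frozenset((edge.node_a, edge.node_b))
        for eid in self._adj[edge.node_a]:
            e = self.edges[eid]
            if frozenset((e.node_a, e.node_b)) == pair:
                raise GraphError(
                    f"edge {edge.id}: duplicate edge between nodes {sorted(pair)}"
                )
        self.edges[edge.id] = edge
        self._adj[edge.node_a].append(edge.id)
        self._adj[edge.node_b].append(edge.id)
        return edge

    # -- queries ------------------------------------------------------
    def incident_edges(self, node_id: int) -> list[VesselSegment]:
        return [self.edges[eid] for eid in self._adj[node_id]]

    def degree(self, node_id: int) -> int:
        return len(self._adj[node_id])

    def neighbors(self, node_id: int) -> list[int]:
        out = []
        for e in self.incident_edges(node_id):
            out.append(e.node_b if e.node_a == node_id else e.node_a)
        return out

    def other_end(self, edge: VesselSegment, node_id: int) -> int:
        return edge.node_b if edge.node_a == node_id else edge.node_a

    def nodes_of_kind(self, *kinds: NodeKind) -> list[GraphNode]:
        return [n for n in self.nodes.values() if n.kind in kinds]

    @property
    def upscaled_nodes(self) -> list[GraphNode]:
        return self.nodes_of_kind(NodeKind.UPSCALED_HEALTHY, NodeKind.UPSCALED_TUMOR)

    @property
    def boundary_nodes(self) -> list[GraphNode]:
        return self.nodes_of_kind(NodeKind.BOUNDARY_ARTERIAL, NodeKind.BOUNDARY_VENOUS)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes.values():
            g.add_node(n.id, kind=n.kind.value, x=n.position[0], y=n.position[1],
                       z=n.position[2], z_offset=n.z_offset)
        for e in self.edges.values():
            g.add_edge(e.node_a, e.node_b, id=e.id, diameter=e.diameter,
                       length=e.length, strahler_order=e.strahler_order,
                       vessel_class=e.vessel_class.value, compliance=e.compliance)
        return g

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise :class:`GraphError` on failure."""
        if not self.nodes:
            raise GraphError("empty graph")
        g = self.to_networkx()
        if self.edges and not nx.is_connected(g):
            raise GraphError("graph is not connected")
        for n in self.nodes.values():
            deg = self.degree(n.id)
            if n.kind in (NodeKind.BOUNDARY_ARTERIAL, NodeKind.BOUNDARY_VENOUS):
                if deg != 1:
                    raise GraphError(f"boundary node {n.id} has degree {deg} != 1")
            if n.kind in (NodeKind.UPSCALED_HEALTHY, NodeKind.UPSCALED_TUMOR):
                if deg != 2:
                    raise GraphError(f"upscaled node {n.id} has degree {deg} != 2")
                for e in self.incident_edges(n.id):
                    if e.vessel_class is not VesselClass.UPSCALED_EDGE:
                        raise GraphError(
                            f"upscaled node {n.id}: incident edge {e.id} has class "
                            f"{e.vessel_class.value}, expected upscaled_edge"
                        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VascularGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.metadata == other.metadata
        )


# ---------------------------------------------------------------------------
# Morphometry of the human pulmonary arterial and venous trees.
# Per Strahler order: (mean diameter [m], length [m]); printed source values
# are in mm.  Orders 1..17 (arterial) and 1..15 (venous).
# ---------------------------------------------------------------------------

def _mm(d: float, l: float) -> tuple[float, float]:
    return (d * 1e-3, l * 1e-3)


ARTERIAL_MORPHOMETRY: dict[int, tuple[float, float]] = {
    17: _mm(30.000, 90.50),
    16: _mm(14.830, 32.00),
    15: _mm(8.060, 10.90),
    14: _mm(5.820, 20.70),
    13: _mm(3.650, 17.90),
    12: _mm(2.090, 10.50),
    11: _mm(1.330, 6.60),
    10: _mm(0.850, 4.69),
    9: _mm(0.525, 3.16),
    8: _mm(0.351, 2.10),
    7: _mm(0.224, 1.38),
    6: _mm(0.138, 0.91),
    5: _mm(0.086, 0.65),
    4: _mm(0.054, 0.44),
    3: _mm(0.034, 0.29),
    2: _mm(0.021, 0.20),
    1: _mm(0.013, 0.13),
}

VENOUS_MORPHOMETRY: dict[int, tuple[float, float]] = {
    15: _mm(13.88, 36.7),
    14: _mm(5.23, 39.0),
    13: _mm(2.90, 25.4),
    12: _mm(1.90, 18.5),
    11: _mm(1.21, 11.0),
    10: _mm(0.61, 3.20),
    9: _mm(0.39, 2.54),
    8: _mm(0.22, 1.98),
    7: _mm(0.14, 1.34),
    6: _mm(0.096, 0.910),
    5: _mm(0.064, 0.617),
    4: _mm(0.043, 0.418),
    3: _mm(0.029, 0.283),
    2: _mm(0.019, 0.192),
    1: _mm(0.013, 0.130),
}


# ---------------------------------------------------------------------------
# Strahler ordering
# ---------------------------------------------------------------------------

def assign_strahler_orders(
    graph: VascularGraph, root: int
) -> tuple[dict[int, int], dict[int, int]]:
    """Label every edge (and node) of a rooted tree with its Strahler order.

    Terminal (leaf) vessels get order 1.  Where two vessels of equal order n
    meet, the confluent vessel has order n+1; where orders differ, the larger
    one carries through.  A node is labelled with the largest order among its
    incident edges.

    Returns ``(node_orders, edge_orders)``.  Rejects graphs with cycles or
    disconnected parts (the operation is defined on trees).
    """
    if root not in graph.nodes:
        raise GraphError(f"root node {root} not in graph")
    g = graph.to_networkx()
    if not nx.is_connected(g):
        raise GraphError("Strahler ordering requires a connected graph")
    if g.number_of_edges() != g.number_of_nodes() - 1:
        raise GraphError("cycle detected: Strahler ordering requires a tree")

    edge_orders: dict[int, int] = {}
    # iterative post-order from the root
    stack: list[tuple[int, int | None, bool]] = [(root, None, False)]
    while stack:
        node, in_edge, processed = stack.pop()
        children = [
            e.id for e in graph.incident_edges(node) if e.id != in_edge
        ]
        if not processed:
            stack.append((node, in_edge, True))
            for eid in children:
                e = graph.edges[eid]
                stack.append((graph.other_end(e, node), eid, False))
            continue
        if in_edge is None:
            continue
        child_orders = sorted((edge_orders[c] for c in children), reverse=True)
        if not child_orders:
            edge_orders[in_edge] = 1
        elif len(child_orders) >= 2 and child_orders[0] == child_orders[1]:
            edge_orders[in_edge] = child_orders[0] + 1
        else:
            edge_orders[in_edge] = child_orders[0]
    # the root itself has no inbound edge; root-side edges are already done
    node_orders = {
        n: max((edge_orders[e.id] for e in graph.incident_edges(n)), default=0)
        for n in graph.nodes
    }
    return node_orders, edge_orders


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------

@dataclass
class _Plan:
    order: int
    children: list["_Plan"] = field(default_factory=list)


def _plan_vessel(order: int, n_leaves: int) -> _Plan:
    """Plan a Strahler-consistent binary subtree with the requested leaves.

    Splits are balanced where possible; an order-2 vessel with more than two
    terminals continues as a chain shedding order-1 side branches (an order-n
    vessel meeting a lower-order one keeps order n).
    """
    if order == 1:
        if n_leaves != 1:
            raise GraphError("order-1 vessel must terminate in exactly 1 leaf")
        return _Plan(1)
    if n_leaves < 2 ** (order - 1):
        raise GraphError(
            f"cannot build an order-{order} tree with {n_leaves} terminals; "
            f"at least {2 ** (order - 1)} are required"
        )
    if order == 2:
        if n_leaves == 2:
            return _Plan(2, [_plan_vessel(1, 1), _plan_vessel(1, 1)])
        return _Plan(2, [_plan_vessel(2, n_leaves - 1), _plan_vessel(1, 1)])
    n1 = (n_leaves + 1) // 2
    n2 = n_leaves - n1
    if n2 >= 2 ** (order - 2):
        return _Plan(order, [_plan_vessel(order - 1, n1), _plan_vessel(order - 1, n2)])
    return _Plan(order, [_plan_vessel(order, n_leaves - 1), _plan_vessel(1, 1)])


def _vessel_class_for(order: int, side: str) -> VesselClass:
    if side == "arterial":
        return VesselClass.ARTERY if order >= 4 else VesselClass.ARTERIOLE
    return VesselClass.VEIN if order >= 4 else VesselClass.VENULE


def build_strahler_tree(
    root_order: int,
    morphometry: Mapping[int, tuple[float, float]],
    n_leaves: int,
    side: str = "arterial",
    *,
    leaf_spacing: float = 5e-4,
    y_sign: float = 1.0,
    node_offset: int = 0,
    edge_offset: int = 0,
) -> VascularGraph:
    """Build a dichotomous Strahler tree carrying per-order morphometry.

    Edges of order k receive the diameter and length of order k from
    ``morphometry``.  The tree is laid out planar (z = 0): terminals sit on
    the y = 0 line spaced ``leaf_spacing`` apart, the root is furthest away
    in ``y_sign`` direction.
    """
    if side not in ("arterial", "venous"):
        raise GraphError(f"unknown side {side!r}")
    if root_order < 1:
        raise GraphError("root_order must be >= 1")
    missing = [k for k in range(1, root_order + 1) if k not in morphometry]
    if missing:
        raise GraphError(f"morphometry missing orders {missing}")
    plan = _plan_vessel(root_order, n_leaves)

    graph = VascularGraph(metadata={
        "generator": "build_strahler_tree",
        "side": side,
        "root_order": root_order,
        "n_leaves": n_leaves,
        "units": {"length": "m"},
    })
    counter = {"node": node_offset, "edge": edge_offset}

    def new_node(pos: tuple[float, float, float], kind: NodeKind) -> GraphNode:
        node = GraphNode(id=counter["node"], position=pos, kind=kind)
        counter["node"] += 1
        return graph.add_node(node)

    # leaf x-positions assigned left-to-right in plan order
    leaf_x = iter(i * leaf_spacing for i in range(n_leaves))

    def build(plan: _Plan, parent: GraphNode, depth_y: float) -> None:
        d, l = morphometry[plan.order]
        child_y = depth_y - y_sign * l
        if not plan.children:
            pos = (next(leaf_x), child_y, 0.0)
        else:
            pos = (parent.position[0], child_y, 0.0)  # fixed up afterwards
        child = new_node(pos, NodeKind.REGULAR)
        graph.add_edge(VesselSegment(
            id=counter["edge"], node_a=parent.id, node_b=child.id,
            diameter=d, length=l, strahler_order=plan.order,
            vessel_class=_vessel_class_for(plan.order, side),
        ))
        counter["edge"] += 1
        for sub in plan.children:
            build(sub, child, child_y)

    root_kind = (NodeKind.BOUNDARY_ARTERIAL if side == "arterial"
                 else NodeKind.BOUNDARY_VENOUS)
    total_depth = sum(morphometry[k][1] for k in range(1, root_order + 1))
    root = new_node((0.0, y_sign * total_depth, 0.0), root_kind)
    build(plan, root, root.position[1])

    _fixup_x_positions(graph, root.id)
    graph.metadata["root_node"] = root.id
    graph.validate()
    return graph


def _fixup_x_positions(graph: VascularGraph, root: int) -> None:
    """Set internal-node x to the mean of their children's x (planar layout)."""
    order: list[tuple[int, int | None]] = []
    stack: list[tuple[int, int | None]] = [(root, None)]
    while stack:
        node, in_edge = stack.pop()
        order.append((node, in_edge))
        for e in graph.incident_edges(node):
            if e.id != in_edge:
                stack.append((graph.other_end(e, node), e.id))
    for node, in_edge in reversed(order):
        children = [
            graph.other_end(e, node)
            for e in graph.incident_edges(node)
            if e.id != in_edge
        ]
        if children:
            n = graph.nodes[node]
            xs = [graph.nodes[c].position[0] for c in children]
            n.position = (sum(xs) / len(xs), n.position[1], n.position[2])


# ---------------------------------------------------------------------------
# Coupled example scenario
# ---------------------------------------------------------------------------

DEFAULT_TUMOR_IDS = frozenset({4, 10, 16})


def build_coupled_example(
    n_alveoli: int = 21,
    tumor_ids: Iterable[int] | None = None,
    *,
    arterial_root_order: int = 4,
    venous_root_order: int = 4,
) -> VascularGraph:
    """Build the coupled example network: two order-4 trees joined by alveoli.

    An arterial tree branches from order 4 down to ``n_alveoli`` order-1
    pre-capillary arterioles; each connects through an upscaled edge to an
    upscaled node (one per alveolus) and onward to a post-capillary venule of
    the mirrored venous tree.  ``tumor_ids`` (indices into 0..n_alveoli-1,
    default three of the 21) marks which alveoli carry tumor properties.
    """
    if n_alveoli < 1:
        raise GraphError("n_alveoli must be >= 1")
    if tumor_ids is None:
        tumor_ids = {i for i in DEFAULT_TUMOR_IDS if i < n_alveoli}
    tumor_ids = set(tumor_ids)
    if not tumor_ids <= set(range(n_alveoli)):
        raise GraphError(f"tumor_ids {sorted(tumor_ids)} outside 0..{n_alveoli - 1}")

    if n_alveoli == 1:
        # smallest valid coupled scenario: one arteriole, one venule
        art = _single_vessel_tree(ARTERIAL_MORPHOMETRY, "arterial")
        ven = _single_vessel_tree(
            VENOUS_MORPHOMETRY, "venous",
            node_offset=len(art.nodes), edge_offset=len(art.edges))
    else:
        art = build_strahler_tree(
            arterial_root_order, ARTERIAL_MORPHOMETRY, n_alveoli, "arterial",
            y_sign=1.0)
        ven = build_strahler_tree(
            venous_root_order, VENOUS_MORPHOMETRY, n_alveoli, "venous",
            y_sign=-1.0, node_offset=len(art.nodes), edge_offset=len(art.edges))

    graph = VascularGraph(metadata={
        "generator": "build_coupled_example",
        "n_alveoli": n_alveoli,
        "tumor_ids": sorted(tumor_ids),
        "units": {"length": "m"},
        "arterial_root": art.metadata["root_node"],
        "venous_root": ven.metadata["root_node"],
    })
    for part in (art, ven):
        for n in part.nodes.values():
            graph.add_node(replace(n))
        for e in part.edges.values():
            graph.add_edge(replace(e))

    art_leaves = _ordered_leaves(art)
    ven_leaves = _ordered_leaves(ven)
    assert len(art_leaves) == len(ven_leaves) == n_alveoli

    next_node = max(graph.nodes) + 1
    next_edge = max(graph.edges) + 1
    d1a, l1a = ARTERIAL_MORPHOMETRY[1]
    d1v, l1v = VENOUS_MORPHOMETRY[1]
    upscaled = []
    for k, (na, nv) in enumerate(zip(art_leaves, ven_leaves)):
        kind = (NodeKind.UPSCALED_TUMOR if k in tumor_ids
                else NodeKind.UPSCALED_HEALTHY)
        pa = graph.nodes[na].position
        pv = graph.nodes[nv].position
        pos = ((pa[0] + pv[0]) / 2, (pa[1] + pv[1]) / 2, 0.0)
        un = graph.add_node(GraphNode(id=next_node, position=pos, kind=kind))
        next_node += 1
        # upscaled edges carry the order-1 geometry of their side's table;
        # their hydraulic role is replaced by the effective upscaled-node
        # resistance in the coupled solve.
        graph.add_edge(VesselSegment(
            id=next_edge, node_a=na, node_b=un.id, diameter=d1a, length=l1a,
            strahler_order=1, vessel_class=VesselClass.UPSCALED_EDGE))
        next_edge += 1
        graph.add_edge(VesselSegment(
            id=next_edge, node_a=un.id, node_b=nv, diameter=d1v, length=l1v,
            strahler_order=1, vessel_class=VesselClass.UPSCALED_EDGE))
        next_edge += 1
        upscaled.append(un.id)
    graph.metadata["upscaled_node_ids"] = upscaled
    graph.validate()
    return graph


def _single_vessel_tree(morphometry, side, node_offset=0, edge_offset=0):
    g = VascularGraph(metadata={"units": {"length": "m"}})
    d, l = morphometry[1]
    kind = (NodeKind.BOUNDARY_ARTERIAL if side == "arterial"
            else NodeKind.BOUNDARY_VENOUS)
    y = l if side == "arterial" else -l
    root = g.add_node(GraphNode(id=node_offset, position=(0.0, y, 0.0), kind=kind))
    leaf = g.add_node(GraphNode(id=node_offset + 1, position=(0.0, 0.0, 0.0)))
    g.add_edge(VesselSegment(
        id=edge_offset, node_a=root.id, node_b=leaf.id, diameter=d, length=l,
        strahler_order=1, vessel_class=_vessel_class_for(1, side)))
    g.metadata["root_node"] = root.id
    return g


def _ordered_leaves(tree: VascularGraph) -> list[int]:
    """Order-1 terminal node ids, sorted left-to-right by x position."""
    root = tree.metadata["root_node"]
    leaves = [
        n.id for n in tree.nodes.values()
        if tree.degree(n.id) == 1 and n.id != root
    ]
    return sorted(leaves, key=lambda nid: tree.nodes[nid].position[0])


def side_subgraph(graph: VascularGraph, side: str = "arterial") -> VascularGraph:
    """Extract the arterial (or venous) tree of a coupled graph.

    Keeps only artery/arteriole (resp. vein/venule) edges and their incident
    nodes, dropping upscaled nodes and edges, so the result is again a rooted
    tree on which Strahler relabeling is well defined.
    """
    if side == "arterial":
        classes = {VesselClass.ARTERY, VesselClass.ARTERIOLE}
    elif side == "venous":
        classes = {VesselClass.VEIN, VesselClass.VENULE}
    else:
        raise GraphError(f"unknown side {side!r}")
    sub = VascularGraph(metadata={"units": {"length": "m"}, "side": side})
    keep_edges = [e for e in graph.edges.values() if e.vessel_class in classes]
    keep_nodes = {e.node_a for e in keep_edges} | {e.node_b for e in keep_edges}
    for nid in sorted(keep_nodes):
        sub.add_node(replace(graph.nodes[nid]))
    for e in keep_edges:
        sub.add_edge(replace(e))
    key = "arterial_root" if side == "arterial" else "venous_root"
    if key in graph.metadata:
        sub.metadata["root_node"] = graph.metadata[key]
    return sub


# ---------------------------------------------------------------------------
# Graph I/O: versioned JSON (native) and GraphML (interoperability)
# ---------------------------------------------------------------------------

def write_graph(graph: VascularGraph, path: str | Path, format: str = "json") -> None:
    path = Path(path)
    if format == "json":
        doc = {
            "schema": GRAPH_SCHEMA,
            "version": GRAPH_SCHEMA_VERSION,
            "units": {"length": "m", "compliance": "m^2/Pa"},
            "metadata": graph.metadata,
            "nodes": [
                {
                    "id": n.id,
                    "position": list(n.position),
                    "kind": n.kind.value,
                    "z_offset": n.z_offset,
                }
                for n in sorted(graph.nodes.values(), key=lambda n: n.id)
            ],
            "edges": [
                {
                    "id": e.id,
                    "node_a": e.node_a,
                    "node_b": e.node_b,
                    "diameter": e.diameter,
                    "length": e.length,
                    "strahler_order": e.strahler_order,
                    "vessel_class": e.vessel_class.value,
                    "compliance": e.compliance,
                }
                for e in sorted(graph.edges.values(), key=lambda e: e.id)
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    elif format == "graphml":
        nx.write_graphml(graph.to_networkx(), path)
    else:
        raise GraphError(f"unknown graph format {format!r}")


_EDGE_REQUIRED = ("id", "node_a", "node_b", "diameter", "length")
_NODE_REQUIRED = ("id",)


def read_graph(path: str | Path, format: str = "json") -> VascularGraph:
    path = Path(path)
    if format == "graphml":
        return _from_networkx(nx.read_graphml(path))
    if format != "json":
        raise GraphError(f"unknown graph format {format!r}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GraphError(f"malformed graph file {path}: {exc}") from exc
    if doc.get("schema") != GRAPH_SCHEMA:
        raise GraphError(f"{path}: missing/unknown schema field 'schema'")
    if doc.get("version") != GRAPH_SCHEMA_VERSION:
        raise GraphError(f"{path}: unsupported schema version {doc.get('version')}")
    units = doc.get("units", {})
    if units.get("length") != "m":
        raise GraphError(f"{path}: unit mismatch in field 'units.length' "
                         f"(expected 'm', got {units.get('length')!r})")
    graph = VascularGraph(metadata=doc.get("metadata", {}))
    for rec in doc.get("nodes", []):
        for key in _NODE_REQUIRED:
            if key not in rec:
                raise GraphError(f"{path}: node record missing field {key!r}")
        graph.add_node(GraphNode(
            id=int(rec["id"]),
            position=tuple(rec.get("position", (0.0, 0.0, 0.0))),
            kind=NodeKind(rec.get("kind", "regular")),
            z_offset=float(rec.get("z_offset", 0.0)),
        ))
    for rec in doc.get("edges", []):
        for key in _EDGE_REQUIRED:
            if key not in rec:
                eid = rec.get("id", "?")
                raise GraphError(
                    f"{path}: edge {eid} missing mandatory attribute {key!r}")
        graph.add_edge(VesselSegment(
            id=int(rec["id"]),
            node_a=int(rec["node_a"]),
            node_b=int(rec["node_b"]),
            diameter=float(rec["diameter"]),
            length=float(rec["length"]),
            strahler_order=int(rec.get("strahler_order", 1)),
            vessel_class=VesselClass(rec.get("vessel_class", "artery")),
            compliance=float(rec.get("compliance", 0.0)),
        ))
    return graph


def _from_networkx(g: nx.Graph) -> VascularGraph:
    graph = VascularGraph()
    for nid, data in g.nodes(data=True):
        graph.add_node(GraphNode(
            id=int(nid),
            position=(float(data.get("x", 0.0)), float(data.get("y", 0.0)),
                      float(data.get("z", 0.0))),
            kind=NodeKind(data.get("kind", "regular")),
            z_offset=float(data.get("z_offset", 0.0)),
        ))
    for a, b, data in g.edges(data=True):
        if "diameter" not in data:
            raise GraphError(f"edge {data.get('id', (a, b))}: missing attribute 'diameter'")
        graph.add_edge(VesselSegment(
            id=int(data.get("id", len(graph.edges))),
            node_a=int(a), node_b=int(b),
            diameter=float(data["diameter"]),
            length=float(data["length"]),
            strahler_order=int(data.get("strahler_order", 1)),
            vessel_class=VesselClass(data.get("vessel_class", "artery")),
            compliance=float(data.get("compliance", 0.0)),
        ))
    return graph
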