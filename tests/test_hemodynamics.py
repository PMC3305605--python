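"""Graph hemodynamics: viscosity laws, resistances, the pressure solve."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungflow.hemodynamics import (
    BloodProperties,
    GravityModel,
    compliant_area,
    hematocrit_from_diameter,
    node_volume,
    segment_resistance,
    solve_pressure,
    viscosity_from_hematocrit_diameter,
)
from lungflow.network import (
    ARTERIAL_MORPHOMETRY,
    GraphNode,
    NodeKind,
    VascularGraph,
    VesselSegment,
    build_strahler_tree,
)

CONST_MU_BLOOD = BloodProperties(plasma_viscosity=2.1e-3,
                                 hematocrit_table=((1.0, 0.0),))


def two_node_tube(diameter=8e-6, length=1e-5):
    g = VascularGraph()
    g.add_node(GraphNode(id=0, kind=NodeKind.BOUNDARY_ARTERIAL))
    g.add_node(GraphNode(id=1, kind=NodeKind.BOUNDARY_VENOUS))
    g.add_edge(VesselSegment(id=0, node_a=0, node_b=1,
                             diameter=diameter, length=length))
    return g


class TestHematocrit:
    TABLE = ((10.0, 0.2), (20.0, 0.4))

    def test_tabulated_point_exact(self):
        assert hematocrit_from_diameter(10e-6, self.TABLE) == 0.2

    def test_midpoint_is_mean(self):
        assert hematocrit_from_diameter(15e-6, self.TABLE) == pytest.approx(0.3)

    def test_constant_extrapolation(self):
        assert hematocrit_from_diameter(1e-3, self.TABLE) == 0.4
        assert hematocrit_from_diameter(1e-6, self.TABLE) == 0.2

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hematocrit_from_diameter(1e-5, ())


class TestViscosity:
    def test_zero_hematocrit_gives_plasma(self):
        assert viscosity_from_hematocrit_diameter(0.0, 8e-6, 1.2e-3) == 1.2e-3

    def test_monotone_in_hematocrit(self):
        mus = [viscosity_from_hematocrit_diameter(h, 8e-6)
               for h in (0.1, 0.3, 0.45, 0.6)]
        assert all(a < b for a, b in zip(mus, mus[1:]))

    def test_capillary_value_frozen(self):
        # closed-form law at d = 8 um, H = 0.45, plasma 1.2 mPa s
        mu = viscosity_from_hematocrit_diameter(0.45, 8e-6, 1.2e-3)
        assert mu == pytest.approx(1.5203060932953822e-3, rel=1e-9)

    def test_never_below_plasma(self):
        for d in (4e-6, 8e-6, 1e-4, 1e-2):
            for h in (0.0, 0.2, 0.45):
                assert viscosity_from_hematocrit_diameter(h, d) >= 1.2e-3


class TestSegmentResistance:
    def test_hand_value(self):
        # d = 8 um, l = 10 um, mu = 2.1 mPa s
        R = segment_resistance(8e-6, 1e-5, 2.1e-3)
        assert R == pytest.approx(8 * 2.1e-3 * 1e-5 / (math.pi * 4e-6**4))
        assert R == pytest.approx(2.09e14, rel=0.01)

    def test_fourth_power_diameter_scaling(self):
        R1 = segment_resistance(8e-6, 1e-5, 2.1e-3)
        R2 = segment_resistance(16e-6, 1e-5, 2.1e-3)
        assert R1 / R2 == pytest.approx(16.0, rel=1e-12)

    def test_series_resistance_doubles(self):
        g = VascularGraph()
        for i in range(3):
            g.add_node(GraphNode(id=i))
        for i in range(2):
            g.add_edge(VesselSegment(id=i, node_a=i, node_b=i + 1,
                                     diameter=8e-6, length=1e-5))
        sol = solve_pressure(g, CONST_MU_BLOOD, bcs={0: 100.0, 2: 0.0})
        R_net = 100.0 / sol.edge_flows[0]
        assert R_net == pytest.approx(
            2 * segment_resistance(8e-6, 1e-5, 2.1e-3), rel=1e-12)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            segment_resistance(0.0, 1e-5, 2.1e-3)


class TestNodeVolume:
    def test_leaf_gets_half_edge_volume(self):
        g = two_node_tube()
        e = g.edges[0]
        assert node_volume(g, 0) == pytest.approx(e.area * e.length / 2)

    def test_two_identical_edges_give_full_volume(self):
        g = VascularGraph()
        for i in range(3):
            g.add_node(GraphNode(id=i))
        for i in range(2):
            g.add_edge(VesselSegment(id=i, node_a=i, node_b=i + 1,
                                     diameter=8e-6, length=1e-5))
        e = g.edges[0]
        assert node_volume(g, 1) == pytest.approx(e.area * e.length)

    def test_order1_arterial_half_volume(self):
        d, l = ARTERIAL_MORPHOMETRY[1]
        g = two_node_tube(d, l)
        assert node_volume(g, 0) == pytest.approx(8.63e-15, rel=0.01)

    def test_isolated_node_rejected(self):
        g = VascularGraph()
        g.add_node(GraphNode(id=0))
        with pytest.raises(ValueError, match="isolated"):
            node_volume(g, 0)


class TestCompliantArea:
    def test_disabled_compliance_returns_reference(self):
        assert compliant_area(1e-10, 0.0, 5000.0, 0.0) == 1e-10

    def test_reference_pressure_returns_reference(self):
        assert compliant_area(1e-10, 1e-14, 500.0, 500.0) == 1e-10

    def test_positive_compliance_dilates(self):
        assert compliant_area(1e-10, 1e-14, 600.0, 500.0) > 1e-10

    def test_area_floor(self):
        assert compliant_area(1e-10, 1e-12, -1e6, 0.0) == pytest.approx(1e-11)


class TestSolvePressure:
    def test_chain_midpoint_pressure(self):
        g = VascularGraph()
        for i in range(3):
            g.add_node(GraphNode(id=i))
        for i in range(2):
            g.add_edge(VesselSegment(id=i, node_a=i, node_b=i + 1,
                                     diameter=1e-5, length=1e-4))
        sol = solve_pressure(g, bcs={0: 1064.0, 2: 199.5})
        assert sol.pressures[1] == pytest.approx(631.75)

    def test_single_tube_matches_poiseuille(self):
        g = two_node_tube()
        sol = solve_pressure(g, CONST_MU_BLOOD, bcs={0: 100.0, 1: 0.0})
        Q_exact = math.pi * (4e-6) ** 4 * 100.0 / (8 * 2.1e-3 * 1e-5)
        assert sol.edge_flows[0] == pytest.approx(Q_exact, rel=1e-14)

    def test_balanced_tree_mirror_symmetric_flows(self):
        tree = build_strahler_tree(4, ARTERIAL_MORPHOMETRY, 8, "arterial")
        root = tree.metadata["root_node"]
        leaves = [n.id for n in tree.nodes.values()
                  if tree.degree(n.id) == 1 and n.id != root]
        bcs = {root: 1064.0}
        bcs.update({leaf: 199.5 for leaf in leaves})
        sol = solve_pressure(tree, bcs=bcs)
        by_order = {}
        for e in tree.edges.values():
            by_order.setdefault(e.strahler_order, []).append(
                abs(sol.edge_flows[e.id]))
        for order, flows in by_order.items():
            assert np.ptp(flows) <= 1e-10 * max(flows)

    def test_mass_conservation_boundary_balance(self, example_graph):
        g = example_graph
        sol = solve_pressure(g, bcs={
            g.metadata["arterial_root"]: 1064.0,
            g.metadata["venous_root"]: 199.5})
        inflow = sol.outflow(g, g.metadata["arterial_root"])
        outflow = sum(q for _, q in sol.inflows(g, g.metadata["venous_root"]))
        assert abs(inflow - outflow) <= 1e-10 * inflow
        assert sol.residual <= 1e-10

    def test_pressure_monotone_root_to_leaf(self):
        tree = build_strahler_tree(4, ARTERIAL_MORPHOMETRY, 21, "arterial")
        root = tree.metadata["root_node"]
        leaves = [n.id for n in tree.nodes.values()
                  if tree.degree(n.id) == 1 and n.id != root]
        bcs = {root: 1064.0}
        bcs.update({leaf: 199.5 for leaf in leaves})
        sol = solve_pressure(tree, bcs=bcs)
        stack = [(root, None)]
        while stack:
            node, in_edge = stack.pop()
            for e in tree.incident_edges(node):
                if e.id == in_edge:
                    continue
                child = tree.other_end(e, node)
                assert sol.pressures[child] <= sol.pressures[node] + 1e-9
                stack.append((child, e.id))

    def test_permutation_equivalence(self):
        tree = build_strahler_tree(3, ARTERIAL_MORPHOMETRY, 5, "arterial")
        root = tree.metadata["root_node"]
        leaves = [n.id for n in tree.nodes.values()
                  if tree.degree(n.id) == 1 and n.id != root]
        bcs = {root: 1064.0, **{l: 199.5 for l in leaves}}
        sol = solve_pressure(tree, bcs=bcs)

        perm = {nid: 1000 - nid for nid in tree.nodes}
        relabeled = VascularGraph()
        for nid, n in sorted(tree.nodes.items()):
            relabeled.add_node(GraphNode(id=perm[nid], position=n.position,
                                         kind=n.kind))
        for eid, e in tree.edges.items():
            relabeled.add_edge(VesselSegment(
                id=eid, node_a=perm[e.node_a], node_b=perm[e.node_b],
                diameter=e.diameter, length=e.length,
                strahler_order=e.strahler_order, vessel_class=e.vessel_class))
        sol2 = solve_pressure(relabeled,
                              bcs={perm[n]: p for n, p in bcs.items()})
        for nid in tree.nodes:
            assert sol2.pressures[perm[nid]] == pytest.approx(
                sol.pressures[nid], rel=1e-12)

    def test_no_dirichlet_rejected(self):
        with pytest.raises(ValueError, match="Dirichlet"):
            solve_pressure(two_node_tube(), bcs={})

    def test_gravity_hydrostatic_equilibrium(self):
        g = two_node_tube()
        g.nodes[0].z_offset = 0.0
        g.nodes[1].z_offset = -0.01  # 1 cm below entry
        blood = BloodProperties()
        dz_head = blood.mass_density * 9.81 * 0.01
        sol = solve_pressure(
            g, blood, bcs={0: 0.0, 1: dz_head},
            gravity=GravityModel(enabled=True))
        assert abs(sol.edge_flows[0]) <= 1e-20

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(dp=st.floats(1.0, 1e4), d=st.floats(5e-6, 1e-3),
           l=st.floats(1e-5, 1e-2))
    def test_property_flow_linear_in_pressure(self, dp, d, l):
        g = two_node_tube(d, l)
        sol1 = solve_pressure(g, CONST_MU_BLOOD, bcs={0: dp, 1: 0.0})
        sol2 = solve_pressure(g, CONST_MU_BLOOD, bcs={0: 2 * dp, 1: 0.0})
        assert sol2.edge_flows[0] == pytest.approx(2 * sol1.edge_flows[0],
                                                   rel=1e-12)
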