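"""Vascular graph model: Strahler ordering, tree generation, graph I/O."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungflow.network import (
    ARTERIAL_MORPHOMETRY,
    VENOUS_MORPHOMETRY,
    GraphError,
    GraphNode,
    NodeKind,
    VascularGraph,
    VesselClass,
    VesselSegment,
    assign_strahler_orders,
    build_coupled_example,
    build_strahler_tree,
    read_graph,
    side_subgraph,
    write_graph,
)


def chain_graph(n_edges, diameter=1e-5, length=1e-4):
    g = VascularGraph()
    for i in range(n_edges + 1):
        g.add_node(GraphNode(id=i))
    for i in range(n_edges):
        g.add_edge(VesselSegment(id=i, node_a=i, node_b=i + 1,
                                 diameter=diameter, length=length))
    return g


class TestStrahlerOrdering:
    def test_two_equal_children_increment_parent(self):
        # nodes: 0 root -- 1 junction -- leaves 2, 3
        g = VascularGraph()
        for i in range(4):
            g.add_node(GraphNode(id=i))
        g.add_edge(VesselSegment(id=0, node_a=0, node_b=1, diameter=1e-5, length=1e-4))
        g.add_edge(VesselSegment(id=1, node_a=1, node_b=2, diameter=1e-5, length=1e-4))
        g.add_edge(VesselSegment(id=2, node_a=1, node_b=3, diameter=1e-5, length=1e-4))
        _, eo = assign_strahler_orders(g, root=0)
        assert eo[1] == eo[2] == 1
        assert eo[0] == 2

    def test_unequal_children_keep_max_order(self):
        # an order-3 branch meeting an order-1 branch stays order 3
        g = VascularGraph()
        for i in range(10):
            g.add_node(GraphNode(id=i))
        edges = [
            (0, 1),  # trunk (to be order 3)
            (1, 2),  # order-1 side branch (leaf)
            (1, 3),  # order-3 subtree root
            (3, 4), (3, 5),  # two order-2 children
            (4, 6), (4, 7),  # leaves
            (5, 8), (5, 9),  # leaves
        ]
        for k, (a, b) in enumerate(edges):
            g.add_edge(VesselSegment(id=k, node_a=a, node_b=b,
                                     diameter=1e-5, length=1e-4))
        _, eo = assign_strahler_orders(g, root=0)
        assert eo[2] == 3  # (2,2) -> 3
        assert eo[1] == 1
        assert eo[0] == 3  # 3 meets 1 -> stays 3

    def test_single_edge_is_order_one(self):
        g = chain_graph(1)
        _, eo = assign_strahler_orders(g, root=0)
        assert eo == {0: 1}

    def test_cycle_rejected(self):
        g = chain_graph(2)
        g.add_edge(VesselSegment(id=99, node_a=2, node_b=0,
                                 diameter=1e-5, length=1e-4))
        with pytest.raises(GraphError, match="cycle"):
            assign_strahler_orders(g, root=0)

    def test_disconnected_rejected(self):
        g = chain_graph(1)
        g.add_node(GraphNode(id=50))
        g.add_node(GraphNode(id=51))
        g.add_edge(VesselSegment(id=7, node_a=50, node_b=51,
                                 diameter=1e-5, length=1e-4))
        with pytest.raises(GraphError, match="connected"):
            assign_strahler_orders(g, root=0)


class TestBuildStrahlerTree:
    def test_default_arterial_tree_has_21_terminals(self):
        tree = build_strahler_tree(4, ARTERIAL_MORPHOMETRY, 21, "arterial")
        root = tree.metadata["root_node"]
        _, eo = assign_strahler_orders(tree, root)
        assert sum(1 for o in eo.values() if o == 1) == 21

    def test_order4_edge_carries_table_geometry(self):
        tree = build_strahler_tree(4, ARTERIAL_MORPHOMETRY, 21, "arterial")
        order4 = [e for e in tree.edges.values() if e.strahler_order == 4]
        assert order4
        for e in order4:
            assert e.diameter == pytest.approx(0.054e-3)
            assert e.length == pytest.approx(0.44e-3)

    def test_generation_labels_match_relabeling(self):
        tree = build_strahler_tree(4, VENOUS_MORPHOMETRY, 21, "venous")
        _, eo = assign_strahler_orders(tree, tree.metadata["root_node"])
        for eid, order in eo.items():
            assert tree.edges[eid].strahler_order == order

    def test_balanced_power_of_two_tree(self):
        tree = build_strahler_tree(4, ARTERIAL_MORPHOMETRY, 8, "arterial")
        # perfectly balanced: every order-k vessel splits into two order-(k-1)
        from collections import Counter

        counts = Counter(e.strahler_order for e in tree.edges.values())
        assert counts == {4: 1, 3: 2, 2: 4, 1: 8}

    def test_orders_non_increasing_toward_leaves(self):
        tree = build_strahler_tree(4, ARTERIAL_MORPHOMETRY, 21, "arterial")
        root = tree.metadata["root_node"]
        stack = [(root, None, 10**9)]
        while stack:
            node, in_edge, parent_order = stack.pop()
            for e in tree.incident_edges(node):
                if e.id == in_edge:
                    continue
                assert e.strahler_order <= parent_order
                stack.append((tree.other_end(e, node), e.id, e.strahler_order))

    def test_infeasible_leaf_count_rejected(self):
        with pytest.raises(GraphError, match="at least 8"):
            build_strahler_tree(4, ARTERIAL_MORPHOMETRY, 7, "arterial")

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(root_order=st.integers(2, 5), extra=st.integers(0, 40))
    def test_property_leaf_count_and_idempotence(self, root_order, extra):
        n_leaves = 2 ** (root_order - 1) + extra
        tree = build_strahler_tree(
            root_order, ARTERIAL_MORPHOMETRY, n_leaves, "arterial")
        root = tree.metadata["root_node"]
        _, eo = assign_strahler_orders(tree, root)
        assert sum(1 for o in eo.values() if o == 1) == n_leaves
        for eid, order in eo.items():
            assert tree.edges[eid].strahler_order == order


class TestCoupledExample:
    def test_default_counts(self, example_graph):
        ups = example_graph.upscaled_nodes
        assert len(ups) == 21
        assert sum(1 for n in ups if n.kind is NodeKind.UPSCALED_TUMOR) == 3

    def test_upscaled_nodes_bridge_arterial_and_venous_sides(self, example_graph):
        for n in example_graph.upscaled_nodes:
            edges = example_graph.incident_edges(n.id)
            assert len(edges) == 2
            assert all(e.vessel_class is VesselClass.UPSCALED_EDGE for e in edges)

    def test_single_alveolus_scenario(self):
        g = build_coupled_example(n_alveoli=1, tumor_ids=set())
        assert len(g.upscaled_nodes) == 1
        assert len(g.edges) == 4  # arteriole, venule, two upscaled edges
        g.validate()

    def test_no_tumors_identical_structure(self, example_graph):
        g = build_coupled_example(tumor_ids=set())
        assert len(g.nodes) == len(example_graph.nodes)
        assert len(g.edges) == len(example_graph.edges)
        assert all(n.kind is NodeKind.UPSCALED_HEALTHY
                   for n in g.upscaled_nodes)
        for eid, e in g.edges.items():
            ref = example_graph.edges[eid]
            assert (e.node_a, e.node_b, e.diameter, e.length) == (
                ref.node_a, ref.node_b, ref.diameter, ref.length)

    def test_out_of_range_tumor_ids_rejected(self):
        with pytest.raises(GraphError, match="tumor_ids"):
            build_coupled_example(n_alveoli=5, tumor_ids={7})

    def test_arterial_subgraph_is_a_tree(self, example_graph):
        sub = side_subgraph(example_graph, "arterial")
        assert len(sub.edges) == len(sub.nodes) - 1
        _, eo = assign_strahler_orders(sub, sub.metadata["root_node"])
        assert max(eo.values()) == 4


class TestGraphIO:
    def test_json_round_trip_identity(self, example_graph, tmp_path):
        path = tmp_path / "graph.json"
        write_graph(example_graph, path, "json")
        back = read_graph(path, "json")
        assert back == example_graph

    def test_missing_diameter_names_edge(self, tmp_path):
        import json

        path = tmp_path / "graph.json"
        write_graph(chain_graph(1), path, "json")
        doc = json.loads(path.read_text())
        del doc["edges"][0]["diameter"]
        path.write_text(json.dumps(doc))
        with pytest.raises(GraphError, match="diameter"):
            read_graph(path, "json")

    def test_unit_mismatch_rejected(self, tmp_path):
        import json

        path = tmp_path / "graph.json"
        write_graph(chain_graph(1), path, "json")
        doc = json.loads(path.read_text())
        doc["units"]["length"] = "mm"
        path.write_text(json.dumps(doc))
        with pytest.raises(GraphError, match="units.length"):
            read_graph(path, "json")

    def test_graphml_preserves_node_kind(self, example_graph, tmp_path):
        path = tmp_path / "graph.graphml"
        write_graph(example_graph, path, "graphml")
        back = read_graph(path, "graphml")
        assert back.nodes.keys() == example_graph.nodes.keys()
        for nid, node in example_graph.nodes.items():
            assert back.nodes[nid].kind is node.kind
        assert len(back.edges) == len(example_graph.edges)

    def test_duplicate_edge_rejected(self):
        g = chain_graph(1)
        with pytest.raises(GraphError, match="duplicate"):
            g.add_edge(VesselSegment(id=5, node_a=1, node_b=0,
                                     diameter=1e-5, length=1e-4))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(GraphError):
            VesselSegment(id=0, node_a=0, node_b=1, diameter=-1e-5, length=1e-4)
        with pytest.raises(GraphError):
            VesselSegment(id=0, node_a=0, node_b=0, diameter=1e-5, length=1e-4)
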