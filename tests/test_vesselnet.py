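import math
import warnings

import numpy as np
import pytest

from angiocam import (
    DisconnectedNetworkWarning,
    GraphValidationError,
    InvalidROIError,
    RingROI,
    Segment,
    VesselGraph,
    assign_branch_degrees,
    canonicalize,
    compute_metrics,
    count_junctions,
    hierarchy_ratio,
    length_metrics,
    vessel_density,
)

from _reference import brute_metrics, insert_degree2_nodes, random_vessel_tree


def _chain_graph(lengths):
    """Open chain of straight segments along the x axis."""
    xs = np.concatenate([[0.0], np.cumsum(lengths)])
    nodes = {i: (float(x), 0.0) for i, x in enumerate(xs)}
    edges = [
        Segment.make(id=i, u=i, v=i + 1, points=(nodes[i], nodes[i + 1]))
        for i in range(len(lengths))
    ]
    return VesselGraph(nodes=nodes, edges=edges, roots=(0,))


class TestRingROI:
    def test_area_matches_annulus_formula(self):
        roi = RingROI(center=(1.0, -2.0), inner_radius=500.0, outer_radius=2000.0)
        expected = math.pi * (2000.0**2 - 500.0**2) / 1e6
        assert math.isclose(roi.area_mm2, expected, rel_tol=1e-9)

    @pytest.mark.parametrize("inner,outer", [(100.0, 100.0), (200.0, 100.0), (-1.0, 50.0)])
    def test_rejects_degenerate_geometry(self, inner, outer):
        with pytest.raises(InvalidROIError):
            RingROI(inner_radius=inner, outer_radius=outer)


class TestCanonicalize:
    def test_chain_merges_and_conserves_length(self):
        g = canonicalize(_chain_graph([3.0, 4.0]))
        assert len(g.edges) == 1
        assert math.isclose(g.edges[0].length, 7.0, rel_tol=1e-12)
        assert set(g.nodes) == {0, 2}
        assert g.roots == (g.edges[0].id,)

    def test_idempotent_on_canonical_graph(self, y_graph):
        once = canonicalize(y_graph)
        twice = canonicalize(once)
        assert [e.id for e in once.edges] == [e.id for e in twice.edges]
        assert once.nodes == twice.nodes
        assert all(
            a.points == b.points for a, b in zip(once.edges, twice.edges)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_degree2_insertion_invisible_to_metrics(self, seed, unit_roi):
        rng = np.random.default_rng(seed)
        tree = random_vessel_tree(rng, n_branch_events=10, n_roots=2, bounding=500.0)
        split = insert_degree2_nodes(tree, rng, k=5)
        m0 = compute_metrics(tree, unit_roi)
        m1 = compute_metrics(split, unit_roi)
        assert m1.junction_count == m0.junction_count
        assert m1.segment_count == m0.segment_count
        assert math.isclose(m1.total_length, m0.total_length, rel_tol=1e-9)
        assert m1.branch_counts == m0.branch_counts

    def test_rejects_self_loop(self):
        nodes = {0: (0.0, 0.0), 1: (10.0, 0.0)}
        loop = Segment(id=0, u=0, v=0,
                       points=((0.0, 0.0), (10.0, 0.0), (0.0, 0.0)),
                       length=20.0)
        g = VesselGraph(nodes=nodes, edges=[loop])
        with pytest.raises(GraphValidationError):
            canonicalize(g)

    def test_empty_graph(self):
        g = canonicalize(VesselGraph(nodes={}, edges=[]))
        assert g.nodes == {} and g.edges == []


class TestJunctionsAndLengths:
    def test_single_segment_has_no_junction(self):
        assert count_junctions(_chain_graph([5.0])) == 0

    def test_y_graph_has_one_junction(self, y_graph):
        assert count_junctions(y_graph) == 1

    def test_binary_tree_junctions(self, rng, unit_roi):
        # 7 segments: root + 3 branchings -> 3 nodes of degree 3
        tree = random_vessel_tree(rng, n_branch_events=3, n_roots=1, bounding=500.0)
        assert len(tree.edges) == 7
        assert count_junctions(tree) == 3

    def test_length_metrics_values(self):
        nodes = {0: (0.0, 0.0), 1: (100.0, 0.0), 2: (0.0, 100.0), 3: (0.0, -100.0),
                 4: (300.0, 0.0), 5: (0.0, 300.0)}
        edges = [
            Segment.make(id=0, u=0, v=1, points=(nodes[0], nodes[1])),
            Segment.make(id=1, u=2, v=4, points=(nodes[2], nodes[4])),  # ~360.6
        ]
        # use exact lengths 100, 200, 300 instead
        nodes = {0: (0.0, 0.0), 1: (100.0, 0.0), 2: (0.0, 10.0), 3: (200.0, 10.0),
                 4: (0.0, 20.0), 5: (300.0, 20.0)}
        edges = [
            Segment.make(id=0, u=0, v=1, points=(nodes[0], nodes[1])),
            Segment.make(id=1, u=2, v=3, points=(nodes[2], nodes[3])),
            Segment.make(id=2, u=4, v=5, points=(nodes[4], nodes[5])),
        ]
        g = VesselGraph(nodes=nodes, edges=edges)
        total, n, mean = length_metrics(g)
        assert (total, n) == (600.0, 3)
        assert math.isclose(mean, 200.0, rel_tol=1e-12)

    def test_length_metrics_empty(self):
        total, n, mean = length_metrics(VesselGraph(nodes={}, edges=[]))
        assert (total, n) == (0.0, 0)
        assert math.isnan(mean)


class TestDensity:
    def test_known_ratio(self):
        roi = RingROI(outer_radius=math.sqrt(2.0e6 / math.pi))  # 2 mm²
        g = _chain_graph([1000.0])
        assert math.isclose(vessel_density(g, roi), 500.0, rel_tol=1e-9)

    def test_empty_graph_zero(self, unit_roi):
        assert vessel_density(VesselGraph(nodes={}, edges=[]), unit_roi) == 0.0

    def test_homogeneous_in_length(self, rng, unit_roi):
        g = random_vessel_tree(rng, n_branch_events=6, bounding=500.0)
        doubled = VesselGraph(
            nodes={k: (2 * x, 2 * y) for k, (x, y) in g.nodes.items()},
            edges=[
                Segment.make(id=e.id, u=e.u, v=e.v,
                             points=[(2 * x, 2 * y) for x, y in e.points])
                for e in g.edges
            ],
            roots=g.roots,
        )
        assert math.isclose(
            vessel_density(doubled, unit_roi), 2 * vessel_density(g, unit_roi),
            rel_tol=1e-9,
        )


class TestBranchDegrees:
    def test_root_split(self, y_graph):
        deg = assign_branch_degrees(y_graph)
        assert deg == {0: 1, 1: 2, 2: 2}

    def test_linear_chain_caps_at_four(self):
        g = _chain_graph([10.0] * 6)
        deg = assign_branch_degrees(g)
        assert [deg[i] for i in range(6)] == [1, 2, 3, 4, 4, 4]

    def test_balanced_tree_matches_generation_depth(self, unit_roi):
        # depth-5 balanced binary tree built by hand; degree = min(depth, 4)
        nodes = {0: (0.0, 0.0)}
        edges = []
        frontier = [(0, 0.0, 0.0, 0.0)]  # node, x, y, direction
        next_node, next_edge = 1, 0
        expected = {}
        for depth in range(1, 6):
            new_frontier = []
            for node, x, y, d in frontier:
                for sign in (+1, -1):
                    dd = d + sign * 0.5 / depth
                    nx_, ny_ = x + 50 * math.cos(dd), y + 50 * math.sin(dd)
                    nodes[next_node] = (nx_, ny_)
                    edges.append(
                        Segment.make(id=next_edge, u=node, v=next_node,
                                     points=((x, y), (nx_, ny_)))
                    )
                    expected[next_edge] = min(depth, 4)
                    new_frontier.append((next_node, nx_, ny_, dd))
                    next_node += 1
                    next_edge += 1
            frontier = new_frontier
        g = VesselGraph(nodes=nodes, edges=edges, roots=(0, 1))
        assert assign_branch_degrees(g) == expected

    def test_unreachable_component_warns_and_gets_degree_four(self, y_graph):
        nodes = dict(y_graph.nodes)
        nodes["x"] = (1000.0, 1000.0)
        nodes["y"] = (1100.0, 1000.0)
        edges = list(y_graph.edges) + [
            Segment.make(id=9, u="x", v="y", points=(nodes["x"], nodes["y"]))
        ]
        g = VesselGraph(nodes=nodes, edges=edges, roots=(0,))
        with pytest.warns(DisconnectedNetworkWarning):
            deg = assign_branch_degrees(g)
        assert deg[9] == 4

    def test_fallback_roots_boundary_then_longest(self, unit_roi):
        r = unit_roi.outer_radius
        nodes = {0: (r, 0.0), 1: (0.0, 0.0), 2: (-50.0, 50.0), 3: (-50.0, -50.0)}
        edges = [
            Segment.make(id=0, u=0, v=1, points=(nodes[0], nodes[1])),
            Segment.make(id=1, u=1, v=2, points=(nodes[1], nodes[2])),
            Segment.make(id=2, u=1, v=3, points=(nodes[1], nodes[3])),
        ]
        g = VesselGraph(nodes=nodes, edges=edges)  # no designated roots
        deg = assign_branch_degrees(g, unit_roi)
        assert deg[0] == 1 and deg[1] == deg[2] == 2
        # without an ROI the longest segment becomes the root
        deg2 = assign_branch_degrees(g)
        longest = max(edges, key=lambda e: e.length).id
        assert deg2[longest] == 1


class TestHierarchyRatio:
    @pytest.mark.parametrize(
        "counts,expected",
        [((2, 4, 6, 8), 14 / 6), ((1, 1, 0, 0), 0.0)],
    )
    def test_values(self, counts, expected):
        assert math.isclose(hierarchy_ratio(counts), expected, rel_tol=1e-12)

    def test_zero_denominator_is_nan(self):
        assert math.isnan(hierarchy_ratio((0, 0, 3, 3)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hierarchy_ratio((1, -1, 0, 0))


class TestComputeMetrics:
    def test_y_graph_worked_example(self, y_graph, unit_roi):
        m = compute_metrics(y_graph, unit_roi)
        assert m.junction_count == 1
        assert m.segment_count == 3
        assert math.isclose(m.total_length, 200.0, rel_tol=1e-9)
        assert math.isclose(m.mean_length, 200.0 / 3.0, rel_tol=1e-9)
        assert math.isclose(m.density, 200.0, rel_tol=1e-9)
        assert m.branch_counts == (1, 2, 0, 0)
        assert m.hierarchy_ratio == 0.0

    def test_empty_graph(self, unit_roi):
        m = compute_metrics(VesselGraph(nodes={}, edges=[]), unit_roi)
        assert m.junction_count == m.segment_count == 0
        assert m.total_length == 0.0 and m.density == 0.0
        assert math.isnan(m.mean_length) and math.isnan(m.hierarchy_ratio)
        assert m.branch_counts == (0, 0, 0, 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_bruteforce_on_random_trees(self, seed, unit_roi):
        rng = np.random.default_rng(1000 + seed)
        g = random_vessel_tree(rng, n_branch_events=int(rng.integers(3, 15)),
                               n_roots=int(rng.integers(1, 4)), bounding=500.0)
        if rng.random() < 0.5:
            g = insert_degree2_nodes(g, rng, k=int(rng.integers(1, 5)))
        m = compute_metrics(g, unit_roi)
        ref = brute_metrics(g, unit_roi)
        assert m.junction_count == ref["junction_count"]
        assert m.segment_count == ref["segment_count"]
        assert math.isclose(m.total_length, ref["total_length"], rel_tol=1e-9)
        assert math.isclose(m.density, ref["density"], rel_tol=1e-9)
        assert m.branch_counts == ref["branch_counts"]
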