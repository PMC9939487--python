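"""Graph model, geometry primitives and serialization."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cowlabel import GraphNode, VesselGraph, VesselSegment, read_graph, write_graph
from cowlabel.vessel_graph import (
    DegenerateGeometryError,
    GraphIntegrityError,
    GraphSchemaError,
    ArteryId,
    BifurcationId,
    BIFURCATION_ARTERIES,
    graph_to_dict,
    neighbor_edges,
    read_graph_with_labels,
    transition_weight,
)
from conftest import build_graph, straight_segment


class TestVesselSegment:
    def test_arc_length_equals_sum_of_consecutive_distances(self):
        pts = np.array([[0, 0, 0], [3, 4, 0], [3, 4, 12]], float)
        seg = VesselSegment("e", ("a", "b"), pts, np.ones(3))
        assert seg.length == pytest.approx(5.0 + 12.0, rel=1e-9)

    def test_mean_radius_is_arithmetic_mean(self):
        seg = straight_segment("e", "a", "b", (0, 0, 0), (10, 0, 0), n=4)
        seg.radii = np.array([1.0, 2.0, 3.0, 6.0])
        assert seg.mean_radius == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "points,radii",
        [
            ([[0, 0, 0]], [1.0]),                      # fewer than 2 points
            ([[0, 0, 0], [1, 0, 0]], [1.0]),           # radii count mismatch
            ([[0, 0, 0], [1, 0, 0]], [1.0, 0.0]),      # non-positive radius
        ],
    )
    def test_invalid_segments_rejected(self, points, radii):
        with pytest.raises(GraphSchemaError):
            VesselSegment("e", ("a", "b"), np.asarray(points, float), radii)

    def test_length_bounds_endpoint_distance(self):
        # polyline triangle inequality
        rng = np.random.default_rng(5)
        for _ in range(50):
            pts = rng.uniform(-10, 10, size=(6, 3))
            seg = VesselSegment("e", ("a", "b"), pts, np.ones(6))
            assert seg.length >= np.linalg.norm(pts[-1] - pts[0]) - 1e-12


class TestGraphIntegrity:
    def test_dangling_endpoint_rejected(self):
        nodes = [GraphNode("a", np.zeros(3))]
        seg = straight_segment("e", "a", "missing", (0, 0, 0), (1, 0, 0))
        with pytest.raises(GraphIntegrityError):
            VesselGraph.from_parts(nodes, [seg])

    def test_endpoint_position_mismatch_rejected(self):
        nodes = [GraphNode("a", np.zeros(3)), GraphNode("b", np.array([9.0, 0, 0]))]
        seg = straight_segment("e", "a", "b", (0, 0, 0), (1, 0, 0))
        with pytest.raises(GraphIntegrityError):
            VesselGraph.from_parts(nodes, [seg])

    def test_parallel_edges_permitted(self):
        g = build_graph(
            {"a": np.zeros(3), "b": np.array([5.0, 0, 0])},
            [("e1", "a", "b"), ("e2", "a", "b")],
        )
        assert set(g.incident("a")) == {"e1", "e2"}


class TestNeighborEdges:
    def test_linear_chain(self):
        g = build_graph(
            {"A": np.zeros(3), "B": np.array([5.0, 0, 0]), "C": np.array([10.0, 0, 0])},
            [("e1", "A", "B"), ("e2", "B", "C")],
        )
        assert [e.id for e in neighbor_edges(g, g.edges["e1"], "A")] == ["e2"]

    def test_isolated_edge_has_no_neighbors(self):
        g = build_graph(
            {"A": np.zeros(3), "B": np.array([5.0, 0, 0])}, [("e1", "A", "B")]
        )
        assert neighbor_edges(g, g.edges["e1"], "A") == []

    def test_star_returns_all_edges_at_far_node(self):
        g = build_graph(
            {
                "A": np.zeros(3),
                "B": np.array([5.0, 0, 0]),
                "C": np.array([5.0, 5, 0]),
                "D": np.array([5.0, -5, 0]),
            },
            [("e1", "A", "B"), ("e2", "B", "C"), ("e3", "B", "D")],
        )
        assert {e.id for e in neighbor_edges(g, g.edges["e1"], "A")} == {"e2", "e3"}

    def test_node_must_be_an_endpoint(self):
        g = build_graph(
            {"A": np.zeros(3), "B": np.array([5.0, 0, 0]), "C": np.array([10.0, 0, 0])},
            [("e1", "A", "B"), ("e2", "B", "C")],
        )
        with pytest.raises(ValueError):
            neighbor_edges(g, g.edges["e1"], "C")


class TestTransitionWeight:
    @pytest.fixture()
    def cross(self):
        # four straight edges meeting at the origin
        return build_graph(
            {
                "O": np.zeros(3),
                "E": np.array([10.0, 0, 0]),
                "W": np.array([-10.0, 0, 0]),
                "N": np.array([0.0, 10, 0]),
            },
            [("east", "O", "E"), ("west", "O", "W"), ("north", "O", "N")],
        )

    def test_collinear_continuation_is_max_weight(self, cross):
        w = transition_weight(cross, cross.edges["west"], cross.edges["east"], "O")
        assert w == pytest.approx(1.0)

    def test_reversal_is_min_weight(self, cross):
        # entering O along 'east' and leaving through the same direction
        g = build_graph(
            {"O": np.zeros(3), "E": np.array([10.0, 0, 0]), "E2": np.array([10.0, 0.01, 0])},
            [("in", "E", "O"), ("back", "O", "E2")],
        )
        w = transition_weight(g, g.edges["in"], g.edges["back"], "O")
        assert w == pytest.approx(0.2, abs=1e-4)

    def test_right_angle_is_midpoint_of_range(self, cross):
        w = transition_weight(cross, cross.edges["west"], cross.edges["north"], "O")
        assert w == pytest.approx(0.6)

    def test_symmetric_under_direction_reversal(self, cross):
        a = transition_weight(cross, cross.edges["west"], cross.edges["north"], "O")
        b = transition_weight(cross, cross.edges["north"], cross.edges["west"], "O")
        assert a == pytest.approx(b)

    def test_degenerate_centerline_raises(self):
        pts = np.zeros((3, 3))
        seg = VesselSegment("z", ("a", "b"), pts, np.ones(3))
        with pytest.raises(DegenerateGeometryError):
            seg.direction_from("a")


class TestSerialization:
    def test_round_trip_identity(self, tmp_path):
        g = build_graph(
            {"a": np.array([0.1, 0.2, 0.3]), "b": np.array([5.0, -1, 2])},
            [("e", "a", "b", 1.5)],
        )
        path = tmp_path / "g.json"
        write_graph(g, path, labels={"e": "ICA_L"})
        g2, labels = read_graph_with_labels(path)
        assert set(g2.nodes) == set(g.nodes)
        assert set(g2.edges) == set(g.edges)
        np.testing.assert_allclose(g2.edges["e"].points, g.edges["e"].points, atol=1e-9)
        np.testing.assert_allclose(g2.edges["e"].radii, g.edges["e"].radii, atol=1e-9)
        assert labels == {"e": "ICA_L"}

    def test_unknown_node_id_is_integrity_error(self, tmp_path):
        doc = {
            "nodes": [{"id": "a", "pos": [0, 0, 0]}],
            "edges": [
                {
                    "id": "e",
                    "nodes": ["a", "ghost"],
                    "points": [[0, 0, 0], [1, 0, 0]],
                    "radii": [1, 1],
                }
            ],
        }
        p = tmp_path / "g.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(GraphIntegrityError, match="ghost"):
            read_graph(p)

    def test_missing_field_names_the_offender(self, tmp_path):
        doc = {"nodes": [{"id": "a"}], "edges": []}
        p = tmp_path / "g.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(GraphSchemaError, match="pos"):
            read_graph(p)

    def test_phantom_round_trip_is_bit_stable(self, tmp_path, clean_phantom):
        path = tmp_path / "ph.json"
        write_graph(clean_phantom.graph, path)
        g2 = read_graph(path)
        for eid, e in clean_phantom.graph.edges.items():
            assert g2.edges[eid].length == e.length


class TestAnatomy:
    def test_every_bifurcation_maps_to_three_arteries(self):
        for bif in BifurcationId:
            assert len(BIFURCATION_ARTERIES[bif]) == 3

    def test_inner_arteries_appear_in_exactly_two_bifurcations(self):
        counts = {a: 0 for a in ArteryId}
        for arteries in BIFURCATION_ARTERIES.values():
            for a in arteries:
                counts[a] += 1
        for artery in (ArteryId.ACOMM, ArteryId.ACA1_L, ArteryId.ACA1_R, ArteryId.BASILAR):
            assert counts[artery] == 2
        assert all(c == 1 for a, c in counts.items() if a.role.value != "inner")


@settings(max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(-50, 50, allow_nan=False),
            st.floats(-50, 50, allow_nan=False),
            st.floats(-50, 50, allow_nan=False),
        ),
        min_size=2,
        max_size=12,
    )
)
def test_polyline_length_at_least_chord(coords):
    pts = np.asarray(coords, float)
    seg = VesselSegment("e", ("a", "b"), pts, np.ones(len(pts)))
    assert seg.length >= np.linalg.norm(pts[-1] - pts[0]) - 1e-9
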