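"""Edge cost, recursive path score and bifurcation matching."""

import math

import numpy as np
import pytest

from cowlabel import (
    ArteryId,
    BifurcationId,
    CandidateGraph,
    DistanceScore,
    icp_align,
    build_candidates,
)
from cowlabel.bifurcation_matching import (
    PathRecursionError,
    edge_cost,
    enumerate_configurations,
    match_all_bifurcations,
    match_bifurcation,
    path_score,
)
from cowlabel.config import CostParams
from cowlabel.synthetic_cow import PhantomSpec, generate
from cowlabel.vessel_graph import transition_weight
from conftest import (
    build_graph,
    enumerate_paths_score,
    random_candidate_graph,
    straight_segment,
)

PARAMS = CostParams()


def _score(value, eid="e"):
    return DistanceScore(
        artery=ArteryId.ICA_L, edge_id=eid, value=value,
        point_distances=np.array([value]),
    )


def _candidate(graph, values: dict):
    return CandidateGraph(
        artery=ArteryId.ICA_L,
        scores={eid: _score(v, eid) for eid, v in values.items()},
    )


class TestEdgeCost:
    def test_worked_example(self):
        # w=[1], l=10 mm, d=5 mm, r=2 mm -> (1+1)/2 * 10/5 * 1.2 = 2.4
        seg = straight_segment("e", "a", "b", (0, 0, 0), (10, 0, 0), radius=2.0)
        cost = edge_cost(seg, [1.0], _score(5.0), PARAMS)
        assert cost == pytest.approx(2.4, abs=1e-12)

    def test_zero_delta_removes_radius_influence(self):
        seg = straight_segment("e", "a", "b", (0, 0, 0), (10, 0, 0), radius=2.0)
        cost = edge_cost(seg, [1.0], _score(5.0), CostParams(delta=0.0))
        assert cost == pytest.approx(2.0, abs=1e-12)

    def test_sharper_turns_lower_the_cost(self):
        seg = straight_segment("e", "a", "b", (0, 0, 0), (10, 0, 0))
        smooth = edge_cost(seg, [1.0, 1.0], _score(5.0), PARAMS)
        sharp = edge_cost(seg, [1.0, 0.2], _score(5.0), PARAMS)
        assert sharp < smooth

    def test_distance_floor_prevents_division_by_zero(self):
        seg = straight_segment("e", "a", "b", (0, 0, 0), (10, 0, 0), radius=2.0)
        cost = edge_cost(seg, [1.0], _score(0.0), PARAMS)
        assert cost == pytest.approx(1.0 * (10.0 / 0.1) * 1.2, abs=1e-9)

    def test_infinite_score_is_an_error(self):
        seg = straight_segment("e", "a", "b", (0, 0, 0), (10, 0, 0))
        with pytest.raises(ValueError):
            edge_cost(seg, [1.0], _score(math.inf), PARAMS)

    def test_empty_weight_sequence_is_an_error(self):
        seg = straight_segment("e", "a", "b", (0, 0, 0), (10, 0, 0))
        with pytest.raises(ValueError):
            edge_cost(seg, [], _score(5.0), PARAMS)


class TestPathScore:
    def test_single_edge_base_case(self):
        g = build_graph(
            {"a": np.zeros(3), "b": np.array([10.0, 0, 0])}, [("e", "a", "b")]
        )
        cand = _candidate(g, {"e": 5.0})
        score, path = path_score(g, g.edges["e"], "a", cand, [1.0], PARAMS)
        assert score == edge_cost(g.edges["e"], [1.0], cand.scores["e"], PARAMS)
        assert path == ["e"]

    def test_two_edge_chain_unrolls_once(self):
        g = build_graph(
            {"a": np.zeros(3), "b": np.array([10.0, 0, 0]), "c": np.array([20.0, 0, 0])},
            [("e1", "a", "b"), ("e2", "b", "c")],
        )
        cand = _candidate(g, {"e1": 5.0, "e2": 4.0})
        w = transition_weight(g, g.edges["e1"], g.edges["e2"], "b")
        expected = edge_cost(g.edges["e1"], (1.0,), cand.scores["e1"], PARAMS) + edge_cost(
            g.edges["e2"], (1.0, w), cand.scores["e2"], PARAMS
        )
        score, path = path_score(g, g.edges["e1"], "a", cand, [1.0], PARAMS)
        assert score == expected
        assert path == ["e1", "e2"]

    def test_neighbor_outside_candidate_set_stops_recursion(self):
        g = build_graph(
            {"a": np.zeros(3), "b": np.array([10.0, 0, 0]), "c": np.array([20.0, 0, 0])},
            [("e1", "a", "b"), ("e2", "b", "c")],
        )
        cand = _candidate(g, {"e1": 5.0})
        score, path = path_score(g, g.edges["e1"], "a", cand, [1.0], PARAMS)
        assert path == ["e1"]

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        # a quick version of the deeper sweep in test_acceptance
        rng = np.random.default_rng(2024)
        for _ in range(60):
            graph, cand, node, edge = random_candidate_graph(rng, max_edges=9)
            score, path = path_score(graph, edge, node, cand, [1.0], PARAMS)
            oracle = enumerate_paths_score(graph, edge, node, cand, PARAMS)
            assert score == oracle  # exact, same floating-point expressions
            assert path[0] == edge.id and len(path) == len(set(path))

    def test_unreachable_edge_does_not_change_score(self):
        g = build_graph(
            {
                "a": np.zeros(3), "b": np.array([10.0, 0, 0]),
                "x": np.array([100.0, 0, 0]), "y": np.array([110.0, 0, 0]),
            },
            [("e1", "a", "b"), ("far", "x", "y")],
        )
        small = _candidate(g, {"e1": 5.0})
        bigger = _candidate(g, {"e1": 5.0, "far": 1.0})
        assert (
            path_score(g, g.edges["e1"], "a", small, [1.0], PARAMS)[0]
            == path_score(g, g.edges["e1"], "a", bigger, [1.0], PARAMS)[0]
        )

    def test_reachable_extension_never_decreases_score(self):
        g = build_graph(
            {"a": np.zeros(3), "b": np.array([10.0, 0, 0]), "c": np.array([20.0, 0, 0])},
            [("e1", "a", "b"), ("e2", "b", "c")],
        )
        without = _candidate(g, {"e1": 5.0})
        with_ext = _candidate(g, {"e1": 5.0, "e2": 4.0})
        assert (
            path_score(g, g.edges["e1"], "a", with_ext, [1.0], PARAMS)[0]
            >= path_score(g, g.edges["e1"], "a", without, [1.0], PARAMS)[0]
        )

    def test_recursion_guard_trips_on_loop_dense_graphs(self):
        # many parallel edges between two nodes: edge-simple paths can
        # alternate for a long time
        node_pos = {"a": np.zeros(3), "b": np.array([10.0, 0, 0])}
        edges = [(f"p{i}", "a", "b") for i in range(10)]
        g = build_graph(node_pos, edges)
        cand = _candidate(g, {eid: 5.0 for eid in g.edges})
        params = CostParams(max_path_edges=4)
        with pytest.raises(PathRecursionError):
            path_score(g, g.edges["p0"], "a", cand, [1.0], params)


class TestConfigurations:
    def test_degree_three_gives_six_configurations(self):
        arteries = (ArteryId.ICA_L, ArteryId.MCA_L, ArteryId.ACA1_L)
        assert len(enumerate_configurations(arteries, ["e1", "e2", "e3"])) == 6

    def test_degree_two_leaves_one_artery_unassigned(self):
        arteries = (ArteryId.ICA_L, ArteryId.MCA_L, ArteryId.ACA1_L)
        configs = enumerate_configurations(arteries, ["e1", "e2"])
        assert len(configs) == 6
        assert all(len(c) == 2 for c in configs)

    def test_degree_four_counts_permutations(self):
        arteries = (ArteryId.ICA_L, ArteryId.MCA_L, ArteryId.ACA1_L)
        assert len(enumerate_configurations(arteries, list("abcd"))) == 24


@pytest.fixture(scope="module")
def matched_phantom():
    ph = generate(PhantomSpec(seed=0))
    aligned = icp_align(ph.atlas, ph.graph).atlas
    cands = build_candidates(ph.graph, aligned)
    matches = match_all_bifurcations(ph.graph, aligned, cands, PARAMS)
    return ph, aligned, cands, matches


class TestMatchBifurcation:
    def test_clean_phantom_matches_all_true_nodes(self, matched_phantom):
        ph, _, _, matches = matched_phantom
        for bif in BifurcationId:
            assert matches[bif] is not None
            assert matches[bif].node == ph.truth.bifurcation_nodes[bif]

    def test_artery_paths_start_at_the_matched_node(self, matched_phantom):
        ph, _, _, matches = matched_phantom
        for match in matches.values():
            for path in match.artery_paths.values():
                if path:
                    assert match.node in ph.graph.edges[path[0]].nodes

    def test_matching_is_deterministic(self, matched_phantom):
        ph, aligned, cands, matches = matched_phantom
        again = match_all_bifurcations(ph.graph, aligned, cands, PARAMS)
        for bif in BifurcationId:
            assert again[bif].node == matches[bif].node
            assert again[bif].artery_paths == matches[bif].artery_paths

    def test_occluded_media_still_matched_at_true_node(self):
        ph = generate(PhantomSpec(seed=0, occlusions=[(ArteryId.MCA_L, 1.0)]))
        aligned = icp_align(ph.atlas, ph.graph).atlas
        cands = build_candidates(ph.graph, aligned)
        match = match_bifurcation(ph.graph, aligned, BifurcationId.MEDIA_L, cands, PARAMS)
        assert match is not None
        assert match.node == ph.truth.bifurcation_nodes[BifurcationId.MEDIA_L]
        assert match.artery_paths[ArteryId.MCA_L] == []
        assert match.artery_paths[ArteryId.ICA_L]
        assert match.artery_paths[ArteryId.ACA1_L]

    def test_no_candidates_means_unmatched(self):
        ph = generate(PhantomSpec(seed=0))
        far = build_graph(
            {"a": np.array([500.0, 0, 0]), "b": np.array([510.0, 0, 0]),
             "c": np.array([520.0, 0, 0])},
            [("e1", "a", "b"), ("e2", "b", "c")],
        )
        cands = build_candidates(far, ph.atlas)
        assert (
            match_bifurcation(far, ph.atlas, BifurcationId.MEDIA_L, cands, PARAMS)
            is None
        )
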