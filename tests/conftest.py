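"""Shared fixtures and builders for the cowlabel test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cowlabel import (
    ArteryId,
    CandidateGraph,
    DistanceScore,
    GraphNode,
    VesselGraph,
    VesselSegment,
)
from cowlabel.bifurcation_matching import edge_cost
from cowlabel.config import CostParams
from cowlabel.synthetic_cow import PhantomSpec, generate
from cowlabel.vessel_graph import neighbor_edges, transition_weight


def straight_segment(eid, a, b, pa, pb, radius=2.0, n=5):
    """Straight vessel segment between two points."""
    pts = np.linspace(np.asarray(pa, float), np.asarray(pb, float), n)
    return VesselSegment(id=eid, nodes=(a, b), points=pts, radii=np.full(n, radius))


def build_graph(node_pos: dict, edges: list) -> VesselGraph:
    """Toy graph from node positions and (eid, a, b[, radius]) tuples with
    straight centerlines."""
    nodes = [GraphNode(id=nid, position=pos) for nid, pos in node_pos.items()]
    segs = []
    for spec in edges:
        eid, a, b = spec[:3]
        radius = spec[3] if len(spec) > 3 else 2.0
        segs.append(
            straight_segment(eid, a, b, node_pos[a], node_pos[b], radius=radius)
        )
    return VesselGraph.from_parts(nodes, segs)


@pytest.fixture(scope="session")
def clean_phantom():
    return generate(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def noise_free_phantom():
    return generate(
        PhantomSpec(
            seed=0,
            landmark_rotation_deg=0.0,
            landmark_translation_mm=0.0,
            landmark_jitter_mm=0.0,
            centerline_noise_mm=0.0,
        )
    )


# ---------------------------------------------------------------------------
# random candidate graphs + independent path-score oracle
# ---------------------------------------------------------------------------


def random_candidate_graph(rng: np.random.Generator, max_edges: int = 12):
    """A small random geometric multigraph with random distance scores,
    posing as one artery's candidate graph. Returns (graph, candidate,
    start_node_id, start_edge)."""
    n_nodes = int(rng.integers(5, 9))
    pos = {f"n{i}": rng.uniform(-40, 40, size=3) for i in range(n_nodes)}
    node_ids = sorted(pos)
    edges = []
    # random spanning tree first so paths exist
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        edges.append((f"e{len(edges)}", node_ids[i], node_ids[j]))
    n_extra = int(rng.integers(0, max(1, max_edges - len(edges) + 1)))
    for _ in range(n_extra):
        if len(edges) >= max_edges:
            break
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        edges.append((f"e{len(edges)}", node_ids[int(i)], node_ids[int(j)]))
    graph = build_graph(pos, edges)
    scores = {
        eid: DistanceScore(
            artery=ArteryId.ICA_L,
            edge_id=eid,
            value=float(rng.uniform(0.5, 18.0)),
            point_distances=np.array([1.0]),
        )
        for eid in graph.edges
    }
    candidate = CandidateGraph(artery=ArteryId.ICA_L, scores=scores)
    start_eid = sorted(graph.edges)[int(rng.integers(0, len(graph.edges)))]
    start_node = graph.edges[start_eid].nodes[int(rng.integers(0, 2))]
    return graph, candidate, start_node, graph.edges[start_eid]


def enumerate_paths_score(
    graph: VesselGraph,
    edge: VesselSegment,
    node_id: str,
    candidate: CandidateGraph,
    params: CostParams,
) -> float:
    """Independent oracle: explicitly enumerate every edge-simple path
    starting at (node, edge) within the candidate set, score each path as
    the sum of its edge costs under cumulative transition weights, and
    return the maximum. Each path's sum is folded tail-first so the
    floating-point expression tree matches a recursive evaluation."""

    paths: list[list[tuple[VesselSegment, tuple[float, ...]]]] = []

    def collect(e: VesselSegment, v: str, used: frozenset, weights: tuple, acc: list):
        acc = acc + [(e, weights)]
        paths.append(acc)
        far = e.other_node(v)
        remaining = used | {e.id}
        for nb in neighbor_edges(graph, e, v):
            if nb.id in remaining or nb.id not in candidate:
                continue
            w = transition_weight(graph, e, nb, far)
            collect(nb, far, remaining, weights + (w,), acc)

    collect(edge, node_id, frozenset(), (1.0,), [])

    best = -math.inf
    for path in paths:
        # every enumerated path is maximal-prefix-closed; scoring all
        # prefixes too is redundant but harmless for the maximum
        total = 0.0
        for e, weights in reversed(path):
            total = edge_cost(e, weights, candidate.scores[e.id], params) + total
        best = max(best, total)
    return best
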