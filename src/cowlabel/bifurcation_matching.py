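"""Recursive path scoring and optimal bifurcation node selection.

The core idea: instead of matching arteries individually, each labeled
bifurcation is matched as a whole. For every candidate node, every
assignment of its incident edges to the bifurcation's three adjacent
arteries is scored by recursively maximizing a path score through that
artery's candidate sub-graph, and the node with the best average over the
three arteries wins. Because the average tolerates one silent artery, a
bifurcation can still be matched when a vessel is occluded (stroke) or was
missed by the segmentation.

The edge cost combines smoothness (transition weights w, both the most
recent weight and the cumulative product along the path), length l_e,
landmark distance d_a(e) and mean radius r_e:

    c_a(e, w) = (w_N + prod_i w_i) / 2 * l_e / d_a(e) * (1 + delta * r_e)

and the path score q_a maximizes the sum of edge costs over all edge-simple
continuations within the candidate edge set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Sequence

from .candidate_graphs import (
    CandidateGraph,
    DistanceScore,
    candidate_bifurcation_nodes,
)
from .config import CostParams
from .landmarks import LandmarkAtlas
from .vessel_graph import (
    ArteryId,
    BifurcationId,
    VesselGraph,
    VesselSegment,
    neighbor_edges,
    transition_weight,
)


class PathRecursionError(RuntimeError):
    """Path maximization exceeded the edge budget (pathological loops)."""


@dataclass(eq=False)
class BifurcationMatch:
    """Chosen node for one bifurcation plus the three optimal artery paths."""

    bifurcation: BifurcationId
    node: str
    #: per adjacent artery: ordered edge ids starting at ``node`` (may be empty)
    artery_paths: dict[ArteryId, list[str]]
    #: the maximal q value per adjacent artery (0 for unassigned arteries)
    artery_scores: dict[ArteryId, float]
    #: average of the three artery scores
    mean_score: float
    #: best match at the second-best node (used by the anterior 80 % rule)
    runner_up: "BifurcationMatch | None" = None


def edge_cost(
    edge: VesselSegment,
    weights: Sequence[float],
    score: DistanceScore,
    params: CostParams,
) -> float:
    """Cost of a single edge given the weights accumulated along the path."""
    if not weights:
        raise ValueError("weight sequence must be non-empty (starts at [1])")
    if not math.isfinite(score.value):
        raise ValueError(
            f"edge {edge.id} has an infinite distance score (not a candidate)"
        )
    d = max(score.value, params.distance_floor_mm)
    w_last = weights[-1]
    w_prod = math.prod(weights)
    return ((w_last + w_prod) / 2.0) * (edge.length / d) * (
        1.0 + params.delta * edge.mean_radius
    )


def path_score(
    graph: VesselGraph,
    edge: VesselSegment,
    node_id: str,
    candidate: CandidateGraph,
    weights: Sequence[float],
    params: CostParams,
) -> tuple[float, list[str]]:
    """Maximal score over edge-simple vessel paths starting at (node, edge).

    Returns the score together with the optimal ordered edge-id path. The
    recursion adds the edge's cost and continues through the best candidate
    neighbor at the far node, removing the current edge from the candidate
    set along the branch so explored paths never repeat an edge.
    """
    if edge.id not in candidate:
        raise ValueError(f"edge {edge.id} is not in the candidate graph")
    if node_id not in edge.nodes:
        raise ValueError(f"node {node_id} is not an endpoint of edge {edge.id}")
    return _path_score_rec(
        graph, edge, node_id, candidate.edge_ids, tuple(weights), candidate, params, 1
    )


def _path_score_rec(
    graph: VesselGraph,
    edge: VesselSegment,
    node_id: str,
    allowed: frozenset[str],
    weights: tuple[float, ...],
    candidate: CandidateGraph,
    params: CostParams,
    depth: int,
) -> tuple[float, list[str]]:
    if depth > params.max_path_edges:
        raise PathRecursionError(
            f"path exceeded {params.max_path_edges} edges; "
            "candidate graph is pathologically loop-dense"
        )
    cost = edge_cost(edge, weights, candidate.scores[edge.id], params)
    far = edge.other_node(node_id)
    remaining = allowed - {edge.id}
    best: tuple[float, list[str]] | None = None
    for nb in neighbor_edges(graph, edge, node_id):
        if nb.id not in remaining:
            continue
        w = transition_weight(
            graph, edge, nb, far,
            weight_min=params.weight_min, weight_max=params.weight_max,
        )
        sub_score, sub_path = _path_score_rec(
            graph, nb, far, remaining, weights + (w,), candidate, params, depth + 1
        )
        if best is None or sub_score > best[0]:
            best = (sub_score, sub_path)
    if best is None:
        return cost, [edge.id]
    return cost + best[0], [edge.id] + best[1]


def enumerate_configurations(
    arteries: Sequence[ArteryId], edge_ids: Sequence[str]
) -> list[dict[ArteryId, str]]:
    """All injective assignments of distinct incident edges to arteries.

    A node of degree >= 3 yields P(deg, 3) full assignments (6 for degree
    3). Lower-degree nodes yield partial assignments leaving arteries
    unassigned, which supports matching a bifurcation with a missing
    (e.g. occluded) vessel.
    """
    k = min(len(arteries), len(edge_ids))
    if k == 0:
        return []
    configs: list[dict[ArteryId, str]] = []
    for artery_subset in combinations(arteries, k):
        for edge_perm in permutations(sorted(edge_ids), k):
            configs.append(dict(zip(artery_subset, edge_perm)))
    return configs


def _evaluate_node(
    graph: VesselGraph,
    node_id: str,
    arteries: Sequence[ArteryId],
    candidates: dict[ArteryId, CandidateGraph],
    params: CostParams,
) -> tuple[float, dict[ArteryId, list[str]], dict[ArteryId, float]]:
    """Best configuration score at one candidate node."""
    incident = graph.incident(node_id)
    # q is independent of the configuration it appears in: cache per
    # (artery, first edge)
    cache: dict[tuple[ArteryId, str], tuple[float, list[str]]] = {}

    def artery_edge_score(artery: ArteryId, eid: str) -> tuple[float, list[str]]:
        key = (artery, eid)
        if key not in cache:
            cand = candidates.get(artery)
            if cand is None or eid not in cand:
                cache[key] = (0.0, [])
            else:
                cache[key] = path_score(
                    graph, graph.edges[eid], node_id, cand, (1.0,), params
                )
        return cache[key]

    best_score = -math.inf
    best_paths: dict[ArteryId, list[str]] = {a: [] for a in arteries}
    best_scores: dict[ArteryId, float] = {a: 0.0 for a in arteries}
    for config in enumerate_configurations(arteries, incident):
        scores = {a: 0.0 for a in arteries}
        paths: dict[ArteryId, list[str]] = {a: [] for a in arteries}
        for artery, eid in config.items():
            s, p = artery_edge_score(artery, eid)
            scores[artery] = s
            paths[artery] = p
        mean = sum(scores.values()) / len(arteries)
        if mean > best_score:
            best_score = mean
            best_paths = paths
            best_scores = scores
    if not math.isfinite(best_score):
        best_score = 0.0
    return best_score, best_paths, best_scores


def match_bifurcation(
    graph: VesselGraph,
    atlas: LandmarkAtlas,
    bifurcation: BifurcationId,
    candidates: dict[ArteryId, CandidateGraph],
    params: CostParams,
) -> BifurcationMatch | None:
    """Select the optimal node (and artery paths) for one bifurcation.

    Candidate nodes lie within ``params.node_radius_mm`` of the
    bifurcation-end landmarks. Returns ``None`` when no candidate node
    exists or every configuration scores zero (unmatched — legal for
    stroke, segmentation gaps or anatomical variants). Ties are broken by
    ascending node id, then by the deterministic configuration order.
    """
    arteries = bifurcation.arteries
    nodes = candidate_bifurcation_nodes(
        graph, atlas, bifurcation, radius=params.node_radius_mm
    )
    ranked: list[BifurcationMatch] = []
    for node in nodes:  # already sorted by id
        score, paths, scores = _evaluate_node(
            graph, node.id, arteries, candidates, params
        )
        ranked.append(
            BifurcationMatch(
                bifurcation=bifurcation,
                node=node.id,
                artery_paths=paths,
                artery_scores=scores,
                mean_score=score,
            )
        )
    ranked.sort(key=lambda m: -m.mean_score)  # stable: id order preserved on ties
    if not ranked or ranked[0].mean_score <= 0.0:
        return None
    best = ranked[0]
    if len(ranked) > 1 and ranked[1].mean_score > 0.0:
        best.runner_up = ranked[1]
    return best


def match_all_bifurcations(
    graph: VesselGraph,
    atlas: LandmarkAtlas,
    candidates: dict[ArteryId, CandidateGraph],
    params: CostParams,
) -> dict[BifurcationId, BifurcationMatch | None]:
    return {
        bif: match_bifurcation(graph, atlas, bif, candidates, params)
        for bif in BifurcationId
    }


def match_to_dict(match: BifurcationMatch | None) -> dict | None:
    if match is None:
        return None
    return {
        "node": match.node,
        "mean_score": match.mean_score,
        "arteries": {
            a.value: {"edges": match.artery_paths[a], "score": match.artery_scores[a]}
            for a in match.artery_paths
        },
    }
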