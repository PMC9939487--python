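"""Distance-driven baseline labeler.

A greedy reference method sharing the registration and distance metric of
the main pipeline: edges are processed in descending radius order and
assigned to their closest artery landmark set when the distance score is
below 2 cm and a neighboring edge already belongs to that set (the first
edge of each set is exempt from the neighbor condition); sweeps repeat
until nothing changes. Each artery's final path is then the longest
shortest path within its assigned sub-graph, which avoids branching but —
unlike the bifurcation matching — does not enforce that adjacent arteries
meet at a shared node.
"""

from __future__ import annotations

import math

import networkx as nx

from .candidate_graphs import distance_score
from .fusion import Labeling, _shortest_edge_path
from .landmarks import LandmarkAtlas
from .vessel_graph import ArteryId, BifurcationId, VesselGraph


def baseline_assign(
    graph: VesselGraph,
    atlas: LandmarkAtlas,
    threshold: float = 20.0,
) -> dict[ArteryId, set[str]]:
    """Greedy radius-ordered assignment of edges to artery landmark sets."""
    arteries = sorted(atlas.sets)
    # closest artery (and its distance) per edge, shared metric with the
    # candidate-graph construction
    closest: dict[str, tuple[ArteryId, float]] = {}
    for eid in sorted(graph.edges):
        best: tuple[float, ArteryId] | None = None
        for artery in arteries:
            d = distance_score(graph.edges[eid], atlas.sets[artery]).value
            if math.isfinite(d) and (best is None or d < best[0]):
                best = (d, artery)
        if best is not None:
            closest[eid] = (best[1], best[0])

    order = sorted(
        graph.edges, key=lambda eid: (-graph.edges[eid].mean_radius, eid)
    )
    assigned: dict[str, ArteryId] = {}
    sets: dict[ArteryId, set[str]] = {a: set() for a in arteries}

    def neighbor_ids(eid: str) -> set[str]:
        e = graph.edges[eid]
        out = set(graph.incident(e.nodes[0])) | set(graph.incident(e.nodes[1]))
        out.discard(eid)
        return out

    changed = True
    while changed:
        changed = False
        for eid in order:
            if eid in assigned or eid not in closest:
                continue
            artery, d = closest[eid]
            if d >= threshold:
                continue
            if sets[artery] and not any(n in sets[artery] for n in neighbor_ids(eid)):
                continue
            assigned[eid] = artery
            sets[artery].add(eid)
            changed = True
    return sets


def baseline_extract(
    assigned: dict[ArteryId, set[str]], graph: VesselGraph
) -> Labeling:
    """Longest shortest path per artery within its assigned sub-graph."""
    labeling = Labeling()
    for artery, edge_ids in assigned.items():
        if not edge_ids:
            continue
        sub = nx.MultiGraph()
        for eid in sorted(edge_ids):
            e = graph.edges[eid]
            sub.add_edge(e.nodes[0], e.nodes[1], key=eid, weight=e.length)
        best: tuple[float, tuple[str, str]] | None = None
        lengths = dict(nx.all_pairs_dijkstra_path_length(sub, weight="weight"))
        for u in sorted(lengths):
            for v in sorted(lengths[u]):
                if v <= u:
                    continue
                d = lengths[u][v]
                if best is None or d > best[0] or (d == best[0] and (u, v) < best[1]):
                    best = (d, (u, v))
        if best is None:  # single node (should not happen: edges have 2 nodes)
            continue
        path = _shortest_edge_path(sub, graph, best[1][0], best[1][1])
        labeling.assignments[artery] = path or []
        labeling.provenance[artery] = "baseline"

    # a bifurcation is only implied when all three artery paths share a
    # common terminal node; this is reported, not enforced
    from .fusion import path_terminals

    for bif in BifurcationId:
        terminal_sets = []
        for artery in bif.arteries:
            path = labeling.assignments[artery]
            if not path:
                terminal_sets = []
                break
            terminal_sets.append(set(path_terminals(graph, path)))
        if terminal_sets:
            common = set.intersection(*terminal_sets)
            if common:
                labeling.bifurcation_nodes[bif] = sorted(common)[0]
    return labeling


def baseline_label(
    graph: VesselGraph, atlas: LandmarkAtlas, threshold: float = 20.0
) -> Labeling:
    """Full baseline: greedy assignment followed by path extraction."""
    return baseline_extract(baseline_assign(graph, atlas, threshold), graph)
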