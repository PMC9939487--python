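"""Fuse six bifurcation sub-graphs into one consistent labeling.

The per-bifurcation matches cover the inner arteries (AComm, ACA 1 L/R,
basilar) twice — once from each bordering bifurcation — and every outer and
incoming artery once. Fusion (1) resolves the anterior double-assignment
when both ACA bifurcations land on the same node, (2) merges each inner
artery's two paths according to their overlap (shortest path within the
union; global shortest path between the far ends when they are disjoint),
(3) copies the outer/incoming paths, resolving edge-label collisions in
favor of the higher-scoring bifurcation, and (4) traces outer and incoming
arteries past the landmark extent by repeatedly appending the smoothest
unlabeled continuation with a transition angle above 120 degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .bifurcation_matching import BifurcationMatch
from .config import PipelineConfig, DEFAULT_CONFIG
from .vessel_graph import (
    ArteryId,
    ArteryRole,
    BifurcationId,
    VesselGraph,
    neighbor_edges,
    owning_bifurcation,
    transition_weight,
)

#: inner artery -> the two bifurcations whose matches both carry it
INNER_PAIRS: dict[ArteryId, tuple[BifurcationId, BifurcationId]] = {
    ArteryId.ACOMM: (BifurcationId.ACA_L, BifurcationId.ACA_R),
    ArteryId.ACA1_L: (BifurcationId.MEDIA_L, BifurcationId.ACA_L),
    ArteryId.ACA1_R: (BifurcationId.MEDIA_R, BifurcationId.ACA_R),
    ArteryId.BASILAR: (BifurcationId.VERTEBRAL, BifurcationId.POSTERIOR),
}


@dataclass(eq=False)
class Labeling:
    """Final per-edge artery assignment plus bifurcation node ids."""

    assignments: dict[ArteryId, list[str]] = field(default_factory=dict)
    bifurcation_nodes: dict[BifurcationId, str | None] = field(default_factory=dict)
    #: per artery: how the path was obtained ("matching", "merged",
    #: "interrupted", "baseline", "truth", ...)
    provenance: dict[ArteryId, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in ArteryId:
            self.assignments.setdefault(a, [])
        for b in BifurcationId:
            self.bifurcation_nodes.setdefault(b, None)

    def edge_labels(self) -> dict[str, ArteryId]:
        out: dict[str, ArteryId] = {}
        for artery in ArteryId:
            for eid in self.assignments[artery]:
                if eid in out and out[eid] != artery:
                    raise ValueError(
                        f"edge {eid} labeled both {out[eid]} and {artery}"
                    )
                out[eid] = artery
        return out

    def to_dict(self) -> dict:
        return {
            "arteries": {a.value: list(self.assignments[a]) for a in ArteryId},
            "bifurcations": {
                b.value: self.bifurcation_nodes[b] for b in BifurcationId
            },
            "provenance": {a.value: p for a, p in self.provenance.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Labeling":
        return cls(
            assignments={
                ArteryId(a): list(v) for a, v in data.get("arteries", {}).items()
            },
            bifurcation_nodes={
                BifurcationId(b): v for b, v in data.get("bifurcations", {}).items()
            },
            provenance={
                ArteryId(a): p for a, p in data.get("provenance", {}).items()
            },
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def read(cls, path) -> "Labeling":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def walk_nodes(graph: VesselGraph, edges: list[str], start: str) -> list[str]:
    """Node sequence of an ordered edge walk starting at ``start``.

    Tolerates interrupted paths (fragments of an artery whose middle is
    missing, e.g. after a stroke): when an edge does not attach to the
    current node the walk jumps to that edge's first endpoint.
    """
    nodes = [start]
    cur = start
    for eid in edges:
        e = graph.edges[eid]
        if cur not in e.nodes:
            cur = e.nodes[0]
        cur = e.other_node(cur)
        nodes.append(cur)
    return nodes


def path_far_end(graph: VesselGraph, edges: list[str], start: str) -> str:
    return walk_nodes(graph, edges, start)[-1]


def path_terminals(graph: VesselGraph, edges: list[str]) -> tuple[str, str]:
    """Terminal node ids of an ordered edge walk (orientation unknown)."""
    if not edges:
        raise ValueError("empty path has no terminals")
    first = graph.edges[edges[0]]
    if len(edges) == 1:
        return first.nodes
    second = graph.edges[edges[1]]
    shared = set(first.nodes) & set(second.nodes)
    if shared:
        start = first.other_node(sorted(shared)[0])
    else:  # interrupted path: orient along the first fragment
        start = first.nodes[0]
    return start, path_far_end(graph, edges, start)


def _shortest_edge_path(
    g: nx.MultiGraph, graph: VesselGraph, source: str, target: str
) -> list[str] | None:
    """Arc-length shortest path as an ordered edge-id list, or None."""
    try:
        node_path = nx.dijkstra_path(g, source, target, weight="weight")
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None
    edges: list[str] = []
    for u, v in zip(node_path[:-1], node_path[1:]):
        data = g.get_edge_data(u, v)
        # deterministic parallel-edge choice: min (length, id)
        key = min(data, key=lambda k: (data[k]["weight"], k))
        edges.append(key)
    return edges


def merge_inner(
    match_a: BifurcationMatch | None,
    match_b: BifurcationMatch | None,
    artery: ArteryId,
    graph: VesselGraph,
) -> tuple[list[str], str]:
    """Merge the two bifurcations' paths for one inner artery.

    Returns (ordered edge ids, provenance). Overlapping paths reduce to the
    shortest path between the two bifurcation nodes within the union of
    both paths; disjoint paths are joined by the global shortest path
    between their far endpoints. If no connecting path exists, the artery
    is marked interrupted and both fragments are kept.
    """
    path_a = list(match_a.artery_paths.get(artery, [])) if match_a else []
    path_b = list(match_b.artery_paths.get(artery, [])) if match_b else []
    if not path_a and not path_b:
        return [], "matching"
    if not path_a:
        return path_b, "matching"
    if not path_b:
        return path_a, "matching"
    assert match_a is not None and match_b is not None
    union = set(path_a) | set(path_b)
    if set(path_a) & set(path_b):
        sub = nx.MultiGraph()
        for eid in sorted(union):
            e = graph.edges[eid]
            sub.add_edge(e.nodes[0], e.nodes[1], key=eid, weight=e.length)
        merged = _shortest_edge_path(sub, graph, match_a.node, match_b.node)
        if merged is not None:
            return merged, "merged"
    else:
        far_a = path_far_end(graph, path_a, match_a.node)
        far_b = path_far_end(graph, path_b, match_b.node)
        connector = _shortest_edge_path(graph.to_networkx(), graph, far_a, far_b)
        if connector is not None:
            merged = list(path_a)
            merged += [eid for eid in connector if eid not in merged]
            merged += [eid for eid in reversed(path_b) if eid not in merged]
            return merged, "merged"
    # no connecting route: keep both fragments (stroke / interrupted vessel)
    return path_a + [eid for eid in path_b if eid not in path_a], "interrupted"


def trace_outer(
    graph: VesselGraph,
    path: list[str],
    config: PipelineConfig = DEFAULT_CONFIG,
    labeled: set[str] | None = None,
    start_node: str | None = None,
) -> list[str]:
    """Extend an outer/incoming artery path beyond the landmark extent.

    From the free end, repeatedly append the incident unlabeled edge with
    the maximal transition weight among those whose transition angle
    exceeds 120 degrees (weight > 0.8 under the default map); stop when no
    edge qualifies. Never revisits or relabels an edge; the input path is
    always a prefix of the result.
    """
    if not path:
        return []
    labeled = set(labeled or ())
    if start_node is None:
        start_node = path_terminals(graph, path)[0]
    out = list(path)
    used = set(out) | labeled
    tip = path_far_end(graph, out, start_node)
    params = config.cost
    while True:
        last = graph.edges[out[-1]]
        best: tuple[float, str] | None = None
        for nb in neighbor_edges(graph, last, last.other_node(tip)):
            if nb.id in used:
                continue
            w = transition_weight(
                graph, last, nb, tip,
                weight_min=params.weight_min, weight_max=params.weight_max,
            )
            if w <= config.trace_weight_threshold:
                continue
            if best is None or w > best[0] or (w == best[0] and nb.id < best[1]):
                best = (w, nb.id)
        if best is None:
            break
        out.append(best[1])
        used.add(best[1])
        tip = graph.edges[best[1]].other_node(tip)
    return out


def resolve_anterior(
    match_l: BifurcationMatch | None,
    match_r: BifurcationMatch | None,
    ratio: float = 0.8,
) -> tuple[BifurcationMatch | None, BifurcationMatch | None]:
    """Disambiguate the two anterior (ACA) bifurcations.

    If both matched onto the same node, the weaker match's runner-up is
    promoted when its score reaches ``ratio`` of the weaker match's best
    score (two distinct ACA 2s assumed); otherwise the shared node is kept,
    which corresponds to the single-ACA 2 variant.
    """
    if match_l is None or match_r is None or match_l.node != match_r.node:
        return match_l, match_r
    if match_l.mean_score <= match_r.mean_score:
        lower, other, lower_is_left = match_l, match_r, True
    else:
        lower, other, lower_is_left = match_r, match_l, False
    runner = lower.runner_up
    if runner is not None and runner.mean_score >= ratio * lower.mean_score:
        promoted = runner
        return (promoted, other) if lower_is_left else (other, promoted)
    return match_l, match_r


def fuse(
    matches: dict[BifurcationId, BifurcationMatch | None],
    graph: VesselGraph,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Labeling:
    """Combine the six bifurcation matches into one consistent labeling."""
    matches = dict(matches)
    matches[BifurcationId.ACA_L], matches[BifurcationId.ACA_R] = resolve_anterior(
        matches.get(BifurcationId.ACA_L),
        matches.get(BifurcationId.ACA_R),
        ratio=config.anterior_ratio,
    )

    labeling = Labeling()
    for bif in BifurcationId:
        m = matches.get(bif)
        labeling.bifurcation_nodes[bif] = m.node if m else None

    labels: dict[str, ArteryId] = {}

    def assign(artery: ArteryId, path: list[str], provenance: str) -> None:
        kept: list[str] = []
        for eid in path:
            if eid in labels:
                break  # collision: truncate at the already-labeled edge
            labels[eid] = artery
            kept.append(eid)
        labeling.assignments[artery] = kept
        labeling.provenance[artery] = provenance

    # inner arteries first: their merged course anchors the ring
    for artery in (ArteryId.ACOMM, ArteryId.ACA1_L, ArteryId.ACA1_R, ArteryId.BASILAR):
        bif_a, bif_b = INNER_PAIRS[artery]
        path, provenance = merge_inner(
            matches.get(bif_a), matches.get(bif_b), artery, graph
        )
        assign(artery, path, provenance)

    # outer/incoming arteries, strongest bifurcation first so that label
    # collisions between two outer arteries favor the higher-scoring match
    remaining = [
        a for a in ArteryId if a.role in (ArteryRole.OUTER, ArteryRole.INCOMING)
    ]
    def owner_score(artery: ArteryId) -> float:
        m = matches.get(owning_bifurcation(artery))
        return m.mean_score if m else 0.0
    remaining.sort(key=lambda a: (-owner_score(a), a.value))
    for artery in remaining:
        m = matches.get(owning_bifurcation(artery))
        path = list(m.artery_paths.get(artery, [])) if m else []
        assign(artery, path, "matching")

    # trace outer and incoming arteries past the landmark extent
    for artery in remaining:
        path = labeling.assignments[artery]
        if not path:
            continue
        m = matches.get(owning_bifurcation(artery))
        start = m.node if m else None
        extended = trace_outer(
            graph, path, config, labeled=set(labels) - set(path), start_node=start
        )
        for eid in extended[len(path):]:
            labels[eid] = artery
        labeling.assignments[artery] = extended
        if len(extended) > len(path):
            labeling.provenance[artery] = labeling.provenance[artery] + "+traced"

    labeling.edge_labels()  # assert uniqueness
    return labeling
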