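"""Per-artery candidate sub-graphs from landmark distance scores.

For every (artery, edge) pair a distance score d_a(e) summarizes how close
the edge's centerline runs to the artery's landmarks:

    d_a(e) = mean_n(s_n) + sqrt( mean_n( (s_n - min_i s_i)^2 ) ),
    s_n    = min_m || x_n - x_m^(a) ||_2

i.e. the mean nearest-landmark distance plus a spread term (a standard
deviation computed against the minimum instead of the mean) that penalizes
edges running perpendicular to the landmark polyline. Centerline points
whose nearest landmark is one of the two end landmarks are omitted from
both terms, so edges extending past the artery's anatomical extent are not
pulled in. Edges with d_a(e) below a 20 mm threshold form the artery's
candidate sub-graph; the generous threshold absorbs residual registration
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .landmarks import LandmarkAtlas, LandmarkSet
from .vessel_graph import ArteryId, BifurcationId, GraphNode, VesselGraph, VesselSegment


@dataclass(eq=False)
class DistanceScore:
    """Distance score of one edge against one artery's landmarks."""

    artery: ArteryId
    edge_id: str
    #: d_a(e) in mm; +inf when every centerline point was omitted
    value: float
    #: nearest-landmark distance of each retained centerline point
    point_distances: np.ndarray

    @property
    def retained_points(self) -> int:
        return len(self.point_distances)


@dataclass(eq=False)
class CandidateGraph:
    """Edges of one artery's candidate sub-graph with their scores."""

    artery: ArteryId
    #: edge id -> DistanceScore, only edges below the threshold
    scores: dict[str, DistanceScore]

    @property
    def edge_ids(self) -> frozenset[str]:
        return frozenset(self.scores)

    def __contains__(self, edge_id: str) -> bool:
        return edge_id in self.scores

    def __len__(self) -> int:
        return len(self.scores)


def distance_score(
    edge: VesselSegment,
    landmarks: LandmarkSet,
    min_retained_fraction: float = 0.25,
) -> DistanceScore:
    """Evaluate d_a(e) for one edge against one artery's landmark set.

    The score averages over the segment's centerline points, so it is only
    meaningful when a substantial part of the segment is matched by
    interior landmarks. When fewer than ``min_retained_fraction`` of the
    points survive the end-landmark omission, the edge lies essentially
    beyond the artery's ends and the score would be computed from a
    handful of junction-area points; such edges get the +inf sentinel,
    exactly like fully-omitted ones.
    """
    lm = landmarks.points
    if len(lm) == 0:
        raise ValueError("empty landmark set")
    dists = np.linalg.norm(edge.points[:, None, :] - lm[None, :, :], axis=2)
    nearest_idx = np.argmin(dists, axis=1)
    s = dists[np.arange(len(edge.points)), nearest_idx]
    first, last = landmarks.end_indices
    keep = (nearest_idx != first) & (nearest_idx != last)
    s = s[keep]
    if len(s) < min_retained_fraction * len(edge.points):
        return DistanceScore(
            artery=landmarks.artery,
            edge_id=edge.id,
            value=math.inf,
            point_distances=s,
        )
    value = float(s.mean() + np.sqrt(np.mean((s - s.min()) ** 2)))
    return DistanceScore(
        artery=landmarks.artery, edge_id=edge.id, value=value, point_distances=s
    )


def build_candidates(
    graph: VesselGraph,
    atlas: LandmarkAtlas,
    threshold: float = 20.0,
) -> dict[ArteryId, CandidateGraph]:
    """Candidate sub-graph per artery: edges with d_a(e) strictly below
    ``threshold`` (mm). Candidate graphs of different arteries may overlap;
    an empty candidate graph is legal and signals a possibly missing artery.
    """
    out: dict[ArteryId, CandidateGraph] = {}
    for artery in sorted(atlas.sets):
        lm = atlas.sets[artery]
        scores: dict[str, DistanceScore] = {}
        for eid in sorted(graph.edges):
            sc = distance_score(graph.edges[eid], lm)
            if sc.value < threshold:
                scores[eid] = sc
        out[artery] = CandidateGraph(artery=artery, scores=scores)
    return out


def candidate_bifurcation_nodes(
    graph: VesselGraph,
    atlas: LandmarkAtlas,
    bifurcation: BifurcationId,
    radius: float = 15.0,
) -> list[GraphNode]:
    """Graph nodes within ``radius`` mm of at least one of the bifurcation-end
    landmarks of the bifurcation's three arteries, sorted by id."""
    ends = atlas.bifurcation_end_landmarks(bifurcation)
    if len(ends) == 0 or not graph.nodes:
        return []
    node_ids = sorted(graph.nodes)
    positions = np.asarray([graph.nodes[nid].position for nid in node_ids])
    tree = cKDTree(ends)
    dist, _ = tree.query(positions)
    return [graph.nodes[nid] for nid, d in zip(node_ids, dist) if d <= radius]


def scores_to_records(
    candidates: dict[ArteryId, CandidateGraph]
) -> list[dict]:
    """Flatten candidate scores for CSV/debug export."""
    return [
        {"artery": artery.value, "edge": eid, "distance_mm": sc.value}
        for artery in sorted(candidates)
        for eid, sc in sorted(candidates[artery].scores.items())
    ]
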