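"""Centerline graph model for cerebrovascular segmentations.

A patient is represented as an undirected graph: nodes are vessel
bifurcations and endpoints (3-D positions, mm), edges are vessel segments
carrying an ordered centerline polyline with per-point radii. Parallel
edges and cycles are permitted — segmentation artifacts such as loops and
shortcuts are part of the input contract, not an error.

Coordinates are millimeters in a right-handed LPS-style frame; serialization
uses a small JSON dialect (see :func:`read_graph` / :func:`write_graph`)
with 0-based indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx
import numpy as np


class GraphSchemaError(ValueError):
    """The serialized graph violates the documented JSON schema."""


class GraphIntegrityError(ValueError):
    """The graph violates a structural invariant (e.g. dangling node id)."""


class DegenerateGeometryError(ValueError):
    """A geometric primitive (direction, polyline) is degenerate."""


class ArteryRole(str, Enum):
    #: feeds the Circle of Willis (ICA, vertebral arteries)
    INCOMING = "incoming"
    #: spans two labeled bifurcations (AComm, ACA 1, basilar artery)
    INNER = "inner"
    #: leaves the Circle of Willis (ACA 2, middle and posterior cerebral)
    OUTER = "outer"


class ArteryId(str, Enum):
    """The 14 arteries of interest around the Circle of Willis."""

    ICA_L = "ICA_L"
    ICA_R = "ICA_R"
    VERT_L = "VERT_L"
    VERT_R = "VERT_R"
    BASILAR = "BASILAR"
    ACA1_L = "ACA1_L"
    ACA1_R = "ACA1_R"
    ACA2_L = "ACA2_L"
    ACA2_R = "ACA2_R"
    ACOMM = "ACOMM"
    MCA_L = "MCA_L"
    MCA_R = "MCA_R"
    PCA_L = "PCA_L"
    PCA_R = "PCA_R"

    @property
    def role(self) -> ArteryRole:
        return _ARTERY_ROLES[self]


class BifurcationId(str, Enum):
    """The 6 labeled bifurcations of the Circle of Willis."""

    VERTEBRAL = "Vertebral"
    POSTERIOR = "Posterior"
    MEDIA_L = "Media-L"
    MEDIA_R = "Media-R"
    ACA_L = "ACA-L"
    ACA_R = "ACA-R"

    @property
    def arteries(self) -> tuple[ArteryId, ArteryId, ArteryId]:
        return BIFURCATION_ARTERIES[self]


_ARTERY_ROLES: dict[ArteryId, ArteryRole] = {
    ArteryId.ICA_L: ArteryRole.INCOMING,
    ArteryId.ICA_R: ArteryRole.INCOMING,
    ArteryId.VERT_L: ArteryRole.INCOMING,
    ArteryId.VERT_R: ArteryRole.INCOMING,
    ArteryId.BASILAR: ArteryRole.INNER,
    ArteryId.ACA1_L: ArteryRole.INNER,
    ArteryId.ACA1_R: ArteryRole.INNER,
    ArteryId.ACOMM: ArteryRole.INNER,
    ArteryId.ACA2_L: ArteryRole.OUTER,
    ArteryId.ACA2_R: ArteryRole.OUTER,
    ArteryId.MCA_L: ArteryRole.OUTER,
    ArteryId.MCA_R: ArteryRole.OUTER,
    ArteryId.PCA_L: ArteryRole.OUTER,
    ArteryId.PCA_R: ArteryRole.OUTER,
}

#: the three arteries adjacent to each labeled bifurcation
BIFURCATION_ARTERIES: dict[BifurcationId, tuple[ArteryId, ArteryId, ArteryId]] = {
    BifurcationId.VERTEBRAL: (ArteryId.VERT_L, ArteryId.VERT_R, ArteryId.BASILAR),
    BifurcationId.POSTERIOR: (ArteryId.BASILAR, ArteryId.PCA_L, ArteryId.PCA_R),
    BifurcationId.MEDIA_L: (ArteryId.ICA_L, ArteryId.MCA_L, ArteryId.ACA1_L),
    BifurcationId.MEDIA_R: (ArteryId.ICA_R, ArteryId.MCA_R, ArteryId.ACA1_R),
    BifurcationId.ACA_L: (ArteryId.ACA1_L, ArteryId.ACA2_L, ArteryId.ACOMM),
    BifurcationId.ACA_R: (ArteryId.ACA1_R, ArteryId.ACA2_R, ArteryId.ACOMM),
}

#: canonical orientation of each artery: which bifurcation its ordered
#: point list starts at and ends at (``None`` marks a free end). Inner
#: arteries border two bifurcations; incoming arteries run free end ->
#: bifurcation; outer arteries run bifurcation -> free end.
ARTERY_BIFURCATIONS: dict[ArteryId, tuple[BifurcationId | None, BifurcationId | None]] = {
    ArteryId.ICA_L: (None, BifurcationId.MEDIA_L),
    ArteryId.ICA_R: (None, BifurcationId.MEDIA_R),
    ArteryId.VERT_L: (None, BifurcationId.VERTEBRAL),
    ArteryId.VERT_R: (None, BifurcationId.VERTEBRAL),
    ArteryId.BASILAR: (BifurcationId.VERTEBRAL, BifurcationId.POSTERIOR),
    ArteryId.PCA_L: (BifurcationId.POSTERIOR, None),
    ArteryId.PCA_R: (BifurcationId.POSTERIOR, None),
    ArteryId.MCA_L: (BifurcationId.MEDIA_L, None),
    ArteryId.MCA_R: (BifurcationId.MEDIA_R, None),
    ArteryId.ACA1_L: (BifurcationId.MEDIA_L, BifurcationId.ACA_L),
    ArteryId.ACA1_R: (BifurcationId.MEDIA_R, BifurcationId.ACA_R),
    ArteryId.ACA2_L: (BifurcationId.ACA_L, None),
    ArteryId.ACA2_R: (BifurcationId.ACA_R, None),
    ArteryId.ACOMM: (BifurcationId.ACA_L, BifurcationId.ACA_R),
}


def owning_bifurcation(artery: ArteryId) -> BifurcationId:
    """The single bifurcation an incoming/outer artery is attached to."""
    start, end = ARTERY_BIFURCATIONS[artery]
    if start is not None and end is not None:
        raise ValueError(f"{artery} is an inner artery bordering two bifurcations")
    bif = start if start is not None else end
    assert bif is not None
    return bif


@dataclass(eq=False)
class GraphNode:
    id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass(eq=False)
class VesselSegment:
    """One vessel segment: an ordered 3-D centerline with per-point radii.

    ``points[0]`` coincides with the position of ``nodes[0]`` and
    ``points[-1]`` with ``nodes[1]`` (checked at graph level).
    """

    id: str
    nodes: tuple[str, str]
    points: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = (str(self.nodes[0]), str(self.nodes[1]))
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise GraphSchemaError(f"edge {self.id}: points must be (N, 3)")
        if len(self.points) < 2:
            raise GraphSchemaError(f"edge {self.id}: centerline needs >= 2 points")
        if len(self.radii) != len(self.points):
            raise GraphSchemaError(
                f"edge {self.id}: radii count {len(self.radii)} != "
                f"point count {len(self.points)}"
            )
        if not np.all(self.radii > 0):
            raise GraphSchemaError(f"edge {self.id}: radii must be > 0")

    @property
    def length(self) -> float:
        """Arc length: sum of consecutive point distances (mm)."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def mean_radius(self) -> float:
        """Arithmetic mean of the per-point radii (mm)."""
        return float(self.radii.mean())

    def other_node(self, node_id: str) -> str:
        if node_id == self.nodes[0]:
            return self.nodes[1]
        if node_id == self.nodes[1]:
            return self.nodes[0]
        raise ValueError(f"node {node_id} is not an endpoint of edge {self.id}")

    def oriented_points(self, from_node: str) -> np.ndarray:
        """Centerline ordered so that it starts at ``from_node``."""
        if from_node == self.nodes[0]:
            return self.points
        if from_node == self.nodes[1]:
            return self.points[::-1]
        raise ValueError(f"node {from_node} is not an endpoint of edge {self.id}")

    def direction_from(self, node_id: str, chord_mm: float = 3.0) -> np.ndarray:
        """Unit direction leaving ``node_id`` along this segment.

        Measured as the chord from the endpoint to the centerline point at
        arc length ``min(chord_mm, length/2)``, which is robust to curvature
        compared to the full-edge chord.
        """
        pts = self.oriented_points(node_id)
        target = min(chord_mm, self.length / 2.0)
        p = point_at_arclength(pts, target)
        v = p - pts[0]
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise DegenerateGeometryError(
                f"edge {self.id}: zero-length direction at node {node_id}"
            )
        return v / norm


def point_at_arclength(points: np.ndarray, s: float) -> np.ndarray:
    """Interpolated point at arc length ``s`` along an ordered polyline."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg) - 1)
    if seg[i] < 1e-15:
        return points[i].copy()
    t = (s - cum[i]) / seg[i]
    return points[i] + t * (points[i + 1] - points[i])


@dataclass(eq=False)
class VesselGraph:
    """Undirected multigraph of vessel segments."""

    nodes: dict[str, GraphNode] = field(default_factory=dict)
    edges: dict[str, VesselSegment] = field(default_factory=dict)
    _adjacency: dict[str, list[str]] | None = field(default=None, repr=False)

    @classmethod
    def from_parts(
        cls, nodes: Iterable[GraphNode], edges: Iterable[VesselSegment]
    ) -> "VesselGraph":
        node_map: dict[str, GraphNode] = {}
        for n in nodes:
            if n.id in node_map:
                raise GraphIntegrityError(f"duplicate node id {n.id}")
            node_map[n.id] = n
        edge_map: dict[str, VesselSegment] = {}
        for e in edges:
            if e.id in edge_map:
                raise GraphIntegrityError(f"duplicate edge id {e.id}")
            edge_map[e.id] = e
        g = cls(nodes=node_map, edges=edge_map)
        g.validate()
        return g

    def validate(self, endpoint_tol: float = 1e-6) -> None:
        for e in self.edges.values():
            for which, nid in enumerate(e.nodes):
                if nid not in self.nodes:
                    raise GraphIntegrityError(
                        f"edge {e.id} references unknown node id {nid}"
                    )
                pt = e.points[0] if which == 0 else e.points[-1]
                if np.linalg.norm(pt - self.nodes[nid].position) > endpoint_tol:
                    raise GraphIntegrityError(
                        f"edge {e.id}: endpoint {which} does not coincide with "
                        f"node {nid} position"
                    )

    def incident(self, node_id: str) -> list[str]:
        """Sorted ids of edges incident to ``node_id``."""
        if self._adjacency is None:
            adj: dict[str, list[str]] = {nid: [] for nid in self.nodes}
            for e in self.edges.values():
                adj[e.nodes[0]].append(e.id)
                if e.nodes[1] != e.nodes[0]:
                    adj[e.nodes[1]].append(e.id)
            self._adjacency = {nid: sorted(eids) for nid, eids in adj.items()}
        return self._adjacency[node_id]

    def invalidate_adjacency(self) -> None:
        self._adjacency = None

    def all_centerline_points(self) -> np.ndarray:
        """All centerline points of all edges pooled into one (P, 3) array."""
        if not self.edges:
            return np.zeros((0, 3))
        return np.vstack([self.edges[eid].points for eid in sorted(self.edges)])

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for nid in self.nodes:
            g.add_node(nid)
        for e in self.edges.values():
            g.add_edge(e.nodes[0], e.nodes[1], key=e.id, weight=e.length)
        return g


def neighbor_edges(
    graph: VesselGraph, edge: VesselSegment, node_id: str
) -> list[VesselSegment]:
    """Edges reachable by traveling through ``edge`` away from ``node_id``.

    Returns all edges incident to the *other* endpoint of ``edge``
    (excluding ``edge`` itself), sorted by id for determinism.
    """
    other = edge.other_node(node_id)
    return [graph.edges[eid] for eid in graph.incident(other) if eid != edge.id]


def transition_weight(
    graph: VesselGraph,
    edge_in: VesselSegment,
    edge_out: VesselSegment,
    shared_node_id: str,
    weight_min: float = 0.2,
    weight_max: float = 1.0,
) -> float:
    """Smoothness weight for traveling from ``edge_in`` into ``edge_out``.

    The dot product of the unit travel directions (into the shared node,
    then out of it) is linearly mapped onto ``[weight_min, weight_max]``:
    straight continuation (180 deg between the edges as drawn) gives the
    maximum, a full reversal the minimum. Default map: w = 0.6 + 0.4 u.v.
    """
    if edge_in.id == edge_out.id:
        raise ValueError("transition weight requires two distinct edges")
    u = -edge_in.direction_from(shared_node_id)
    v = edge_out.direction_from(shared_node_id)
    dot = float(np.clip(u @ v, -1.0, 1.0))
    mid = (weight_min + weight_max) / 2.0
    half = (weight_max - weight_min) / 2.0
    return mid + half * dot


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _require(obj: dict, key: str, context: str):
    if key not in obj:
        raise GraphSchemaError(f"{context}: missing field '{key}'")
    return obj[key]


def graph_to_dict(graph: VesselGraph, labels: dict[str, str] | None = None) -> dict:
    labels = labels or {}
    return {
        "nodes": [
            {"id": n.id, "pos": [float(x) for x in n.position]}
            for n in (graph.nodes[nid] for nid in sorted(graph.nodes))
        ],
        "edges": [
            {
                "id": e.id,
                "nodes": list(e.nodes),
                "points": [[float(x) for x in p] for p in e.points],
                "radii": [float(r) for r in e.radii],
                **({"label": labels[e.id]} if e.id in labels else {}),
            }
            for e in (graph.edges[eid] for eid in sorted(graph.edges))
        ],
    }


def graph_from_dict(data: dict) -> tuple[VesselGraph, dict[str, str]]:
    if not isinstance(data, dict):
        raise GraphSchemaError("graph document must be a JSON object")
    nodes = []
    for i, nd in enumerate(_require(data, "nodes", "graph")):
        pos = _require(nd, "pos", f"nodes[{i}]")
        if len(pos) != 3:
            raise GraphSchemaError(f"nodes[{i}]: 'pos' must have 3 components")
        nodes.append(GraphNode(id=str(_require(nd, "id", f"nodes[{i}]")), position=pos))
    edges = []
    labels: dict[str, str] = {}
    for i, ed in enumerate(_require(data, "edges", "graph")):
        ctx = f"edges[{i}]"
        eid = str(_require(ed, "id", ctx))
        nids = _require(ed, "nodes", ctx)
        if len(nids) != 2:
            raise GraphSchemaError(f"{ctx}: 'nodes' must list exactly 2 node ids")
        edges.append(
            VesselSegment(
                id=eid,
                nodes=(str(nids[0]), str(nids[1])),
                points=_require(ed, "points", ctx),
                radii=_require(ed, "radii", ctx),
            )
        )
        if "label" in ed and ed["label"] is not None:
            labels[eid] = str(ed["label"])
    return VesselGraph.from_parts(nodes, edges), labels


def write_graph(
    graph: VesselGraph, path, labels: dict[str, str] | None = None
) -> None:
    with open(path, "w") as fh:
        json.dump(graph_to_dict(graph, labels), fh, indent=1)


def read_graph(path) -> VesselGraph:
    with open(path) as fh:
        data = json.load(fh)
    graph, _ = graph_from_dict(data)
    return graph


def read_graph_with_labels(path) -> tuple[VesselGraph, dict[str, str]]:
    with open(path) as fh:
        data = json.load(fh)
    return graph_from_dict(data)
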