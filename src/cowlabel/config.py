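"""Central configuration for the labeling pipeline.

All distance-like parameters are in millimeters. The defaults encode the
constants the whole pipeline is built around: the 20 mm candidate threshold,
the 15 mm bifurcation-node search radius, the radius influence delta = 0.1,
the [0.2, 1.0] transition-weight range, the 120 deg outer-tracing cutoff, the
80 % anterior reassignment ratio, the 5 mm bifurcation placement tolerance
and the 20 mm evaluation extent for outgoing vessels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping


@dataclass
class CostParams:
    """Parameters of the path scoring used during bifurcation matching.

    delta
        Influence of the mean vessel radius on the edge cost (per mm of
        radius); kept low so geometry and landmark distance dominate.
    weight_min / weight_max
        Range onto which the dot product of adjacent edge directions is
        linearly mapped; straight continuation maps to ``weight_max``, a
        full reversal to ``weight_min``.
    candidate_threshold_mm
        Edges whose landmark distance score is below this value enter an
        artery's candidate sub-graph.
    node_radius_mm
        Nodes within this distance of a bifurcation-end landmark are
        candidate bifurcation nodes.
    distance_floor_mm
        Floor applied to the distance score inside the edge cost to avoid
        division by (sub-resolution) zero distances.
    max_path_edges
        Recursion guard for the path maximization; exceeded only on
        pathological loop-dense graphs.
    """

    delta: float = 0.1
    weight_min: float = 0.2
    weight_max: float = 1.0
    candidate_threshold_mm: float = 20.0
    node_radius_mm: float = 15.0
    distance_floor_mm: float = 0.1
    max_path_edges: int = 64


@dataclass
class PipelineConfig:
    """End-to-end configuration: cost parameters, ICP, fusion, evaluation."""

    cost: CostParams = field(default_factory=CostParams)
    icp_max_iter: int = 50
    icp_tol_mm: float = 1e-3
    #: minimum transition weight for outer tracing; equals a 120 deg
    #: transition angle under the linear weight map (u.v > cos 60 deg = 0.5).
    trace_weight_threshold: float = 0.8
    #: runner-up score ratio above which a shared anterior bifurcation node
    #: is split onto the second-best node.
    anterior_ratio: float = 0.8
    bifurcation_tolerance_mm: float = 5.0
    outgoing_extent_mm: float = 20.0

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        cost = CostParams(**data.pop("cost", {}))
        return cls(cost=cost, **data)

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = PipelineConfig()
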