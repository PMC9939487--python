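"""End-to-end labeling pipeline: ICP -> candidates -> matching -> fusion."""

from __future__ import annotations

from dataclasses import dataclass

from .bifurcation_matching import BifurcationMatch, match_all_bifurcations
from .candidate_graphs import CandidateGraph, build_candidates
from .config import PipelineConfig, DEFAULT_CONFIG
from .fusion import Labeling, fuse
from .landmarks import ICPResult, LandmarkAtlas, icp_align
from .vessel_graph import ArteryId, BifurcationId, VesselGraph


@dataclass(eq=False)
class PipelineResult:
    labeling: Labeling
    icp: ICPResult | None
    candidates: dict[ArteryId, CandidateGraph]
    matches: dict[BifurcationId, BifurcationMatch | None]


def label_graph(
    graph: VesselGraph,
    atlas: LandmarkAtlas,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> PipelineResult:
    """Run the full labeling pipeline on one centerline graph.

    An empty graph yields an all-empty labeling rather than an error;
    unmatched bifurcations are a legal outcome (stroke, variants,
    segmentation gaps).
    """
    if not graph.edges:
        return PipelineResult(
            labeling=Labeling(), icp=None,
            candidates={}, matches={b: None for b in BifurcationId},
        )
    icp = icp_align(
        atlas, graph, max_iter=config.icp_max_iter, tol=config.icp_tol_mm
    )
    candidates = build_candidates(
        graph, icp.atlas, threshold=config.cost.candidate_threshold_mm
    )
    matches = match_all_bifurcations(graph, icp.atlas, candidates, config.cost)
    labeling = fuse(matches, graph, config)
    return PipelineResult(
        labeling=labeling, icp=icp, candidates=candidates, matches=matches
    )


def baseline_graph(
    graph: VesselGraph,
    atlas: LandmarkAtlas,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[Labeling, ICPResult | None]:
    """Run the distance-driven baseline with the same ICP registration."""
    from .baseline_labeler import baseline_label

    if not graph.edges:
        return Labeling(), None
    icp = icp_align(
        atlas, graph, max_iter=config.icp_max_iter, tol=config.icp_tol_mm
    )
    labeling = baseline_label(
        graph, icp.atlas, threshold=config.cost.candidate_threshold_mm
    )
    return labeling, icp
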