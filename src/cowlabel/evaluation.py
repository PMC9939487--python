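"""Automatic scoring of a predicted labeling against ground truth.

Per-vessel verdicts use an 8-class taxonomy: TP* (complete), TP-
(underestimated), TP+ (overestimated), TP± (misestimated), TN (vessel
absent and dismissed), FN (missed), FP+ (wrong vessel labeled, vessel
present), FP- (labeled although absent). "Detected" aggregates the four TP
classes plus TN; "complete" counts TP* plus TN.

Outgoing arteries (ACA 2, middle and posterior cerebral) branch soon after
the Circle of Willis, so both prediction and truth are clipped to 20 mm of
arc length after the bifurcation before comparison; incoming and inner
arteries are assessed over their whole length. Since an automatic
comparison needs a numeric boundary where a visual review had none, "main
part found" is operationalized as >= 0.5 of the (clipped) truth arc length
covered — a declared convention of this package.

Bifurcation verdicts: correct (same node), within 5 mm (geodesic
along-centerline displacement <= 5 mm, reached through correctly labeled
vessels only), or false.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG
from .fusion import Labeling, path_terminals, walk_nodes
from .vessel_graph import (
    ARTERY_BIFURCATIONS,
    ArteryId,
    ArteryRole,
    BifurcationId,
    VesselGraph,
)

CATEGORIES = ("TP_star", "TP_minus", "TP_plus", "TP_pm", "TN", "FN", "FP_plus", "FP_minus")
DETECTED = frozenset({"TP_star", "TP_minus", "TP_plus", "TP_pm", "TN"})
COMPLETE = frozenset({"TP_star", "TN"})

_LEN_TOL = 1e-6  # mm; sub-micrometer agreement counts as exact


@dataclass
class VesselVerdict:
    artery: ArteryId
    category: str
    #: fraction of (clipped) truth arc length covered by the prediction
    overlap_fraction: float
    #: (clipped) predicted arc length outside the truth path, mm
    excess_length_mm: float


@dataclass
class BifurcationVerdict:
    bifurcation: BifurcationId
    category: str  # correct | within_5mm | false
    #: geodesic displacement between predicted and true node, mm
    displacement_mm: float


def _clip_portions(
    graph: VesselGraph, edges: list[str], start: str, max_len: float | None
) -> dict[str, float]:
    """Arc length of each edge retained when walking from ``start`` and
    keeping only the first ``max_len`` mm (all of it when ``None``)."""
    out: dict[str, float] = {}
    s = 0.0
    for eid in edges:
        length = graph.edges[eid].length
        if max_len is None:
            out[eid] = length
        else:
            take = min(max(max_len - s, 0.0), length)
            if take > _LEN_TOL:
                out[eid] = take
        s += length
    return out


def _walk_start(graph: VesselGraph, edges: list[str], anchor: str | None) -> str:
    """Choose the walk end closest to the anchor node (the true
    bifurcation); prediction and truth are then clipped from matching ends."""
    t0, t1 = path_terminals(graph, edges)
    if anchor is None or anchor not in graph.nodes:
        return t0
    if anchor in (t0, t1):
        return anchor
    pos = graph.nodes[anchor].position
    import numpy as np

    d0 = np.linalg.norm(graph.nodes[t0].position - pos)
    d1 = np.linalg.norm(graph.nodes[t1].position - pos)
    return t0 if d0 <= d1 else t1


def evaluate_vessel(
    pred: list[str],
    truth: list[str],
    artery: ArteryId,
    graph: VesselGraph,
    true_bifurcation_node: str | None,
    outgoing_extent_mm: float = 20.0,
) -> VesselVerdict:
    """Classify one artery's predicted path against ground truth."""
    if not truth and not pred:
        return VesselVerdict(artery, "TN", 1.0, 0.0)
    if not truth:
        return VesselVerdict(artery, "FP_minus", 0.0, _total(graph, pred))
    if not pred:
        return VesselVerdict(artery, "FN", 0.0, 0.0)

    clip = outgoing_extent_mm if artery.role == ArteryRole.OUTER else None
    truth_portions = _clip_portions(
        graph, truth, _walk_start(graph, truth, true_bifurcation_node), clip
    )
    pred_portions = _clip_portions(
        graph, pred, _walk_start(graph, pred, true_bifurcation_node), clip
    )
    truth_total = sum(truth_portions.values())
    covered = sum(
        min(truth_portions[e], pred_portions[e]) for e in truth_portions
        if e in pred_portions
    )
    excess = sum(
        p for e, p in pred_portions.items() if e not in truth_portions
    ) + sum(
        max(pred_portions[e] - truth_portions[e], 0.0)
        for e in pred_portions
        if e in truth_portions
    )
    overlap = covered / truth_total if truth_total > 0 else 1.0

    if overlap < 0.5:
        return VesselVerdict(artery, "FP_plus", overlap, excess)
    complete = truth_total - covered <= _LEN_TOL
    no_excess = excess <= _LEN_TOL
    if complete and no_excess:
        cat = "TP_star"
    elif no_excess:
        cat = "TP_minus"
    elif complete:
        cat = "TP_plus"
    else:
        cat = "TP_pm"
    return VesselVerdict(artery, cat, overlap, excess)


def _total(graph: VesselGraph, edges: list[str]) -> float:
    return sum(graph.edges[e].length for e in edges)


def evaluate_bifurcation(
    pred_node: str | None,
    truth_node: str | None,
    graph: VesselGraph,
    truth: Labeling,
    bifurcation: BifurcationId,
    tolerance_mm: float = 5.0,
) -> BifurcationVerdict:
    """Classify one bifurcation placement.

    ``within_5mm`` requires the geodesic (along-centerline) path from the
    predicted to the true node to stay on the bifurcation's own arteries as
    labeled in ground truth — a nearby node on an unrelated vessel is
    ``false`` no matter its Euclidean distance.
    """
    if pred_node is None or truth_node is None:
        return BifurcationVerdict(bifurcation, "false", math.inf)
    if pred_node == truth_node:
        return BifurcationVerdict(bifurcation, "correct", 0.0)
    g = graph.to_networkx()
    try:
        displacement = nx.dijkstra_path_length(g, pred_node, truth_node, weight="weight")
        node_path = nx.dijkstra_path(g, pred_node, truth_node, weight="weight")
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return BifurcationVerdict(bifurcation, "false", math.inf)
    if displacement > tolerance_mm:
        return BifurcationVerdict(bifurcation, "false", float(displacement))
    artery_edges = {
        eid for a in bifurcation.arteries for eid in truth.assignments[a]
    }
    for u, v in zip(node_path[:-1], node_path[1:]):
        data = g.get_edge_data(u, v)
        if not any(k in artery_edges for k in data):
            return BifurcationVerdict(bifurcation, "false", float(displacement))
    return BifurcationVerdict(bifurcation, "within_5mm", float(displacement))


def evaluate_labeling(
    pred: Labeling,
    truth: Labeling,
    graph: VesselGraph,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[VesselVerdict], list[BifurcationVerdict]]:
    """Evaluate all 14 arteries and all 6 bifurcations of one case."""
    vessel_verdicts = []
    for artery in ArteryId:
        start_bif, end_bif = ARTERY_BIFURCATIONS[artery]
        owner = start_bif if start_bif is not None else end_bif
        true_node = truth.bifurcation_nodes.get(owner) if owner else None
        vessel_verdicts.append(
            evaluate_vessel(
                pred.assignments[artery],
                truth.assignments[artery],
                artery,
                graph,
                true_node,
                outgoing_extent_mm=config.outgoing_extent_mm,
            )
        )
    bif_verdicts = [
        evaluate_bifurcation(
            pred.bifurcation_nodes.get(bif),
            truth.bifurcation_nodes.get(bif),
            graph,
            truth,
            bif,
            tolerance_mm=config.bifurcation_tolerance_mm,
        )
        for bif in BifurcationId
    ]
    return vessel_verdicts, bif_verdicts


@dataclass
class EvaluationReport:
    """Aggregated rates over a suite of evaluated cases."""

    vessel_table: pd.DataFrame       # per-artery fraction of each category
    bifurcation_table: pd.DataFrame  # per-bifurcation correct/<=5mm/false rates
    detection_rate: float            # fraction of vessel verdicts in TP_SUM + TN
    complete_rate: float             # fraction of vessel verdicts in TP* + TN
    n_cases: int

    def to_json_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "detection_rate": self.detection_rate,
            "complete_rate": self.complete_rate,
            "vessels": self.vessel_table.to_dict(orient="index"),
            "bifurcations": self.bifurcation_table.to_dict(orient="index"),
        }

    def write_csv(self, path) -> None:
        self.vessel_table.to_csv(path)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


def aggregate(
    results: list[tuple[list[VesselVerdict], list[BifurcationVerdict]]]
) -> EvaluationReport:
    """Per-artery and per-bifurcation rates plus the headline aggregates."""
    if not results:
        raise ValueError("aggregate needs at least one evaluated case")
    vessel_rows = [
        {"artery": v.artery.value, "category": v.category}
        for vessels, _ in results
        for v in vessels
    ]
    vdf = pd.DataFrame(vessel_rows, columns=["artery", "category"])
    vessel_table = (
        vdf.groupby("artery")["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(CATEGORIES), fill_value=0.0)
        .reindex(index=[a.value for a in ArteryId], fill_value=0.0)
    ) if len(vdf) else pd.DataFrame(
        0.0, index=[a.value for a in ArteryId], columns=list(CATEGORIES)
    )
    bif_rows = [
        {"bifurcation": b.bifurcation.value, "category": b.category}
        for _, bifs in results
        for b in bifs
    ]
    bdf = pd.DataFrame(bif_rows, columns=["bifurcation", "category"])
    bifurcation_table = (
        bdf.groupby("bifurcation")["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["correct", "within_5mm", "false"], fill_value=0.0)
        .reindex(index=[b.value for b in BifurcationId], fill_value=0.0)
    ) if len(bdf) else pd.DataFrame(
        0.0,
        index=[b.value for b in BifurcationId],
        columns=["correct", "within_5mm", "false"],
    )
    detection = float(vdf["category"].isin(DETECTED).mean()) if len(vdf) else 0.0
    complete = float(vdf["category"].isin(COMPLETE).mean()) if len(vdf) else 0.0
    return EvaluationReport(
        vessel_table=vessel_table,
        bifurcation_table=bifurcation_table,
        detection_rate=detection,
        complete_rate=complete,
        n_cases=len(results),
    )
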