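"""Ground-truth-labeled Circle of Willis phantoms.

Generates schematic but geometrically plausible cerebrovascular centerline
graphs (smooth 3-D polylines with tapering radii inside a ~120 mm cube),
together with a matching landmark atlas and a ground-truth labeling, so
that every pipeline stage can be exercised without patient data.

Covered phenomena:

* anatomical variants — fetal-type PCA (the PCA originates from the ICA
  instead of the basilar top), a single/azygos ACA 2, and a missing AComm;
* stroke occlusions — a fraction of an artery removed from its
  bifurcation end (1.0 removes the vessel entirely, as in an M1 occlusion
  whose sub-tree the segmentation never sees);
* segmentation artifacts — shortcut edges between non-adjacent nodes,
  duplicated parallel edges (loops), spurious unlabeled branches
  (veins/noise), and edges split at arbitrary interior points;
* registration error — the landmark atlas is sampled from the unperturbed
  normal template, then rigidly displaced and jittered per point.

All randomness flows through one generator seeded from the spec, so equal
specs produce bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.interpolate import CubicSpline

from .fusion import Labeling
from .landmarks import LandmarkAtlas, LandmarkSet
from .vessel_graph import (
    ArteryId,
    BifurcationId,
    GraphNode,
    VesselGraph,
    VesselSegment,
)

VARIANTS = ("normal", "fetal_pca_left", "fetal_pca_right", "missing_acomm", "single_aca2")
ARTIFACT_TYPES = ("shortcut", "loop", "spurious_branch", "split_edge")

#: centerline sampling step of the template polylines (mm)
_STEP_MM = 1.5
#: landmark spacing along the template arteries (mm)
_LANDMARK_SPACING_MM = 5.0

# schematic junction positions (mm); x: left+, y: posterior+, z: superior+
_JUNCTIONS: dict[str, tuple[float, float, float]] = {
    "VB": (0.0, 28.0, -12.0),   # vertebrobasilar junction
    "BT": (0.0, 25.0, 12.0),    # basilar top
    "ML": (26.0, -2.0, 18.0),   # left ICA terminus (Media-L)
    "MR": (-26.0, -2.0, 18.0),
    "AL": (4.0, -16.0, 26.0),   # left anterior (ACA-L)
    "AR": (-4.0, -16.0, 26.0),
}

_BIF_NODE: dict[BifurcationId, str] = {
    BifurcationId.VERTEBRAL: "N_VB",
    BifurcationId.POSTERIOR: "N_BT",
    BifurcationId.MEDIA_L: "N_ML",
    BifurcationId.MEDIA_R: "N_MR",
    BifurcationId.ACA_L: "N_AL",
    BifurcationId.ACA_R: "N_AR",
}


def _mirror(points: list[tuple[float, float, float]]):
    return [(-x, y, z) for (x, y, z) in points]


def _left_controls() -> dict[ArteryId, tuple[list, float, float]]:
    """Control polygons (and start/end radii, mm) of the left-side and
    midline arteries; right-side arteries are x-mirrored."""
    J = _JUNCTIONS
    return {
        ArteryId.ICA_L: (
            [(22, 8, -45), (24, 12, -25), (26, 14, -10), (24, 8, 2), (25, 2, 10), J["ML"]],
            4.0, 3.6,
        ),
        ArteryId.VERT_L: ([(10, 42, -45), (7, 38, -30), (3, 32, -20), J["VB"]], 2.8, 2.7),
        ArteryId.BASILAR: ([J["VB"], (0, 27, 0), J["BT"]], 3.2, 3.0),
        ArteryId.PCA_L: ([J["BT"], (8, 28, 14), (18, 32, 15), (30, 38, 14)], 2.3, 2.1),
        ArteryId.MCA_L: ([J["ML"], (33, -4, 19), (43, -1, 20), (52, 3, 22)], 2.6, 2.4),
        ArteryId.ACA1_L: ([J["ML"], (18, -8, 21), (10, -13, 24), J["AL"]], 2.1, 2.0),
        ArteryId.ACA2_L: ([J["AL"], (3, -22, 32), (3, -26, 42), (4, -24, 55)], 1.9, 1.7),
        ArteryId.ACOMM: ([J["AL"], (0, -16.5, 26), J["AR"]], 1.4, 1.4),
    }


_MIRRORED = {
    ArteryId.ICA_L: ArteryId.ICA_R,
    ArteryId.VERT_L: ArteryId.VERT_R,
    ArteryId.PCA_L: ArteryId.PCA_R,
    ArteryId.MCA_L: ArteryId.MCA_R,
    ArteryId.ACA1_L: ArteryId.ACA1_R,
    ArteryId.ACA2_L: ArteryId.ACA2_R,
}


def template_controls() -> dict[ArteryId, tuple[list, float, float]]:
    """Control polygons for all 14 arteries of the normal template."""
    left = _left_controls()
    out: dict[ArteryId, tuple[list, float, float]] = {}
    for artery, (ctrl, r0, r1) in left.items():
        out[artery] = ([tuple(map(float, p)) for p in ctrl], r0, r1)
        if artery in _MIRRORED:
            out[_MIRRORED[artery]] = (_mirror(ctrl), r0, r1)
    return out


def _sample_spline(controls: list, step: float = _STEP_MM) -> np.ndarray:
    pts = np.asarray(controls, dtype=float)
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    if t[-1] < 1e-9:
        raise ValueError("degenerate control polygon")
    if len(pts) < 3:
        n = max(2, int(np.ceil(t[-1] / step)) + 1)
        s = np.linspace(0.0, 1.0, n)[:, None]
        return pts[0] + s * (pts[1] - pts[0])
    cs = CubicSpline(t, pts, axis=0)
    n = max(2, int(np.ceil(t[-1] / step)) + 1)
    return np.asarray(cs(np.linspace(0.0, t[-1], n)))


def template_polylines() -> dict[ArteryId, np.ndarray]:
    """Noise-free centerline polylines of the normal 14-artery template."""
    return {a: _sample_spline(c[0]) for a, c in template_controls().items()}


@dataclass
class PhantomSpec:
    """Everything that determines one phantom, reproducibly."""

    seed: int = 0
    variant: str = "normal"
    #: (artery, fraction of arc length removed from the bifurcation end]
    occlusions: list[tuple[ArteryId, float]] = field(default_factory=list)
    #: artifact type -> count
    artifacts: dict[str, int] = field(default_factory=dict)
    landmark_rotation_deg: float = 8.0
    landmark_translation_mm: float = 6.0
    landmark_jitter_mm: float = 1.0
    centerline_noise_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        self.occlusions = [(ArteryId(a), float(f)) for a, f in self.occlusions]
        for artery, frac in self.occlusions:
            if not (0.0 < frac <= 1.0):
                raise ValueError(
                    f"occlusion fraction for {artery} must be in (0, 1], got {frac}"
                )
        for kind in self.artifacts:
            if kind not in ARTIFACT_TYPES:
                raise ValueError(f"unknown artifact type {kind!r}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "variant": self.variant,
            "occlusions": [[a.value, f] for a, f in self.occlusions],
            "artifacts": dict(self.artifacts),
            "landmark_rotation_deg": self.landmark_rotation_deg,
            "landmark_translation_mm": self.landmark_translation_mm,
            "landmark_jitter_mm": self.landmark_jitter_mm,
            "centerline_noise_mm": self.centerline_noise_mm,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


@dataclass(eq=False)
class Phantom:
    graph: VesselGraph
    truth: Labeling
    atlas: LandmarkAtlas
    spec: PhantomSpec


@dataclass(eq=False)
class _Draft:
    """Mutable graph-under-construction."""

    node_pos: dict[str, np.ndarray] = field(default_factory=dict)
    #: edge id -> (node_a, node_b, points oriented a->b, radii)
    edges: dict[str, tuple[str, str, np.ndarray, np.ndarray]] = field(default_factory=dict)
    #: artery -> ordered edge ids, oriented along the canonical walk
    truth_edges: dict[ArteryId, list[str]] = field(default_factory=dict)


def _radii_profile(rng: np.random.Generator, n: int, r0: float, r1: float) -> np.ndarray:
    """Linearly tapering radii with a smooth ±10 % along-edge variation."""
    t = np.linspace(0.0, 1.0, n)
    base = r0 + (r1 - r0) * t
    freq = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return base * (1.0 + 0.1 * np.sin(2.0 * np.pi * freq * t + phase))


def _arc_cumlen(points: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    )


def _build_draft(spec: PhantomSpec, rng: np.random.Generator) -> _Draft:
    controls = template_controls()
    draft = _Draft()

    junctions = {f"N_{k}": np.asarray(v, float) for k, v in _JUNCTIONS.items()}
    variant = spec.variant

    present = dict(controls)
    if variant == "missing_acomm":
        del present[ArteryId.ACOMM]
    if variant == "single_aca2":
        am = np.asarray([0.0, -16.0, 26.0])
        junctions["N_AM"] = am
        del junctions["N_AL"], junctions["N_AR"]
        del present[ArteryId.ACOMM], present[ArteryId.ACA2_L]
        c, r0, r1 = present[ArteryId.ACA1_L]
        present[ArteryId.ACA1_L] = (c[:-1] + [tuple(am)], r0, r1)
        c, r0, r1 = present[ArteryId.ACA1_R]
        present[ArteryId.ACA1_R] = (c[:-1] + [tuple(am)], r0, r1)
        present[ArteryId.ACA2_R] = (
            [tuple(am), (0, -22, 32), (0, -26, 42), (0, -24, 55)], 1.9, 1.7,
        )

    fetal_side = {"fetal_pca_left": "L", "fetal_pca_right": "R"}.get(variant)

    def endpoint_node(artery: ArteryId, which: str, point: np.ndarray) -> str:
        # junction nodes by position; free ends get their own node
        for nid, pos in junctions.items():
            if np.linalg.norm(pos - point) < 1e-6:
                return nid
        nid = f"N_{artery.value}_{which}"
        draft.node_pos[nid] = np.asarray(point, float)
        return nid

    draft.node_pos.update(junctions)

    fetal_anchor: dict[str, np.ndarray] = {}
    for artery in sorted(present, key=lambda a: a.value):
        ctrl, r0, r1 = present[artery]
        pts = _sample_spline(ctrl)
        if fetal_side and artery == ArteryId(f"PCA_{fetal_side}"):
            continue  # rebuilt below, re-rooted on the ICA
        if fetal_side and artery == ArteryId(f"ICA_{fetal_side}"):
            # split the ICA ~12 mm before its terminus; the fetal PCA
            # originates there instead of at the basilar top
            cum = _arc_cumlen(pts)
            i = int(np.searchsorted(cum, cum[-1] - 12.0))
            i = min(max(i, 1), len(pts) - 2)
            fnode = f"N_F_{fetal_side}"
            draft.node_pos[fnode] = pts[i].copy()
            fetal_anchor[fetal_side] = pts[i].copy()
            a = endpoint_node(artery, "start", pts[0])
            b = endpoint_node(artery, "end", pts[-1])
            r = _radii_profile(rng, len(pts), r0, r1)
            e1, e2 = f"E_{artery.value}_1", f"E_{artery.value}_2"
            draft.edges[e1] = (a, fnode, pts[: i + 1], r[: i + 1])
            draft.edges[e2] = (fnode, b, pts[i:], r[i:])
            draft.truth_edges[artery] = [e1, e2]
            continue
        a = endpoint_node(artery, "start", pts[0])
        b = endpoint_node(artery, "end", pts[-1])
        eid = f"E_{artery.value}"
        draft.edges[eid] = (a, b, pts, _radii_profile(rng, len(pts), r0, r1))
        draft.truth_edges[artery] = [eid]

    if fetal_side:
        artery = ArteryId(f"PCA_{fetal_side}")
        sign = 1.0 if fetal_side == "L" else -1.0
        f = fetal_anchor[fetal_side]
        ctrl = [
            tuple(f),
            (f[0] + sign * 2.0, f[1] + 12.0, f[2] + 4.0),
            (sign * 22.0, 30.0, 14.0),
            (sign * 30.0, 38.0, 14.0),
        ]
        pts = _sample_spline(ctrl)
        b = endpoint_node(artery, "end", pts[-1])
        eid = f"E_{artery.value}"
        draft.edges[eid] = (
            f"N_F_{fetal_side}", b, pts, _radii_profile(rng, len(pts), 2.3, 2.1)
        )
        draft.truth_edges[artery] = [eid]

    return draft


def _truth_bifurcation_nodes(spec: PhantomSpec) -> dict[BifurcationId, str]:
    nodes = dict(_BIF_NODE)
    if spec.variant == "single_aca2":
        nodes[BifurcationId.ACA_L] = "N_AM"
        nodes[BifurcationId.ACA_R] = "N_AM"
    return nodes


def _apply_occlusions(draft: _Draft, spec: PhantomSpec) -> None:
    occ_counter = 0
    for artery, frac in spec.occlusions:
        edges = draft.truth_edges.get(artery, [])
        if not edges:
            continue
        # the canonical walk starts at the artery's bifurcation (outer
        # arteries) or ends there (incoming); occlude from that end
        from .vessel_graph import ARTERY_BIFURCATIONS

        start_bif, end_bif = ARTERY_BIFURCATIONS[artery]
        from_start = start_bif is not None
        walk = edges if from_start else list(reversed(edges))
        total = sum(
            _arc_cumlen(draft.edges[eid][2])[-1] for eid in walk
        )
        target = frac * total
        removed = 0.0
        for eid in list(walk):
            a, b, pts, radii = draft.edges[eid]
            # orient the edge along the occlusion direction
            if not from_start:
                a, b, pts, radii = b, a, pts[::-1], radii[::-1]
            length = _arc_cumlen(pts)[-1]
            if removed + length <= target + 1e-9:
                del draft.edges[eid]
                draft.truth_edges[artery].remove(eid)
                removed += length
                continue
            cut = target - removed
            if cut <= 1e-9:
                break
            cum = _arc_cumlen(pts)
            j = int(np.searchsorted(cum, cut))
            j = min(max(j, 1), len(pts) - 2)
            new_node = f"N_occ{occ_counter}"
            occ_counter += 1
            new_pts, new_radii = pts[j:], radii[j:]
            if not from_start:
                new_pts, new_radii = new_pts[::-1], new_radii[::-1]
                draft.edges[eid] = (draft.edges[eid][0], new_node, new_pts, new_radii)
            else:
                draft.edges[eid] = (new_node, draft.edges[eid][1], new_pts, new_radii)
            draft.node_pos[new_node] = new_pts[0 if from_start else -1].copy()
            break
        # prune nodes that lost all their edges
        used = {n for (na, nb, _, _) in draft.edges.values() for n in (na, nb)}
        for nid in [n for n in draft.node_pos if n not in used]:
            del draft.node_pos[nid]


def _node_degree(draft: _Draft) -> dict[str, int]:
    deg: dict[str, int] = {n: 0 for n in draft.node_pos}
    for na, nb, _, _ in draft.edges.values():
        deg[na] += 1
        deg[nb] += 1
    return deg


def _apply_artifacts(draft: _Draft, spec: PhantomSpec, rng: np.random.Generator) -> None:
    counts = dict(spec.artifacts)

    for k in range(counts.get("split_edge", 0)):
        labeled = sorted(
            eid
            for edges in draft.truth_edges.values()
            for eid in edges
            if len(draft.edges[eid][2]) >= 4
        )
        if not labeled:
            break
        eid = labeled[rng.integers(len(labeled))]
        a, b, pts, radii = draft.edges[eid]
        i = int(rng.integers(1, len(pts) - 1))
        nid = f"N_split{k}"
        draft.node_pos[nid] = pts[i].copy()
        e1, e2 = f"{eid}_s1a{k}", f"{eid}_s2a{k}"
        del draft.edges[eid]
        draft.edges[e1] = (a, nid, pts[: i + 1], radii[: i + 1])
        draft.edges[e2] = (nid, b, pts[i:], radii[i:])
        for edges in draft.truth_edges.values():
            if eid in edges:
                j = edges.index(eid)
                edges[j : j + 1] = [e1, e2]

    for k in range(counts.get("shortcut", 0)):
        ids = sorted(draft.node_pos)
        adjacent = {
            frozenset((na, nb)) for (na, nb, _, _) in draft.edges.values()
        }
        pairs = [
            (u, v)
            for i, u in enumerate(ids)
            for v in ids[i + 1 :]
            if frozenset((u, v)) not in adjacent
            and 5.0 < np.linalg.norm(draft.node_pos[u] - draft.node_pos[v]) < 40.0
        ]
        if not pairs:
            break
        u, v = pairs[rng.integers(len(pairs))]
        pts = np.linspace(draft.node_pos[u], draft.node_pos[v], 5)
        draft.edges[f"X_shortcut{k}"] = (u, v, pts, np.full(5, 1.2))

    for k in range(counts.get("loop", 0)):
        ids = sorted(draft.edges)
        eid = ids[rng.integers(len(ids))]
        a, b, pts, radii = draft.edges[eid]
        chord = pts[-1] - pts[0]
        norm = np.linalg.norm(chord)
        if norm < 1e-9:
            continue
        raw = rng.normal(size=3)
        perp = raw - (raw @ chord) / norm**2 * chord
        perp /= max(np.linalg.norm(perp), 1e-9)
        t = np.linspace(0.0, 1.0, len(pts))
        bump = (2.0 * np.sin(np.pi * t))[:, None] * perp
        draft.edges[f"X_loop{k}"] = (a, b, pts + bump, radii * 0.8)

    for k in range(counts.get("spurious_branch", 0)):
        ids = sorted(draft.node_pos)
        nid = ids[rng.integers(len(ids))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(10.0, 20.0)
        start = draft.node_pos[nid]
        end = start + direction * length
        pts = np.linspace(start, end, 8)
        # slight curvature so spurious branches are not perfectly straight
        t = np.linspace(0.0, 1.0, 8)
        curve = rng.normal(size=3)
        curve -= (curve @ direction) * direction
        pts = pts + (2.0 * np.sin(np.pi * t))[:, None] * curve / max(
            np.linalg.norm(curve), 1e-9
        )
        new_node = f"N_spur{k}"
        draft.node_pos[new_node] = pts[-1].copy()
        draft.edges[f"X_spur{k}"] = (nid, new_node, pts, np.full(8, 1.2))


def _apply_noise(draft: _Draft, spec: PhantomSpec, rng: np.random.Generator) -> None:
    if spec.centerline_noise_mm <= 0:
        return
    for eid in sorted(draft.edges):
        a, b, pts, radii = draft.edges[eid]
        if len(pts) > 2:
            jitter = rng.normal(0.0, spec.centerline_noise_mm, size=(len(pts) - 2, 3))
            pts = pts.copy()
            pts[1:-1] += jitter
            draft.edges[eid] = (a, b, pts, radii)


def make_template_atlas(spacing: float = _LANDMARK_SPACING_MM) -> LandmarkAtlas:
    """Landmark atlas sampled directly on the normal template centerlines.

    Landmarks are a subset of the polyline vertices (roughly one per
    ``spacing`` mm, at least 5 per artery, always including both ends), so
    the unperturbed atlas lies exactly on the template centerlines.
    """
    sets = {}
    for artery, pts in template_polylines().items():
        n = len(pts)
        step_est = _arc_cumlen(pts)[-1] / (n - 1)
        k = max(1, int(round(spacing / step_est)))
        k = max(1, min(k, (n - 1) // 4))
        idx = list(range(0, n, k))
        if idx[-1] != n - 1:
            idx.append(n - 1)
        sets[artery] = LandmarkSet(artery=artery, points=pts[idx])
    return LandmarkAtlas(sets=sets)


def _perturb_atlas(
    atlas: LandmarkAtlas, spec: PhantomSpec, rng: np.random.Generator
) -> LandmarkAtlas:
    angle = np.deg2rad(spec.landmark_rotation_deg)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t_dir = rng.normal(size=3)
    t_dir /= np.linalg.norm(t_dir)
    center = atlas.all_points().mean(axis=0)
    # rotate about the atlas centroid, then translate
    t = center - R @ center + t_dir * spec.landmark_translation_mm
    moved = atlas.transformed(R, t)
    if spec.landmark_jitter_mm > 0:
        moved = LandmarkAtlas(
            sets={
                a: LandmarkSet(
                    artery=a,
                    points=s.points
                    + rng.normal(0.0, spec.landmark_jitter_mm, size=s.points.shape),
                )
                for a, s in sorted(moved.sets.items())
            }
        )
    return moved


def generate(spec: PhantomSpec) -> Phantom:
    """Build one phantom: graph + ground truth + perturbed landmark atlas."""
    rng = np.random.default_rng(spec.seed)
    draft = _build_draft(spec, rng)
    _apply_occlusions(draft, spec)
    _apply_artifacts(draft, spec, rng)
    _apply_noise(draft, spec, rng)

    nodes = [GraphNode(id=nid, position=pos) for nid, pos in sorted(draft.node_pos.items())]
    edges = []
    for eid in sorted(draft.edges):
        a, b, pts, radii = draft.edges[eid]
        pts = pts.copy()
        pts[0] = draft.node_pos[a]
        pts[-1] = draft.node_pos[b]
        edges.append(VesselSegment(id=eid, nodes=(a, b), points=pts, radii=radii))
    graph = VesselGraph.from_parts(nodes, edges)

    bif_nodes = {
        bif: (nid if nid in graph.nodes else None)
        for bif, nid in _truth_bifurcation_nodes(spec).items()
    }
    truth = Labeling(
        assignments={a: list(draft.truth_edges.get(a, [])) for a in ArteryId},
        bifurcation_nodes=dict(bif_nodes),
        provenance={a: "truth" for a in ArteryId},
    )

    atlas = _perturb_atlas(make_template_atlas(), spec, rng)
    return Phantom(graph=graph, truth=truth, atlas=atlas, spec=spec)


def scenario_suite(n_seeds: int) -> list[PhantomSpec]:
    """Deterministic mixture of scenario specs: clean, media occlusion,
    artifact-laden, fetal PCA, single ACA 2 and missing AComm, with seeds
    0..n_seeds-1 per scenario class."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    specs: list[PhantomSpec] = []
    for seed in range(n_seeds):
        media = ArteryId.MCA_L if seed % 2 == 0 else ArteryId.MCA_R
        fetal = "fetal_pca_right" if seed % 2 == 0 else "fetal_pca_left"
        specs.append(PhantomSpec(seed=seed))
        specs.append(PhantomSpec(seed=seed, occlusions=[(media, 1.0)]))
        specs.append(
            PhantomSpec(
                seed=seed,
                artifacts={"shortcut": 2, "loop": 1, "spurious_branch": 3, "split_edge": 2},
            )
        )
        specs.append(PhantomSpec(seed=seed, variant=fetal))
        specs.append(PhantomSpec(seed=seed, variant="single_aca2"))
        specs.append(PhantomSpec(seed=seed, variant="missing_acomm"))
    return specs
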