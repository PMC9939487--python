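"""Per-artery landmark sets and rigid ICP alignment onto centerlines.

Landmarks are ordered 3-D points drawn along each artery of interest in an
atlas/template frame and are assumed to be roughly pre-aligned to patient
space (the upstream deformable atlas registration is outside this package;
the synthetic generator emulates its residual error as a rigid misalignment
plus per-point jitter). A final rigid point-to-point ICP onto the pooled
segmentation centerline points removes the bulk of that misalignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .vessel_graph import (
    ARTERY_BIFURCATIONS,
    ArteryId,
    BifurcationId,
    VesselGraph,
)


class AlignmentError(RuntimeError):
    """ICP could not run (empty atlas, degenerate point cloud, ...)."""


@dataclass(eq=False)
class LandmarkSet:
    """Ordered landmarks of one artery, in canonical artery orientation.

    The first and last entries are the artery's end landmarks; for arteries
    bordering a labeled bifurcation the corresponding end (see
    ``ARTERY_BIFURCATIONS``) is the bifurcation-end landmark.
    """

    artery: ArteryId
    points: np.ndarray

    def __post_init__(self) -> None:
        self.artery = ArteryId(self.artery)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"{self.artery}: landmark points must be (M, 3)")
        if len(self.points) < 2:
            raise ValueError(f"{self.artery}: need at least 2 landmarks")

    @property
    def end_indices(self) -> tuple[int, int]:
        return (0, len(self.points) - 1)

    def bifurcation_end_index(self, bifurcation: BifurcationId) -> int:
        start, end = ARTERY_BIFURCATIONS[self.artery]
        if bifurcation == start:
            return 0
        if bifurcation == end:
            return len(self.points) - 1
        raise ValueError(f"{self.artery} does not border {bifurcation}")


@dataclass(eq=False)
class LandmarkAtlas:
    """One landmark set per artery of interest."""

    sets: dict[ArteryId, LandmarkSet]

    def __post_init__(self) -> None:
        self.sets = {ArteryId(a): s for a, s in self.sets.items()}

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def all_points(self) -> np.ndarray:
        if not self.sets:
            return np.zeros((0, 3))
        return np.vstack([self.sets[a].points for a in sorted(self.sets)])

    def bifurcation_end_landmarks(self, bifurcation: BifurcationId) -> np.ndarray:
        """The bifurcation-end landmark of each adjacent artery, (k, 3)."""
        pts = []
        for artery in bifurcation.arteries:
            lm = self.sets.get(artery)
            if lm is None:
                continue
            pts.append(lm.points[lm.bifurcation_end_index(bifurcation)])
        if not pts:
            return np.zeros((0, 3))
        return np.asarray(pts)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkAtlas":
        """Apply the rigid map ``x -> R x + t`` to every landmark."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        return LandmarkAtlas(
            sets={
                a: LandmarkSet(artery=a, points=s.points @ R.T + t)
                for a, s in self.sets.items()
            }
        )


@dataclass
class ICPResult:
    atlas: LandmarkAtlas
    rotation: np.ndarray
    translation: np.ndarray
    rms_mm: float
    #: RMS nearest-neighbor residual after each iteration (non-increasing)
    history: list[float]
    iterations: int


def _kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (rotation + translation, no scale)."""
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ sc
    return R, t


def icp_align(
    atlas: LandmarkAtlas,
    graph: VesselGraph,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> ICPResult:
    """Rigidly align all atlas landmarks onto the pooled centerline points.

    Point-to-point ICP: alternate nearest-neighbor correspondence against
    every centerline point of every edge with a closed-form rigid fit, until
    the RMS residual changes by less than ``tol`` (mm) or ``max_iter`` is
    reached. A single rigid transform is applied to the whole atlas.
    """
    if len(atlas) == 0:
        raise AlignmentError("empty landmark atlas")
    cloud = graph.all_centerline_points()
    if len(cloud) < 3:
        raise AlignmentError("graph has fewer than 3 centerline points")
    centered = cloud - cloud.mean(axis=0)
    # degenerate (coincident / collinear) clouds cannot anchor a rotation
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise AlignmentError("centerline point cloud is collinear or coincident")

    tree = cKDTree(cloud)
    source0 = atlas.all_points()
    R = np.eye(3)
    t = np.zeros(3)
    history: list[float] = []
    prev_rms = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        current = source0 @ R.T + t
        _, idx = tree.query(current)
        matched = cloud[idx]
        R, t = _kabsch(source0, matched)
        current = source0 @ R.T + t
        dist, _ = tree.query(current)
        rms = float(np.sqrt(np.mean(dist**2)))
        history.append(rms)
        if abs(prev_rms - rms) < tol:
            break
        prev_rms = rms
    return ICPResult(
        atlas=atlas.transformed(R, t),
        rotation=R,
        translation=t,
        rms_mm=history[-1],
        history=history,
        iterations=iterations,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def atlas_to_dict(atlas: LandmarkAtlas) -> dict:
    return {
        "arteries": [
            {
                "artery": a.value,
                "points": [[float(x) for x in p] for p in atlas.sets[a].points],
            }
            for a in sorted(atlas.sets)
        ]
    }


def atlas_from_dict(data: dict) -> LandmarkAtlas:
    if "arteries" not in data:
        raise ValueError("landmark document: missing field 'arteries'")
    sets = {}
    for entry in data["arteries"]:
        artery = ArteryId(entry["artery"])
        sets[artery] = LandmarkSet(artery=artery, points=entry["points"])
    return LandmarkAtlas(sets=sets)


def write_atlas(atlas: LandmarkAtlas, path) -> None:
    with open(path, "w") as fh:
        json.dump(atlas_to_dict(atlas), fh, indent=1)


def read_atlas(path) -> LandmarkAtlas:
    with open(path) as fh:
        return atlas_from_dict(json.load(fh))
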