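# Methods

## Problem and model

`cowlabel` assigns anatomical labels to cerebrovascular centerline graphs
around the Circle of Willis (CoW). The input is a patient model
`G(V, E)`: nodes are bifurcations and vessel endpoints with 3-D positions
(mm), and each edge carries an ordered centerline polyline with per-point
radii. Such graphs — typically skeletonized from CTA segmentations — are
artifact-prone: segments may be missing (stroke occlusions, segmentation
gaps) or artificially created (shortcuts, loops, spurious branches), and
junctions may be split into chains of short edges. The package labels the
14 major arteries (ICA, vertebral, basilar, ACA 1/2, AComm, middle and
posterior cerebral, each side where applicable) and the 6 bifurcations
that join them (vertebral confluence, basilar top, left/right ICA
terminus, left/right anterior).

The design premise is that bifurcations, not individual arteries, are the
stable unit of labeling: when each bifurcation is matched as a whole — one
node plus one optimal path per adjacent artery — adjacent labels are
consistent by construction and a missing artery does not prevent
identifying the junction it should have joined.

## Pipeline

1. **Registration.** Per-artery landmark chains (ordered 3-D points
   drawn along each artery in a template frame, assumed roughly
   pre-aligned to patient space) are rigidly aligned to the pooled
   centerline points by point-to-point ICP: nearest-neighbor
   correspondences against every centerline vertex, closed-form rigid fit
   per iteration, no scale, no outlier trimming. Defaults: `max_iter=50`,
   `tol=1e-3 mm`. Trimming is deliberately omitted; the generous candidate
   threshold downstream absorbs residual registration error.

2. **Candidate graphs.** For every artery `a` and edge `e` a distance
   score is computed from the per-point nearest-landmark distances `s_n`:

       d_a(e) = mean_n(s_n) + sqrt( mean_n( (s_n − min_i s_i)² ) )

   The second term is a spread statistic (a standard deviation taken
   against the minimum rather than the mean) that penalizes edges running
   perpendicular to the landmark chain. Centerline points whose nearest
   landmark is one of the chain's two *end* landmarks are omitted from
   both terms, so an edge extending past the artery's anatomical extent is
   not punished for its overhang. Edges with `d_a(e) < 20 mm` form the
   artery's candidate sub-graph; candidate sets of different arteries may
   overlap, and empty sets are legal (possibly missing artery).

   *Robustness guard.* The score is an average over the segment, so it is
   only meaningful when a substantial part of the segment is matched by
   interior landmarks. If fewer than 25 % of an edge's points survive the
   end-landmark omission, the edge receives the +inf sentinel, exactly
   like a fully-omitted edge. Without this guard a single junction-area
   point of a *neighboring* artery's edge can survive omission under
   landmark jitter and yield a tiny `d_a(e)` that the cost function (which
   multiplies the full edge length by `1/d`) turns into a dominant score;
   with it, genuine edges (≈ 90 % retention) and foreign edges (≤ ~15 %)
   separate cleanly. The threshold sits between those two regimes and is
   not sensitive within ±10 points.

3. **Bifurcation matching.** The cost of one edge, given the transition
   weights `w` accumulated along a path (starting at `[1]`), is

       c_a(e, w) = (w_N + Π_i w_i)/2 · l_e / d_a(e) · (1 + δ·r_e)

   with edge length `l_e`, mean radius `r_e` and `δ = 0.1` (radius matters,
   but weakly). Transition weights map the dot product of the unit travel
   directions at a shared node linearly onto `[0.2, 1.0]`
   (`w = 0.6 + 0.4·u·v`): straight continuation → 1.0, reversal → 0.2.
   Directions are measured as the chord from the node to the centerline
   point at arc length `min(3 mm, l_e/2)`, which is robust to curvature.
   `d_a(e)` is floored at 0.1 mm inside the cost — sub-resolution
   distances are geometrically meaningless and would otherwise explode the
   quotient.

   The path score `q_a(e, v, E_a, w)` maximizes the sum of edge costs over
   all edge-simple continuations: it adds `c_a(e, w)`, then recurses into
   the best candidate neighbor at the far node with the current edge
   removed from the candidate set and the new transition weight appended.
   A recursion guard (`max_path_edges=64`) catches pathological loop-dense
   graphs.

   For each bifurcation, candidate nodes are those within 15 mm of the
   bifurcation-end landmarks of its three arteries. At each candidate
   node, every injective assignment of distinct incident edges to the
   three arteries is scored (6 configurations at degree 3, P(d,3) at
   higher degree); at degree < 3, partial assignments leave arteries
   unassigned with score 0 — this is what lets an occluded-media
   bifurcation still match on the strength of the ICA and ACA 1 alone.
   An assigned edge outside its artery's candidate set also scores 0.
   The configuration score is the unnormalized mean of the three artery
   scores; the node with the best configuration wins. Ties break by
   ascending node id, then by the deterministic configuration order. The
   runner-up node and its best configuration are recorded for the
   anterior disambiguation.

4. **Fusion.** The six bifurcation sub-graphs overlap on the inner
   arteries (AComm, ACA 1 L/R, basilar), which both bordering
   bifurcations propose. Fusion proceeds in a fixed order:

   - *Anterior resolution.* If both anterior bifurcations chose the same
     node, the lower-scoring match's runner-up is promoted when it reaches
     80 % of that match's best score (two distinct ACA 2s assumed);
     otherwise the shared node is kept, which is the single/azygos-ACA 2
     configuration. The 80 % comparison is against the lower match's own
     best score; the grammar of the rule also admits comparing against the
     other side's best, which we do not do.
   - *Inner merges.* Overlapping paths reduce to the arc-length shortest
     path between the two bifurcation nodes within the union of both
     paths; disjoint paths are joined through the global shortest path
     between their far endpoints; if no connecting route exists the artery
     is kept as two fragments and marked `interrupted` (stroke case).
   - *Outer/incoming copy.* Remaining paths are copied in descending
     order of their bifurcation's score; an edge already labeled truncates
     the incoming path at the collision (the higher-scoring bifurcation
     keeps it).
   - *Tracing.* Outer and incoming arteries often extend past the
     landmark coverage, so from each free end the unlabeled incident edge
     with the highest transition weight is appended repeatedly, provided
     the transition angle exceeds 120° (weight > 0.8 under the map above);
     tracing stops at labeled edges and never revisits an edge.

## Baseline

The distance-driven baseline shares the registration and the exact
distance score. Edges are processed in descending mean-radius order
(ties: ascending edge id) and an edge joins its *closest* artery set when
`d_a(e) < 20 mm` and a neighboring edge already belongs to that set; the
first edge of each set is exempt from the neighbor condition (applied per
artery set — otherwise only one artery could ever seed). Sweeps repeat to
a fixed point. Each artery's path is then the longest shortest path
(arc-length weighted) within its assigned sub-graph, which suppresses
branching but enforces no shared bifurcation nodes; a bifurcation is
credited only when all three artery paths happen to share a terminal node.

## Synthetic phantoms

Real CTA data cannot ship with the package, so every stage is exercised on
generated phantoms: a schematic 14-artery CoW template (piecewise-cubic
centerlines through anatomically placed junctions in a ~120 mm cube;
radii ICA 4 mm tapering to AComm 1.4 mm, with a smooth ±10 % along-edge
variation so radius ordering is non-degenerate). A spec controls

- *variants*: fetal-type PCA (re-rooted on the ICA ~12 mm below the
  terminus, splitting the ICA in two edges), single/azygos ACA 2 (both
  ACA 1s meet at one midline node; no AComm), missing AComm;
- *occlusions*: a fraction of an artery's arc length removed from its
  bifurcation end (1.0 removes it entirely);
- *artifacts*: shortcut edges between non-adjacent nodes, duplicated
  parallel edges (loops), spurious branches from random nodes
  (veins/noise), and splits of labeled edges at random interior vertices;
- *noise*: centerline vertex jitter (default σ = 0.3 mm) and landmark
  misalignment — a rigid rotation + translation (defaults 8°, 6 mm) plus
  per-point jitter (default σ = 1 mm) emulating the upstream atlas
  registration error.

Landmarks are sampled from the unperturbed template at every ~5 mm
(always ≥ 5 per artery, including both ends), as exact subsets of the
template polyline vertices. All randomness flows through a single
generator seeded from the spec; equal specs give bit-identical phantoms.

What the phantoms do *not* emulate: patient-specific tortuosity and
caliber variation, non-rigid registration residue beyond a rigid offset +
jitter, intensity-dependent segmentation dropouts, posterior communicating
arteries, and graphs an order of magnitude larger than the CoW
neighborhood. Passing phantom suites therefore demonstrates the
algorithmic properties (consistency, occlusion tolerance, artifact
robustness, the documented failure modes) — not clinical accuracy on real
CTA scans.

## Evaluation

Per-vessel verdicts use an 8-class taxonomy: TP\* complete, TP− under-,
TP+ over-, TP± misestimated, TN dismissed (absent and not labeled), FN
missed, FP+ misplaced, FP− wrongly detected. "Detection" aggregates the
four TP classes plus TN; "complete" counts TP\* plus TN. Outgoing arteries
(ACA 2, MCA, PCA) branch quickly, so both prediction and truth are clipped
to 20 mm of arc length from the bifurcation before comparison (prediction
clipped from its own bifurcation-side end); incoming and inner arteries
are assessed over their full length. Where a visual review needs no
numeric boundary, an automatic one does: "main part found" is
operationalized as ≥ 0.5 of the (clipped) truth arc length covered, and
sub-micrometer length differences (1e-6 mm) count as exact. These two
conventions are artifacts of automation, not statements about any
particular dataset.

Bifurcation placements are `correct` (same node), `within_5mm`, or
`false`. Displacement is geodesic — measured along the centerlines, not
Euclidean — and the `within_5mm` class additionally requires the geodesic
path to run entirely on the bifurcation's own arteries as labeled in
ground truth, so a nearby node on an unrelated vessel is `false` no matter
its Euclidean distance.

## Known limitations

- **Fetal-type PCA** breaks the fixed bifurcation-adjacency assumption by
  construction: the fetal-side PCA attaches to the ICA, the posterior
  bifurcation degrades to degree 2, and the PCA on that side is missed or
  mislabeled. This is the method's documented failure mode and is asserted
  (not worked around) in the test suite.
- **Unilateral occlusions bias the registration.** A missing artery
  leaves its landmark chain without corresponding structure; with no
  outlier trimming the rigid ICP optimum drags everything toward the
  remaining vessels (~3–4 mm locally in media-occlusion phantoms). The
  CoW survives this except at its most ambiguous spot: the two ACA 2s run
  ~7 mm apart, and in a small fraction of occlusion phantoms (~5–10 %) the
  drift lets an anterior bifurcation match the contralateral node. The
  80 % runner-up rule only re-examines the lower-scoring anterior match,
  so it cannot repair the case where the higher-scoring one is wrong.
- **AComm over-claiming.** When the AComm is absent but its neighbors
  survive, the length-driven score can still assemble a short AComm path
  from anterior edges (FP−); conversely the shortest inner artery benefits
  least from the length term. The anterior region is the least reliable
  part of the labeling, consistent with the method's design trade-offs.
- The evaluation thresholds (0.5 overlap, 1e-6 mm exactness) are declared
  conventions; rates move smoothly, not discontinuously, under reasonable
  alternatives.

## Problem sizes and runtimes

The shipped suites use 20 clean, 20 media-occlusion, 40 artifact and 10
fetal phantoms plus 200 random graphs for the recursion oracle — sizes at
which every property above is decisive yet the whole acceptance run
completes in well under a minute on one CPU. Scores and matches are exact
computations (no sampling), so larger suites change only the confidence of
the rate estimates, not the individual case outcomes.
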