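# Methods

## The measurement model

A scanned plate holds dissected seedlings (or coleoptiles) that do not touch,
over a blue backing, with a horizontal scale bar of known physical length in
one bottom corner. Every trait is defined on the skeleton graph of a
segmented plant:

* **Nodes and edges.** Skeleton pixels with one 8-neighbor are terminal
  nodes; more than two, branching nodes; exactly two, edge points. Mutually
  adjacent branching pixels — a routine thinning artifact at junctions — are
  collapsed into a single branching node placed at the member pixel nearest
  the cluster centroid. Edge polylines are extended through the cluster to
  that representative pixel, so collapsing a junction to a point never
  shortens a geodesic.
* **Lengths.** An edge's length is the digital geodesic length of its pixel
  polyline: 1 per orthogonal step, √2 per diagonal step. This metric is
  exact for axis-aligned and 45°-diagonal paths and overestimates
  intermediate angles by up to ~8 % (chamfer anisotropy); see "What the
  generator does and does not emulate".
* **Pruning.** One pass over the terminal edges of the freshly built graph:
  every terminal edge strictly shorter than `prune_threshold_px` is deleted
  with its terminal node, except the basal edge — the terminal edge whose
  endpoint is the bottom-most node (ties to the smaller column). Junctions
  left with degree 2 are then dissolved, merging their edges
  length-conservingly. Pruning is deliberately not iterated: spurs are
  assumed to hang off junctions whose remaining edges are long, which holds
  for plate-grid artifacts and cut-off ends. Coleoptile runs skip pruning,
  since a whole coleoptile may be shorter than the threshold.
* **Traits.** With Dijkstra distances from the lowest node: total shoot is
  the distance to the highest node (smallest row, ties to the smaller
  column); internode is the distance to the first branching node on that
  path; each off-path subtree at a path junction is a leaf measured as the
  longest geodesic from its junction, and the apical stretch of the path
  above the last junction is also a leaf. Leaves are numbered by junction
  from the base; at a shared junction the longer leaf gets the lower number,
  reflecting that older leaves are longer in a 7-day seedling. A branchless
  plant reports internode = total shoot and no leaves (with a warning)
  rather than failing: without a junction the blade cannot be delimited.
  Coleoptile length is the longest geodesic from the lowest node of the
  unpruned graph, so a small fork near the tip resolves to the longer
  branch.

## Parameters

| parameter | default | unit | why |
|---|---|---|---|
| `prune_threshold_px` | 50 | px | spurs from plate grid / cut-off ends are shorter than this; the basal edge is always exempt |
| `min_detection_area_px` | 500 | px | components at or above this are plants; *at* the minimum is kept, so a blob exactly at the setting is detected |
| `scale_bar_length_mm` | 20 | mm | the 2-cm bar scanned with every plate |
| `hsv_bounds` | (55, 135, 70, 255, 50, 255) | 0–255 | inclusive green window; rejects blue background, pale grid lines, dark bar |
| `corner_window_frac` | 0.15 | – | fraction of height/width searched for the bar; raise it when the bar is wide relative to the scan |
| `median_kernel_px` | 5 | px | removes scanner salt noise below this scale |
| bilateral diameter / σ_color / σ_space | 5 / 25 / 3 | px, 8-bit, px | homogenizes tissue color without moving organ boundaries |

Segmentation-polarity and bar-detection choices: the scale-bar corner window
is excised from plant segmentation before labeling; bar detection always
thresholds the grayscale corner window (median-filtered at 3 px to shed salt
noise) and takes the class whose mean is farther from the window border as
foreground, then the largest component's column extent as the bar width.
The same border-contrast rule gives the foreground polarity of coleoptile
thresholding, so pale organs on a dark backing and dark objects on a pale
plate both resolve correctly.

## The synthetic-scene generator

The generator (`shootscan.fixtures`) stands in for scans that were never
deposited. It emulates the imaging conventions — blue background, green
plants with 1–4 open leaves laid out without overlap, pale plate grid lines,
a dark 20-mm bar in a lower corner, scanner noise — at a default calibration
of 390 px per 20 mm (≈ 0.051 mm/px, a quarter of the original 600-dpi
resolution, chosen so a full test run stays in minutes). Organ magnitudes
follow a 7-day seedling: internode ≈ 600 px (≈ 31 mm), leaf blades from
≈ 330 px (oldest) down to ≈ 130 px (youngest).

Choices that make the ground truth exact rather than approximate:

* **Octilinear centerlines.** Every organ polyline runs along an image axis
  or an exact 45° diagonal, so the digital geodesic length of the rasterized
  centerline equals its Euclidean arc length and the recorded truth is
  analytic. Curvature enters through 45° jogs of varying size. This also
  sidesteps the chamfer anisotropy: at intermediate angles the 1/√2 metric
  itself would overestimate a straight segment by up to ~8 %, which is a
  property of the metric, not a fixture artifact.
* **Cap extension.** Thinning a round-capped stroke retracts the skeleton
  terminal about half a stroke width inside the cap. Strokes are therefore
  drawn half a width past each *free* organ endpoint (not past
  attachments), so the medial axis of the rendered organ terminates at the
  nominal endpoint and the centerline truth is what the pipeline should
  recover.
* **Grid ticks.** A short stem-colored horizontal tick crosses each stem
  near its base, deliberately creating two sub-threshold spurs at a stem
  junction — the exact artifact the pruning stage exists to remove.
* **Noise after truth.** Per-pixel truth masks are captured before Gaussian
  noise (σ = 5) and 1 % salt are added; salt is kept a 5-px margin away from
  plants so it stays strictly below the median-filter removal scale.
* **Single-blade plants are branchless.** A one-leaf seedling renders as one
  unbranched polyline (internode and blade separated only by a kink), and
  its truth accordingly records zero measurable leaves and
  internode = total — matching what any junction-based measurement can
  report.

What the generator does **not** emulate: anti-aliased or textured strokes,
shadows, lens/scanner distortion, touching or overlapping plants, roots, and
smoothly curved (non-octilinear) blades. Passing tests therefore demonstrate
correctness of the segmentation-graph-measurement chain under the stated
layout conventions, not robustness to arbitrary real-world scan quality; on
real scans, obliquely growing organs will additionally carry the metric's
angle-dependent bias of up to a few percent.

## Numerical and design notes

* The automatic gray threshold scans all integer cuts 0–255 for the maximum
  between-class variance and returns the smallest maximizing cut, so
  plateaus resolve deterministically. Pixels `< T` and `>= T` form the two
  classes; a constant window raises a degenerate-histogram error.
* Thinning uses topology-preserving morphological skeletonization
  (Zhang–Suen as provided by scikit-image); it is idempotent on the
  one-pixel structures used here, and any thinning with those properties
  would serve.
* All tie-breaks are total orders (bottom-most terminal: greatest row then
  smallest column; node numbering: lexicographic pixel order), so repeated
  runs are byte-identical down to the exported CSVs and overlay PNGs.
* `sd` is the sample (n−1) estimator, `se = sd/√n`; groups with a single
  plant are omitted from summaries rather than reported with undefined
  spread. The program-vs-manual comparison applies Shapiro–Wilk per series,
  a two-sided variance-ratio F-test, then a pooled-variance two-sided
  t-test, in that order.
* Merging regions (e.g. re-attaching a cut-off stem fragment) unites the
  pixel sets and, if disconnected, bridges the nearest pixel pair between
  components with a rasterized straight segment, repeatedly, before
  re-analysis.
* The rescaling check in the acceptance suite doubles all scene geometry and
  the bar while keeping the stroke width: the pixel-scale thinning bias is
  then identical at both resolutions and the comparison isolates what it is
  meant to test — that the mm-per-px calibration compensates resolution.
  (Scaling the stroke width too changes the thinning bias non-proportionally
  and would test the thinning algorithm, not the calibration.)
* Problem sizes in the test suite and acceptance script — 50 and 24 recovery
  scenes at 1200×1600 px, 60–100 oracle images, 100–200 oracle graphs — are
  the package's chosen desk-scale study sizes; errors are bias-dominated and
  stable across seeds, so larger samples change the reported numbers only in
  the third digit.

## Known limitations

* Lengths of obliquely oriented organs carry the chamfer metric's
  angle-dependent bias (up to ~8 % at 22.5°); a corrected step-weight
  estimator would reduce this but would break the exact worked examples of
  the step metric and is left out deliberately.
* Touching or overlapping plants merge into one region; the layout
  convention (non-overlapping arrangement) is assumed, and cycles formed by
  touching organs are rejected rather than untangled.
* The internode/leaf split is a stated graph convention (basal path segment
  up to the first junction); anatomical mesocotyl-vs-sheath boundaries are
  not resolvable from a skeleton.
* Root traits are out of scope.
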