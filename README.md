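# shootscan

Automated measurement of shoot traits from flatbed scans of dissected cereal
seedlings.

Small-scale in vitro screens (hormone treatments, abiotic stress, candidate
biostimulants) read out as lengths of the seedling's above-ground organs:
total shoot, basal internode, the individual leaves, and — for germination
assays — the coleoptile. Measuring those by hand in an image editor is slow
and error-prone. `shootscan` replaces the ruler: seedlings are laid out
without overlap on an agar plate over a blue backing sheet together with a
2-cm scale bar, scanned in color, and every plant in the scan is measured
automatically.

## Method

The pipeline follows the standard image-analysis chain of preprocessing,
segmentation and feature extraction, with the skeleton graph as its core
representation:

1. **Preprocess** — median blur, then edge-preserving bilateral filtering,
   then conversion to HSV.
2. **Segment** — per-pixel HSV color window (green tissue vs. blue
   background) for seedlings; for coleoptiles, where color carries no
   information, grayscale thresholding at the cut `T*` maximizing the
   between-class variance `σ_b²(T) = w₀w₁(μ₀ − μ₁)²`. 8-connected
   components below a minimum area (default 500 px) are discarded as noise.
3. **Skeletonize and build the graph** — each plant is thinned to a
   one-pixel-wide skeleton; pixels with one 8-neighbor become terminal
   nodes, more than two neighbors branching nodes, exactly two neighbors
   edge points. Edge lengths use the digital geodesic metric
   (1 per orthogonal, √2 per diagonal step).
4. **Prune** — terminal edges shorter than 50 px (plate-grid artifacts, the
   cut-off stem end) are removed in a single pass, except the basal edge
   below the lowest node, which anchors the shoot base. Coleoptiles are not
   pruned.
5. **Measure** — with Dijkstra shortest paths from the lowest node:
   total shoot = geodesic length from the lowest to the highest node;
   internode = the stretch of that path below the first branching node;
   every off-path subtree (and the apical stretch above the last junction)
   is a leaf, numbered from the base, longer-first at a shared junction.
   The scale bar's pixel width converts everything to millimetres.
6. **Report** — one CSV row per plant, per-group mean/SD/SE, an annotated
   overlay (numbered frames, leaves traced in yellow), and a JSON manifest.
   A Shapiro–Wilk + F-test + pooled two-sided t-test report
   (`compare_measurements`) supports validation against manual
   measurements.

Because no public scan archive exists for this protocol, the package ships a
seeded scene generator (`shootscan.fixtures`) that renders plate scans with
*exact* analytic ground truth — organ centerlines are octilinear, so their
digital geodesic length equals their Euclidean arc length — plus raw skeleton
fixtures for unit-testing the graph stage.

## Worked example

Render a two-seedling scene and analyze it:

```
$ shootscan simulate --seed 11 --out demo/sim
wrote scene with 2 plant(s) to demo/sim

$ shootscan analyze --plant-type seedling --scale-side left \
      --corner-frac 0.25 --out demo/run demo/sim/scene.png
analyzed 1/1 image(s), 2 plant(s)
```

`demo/run/records.csv`:

```
image,region_id,group,total_shoot_mm,internode_mm,leaf1_mm,leaf2_mm,leaf3_mm,coleoptile_mm,area_px
scene.png,1,,45.999,29.864,16.135,13.553,,,5583
scene.png,2,,43.803,30.459,17.755,12.567,8.892,,6607
```

Each row is one detected plant: region 1 is a two-leaf seedling with a
46.0 mm shoot, a 29.9 mm internode and leaves of 16.1 and 13.6 mm; region 2
carries three leaves. The generator's ground truth for the same scene
(`demo/sim/truth.csv`) lists 46.01 / 29.84 / 16.16 / 13.44 mm for plant 1 —
the program recovers every length to within a few hundredths of a
millimetre, about one pixel at the scene's 0.051 mm/px calibration.
`summaries.csv` adds per-group mean, standard deviation and standard error;
`scene_overlay.png` shows the numbered frames and yellow-traced leaves for
visual checking.

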