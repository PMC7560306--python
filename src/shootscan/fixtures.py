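"""Seeded synthetic plate scans and skeleton rasters with exact ground truth.

No scan archive accompanies the screening protocol this package implements,
so every stage is exercised against generated scenes that emulate the real
imaging conventions: green seedlings laid out without overlap on a plate over
a blue background, pale plate grid lines, a dark horizontal scale bar of
known physical length (20 mm) in a lower corner, and scanner noise.
Coleoptile scenes use pale strokes on a dark backing suitable for grayscale
thresholding.

Design choices that make the ground truth exact:

* organ centerlines are **octilinear** polylines (every segment runs along an
  image axis or an exact 45-degree diagonal), so the digital geodesic length
  (1 per orthogonal step, sqrt(2) per diagonal step) of the rasterized
  centerline equals its Euclidean arc length;
* strokes are stamped without anti-aliasing, so the per-pixel foreground
  truth is exact; noise is added only after truth capture;
* short stem-colored "grid ticks" crossing each stem near its base emulate
  the plate grid artifacts that the skeleton pruning step exists to remove;
* impulse (salt) noise is kept clear of a safety margin around the plants so
  it stays strictly below the median-filter removal scale.

Everything is reproducible from ``(spec, seed)`` alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .errors import FixtureError, InvalidSceneError
from .skeletongraph import Skeleton, build_graph, classify_pixels

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)

Point = tuple[int, int]


# ---------------------------------------------------------------------------
# octilinear polylines
# ---------------------------------------------------------------------------


def chain(start: Point, segs: Sequence[tuple[int, int, int]]) -> list[Point]:
    """Polyline from ``start`` through unit-direction segments
    ``(dr, dc, steps)`` with ``dr, dc`` in {-1, 0, 1}."""
    pts = [start]
    r, c = start
    for dr, dc, k in segs:
        if (dr, dc) == (0, 0) or abs(dr) > 1 or abs(dc) > 1 or k < 1:
            raise FixtureError(f"invalid segment {(dr, dc, k)}")
        r, c = r + dr * k, c + dc * k
        pts.append((r, c))
    return pts


def polyline_arc(points: Sequence[Point]) -> float:
    """Euclidean arc length of an octilinear polyline (equals its digital
    geodesic length by construction)."""
    total = 0.0
    for (r0, c0), (r1, c1) in zip(points, points[1:]):
        dr, dc = abs(r1 - r0), abs(c1 - c0)
        if dr == dc:
            total += dr * SQRT2
        elif dr == 0 or dc == 0:
            total += dr + dc
        else:
            raise FixtureError(
                f"segment {(r0, c0)} -> {(r1, c1)} is not axis- or 45-degree-aligned"
            )
    return total


def rasterize_polyline(points: Sequence[Point]) -> np.ndarray:
    """(N, 2) pixel coordinates of a polyline (1-px wide, 8-connected)."""
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for (r0, c0), (r1, c1) in zip(points, points[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        rows.append(rr)
        cols.append(cc)
    coords = np.unique(
        np.stack([np.concatenate(rows), np.concatenate(cols)], axis=1), axis=0
    )
    return coords


# ---------------------------------------------------------------------------
# plant and scene specifications
# ---------------------------------------------------------------------------


@dataclass
class PlantSpec:
    """Geometry of one synthetic plant.

    ``stem_points`` runs from the shoot base (bottom) to the apical tip; each
    leaf is ``(stem_vertex_index, polyline)`` attached at a stem vertex, its
    polyline starting at that vertex.  ``tick`` optionally places a short
    stem-colored horizontal grid artifact crossing the stem:
    ``(row, col, half_len)``.
    """

    stem_points: list[Point]
    leaves: list[tuple[int, list[Point]]] = field(default_factory=list)
    stroke_width: int = 5
    tick: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        for idx, pts in self.leaves:
            if pts[0] != self.stem_points[idx]:
                raise FixtureError("leaf polyline must start at its stem vertex")

    def stem_arc(self) -> float:
        return polyline_arc(self.stem_points)

    def expected_traits(self) -> dict:
        """Trait ground truth (in pixels) under the measurement conventions.

        Leaves are ordered by attachment height along the stem then by
        decreasing length; the stretch of stem above the last attachment is
        itself a leaf.  A plant without leaf attachments is branchless:
        ``internode == total_shoot`` and the leaf list is empty.
        """
        total = self.stem_arc()
        if not self.leaves:
            return {
                "total_shoot_px": total,
                "internode_px": total,
                "leaf_px": (),
                "leaf_count": 0,
            }
        cum = [0.0]
        for a, b in zip(self.stem_points, self.stem_points[1:]):
            cum.append(cum[-1] + polyline_arc([a, b]))
        entries = [
            (cum[idx], polyline_arc(pts)) for idx, pts in self.leaves
        ]
        first_attach = min(pos for pos, _ in entries)
        last_attach = max(pos for pos, _ in entries)
        entries.append((last_attach, total - last_attach))  # terminal leaf
        entries.sort(key=lambda e: (e[0], -e[1]))
        return {
            "total_shoot_px": total,
            "internode_px": first_attach,
            "leaf_px": tuple(length for _, length in entries),
            "leaf_count": len(entries),
        }


@dataclass
class SceneSpec:
    """Canvas, palette, scale bar and noise model of a synthetic scan."""

    height: int = 1200
    width: int = 1600
    seed: int = 0
    background_rgb: tuple[int, int, int] = (35, 55, 160)
    plant_rgb: tuple[int, int, int] = (45, 165, 70)
    grid_rgb: tuple[int, int, int] = (120, 140, 200)
    grid_spacing: int = 200
    bar_side: Literal["left", "right"] = "left"
    bar_width_px: int = 390
    bar_length_mm: float = 20.0
    bar_corner_frac: float = 0.25
    noise_sigma: float = 5.0
    salt_frac: float = 0.01

    @property
    def mm_per_px(self) -> float:
        return self.bar_length_mm / self.bar_width_px


@dataclass
class PlantTruth:
    """Ground truth for one rendered plant."""

    plant_index: int
    mask: np.ndarray
    total_shoot_px: float
    internode_px: float
    leaf_px: tuple[float, ...]
    leaf_count: int
    mm_per_px: float
    coleoptile_px: Optional[float] = None

    @property
    def total_shoot_mm(self) -> float:
        return self.total_shoot_px * self.mm_per_px

    @property
    def internode_mm(self) -> float:
        return self.internode_px * self.mm_per_px

    @property
    def leaf_mm(self) -> tuple[float, ...]:
        return tuple(v * self.mm_per_px for v in self.leaf_px)

    @property
    def coleoptile_mm(self) -> Optional[float]:
        if self.coleoptile_px is None:
            return None
        return self.coleoptile_px * self.mm_per_px


@dataclass
class SceneTruth:
    """Ground truth for a whole scene."""

    plants: list[PlantTruth]
    bar_width_px: int
    mm_per_px: float
    image_shape: tuple[int, int]
    seed: int

    def plant_for_region(self, region) -> PlantTruth:
        """Match an extracted region to its plant by pixel overlap."""
        best, best_overlap = None, 0
        for plant in self.plants:
            overlap = int(plant.mask[region.coords[:, 0], region.coords[:, 1]].sum())
            if overlap > best_overlap:
                best, best_overlap = plant, overlap
        if best is None or best_overlap == 0:
            raise FixtureError(f"region {region.id} matches no ground-truth plant")
        return best


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _stroke_mask(
    shape: tuple[int, int], points: Sequence[Point], width: int
) -> np.ndarray:
    mask = np.zeros(shape, bool)
    coords = rasterize_polyline(points)
    inb = (
        (coords[:, 0] >= 0) & (coords[:, 0] < shape[0])
        & (coords[:, 1] >= 0) & (coords[:, 1] < shape[1])
    )
    if not inb.all():
        raise InvalidSceneError("plant stroke leaves the canvas")
    mask[coords[:, 0], coords[:, 1]] = True
    radius = width // 2
    if radius > 0:
        mask = dilation(mask, disk(radius))
    return mask


def _extend(points: Sequence[Point], width: int,
            start: bool, end: bool) -> list[Point]:
    """Prolong a polyline half a stroke width past its free endpoints.

    Morphological thinning of a round-capped stroke retracts the skeleton
    terminal about half a width inside the cap; extending the centerline by
    that much places the medial-axis terminal at the nominal organ endpoint,
    so the analytic centerline arc is what the rendered organ realizes.
    Attachment ends (``start``/``end`` False) are left untouched.
    """
    pts = list(points)
    ext = width // 2
    if ext == 0:
        return pts
    if start:
        (r0, c0), (r1, c1) = pts[0], pts[1]
        dr, dc = int(np.sign(r0 - r1)), int(np.sign(c0 - c1))
        pts = [(r0 + dr * ext, c0 + dc * ext)] + pts
    if end:
        (r0, c0), (r1, c1) = pts[-1], pts[-2]
        dr, dc = int(np.sign(r0 - r1)), int(np.sign(c0 - c1))
        pts = pts + [(r0 + dr * ext, c0 + dc * ext)]
    return pts


def _plant_mask(shape: tuple[int, int], spec: PlantSpec) -> np.ndarray:
    w = spec.stroke_width
    mask = _stroke_mask(shape, _extend(spec.stem_points, w, True, True), w)
    for _, pts in spec.leaves:
        mask |= _stroke_mask(shape, _extend(pts, w, False, True), w)
    if spec.tick is not None:
        row, col, half = spec.tick
        mask |= _stroke_mask(shape, [(row, col - half), (row, col + half)], 3)
    return mask


def _bar_geometry(scene: SceneSpec) -> tuple[slice, slice]:
    h, w = scene.height, scene.width
    margin = 8
    r0 = h - 70
    r1 = h - 40
    if scene.bar_side == "left":
        c0 = margin
    else:
        c0 = w - margin - scene.bar_width_px
    return slice(r0, r1), slice(c0, c0 + scene.bar_width_px)


def _corner_exclusion(scene: SceneSpec) -> tuple[slice, slice]:
    wh = int(round(scene.height * scene.bar_corner_frac)) + 20
    ww = int(round(scene.width * scene.bar_corner_frac)) + 20
    rows = slice(scene.height - wh, scene.height)
    cols = (
        slice(0, ww) if scene.bar_side == "left" else slice(scene.width - ww, scene.width)
    )
    return rows, cols


def _render(
    specs: Sequence[PlantSpec],
    scene: SceneSpec,
    plant_rgb: tuple[int, int, int],
    background_rgb: tuple[int, int, int],
    bar_rgb: tuple[int, int, int],
    draw_grid: bool,
    coleoptile: bool,
) -> tuple[np.ndarray, SceneTruth]:
    shape = (scene.height, scene.width)
    img = np.empty((*shape, 3), np.uint8)
    img[...] = background_rgb

    if draw_grid:
        grid = np.zeros(shape, bool)
        for r in range(scene.grid_spacing, scene.height, scene.grid_spacing):
            grid[r : r + 2, :] = True
        for c in range(scene.grid_spacing, scene.width, scene.grid_spacing):
            grid[:, c : c + 2] = True
        # the plate margin holding the scale bar is clear of grid lines
        rows, cols = _corner_exclusion(scene)
        grid[rows, cols] = False
        img[grid] = scene.grid_rgb

    masks = [_plant_mask(shape, spec) for spec in specs]
    union = np.zeros(shape, bool)
    for i, m in enumerate(masks):
        if (union & m).any():
            raise InvalidSceneError(f"plant {i + 1} overlaps an earlier plant")
        union |= m

    bar_rows, bar_cols = _bar_geometry(scene)
    bar_mask = np.zeros(shape, bool)
    bar_mask[bar_rows, bar_cols] = True
    if (union & bar_mask).any():
        raise InvalidSceneError("a plant overlaps the scale bar")
    img[bar_mask] = bar_rgb
    for m in masks:
        img[m] = plant_rgb

    plants = []
    for i, (spec, m) in enumerate(zip(specs, masks), start=1):
        truth = spec.expected_traits()
        plants.append(
            PlantTruth(
                plant_index=i,
                mask=m,
                total_shoot_px=truth["total_shoot_px"],
                internode_px=truth["internode_px"],
                leaf_px=truth["leaf_px"],
                leaf_count=truth["leaf_count"],
                mm_per_px=scene.mm_per_px,
                coleoptile_px=truth["total_shoot_px"] if coleoptile else None,
            )
        )
    scene_truth = SceneTruth(
        plants=plants,
        bar_width_px=scene.bar_width_px,
        mm_per_px=scene.mm_per_px,
        image_shape=shape,
        seed=scene.seed,
    )

    # noise is added only after truth capture
    rng = np.random.default_rng(scene.seed)
    if scene.noise_sigma > 0:
        noisy = img.astype(np.float64) + rng.normal(0.0, scene.noise_sigma, img.shape)
        img = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
    if scene.salt_frac > 0:
        guard = ndimage.binary_dilation(union, iterations=5)
        eligible = ~guard
        hits = (rng.random(shape) < scene.salt_frac) & eligible
        img[hits] = (255, 255, 255)
    return img, scene_truth


def make_seedling_scene(
    specs: Sequence[PlantSpec], scene: SceneSpec
) -> tuple[np.ndarray, SceneTruth]:
    """Render a color seedling plate scan plus its ground truth."""
    return _render(
        specs,
        scene,
        plant_rgb=scene.plant_rgb,
        background_rgb=scene.background_rgb,
        bar_rgb=(20, 20, 20),
        draw_grid=True,
        coleoptile=False,
    )


def make_coleoptile_scene(
    specs: Sequence[PlantSpec], scene: SceneSpec
) -> tuple[np.ndarray, SceneTruth]:
    """Render a grayscale-friendly coleoptile scan: pale organs and bar on a
    dark backing (color carries no information in coleoptile runs)."""
    return _render(
        specs,
        scene,
        plant_rgb=(230, 230, 235),
        background_rgb=(45, 45, 45),
        bar_rgb=(240, 240, 240),
        draw_grid=False,
        coleoptile=True,
    )


# ---------------------------------------------------------------------------
# randomized plant geometry
# ---------------------------------------------------------------------------


def _off_leaf(
    origin: Point, arc: float, max_rise: int, side: int
) -> list[Point]:
    """Leaf polyline of roughly ``arc`` length from ``origin``: a horizontal
    run away from the stem, then a single 45-degree climb to the tip, rising
    at most ``max_rise``."""
    k = min(max_rise, int(round(0.62 * arc)))
    h = int(round(arc - k * SQRT2))
    if h < 8:
        h = 8
    return chain(origin, [(0, side, h), (-1, side, k)])


def _terminal_leaf(origin: Point, arc: float, side: int, jog: int) -> list[Point]:
    """Mostly vertical apical blade with a small 45-degree jog for curvature."""
    v1 = int(round(0.4 * (arc - jog * SQRT2)))
    v2 = int(round(arc - jog * SQRT2 - v1))
    return chain(origin, [(-1, 0, v1), (-1, side, jog), (-1, 0, v2)])


def random_seedling_spec(
    rng: np.random.Generator,
    n_leaves: int,
    base: Point,
    stroke_width: int = 5,
) -> PlantSpec:
    """A randomized seedling with the requested number of leaf blades.

    Organ sizes emulate a 7-day seedling at the default scene calibration
    (~0.05 mm/px): internode about 600 px (~31 mm) and leaf blades from about
    330 px (oldest) down to 130 px (youngest).  A single-blade plant is
    branchless — stem and blade form one unbranched polyline, so the
    convention reports it with zero measurable leaves.  Curvature enters
    through 45-degree jogs whose size varies per plant.
    """
    if not 1 <= n_leaves <= 4:
        raise FixtureError("n_leaves must be in 1..4")
    leaf_arcs = {
        1: [int(rng.integers(300, 341))],
        2: [int(rng.integers(310, 351)), int(rng.integers(230, 271))],
        3: [int(rng.integers(310, 351)), int(rng.integers(230, 271)),
            int(rng.integers(170, 201))],
        4: [int(rng.integers(310, 351)), int(rng.integers(230, 271)),
            int(rng.integers(180, 211)), int(rng.integers(125, 156))],
    }[n_leaves]
    side0 = int(rng.choice((-1, 1)))
    jog = int(rng.integers(10, 26))
    v1 = int(rng.integers(160, 241))
    target_internode = int(rng.integers(580, 621))
    v2 = int(round(target_internode - v1 - jog * SQRT2))
    internode_segs = [(-1, 0, v1), (-1, side0, jog), (-1, 0, v2)]

    if n_leaves == 1:
        # single blade: stem and blade form one unbranched chain with a kink
        blade_jog = int(rng.integers(25, 56))
        arc = leaf_arcs[0]
        bv1 = int(round(0.4 * (arc - blade_jog * SQRT2)))
        bv2 = int(round(arc - blade_jog * SQRT2 - bv1))
        segs = internode_segs + [(-1, 0, bv1), (-1, -side0, blade_jog), (-1, 0, bv2)]
        stem = chain(base, segs)
        spec = PlantSpec(stem_points=stem, leaves=[], stroke_width=stroke_width)
    else:
        gaps = [int(rng.integers(70, 91)) for _ in range(n_leaves - 2)]
        term_jog = int(rng.integers(10, 21))
        term_arc = leaf_arcs[-1] if n_leaves == 2 else leaf_arcs[-1]
        # the apical blade is the longest leaf for a two-leaf plant (it tops
        # the plant), otherwise the youngest (shortest) one
        if n_leaves == 2:
            term_arc, off_arcs = leaf_arcs[0], [leaf_arcs[1]]
        else:
            term_arc, off_arcs = leaf_arcs[-1], leaf_arcs[:-1]
        term = _terminal_leaf((0, 0), term_arc, side0, term_jog)
        term_rise = -term[-1][0]

        stem_segs = list(internode_segs)
        junction_vertex_idx = [len(stem_segs)]  # vertex index after internode
        for g in gaps:
            stem_segs.append((-1, 0, g))
            junction_vertex_idx.append(len(stem_segs))
        for a, b in zip(term, term[1:]):
            stem_segs.append(
                (int(np.sign(b[0] - a[0])), int(np.sign(b[1] - a[1])),
                 int(max(abs(b[0] - a[0]), abs(b[1] - a[1]))))
            )
        stem = chain(base, stem_segs)

        leaves = []
        for i, arc in enumerate(off_arcs):
            vidx = junction_vertex_idx[i]
            origin = stem[vidx]
            rise_above = (origin[0] - stem[-1][0]) - 25
            side = side0 if i % 2 else -side0
            leaves.append((vidx, _off_leaf(origin, arc, rise_above, side)))
        spec = PlantSpec(stem_points=stem, leaves=leaves, stroke_width=stroke_width)

    tick_row = base[0] - int(rng.integers(40, 81))
    spec.tick = (tick_row, base[1], int(rng.integers(14, 21)))
    _validate_apex(spec)
    return spec


def _validate_apex(spec: PlantSpec) -> None:
    """The apical stem tip must be the highest point of the plant."""
    tip_row = spec.stem_points[-1][0]
    for _, pts in spec.leaves:
        if min(r for r, _ in pts) <= tip_row + 10:
            raise FixtureError("a leaf rises too close to the apical tip")


def random_coleoptile_spec(
    rng: np.random.Generator, base: Point, stroke_width: int = 5
) -> PlantSpec:
    """A gently S-curved unbranched coleoptile, about 450-650 px of arc."""
    side = int(rng.choice((-1, 1)))
    k1 = int(rng.integers(25, 56))
    k2 = int(rng.integers(25, 56))
    v1 = int(rng.integers(90, 131))
    v2 = int(rng.integers(120, 171))
    v3 = int(rng.integers(90, 131))
    stem = chain(
        base,
        [(-1, 0, v1), (-1, side, k1), (-1, 0, v2), (-1, -side, k2), (-1, 0, v3)],
    )
    return PlantSpec(stem_points=stem, leaves=[], stroke_width=stroke_width)


# ---------------------------------------------------------------------------
# raw skeleton fixtures
# ---------------------------------------------------------------------------


@dataclass
class TreeSpec:
    """Abstract skeleton tree: node coordinates with intended kinds, and
    edges as octilinear waypoint polylines between them."""

    nodes: dict[int, tuple[Point, Literal["terminal", "branching"]]]
    edges: list[tuple[int, int, list[Point]]]

    def edge_polyline(self, a: int, b: int, waypoints: list[Point]) -> list[Point]:
        return [self.nodes[a][0], *waypoints, self.nodes[b][0]]


@dataclass
class TreeTruth:
    """What the rasterized tree should look like as a graph."""

    n_terminal: int
    n_branching: int
    edge_lengths_px: list[float]


def make_skeleton_fixture(spec: TreeSpec) -> tuple[Skeleton, TreeTruth]:
    """Rasterize an abstract tree into a 1-px skeleton and return it with its
    analytic truth.

    The realized skeleton is validated by graph conversion: the terminal and
    branching node counts must match the specification exactly, otherwise the
    rasterization created unintended adjacencies and a
    :class:`~shootscan.errors.FixtureError` is raised.  Analytic edge lengths
    are the arc lengths of the waypoint polylines; junction pixels absorbed
    into branch clusters can shorten realized edges by a couple of pixels.
    """
    coords = []
    lengths = []
    for a, b, waypoints in spec.edges:
        poly = spec.edge_polyline(a, b, waypoints)
        coords.append(rasterize_polyline(poly))
        lengths.append(polyline_arc(poly))
    pixels = np.unique(np.concatenate(coords, axis=0), axis=0)
    skel = Skeleton(pixels=pixels)
    kinds = classify_pixels(skel)
    graph = build_graph(skel)
    want_t = sum(1 for _, k in spec.nodes.values() if k == "terminal")
    want_b = sum(1 for _, k in spec.nodes.values() if k == "branching")
    got_t = sum(1 for n in graph.nodes if n.kind == "terminal")
    got_b = sum(1 for n in graph.nodes if n.kind == "branching")
    if (got_t, got_b) != (want_t, want_b):
        raise FixtureError(
            f"rasterization realized {got_t} terminal / {got_b} branching nodes, "
            f"specification wants {want_t} / {want_b}"
        )
    if len(graph.edges) != len(spec.edges):
        raise FixtureError(
            f"rasterization realized {len(graph.edges)} edges, "
            f"specification wants {len(spec.edges)}"
        )
    del kinds
    return skel, TreeTruth(
        n_terminal=want_t, n_branching=want_b, edge_lengths_px=lengths
    )


def y_tree_spec() -> TreeSpec:
    """A Y: three terminals joined at one branching node."""
    return TreeSpec(
        nodes={
            0: ((200, 100), "terminal"),
            1: ((100, 100), "branching"),
            2: ((20, 20), "terminal"),
            3: ((20, 180), "terminal"),
        },
        edges=[(0, 1, []), (1, 2, []), (1, 3, [])],
    )


def spur_tree_spec() -> TreeSpec:
    """Nine-node tree with two sub-threshold spurs, each at a junction of
    degree >= 4: the worked pruning example (9 nodes before, 7 after)."""
    return TreeSpec(
        nodes={
            0: ((900, 400), "terminal"),   # shoot base
            1: ((700, 400), "branching"),  # degree 4
            2: ((700, 430), "terminal"),   # spur, 30 px
            3: ((600, 300), "terminal"),   # leaf, ~141 px
            4: ((520, 400), "branching"),  # degree 5
            5: ((520, 365), "terminal"),   # spur, 35 px
            6: ((430, 490), "terminal"),   # leaf, ~127 px
            7: ((440, 320), "terminal"),   # leaf, ~113 px
            8: ((370, 400), "terminal"),   # apical tip, 150 px
        },
        edges=[
            (0, 1, []),
            (1, 2, []),
            (1, 3, []),
            (1, 4, []),
            (4, 5, []),
            (4, 6, []),
            (4, 7, []),
            (4, 8, []),
        ],
    )
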