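"""Calibrated trait extraction and group statistics.

Given a pruned plant graph and the scale-bar calibration, the shoot traits
are defined on the skeleton graph:

* **total shoot** — geodesic path length from the lowest node (greatest row;
  the cut shoot base) to the highest node (smallest row; the apical leaf
  tip);
* **internode** — length along that main path from the base up to the first
  branching node (the basal stem segment below the first leaf attachment);
  for a branchless plant the internode equals the total shoot;
* **leaves** — for every junction on the main path, each off-path subtree is
  a leaf whose length is the longest geodesic from the junction into the
  subtree; the terminal stretch of the main path above the last junction is
  likewise a leaf.  Leaves are numbered by attachment junction from the base
  upward; at a shared junction the longer leaf gets the lower number (older
  leaves are longer in a 7-day seedling);
* **coleoptile** — measured on unpruned graphs as the longest geodesic from
  the lowest node.

All pixel lengths convert to millimetres through the scale bar.  Per-image
(or per-group) means, sample standard deviations and standard errors are
produced, and a program-vs-manual comparison report (Shapiro-Wilk normality,
variance-ratio F-test, pooled two-sided t-test) is available for validating
the pipeline against hand measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line

from . import skeletongraph as sg
from .errors import (
    InsufficientSampleError,
    MeasurementError,
    UnknownRegionError,
)
from .imaging import Region, ScaleBar
from .skeletongraph import GeodesicTable, PlantGraph, geodesics

logger = logging.getLogger(__name__)

SHOOT_PARAMETERS = ("total_shoot_mm", "internode_mm")


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass
class TraitRecord:
    """Calibrated per-plant measurements (all lengths in millimetres)."""

    region_id: int
    total_shoot_mm: float = 0.0
    internode_mm: float = 0.0
    leaf_mm: tuple[float, ...] = ()
    coleoptile_mm: Optional[float] = None
    group_label: Optional[str] = None
    area_px: int = 0
    leaf_polylines: list[list[tuple[int, int]]] = field(
        default_factory=list, repr=False, compare=False
    )

    def parameters(self) -> dict[str, float]:
        """Flat name -> value map of the populated traits."""
        out: dict[str, float] = {}
        if self.coleoptile_mm is not None:
            out["coleoptile_mm"] = self.coleoptile_mm
            return out
        out["total_shoot_mm"] = self.total_shoot_mm
        out["internode_mm"] = self.internode_mm
        for i, length in enumerate(self.leaf_mm, start=1):
            out[f"leaf{i}_mm"] = length
        return out


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(self.n)


@dataclass(frozen=True)
class ComparisonReport:
    """Two-sample agreement report mirroring a program-vs-manual protocol."""

    n: int
    mean_a: float
    mean_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    f_test_p: float
    t_statistic: float
    t_test_p: float


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def to_mm(length_px: float, bar: ScaleBar) -> float:
    """Convert a pixel length to millimetres through the scale bar."""
    if length_px < 0:
        raise MeasurementError(f"negative length {length_px}")
    return length_px * bar.length_mm / bar.width_px


# ---------------------------------------------------------------------------
# graph measurement
# ---------------------------------------------------------------------------


def anchor_nodes(graph: PlantGraph) -> tuple[int, int]:
    """(lowest, highest) node ids: greatest/smallest row, ties broken by the
    smaller column."""
    if len(graph.nodes) < 2:
        raise MeasurementError("graph needs at least two nodes")
    lowest = min(graph.nodes, key=lambda n: (-n.coord[0], n.coord[1])).id
    highest = min(graph.nodes, key=lambda n: (n.coord[0], n.coord[1])).id
    return lowest, highest


def _path_edges(
    graph: PlantGraph, node_path: Sequence[int]
) -> list[sg.GraphEdge]:
    """Edge objects realizing a node path (shortest edge between each pair)."""
    out = []
    for a, b in zip(node_path, node_path[1:]):
        candidates = [
            e for e in graph.edges if {e.node_a, e.node_b} == {a, b}
        ]
        out.append(min(candidates, key=lambda e: e.length_px))
    return out


def _subtree_reach(
    graph: PlantGraph,
    junction: int,
    first_edge: sg.GraphEdge,
    blocked: set[int],
) -> tuple[float, list[list[tuple[int, int]]]]:
    """Longest geodesic from ``junction`` into the subtree entered through
    ``first_edge``, plus the polylines of every edge of that subtree."""
    start = first_edge.node_b if first_edge.node_a == junction else first_edge.node_a
    best = first_edge.length_px
    polys = [list(first_edge.polyline)]
    stack = [(start, first_edge.length_px)]
    visited = {junction, start} | blocked
    while stack:
        node, d = stack.pop()
        for e in graph.incident(node):
            other = e.node_b if e.node_a == node else e.node_a
            if other in visited:
                continue
            visited.add(other)
            polys.append(list(e.polyline))
            nd = d + e.length_px
            best = max(best, nd)
            stack.append((other, nd))
    return best, polys


def measure_seedling(graph: PlantGraph, bar: ScaleBar) -> TraitRecord:
    """Extract total shoot, internode and ordered leaf lengths from a pruned
    seedling graph.

    A plant without any branching node is reported with zero leaves and
    ``internode == total_shoot`` (blade and stem cannot be separated without
    a junction), with a warning.
    """
    lowest, highest = anchor_nodes(graph)
    table = geodesics(graph, lowest)
    node_path = table.path_to(highest)
    total_px = table.dist[highest]

    deg = graph.degrees()
    junctions = [nid for nid in node_path if deg[nid] >= 3]

    if not junctions:
        logger.warning(
            "region %d: branchless plant; internode set to total shoot and "
            "no leaves reported", graph.source_region_id,
        )
        total = to_mm(total_px, bar)
        return TraitRecord(
            region_id=graph.source_region_id,
            total_shoot_mm=total,
            internode_mm=total,
            leaf_mm=(),
        )

    internode_px = table.dist[junctions[0]]
    path_edges = _path_edges(graph, node_path)
    path_edge_ids = {id(e) for e in path_edges}
    path_nodes = set(node_path)

    # (junction position along the path, length, polylines) per leaf
    leaves: list[tuple[float, float, list[list[tuple[int, int]]]]] = []
    for j in junctions:
        pos = table.dist[j]
        for e in graph.incident(j):
            if id(e) in path_edge_ids:
                continue
            other = e.node_b if e.node_a == j else e.node_a
            if other in path_nodes and other != j:
                continue  # a cycle chord back onto the path; not a leaf
            reach, polys = _subtree_reach(graph, j, e, path_nodes - {j})
            leaves.append((pos, reach, polys))
    # terminal stretch of the main path above the last junction
    last = junctions[-1]
    tip_len = total_px - table.dist[last]
    if tip_len > 0:
        idx = node_path.index(last)
        tip_polys = [list(e.polyline) for e in path_edges[idx:]]
        leaves.append((table.dist[last], tip_len, tip_polys))

    leaves.sort(key=lambda item: (item[0], -item[1]))
    record = TraitRecord(
        region_id=graph.source_region_id,
        total_shoot_mm=to_mm(total_px, bar),
        internode_mm=to_mm(internode_px, bar),
        leaf_mm=tuple(to_mm(length, bar) for _, length, _ in leaves),
        leaf_polylines=[p for _, _, polys in leaves for p in polys],
    )
    return record


def measure_coleoptile(graph: PlantGraph, bar: ScaleBar) -> float:
    """Total coleoptile length: the longest geodesic from the lowest node of
    an *unpruned* graph (short skeleton forks near the tip are dominated by
    the longer branch rather than pruned away)."""
    lowest, _ = anchor_nodes(graph)
    table = geodesics(graph, lowest)
    return to_mm(max(table.dist.values()), bar)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample standard deviation (n-1 denominator) and standard error."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientSampleError(
            f"need at least 2 values for sd/se, got {arr.size}"
        )
    return SummaryStats(n=int(arr.size), mean=float(arr.mean()),
                        sd=float(arr.std(ddof=1)))


def group_and_summarize(
    records: Sequence[TraitRecord],
    labels: Optional[dict[int, str]] = None,
) -> dict[str, dict[str, SummaryStats]]:
    """Per-group, per-parameter summary statistics.

    ``labels`` maps region ids to group names; unlabeled records fall into
    the group ``"ungrouped"``.  Parameters with fewer than two observations
    in a group are omitted (a single plant has no spread).
    """
    labels = labels or {}
    known = {r.region_id for r in records}
    for rid in labels:
        if rid not in known:
            raise UnknownRegionError(f"group label references unknown region {rid}")
    grouped: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        group = labels.get(rec.region_id, rec.group_label or "ungrouped")
        params = grouped.setdefault(group, {})
        for name, value in rec.parameters().items():
            params.setdefault(name, []).append(value)
    out: dict[str, dict[str, SummaryStats]] = {}
    for group, params in grouped.items():
        out[group] = {
            name: summarize(vals)
            for name, vals in params.items()
            if len(vals) >= 2
        }
    return out


def compare_measurements(
    a: Sequence[float], b: Sequence[float]
) -> ComparisonReport:
    """Agreement protocol between two measurement series of the same plants
    (e.g. automated vs manual): Shapiro-Wilk normality per series, two-sided
    variance-ratio F-test, then a pooled-variance two-sided Student t-test."""
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    if xa.size != xb.size:
        raise InsufficientSampleError("series must have equal length")
    if xa.size < 3:
        raise InsufficientSampleError("need at least 3 paired measurements")
    sw_a = float(stats.shapiro(xa).pvalue)
    sw_b = float(stats.shapiro(xb).pvalue)
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if vb == 0 and va == 0:
        f_p = 1.0
    else:
        big, small = (va, vb) if va >= vb else (vb, va)
        dfn = xa.size - 1 if va >= vb else xb.size - 1
        dfd = xb.size - 1 if va >= vb else xa.size - 1
        ratio = np.inf if small == 0 else big / small
        f_p = float(min(1.0, 2.0 * stats.f.sf(ratio, dfn, dfd)))
    t_res = stats.ttest_ind(xa, xb, equal_var=True)
    return ComparisonReport(
        n=int(xa.size),
        mean_a=float(xa.mean()),
        mean_b=float(xb.mean()),
        shapiro_p_a=sw_a,
        shapiro_p_b=sw_b,
        f_test_p=f_p,
        t_statistic=float(t_res.statistic),
        t_test_p=float(t_res.pvalue),
    )


# ---------------------------------------------------------------------------
# region post-processing
# ---------------------------------------------------------------------------


def merge_regions(regions: Sequence[Region], ids: Sequence[int]) -> Region:
    """Merge regions (e.g. a plant and its cut-off stem fragment) into one.

    The pixel sets are united; if the union is disconnected, the nearest
    pixel pair between components is bridged with a rasterized straight
    segment (repeatedly, until connected) so the merged plant skeletonizes as
    a single structure.  The merged region takes the smallest input id.
    """
    ids = list(ids)
    if len(set(ids)) < 2:
        raise UnknownRegionError("merge needs at least two distinct region ids")
    by_id = {r.id: r for r in regions}
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise UnknownRegionError(f"unknown region id(s): {missing}")
    shape = by_id[ids[0]].image_shape
    mask = np.zeros(shape, bool)
    for i in ids:
        m = by_id[i].mask()
        mask |= m

    from scipy import ndimage

    from .imaging import EIGHT_CONNECTED, Region as _Region, _ordered_contour

    labels, n = ndimage.label(mask, structure=EIGHT_CONNECTED)
    while n > 1:
        comps = [np.argwhere(labels == k) for k in range(1, n + 1)]
        best: tuple[float, tuple[int, int], tuple[int, int]] | None = None
        base = comps[0]
        tree = cKDTree(base)
        for other in comps[1:]:
            d, idx = tree.query(other)
            k = int(np.argmin(d))
            cand = (float(d[k]), tuple(base[idx[k]]), tuple(other[k]))
            if best is None or cand[0] < best[0]:
                best = cand
        assert best is not None
        (_, (r0, c0), (r1, c1)) = best
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        mask[rr, cc] = True
        labels, n = ndimage.label(mask, structure=EIGHT_CONNECTED)

    coords = np.argwhere(mask)
    r_min, c_min = coords.min(axis=0)
    r_max, c_max = coords.max(axis=0)
    sub = mask[r_min : r_max + 1, c_min : c_max + 1]
    contour = [(r + int(r_min), c + int(c_min)) for r, c in _ordered_contour(sub)]
    return _Region(
        id=min(ids),
        coords=coords,
        contour=contour,
        bbox=(int(r_min), int(c_min), int(r_max), int(c_max)),
        image_shape=shape,
    )
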