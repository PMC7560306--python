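"""Skeletonization, skeleton-to-graph conversion, spur pruning, geodesics.

A segmented plant region is thinned to a one-pixel-wide skeleton and
converted into a graph: skeleton pixels with one 8-neighbor are terminal
nodes, pixels with more than two neighbors are branching nodes, and pixels
with exactly two neighbors form the edges between them.  Edge lengths use the
standard digital geodesic metric: 1 per orthogonal step and sqrt(2) per
diagonal step along the pixel polyline.

Plate grid lines and the cut-off end of the stem leave short terminal
"spurs" on the skeleton; pruning removes, in a single pass, every terminal
edge shorter than a threshold (50 px by default) except the basal edge — the
terminal edge whose endpoint is the bottom-most node, which anchors the shoot
base and is exempt regardless of length.  After pruning, junctions left with
degree 2 are dissolved and their edges merged, conserving total length.

Shortest paths from the basal node to every other node (Dijkstra on the edge
lengths) underlie all downstream trait measurements.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import networkx as nx
import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize

from .errors import AllPrunedError, TooSmallObjectError, UnreachableNodeError
from .imaging import AnalysisConfig, Region

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)

_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def polyline_length(polyline: Iterable[tuple[int, int]]) -> float:
    """Digital geodesic length of a pixel polyline (1 / sqrt(2) steps)."""
    pts = list(polyline)
    total = 0.0
    for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
        dr, dc = abs(r1 - r0), abs(c1 - c0)
        if dr > 1 or dc > 1 or (dr == 0 and dc == 0):
            raise ValueError(f"polyline step {(r0, c0)} -> {(r1, c1)} is not a king move")
        total += SQRT2 if dr == 1 and dc == 1 else 1.0
    return total


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------


@dataclass
class Skeleton:
    """One-pixel-wide 8-connected medial representation of a region."""

    pixels: np.ndarray  # (N, 2) int array of (row, col)
    source_region_id: int = 0

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels, dtype=np.intp).reshape(-1, 2)
        order = np.lexsort((pix[:, 1], pix[:, 0]))
        self.pixels = pix[order]

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}


def skeletonize(region: Region) -> Skeleton:
    """Thin a region to its skeleton (topology-preserving morphological
    thinning), keeping coordinates in the full-image frame."""
    r_min, c_min, r_max, c_max = region.bbox
    sub = np.zeros((r_max - r_min + 3, c_max - c_min + 3), bool)
    sub[region.coords[:, 0] - r_min + 1, region.coords[:, 1] - c_min + 1] = True
    thin = _skimage_skeletonize(sub)
    coords = np.argwhere(thin)
    if len(coords) < 2:
        raise TooSmallObjectError(
            f"region {region.id}: skeleton has {len(coords)} pixel(s)"
        )
    coords = coords + np.array([r_min - 1, c_min - 1])
    return Skeleton(pixels=coords, source_region_id=region.id)


def classify_pixels(
    skel: Skeleton,
) -> dict[tuple[int, int], Literal["terminal", "branching", "edge"]]:
    """Label every skeleton pixel by its 8-neighbor count within the
    skeleton: 1 -> terminal, exactly 2 -> edge point, more than 2 -> branching."""
    pixels = skel.pixel_set
    if len(pixels) < 2:
        raise TooSmallObjectError("skeleton must contain at least two pixels")
    out: dict[tuple[int, int], str] = {}
    for (r, c) in pixels:
        n = sum((r + dr, c + dc) in pixels for dr, dc in _NEIGHBOR_OFFSETS)
        if n == 0:
            raise TooSmallObjectError(f"isolated skeleton pixel at {(r, c)}")
        out[(r, c)] = "terminal" if n == 1 else ("edge" if n == 2 else "branching")
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------


@dataclass
class GraphNode:
    id: int
    coord: tuple[int, int]
    kind: Literal["terminal", "branching"]


@dataclass
class GraphEdge:
    node_a: int
    node_b: int
    polyline: list[tuple[int, int]]
    length_px: float


@dataclass
class PlantGraph:
    """Skeleton graph: terminal/branching nodes joined by pixel-polyline
    edges carrying digital geodesic lengths."""

    nodes: list[GraphNode]
    edges: list[GraphEdge]
    source_region_id: int = 0
    _by_id: dict[int, GraphNode] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {n.id: n for n in self.nodes}

    def node(self, node_id: int) -> GraphNode:
        return self._by_id[node_id]

    def degrees(self) -> dict[int, int]:
        deg = {n.id: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.node_a] += 1
            deg[e.node_b] += 1
        return deg

    def incident(self, node_id: int) -> list[GraphEdge]:
        return [e for e in self.edges if node_id in (e.node_a, e.node_b)]

    def total_length(self) -> float:
        return sum(e.length_px for e in self.edges)

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, coord=n.coord, kind=n.kind)
        for i, e in enumerate(self.edges):
            g.add_edge(e.node_a, e.node_b, key=i, weight=e.length_px, index=i)
        return g

    # -- debugging / fixture serialization ---------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "source_region_id": self.source_region_id,
                "nodes": [
                    {"id": n.id, "coord": list(n.coord), "kind": n.kind}
                    for n in self.nodes
                ],
                "edges": [
                    {
                        "node_a": e.node_a,
                        "node_b": e.node_b,
                        "length_px": e.length_px,
                        "polyline": [list(p) for p in e.polyline],
                    }
                    for e in self.edges
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantGraph":
        data = json.loads(text)
        nodes = [
            GraphNode(id=n["id"], coord=tuple(n["coord"]), kind=n["kind"])
            for n in data["nodes"]
        ]
        edges = [
            GraphEdge(
                node_a=e["node_a"],
                node_b=e["node_b"],
                polyline=[tuple(p) for p in e["polyline"]],
                length_px=e["length_px"],
            )
            for e in data["edges"]
        ]
        return cls(nodes=nodes, edges=edges,
                   source_region_id=data.get("source_region_id", 0))


def _cluster_branch_pixels(
    branch: set[tuple[int, int]]
) -> list[list[tuple[int, int]]]:
    """8-connected clusters of branching pixels (adjacent branch pixels are a
    single junction; separate junction nodes one pixel apart are thinning
    artifacts)."""
    clusters: list[list[tuple[int, int]]] = []
    todo = set(branch)
    while todo:
        seed = todo.pop()
        stack, members = [seed], [seed]
        while stack:
            r, c = stack.pop()
            for dr, dc in _NEIGHBOR_OFFSETS:
                q = (r + dr, c + dc)
                if q in todo:
                    todo.remove(q)
                    stack.append(q)
                    members.append(q)
        clusters.append(members)
    return clusters


def _intra_cluster_path(
    cluster: set[tuple[int, int]],
    start: tuple[int, int],
    goal: tuple[int, int],
) -> list[tuple[int, int]]:
    """Shortest 8-connected pixel path within a junction cluster (clusters
    are tiny; plain Dijkstra over the member pixels)."""
    if start == goal:
        return [start]
    import heapq

    dist = {start: 0.0}
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    heap = [(0.0, start)]
    while heap:
        d, p = heapq.heappop(heap)
        if p == goal:
            break
        if d > dist.get(p, math.inf):
            continue
        r, c = p
        for dr, dc in _NEIGHBOR_OFFSETS:
            q = (r + dr, c + dc)
            if q not in cluster:
                continue
            nd = d + (SQRT2 if dr and dc else 1.0)
            if nd < dist.get(q, math.inf):
                dist[q] = nd
                prev[q] = p
                heapq.heappush(heap, (nd, q))
    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    return list(reversed(path))


def build_graph(skel: Skeleton) -> PlantGraph:
    """Convert a classified skeleton into a :class:`PlantGraph`.

    Clusters of mutually adjacent branching pixels collapse into a single
    branching node placed at the member pixel nearest the cluster centroid;
    maximal runs of edge points become polyline edges.  Edge polylines are
    extended through the junction cluster to the representative pixel, so
    collapsing a cluster to a point does not shorten geodesic path lengths.
    """
    pixels = skel.pixel_set
    kinds = classify_pixels(skel)
    branch = {p for p, k in kinds.items() if k == "branching"}
    terminals = sorted(p for p, k in kinds.items() if k == "terminal")

    pixel2node: dict[tuple[int, int], int] = {}
    node_specs: list[tuple[tuple[int, int], str]] = []
    cluster_of: list[set[tuple[int, int]]] = []
    for cluster in _cluster_branch_pixels(branch):
        centroid = np.mean(cluster, axis=0)
        rep = min(
            cluster,
            key=lambda p: (abs(p[0] - centroid[0]) ** 2 + abs(p[1] - centroid[1]) ** 2,
                           p),
        )
        node_specs.append((rep, "branching"))
        cluster_of.append(set(cluster))
        for p in cluster:
            pixel2node[p] = len(node_specs) - 1
    for t in terminals:
        node_specs.append((t, "terminal"))
        cluster_of.append({t})
        pixel2node[t] = len(node_specs) - 1

    # renumber nodes deterministically by coordinate
    order = sorted(range(len(node_specs)), key=lambda i: node_specs[i][0])
    remap = {old: new for new, old in enumerate(order)}
    nodes = [
        GraphNode(id=remap[i], coord=spec[0], kind=spec[1])  # type: ignore[arg-type]
        for i, spec in enumerate(node_specs)
    ]
    nodes.sort(key=lambda n: n.id)
    pixel2node = {p: remap[i] for p, i in pixel2node.items()}
    cluster_by_node = {remap[i]: members for i, members in enumerate(cluster_of)}
    rep_by_node = {n.id: n.coord for n in nodes}
    node_pixels = set(pixel2node)

    def tail(node_id: int, member: tuple[int, int]) -> list[tuple[int, int]]:
        """Pixel path from the node's representative to the given member."""
        return _intra_cluster_path(
            cluster_by_node[node_id], rep_by_node[node_id], member
        )

    edges: list[GraphEdge] = []
    consumed: set[tuple[int, int]] = set()       # interior edge pixels already traced
    direct_seen: set[frozenset] = set()          # node-pixel adjacencies already used

    def neighbors(p: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = p
        return [q for dr, dc in _NEIGHBOR_OFFSETS if (q := (r + dr, c + dc)) in pixels]

    for start_pixel in sorted(node_pixels):
        a = pixel2node[start_pixel]
        for nb in neighbors(start_pixel):
            if nb in node_pixels:
                b = pixel2node[nb]
                if b == a:
                    continue  # within one junction cluster
                key = frozenset((start_pixel, nb))
                if key in direct_seen:
                    continue
                direct_seen.add(key)
                poly = tail(a, start_pixel) + list(reversed(tail(b, nb)))
                edges.append(GraphEdge(a, b, poly, polyline_length(poly)))
                continue
            if nb in consumed:
                continue
            # walk the run of edge points to the next node pixel
            run = [nb]
            consumed.add(nb)
            prev, cur = start_pixel, nb
            while cur not in node_pixels:
                nxts = [q for q in neighbors(cur) if q != prev]
                nxt = nxts[0]
                run.append(nxt)
                if nxt not in node_pixels:
                    consumed.add(nxt)
                prev, cur = cur, nxt
            b = pixel2node[cur]
            poly = tail(a, start_pixel) + run[:-1] + list(reversed(tail(b, cur)))
            edges.append(GraphEdge(a, b, poly, polyline_length(poly)))

    leftover = {p for p, k in kinds.items() if k == "edge"} - consumed
    if leftover:
        raise TooSmallObjectError(
            "skeleton contains a closed loop with no nodes (touching organs?)"
        )
    graph = PlantGraph(nodes=nodes, edges=edges,
                       source_region_id=skel.source_region_id)
    logger.debug("build_graph: %d nodes, %d edges", len(nodes), len(edges))
    return graph


# ---------------------------------------------------------------------------
# simplification and pruning
# ---------------------------------------------------------------------------


def _oriented(edge: GraphEdge, end_node: int) -> list[tuple[int, int]]:
    """Edge polyline oriented so that it finishes at ``end_node``'s side."""
    if edge.node_b == end_node:
        return list(edge.polyline)
    return list(reversed(edge.polyline))


def simplify(graph: PlantGraph) -> PlantGraph:
    """Dissolve every degree-2 node, merging its two incident edges.

    Merged edges concatenate their polylines and sum their lengths, so total
    graph length is conserved exactly.
    """
    nodes = {n.id: n for n in graph.nodes}
    edges = list(graph.edges)
    changed = True
    while changed:
        changed = False
        deg: dict[int, list[GraphEdge]] = {nid: [] for nid in nodes}
        for e in edges:
            deg[e.node_a].append(e)
            deg[e.node_b].append(e)
        for nid, incident in deg.items():
            if len(incident) != 2:
                continue
            e1, e2 = incident
            if e1 is e2:  # self-loop: degree 2 but not dissolvable
                continue
            a = e1.node_a if e1.node_b == nid else e1.node_b
            b = e2.node_b if e2.node_a == nid else e2.node_a
            p1 = _oriented(e1, nid)
            p2 = _oriented(e2, nid)
            p2 = list(reversed(p2))  # now runs from nid outward
            merged_poly = p1 + (p2[1:] if p1[-1] == p2[0] else p2)
            merged = GraphEdge(a, b, merged_poly, e1.length_px + e2.length_px)
            edges = [e for e in edges if e is not e1 and e is not e2]
            edges.append(merged)
            del nodes[nid]
            changed = True
            break
    return PlantGraph(
        nodes=sorted(nodes.values(), key=lambda n: n.id),
        edges=edges,
        source_region_id=graph.source_region_id,
    )


def basal_terminal(graph: PlantGraph) -> int:
    """Id of the bottom-most terminal node (greatest row, ties to the
    smallest column): the anchor of the shoot base."""
    deg = graph.degrees()
    terms = [n for n in graph.nodes if deg[n.id] == 1]
    if not terms:
        terms = list(graph.nodes)
    return min(terms, key=lambda n: (-n.coord[0], n.coord[1])).id


def prune(graph: PlantGraph, cfg: AnalysisConfig) -> PlantGraph:
    """Remove artifact spurs: one pass over the terminal edges of the input
    graph, deleting every one strictly shorter than the threshold together
    with its terminal node — except the basal edge (the terminal edge whose
    endpoint is the bottom-most node), which is exempt regardless of length.

    Former junctions left with degree 2 are then dissolved.  Coleoptile runs
    skip pruning entirely, since a whole coleoptile can be shorter than the
    threshold.
    """
    if cfg.plant_type == "coleoptile":
        return graph
    deg = graph.degrees()
    protected_node = basal_terminal(graph)
    drop_nodes: set[int] = set()
    drop_edges: list[GraphEdge] = []
    for e in graph.edges:
        term_ends = [nid for nid in (e.node_a, e.node_b) if deg[nid] == 1]
        if not term_ends:
            continue
        if protected_node in term_ends:
            continue
        if e.length_px < cfg.prune_threshold_px:
            drop_edges.append(e)
            drop_nodes.update(term_ends)
    drop_ids = {id(e) for e in drop_edges}
    kept_nodes = [n for n in graph.nodes if n.id not in drop_nodes]
    kept_edges = [e for e in graph.edges if id(e) not in drop_ids]
    if len(kept_nodes) < 2:
        raise AllPrunedError("pruning would leave fewer than two nodes")
    pruned = PlantGraph(
        nodes=kept_nodes, edges=kept_edges,
        source_region_id=graph.source_region_id,
    )
    out = simplify(pruned)
    if len(out.nodes) < 2:
        raise AllPrunedError("pruning would leave fewer than two nodes")
    logger.debug(
        "prune: %d -> %d nodes (%d spur(s) removed)",
        len(graph.nodes), len(out.nodes), len(drop_edges),
    )
    return out


# ---------------------------------------------------------------------------
# geodesics
# ---------------------------------------------------------------------------


@dataclass
class GeodesicTable:
    """Single-source shortest-path distances and predecessors."""

    source_node_id: int
    dist: dict[int, float]
    parent: dict[int, Optional[int]]

    def path_to(self, node_id: int) -> list[int]:
        """Node sequence of one shortest path source -> ``node_id``."""
        path = [node_id]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])  # type: ignore[arg-type]
        return list(reversed(path))


def geodesics(graph: PlantGraph, source: int) -> GeodesicTable:
    """All shortest paths from ``source`` (Dijkstra on edge lengths)."""
    g = graph.to_networkx()
    if source not in g:
        raise UnreachableNodeError(f"source node {source} not in graph")
    dist, paths = nx.single_source_dijkstra(g, source, weight="weight")
    if len(dist) < len(graph.nodes):
        missing = sorted(set(n.id for n in graph.nodes) - set(dist))
        raise UnreachableNodeError(f"nodes unreachable from {source}: {missing}")
    parent: dict[int, Optional[int]] = {source: None}
    for nid, p in paths.items():
        if nid != source:
            parent[nid] = p[-2]
    return GeodesicTable(source_node_id=source, dist=dict(dist), parent=parent)
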