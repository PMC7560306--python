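"""Shared test utilities: independent oracles and graph/scene builders."""

from __future__ import annotations

import numpy as np

from shootscan.fixtures import PlantSpec
from shootscan.skeletongraph import GraphEdge, GraphNode, PlantGraph

# The default synthetic scene places a 390-px scale bar on a 1600-px-wide
# canvas, so the corner search window must cover a quarter of the width.
SCENE_CORNER_FRAC = 0.25


def brute_force_otsu(gray: np.ndarray) -> int:
    """Exhaustive between-class-variance scan over all 256 integer cuts.

    Threshold T splits pixels into {v < T} and {v >= T}; the smallest
    maximizing T is returned.  Deliberately a plain Python loop, independent
    of the vectorized implementation it checks.
    """
    vals = np.clip(np.round(np.asarray(gray, float)), 0, 255).astype(int).ravel()
    n = len(vals)
    best_t, best_var = 0, -1.0
    for t in range(256):
        low = vals[vals < t]
        high = vals[vals >= t]
        if len(low) == 0 or len(high) == 0:
            var = 0.0
        else:
            w0, w1 = len(low) / n, len(high) / n
            var = w0 * w1 * (low.mean() - high.mean()) ** 2
        if var > best_var:
            best_t, best_var = t, var
    return best_t


def brute_force_shortest_paths(graph: PlantGraph, source: int) -> dict[int, float]:
    """Shortest-path distances by exhaustive simple-path enumeration."""
    adj: dict[int, list[tuple[int, float]]] = {n.id: [] for n in graph.nodes}
    for e in graph.edges:
        adj[e.node_a].append((e.node_b, e.length_px))
        adj[e.node_b].append((e.node_a, e.length_px))
    best = {n.id: float("inf") for n in graph.nodes}
    best[source] = 0.0

    def walk(node: int, dist: float, seen: set[int]) -> None:
        for other, w in adj[node]:
            if other in seen:
                continue
            nd = dist + w
            if nd < best[other]:
                best[other] = nd
            walk(other, nd, seen | {other})

    walk(source, 0.0, {source})
    return best


def abstract_graph(
    nodes: dict[int, tuple[int, int]], edges: list[tuple[int, int, float]]
) -> PlantGraph:
    """PlantGraph with explicit edge lengths (polylines are just endpoints)."""
    deg = {nid: 0 for nid in nodes}
    for a, b, _ in edges:
        deg[a] += 1
        deg[b] += 1
    gnodes = [
        GraphNode(id=nid, coord=coord, kind="terminal" if deg[nid] == 1 else "branching")
        for nid, coord in nodes.items()
    ]
    gedges = [
        GraphEdge(node_a=a, node_b=b, polyline=[nodes[a], nodes[b]], length_px=w)
        for a, b, w in edges
    ]
    return PlantGraph(nodes=gnodes, edges=gedges)


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 10) -> PlantGraph:
    """Random connected weighted graph (spanning tree plus extra chords)."""
    n = int(rng.integers(2, max_nodes + 1))
    coords = {}
    used = set()
    for i in range(n):
        while True:
            c = (int(rng.integers(0, 200)), int(rng.integers(0, 200)))
            if c not in used:
                used.add(c)
                coords[i] = c
                break
    edges = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.append((j, i, float(rng.uniform(1.0, 50.0))))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.append((int(a), int(b), float(rng.uniform(1.0, 50.0))))
    return abstract_graph(coords, edges)


def random_tree_graph(rng: np.random.Generator, max_nodes: int = 12) -> PlantGraph:
    """Random tree with random edge lengths (for prune/simplify properties)."""
    n = int(rng.integers(3, max_nodes + 1))
    coords = {}
    used = set()
    for i in range(n):
        while True:
            c = (int(rng.integers(0, 500)), int(rng.integers(0, 500)))
            if c not in used:
                used.add(c)
                coords[i] = c
                break
    edges = [
        (int(rng.integers(0, i)), i, float(rng.uniform(5.0, 120.0)))
        for i in range(1, n)
    ]
    return abstract_graph(coords, edges)


def random_plant_tree(rng: np.random.Generator) -> PlantGraph:
    """Plant-like random tree: a vertical backbone of long internal edges
    with short-to-long lateral spurs hanging off random backbone nodes."""
    m = int(rng.integers(3, 7))
    coords = {}
    row = 500
    for i in range(m):
        coords[i] = (row, 250 + int(rng.integers(-3, 4)))
        row -= int(rng.integers(80, 200))
    edges = [
        (i, i + 1, float(abs(coords[i][0] - coords[i + 1][0]))) for i in range(m - 1)
    ]
    nid = m
    for backbone in range(1, m - 1):
        for _ in range(int(rng.integers(0, 3))):
            length = float(rng.uniform(5.0, 150.0))
            coords[nid] = (
                coords[backbone][0] - int(rng.integers(0, 40)),
                coords[backbone][1] + int(rng.choice((-1, 1))) * (40 + nid),
            )
            edges.append((backbone, nid, length))
            nid += 1
    return abstract_graph(coords, edges)


def scale_plant_spec(spec: PlantSpec, s: int) -> PlantSpec:
    """Scale all plant geometry by an integer factor (stroke width kept, so
    the pixel-scale skeletonization bias is identical at both scales)."""
    stem = [(r * s, c * s) for r, c in spec.stem_points]
    leaves = [(i, [(r * s, c * s) for r, c in pts]) for i, pts in spec.leaves]
    tick = None
    if spec.tick is not None:
        tick = (spec.tick[0] * s, spec.tick[1] * s, spec.tick[2] * s)
    return PlantSpec(
        stem_points=stem, leaves=leaves, stroke_width=spec.stroke_width, tick=tick
    )
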