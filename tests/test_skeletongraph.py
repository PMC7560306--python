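"""Skeletonization, graph conversion, pruning, simplification, geodesics."""

import math

import numpy as np
import pytest

from shootscan import fixtures as fx
from shootscan.errors import TooSmallObjectError, UnreachableNodeError
from shootscan.imaging import AnalysisConfig, Region
from shootscan.skeletongraph import (
    Skeleton,
    build_graph,
    classify_pixels,
    geodesics,
    polyline_length,
    prune,
    simplify,
    skeletonize,
)

from helpers import abstract_graph, brute_force_shortest_paths, random_tree_graph

SQRT2 = math.sqrt(2.0)


def region_from_mask(mask, rid=1):
    coords = np.argwhere(mask)
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    return Region(id=rid, coords=coords, contour=[],
                  bbox=(int(r0), int(c0), int(r1), int(c1)),
                  image_shape=mask.shape)


class TestSkeletonize:
    def test_thin_line_is_unchanged(self):
        mask = np.zeros((20, 120), bool)
        mask[10, 5:105] = True
        skel = skeletonize(region_from_mask(mask))
        assert skel.pixel_set == {(10, c) for c in range(5, 105)}

    def test_filled_rectangle_reduces_to_a_path(self):
        mask = np.zeros((20, 120), bool)
        mask[5:10, 5:106] = True  # 5 x 101 rectangle
        skel = skeletonize(region_from_mask(mask))
        graph = build_graph(skel)
        assert len(graph.nodes) == 2
        assert 96 <= graph.total_length() <= 106

    @pytest.mark.parametrize("fixture", ["line", "diagonal", "y", "spurs"])
    def test_idempotent_on_thin_structures(self, fixture):
        if fixture == "line":
            pixels = [(10, c) for c in range(5, 80)]
        elif fixture == "diagonal":
            pixels = [(5 + i, 5 + i) for i in range(60)]
        elif fixture == "y":
            pixels = fx.rasterize_polyline(
                [(200, 100), (100, 100), (20, 20)]
            ).tolist() + fx.rasterize_polyline([(100, 100), (20, 180)]).tolist()
        else:
            skel, _ = fx.make_skeleton_fixture(fx.spur_tree_spec())
            pixels = skel.pixels.tolist()
        coords = np.array(sorted({tuple(p) for p in pixels}))
        shape = tuple(coords.max(axis=0) + 5)
        mask = np.zeros(shape, bool)
        mask[coords[:, 0], coords[:, 1]] = True
        skel = skeletonize(region_from_mask(mask))
        assert skel.pixel_set == {tuple(p) for p in coords}

    def test_single_pixel_region_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        with pytest.raises(TooSmallObjectError):
            skeletonize(region_from_mask(mask))


class TestClassifyPixels:
    def test_neighbor_count_rule(self):
        # horizontal 3-px line: ends terminal, middle is an edge point
        skel = Skeleton(pixels=[(5, 4), (5, 5), (5, 6)])
        kinds = classify_pixels(skel)
        assert kinds[(5, 4)] == "terminal"
        assert kinds[(5, 5)] == "edge"
        assert kinds[(5, 6)] == "terminal"

    def test_plus_center_is_branching(self):
        # plus with 2-px arms: the center has four neighbors
        pixels = [(5, 5)]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            pixels += [(5 + dr, 5 + dc), (5 + 2 * dr, 5 + 2 * dc)]
        kinds = classify_pixels(Skeleton(pixels=pixels))
        assert kinds[(5, 5)] == "branching"
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            assert kinds[(5 + 2 * dr, 5 + 2 * dc)] == "terminal"

    def test_isolated_pixel_rejected(self):
        with pytest.raises(TooSmallObjectError):
            classify_pixels(Skeleton(pixels=[(0, 0), (10, 10)]))


class TestBuildGraph:
    def test_straight_line(self):
        skel = Skeleton(pixels=[(10, c) for c in range(100)])
        g = build_graph(skel)
        assert len(g.nodes) == 2 and len(g.edges) == 1
        assert all(n.kind == "terminal" for n in g.nodes)
        assert g.edges[0].length_px == pytest.approx(99.0)
        assert len(g.edges[0].polyline) == 100

    def test_perfect_diagonal(self):
        skel = Skeleton(pixels=[(i, i) for i in range(100)])
        g = build_graph(skel)
        assert g.edges[0].length_px == pytest.approx(99 * SQRT2)

    def test_y_shape(self):
        skel, _ = fx.make_skeleton_fixture(fx.y_tree_spec())
        g = build_graph(skel)
        kinds = sorted(n.kind for n in g.nodes)
        assert kinds == ["branching", "terminal", "terminal", "terminal"]
        assert len(g.edges) == 3

    def test_closed_loop_without_nodes_rejected(self):
        # diamond ring: every pixel has exactly two (diagonal) neighbors
        ring = [(r, c) for r in range(11) for c in range(11)
                if abs(r - 5) + abs(c - 5) == 3]
        with pytest.raises(TooSmallObjectError):
            build_graph(Skeleton(pixels=ring))


class TestSimplify:
    def test_degree_two_chain_merges(self):
        g = abstract_graph(
            {0: (0, 0), 1: (0, 30), 2: (0, 70)},
            [(0, 1, 30.0), (1, 2, 40.0)],
        )
        out = simplify(g)
        assert len(out.nodes) == 2 and len(out.edges) == 1
        assert out.edges[0].length_px == pytest.approx(70.0)

    def test_no_degree_two_nodes_is_identity(self):
        skel, _ = fx.make_skeleton_fixture(fx.y_tree_spec())
        g = build_graph(skel)
        out = simplify(g)
        assert len(out.nodes) == len(g.nodes)
        assert out.total_length() == pytest.approx(g.total_length())

    @pytest.mark.parametrize("seed", range(8))
    def test_total_length_conserved(self, seed):
        g = random_tree_graph(np.random.default_rng(seed))
        assert simplify(g).total_length() == pytest.approx(g.total_length())


class TestPrune:
    def tree_with_spur(self, spur_len, junction_degree=4):
        nodes = {0: (200, 100), 1: (100, 100), 2: (0, 100), 3: (100, 140)}
        edges = [(0, 1, 100.0), (1, 2, 100.0), (1, 3, spur_len)]
        if junction_degree == 4:
            nodes[4] = (60, 40)
            edges.append((1, 4, 80.0))
        return abstract_graph(nodes, edges)

    def test_short_spur_at_degree4_junction_removed(self):
        g = self.tree_with_spur(49.2)
        out = prune(g, AnalysisConfig())
        assert len(out.nodes) == 4  # junction survives as a degree-3 node
        assert 3 not in {n.id for n in out.nodes}

    def test_spur_of_exactly_threshold_length_kept(self):
        g = self.tree_with_spur(50.0)
        out = prune(g, AnalysisConfig())
        assert len(out.nodes) == 5

    def test_basal_edge_exempt_regardless_of_length(self):
        # bottom-most terminal hangs on a 10-px edge
        g = abstract_graph(
            {0: (210, 100), 1: (200, 100), 2: (100, 100), 3: (0, 100), 4: (100, 160)},
            [(0, 1, 10.0), (1, 2, 100.0), (2, 3, 100.0), (2, 4, 60.0)],
        )
        out = prune(g, AnalysisConfig())
        assert 0 in {n.id for n in out.nodes}

    def test_spur_at_degree3_junction_dissolves_the_junction(self):
        g = self.tree_with_spur(30.0, junction_degree=3)
        out = prune(g, AnalysisConfig())
        assert len(out.nodes) == 2  # spur node and junction both gone
        assert out.total_length() == pytest.approx(200.0)

    def test_nine_node_fixture_prunes_to_seven(self):
        skel, _ = fx.make_skeleton_fixture(fx.spur_tree_spec())
        g = build_graph(skel)
        assert len(g.nodes) == 9
        out = prune(g, AnalysisConfig())
        assert len(out.nodes) == 7

    def test_coleoptile_mode_skips_pruning(self):
        g = self.tree_with_spur(5.0)
        out = prune(g, AnalysisConfig(plant_type="coleoptile"))
        assert len(out.nodes) == len(g.nodes)

    @pytest.mark.parametrize("seed", range(10))
    def test_no_short_terminal_edge_survives_except_basal(self, seed):
        from helpers import random_plant_tree

        g = random_plant_tree(np.random.default_rng(100 + seed))
        cfg = AnalysisConfig()
        out = prune(g, cfg)
        deg = out.degrees()
        basal = max(
            (n for n in out.nodes if deg[n.id] == 1),
            key=lambda n: (n.coord[0], -n.coord[1]),
        )
        for e in out.edges:
            terms = [nid for nid in (e.node_a, e.node_b) if deg[nid] == 1]
            if terms and basal.id not in terms:
                assert e.length_px >= cfg.prune_threshold_px


class TestGeodesics:
    def test_path_graph_distances(self):
        g = abstract_graph(
            {0: (0, 0), 1: (0, 3), 2: (0, 7)}, [(0, 1, 3.0), (1, 2, 4.0)]
        )
        table = geodesics(g, 0)
        assert table.dist == {0: 0.0, 1: 3.0, 2: 7.0}
        assert table.path_to(2) == [0, 1, 2]

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_distance_is_unique_path_sum(self, seed):
        g = random_tree_graph(np.random.default_rng(seed))
        table = geodesics(g, 0)
        oracle = brute_force_shortest_paths(g, 0)
        for nid, d in table.dist.items():
            assert d == pytest.approx(oracle[nid])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        g = random_connected(seed)
        table = geodesics(g, 0)
        oracle = brute_force_shortest_paths(g, 0)
        assert set(table.dist) == set(oracle)
        for nid in oracle:
            assert table.dist[nid] == oracle[nid]  # exact, no tolerance

    def test_disconnected_graph_rejected(self):
        g = abstract_graph(
            {0: (0, 0), 1: (0, 5), 2: (9, 0), 3: (9, 5)},
            [(0, 1, 5.0), (2, 3, 5.0)],
        )
        with pytest.raises(UnreachableNodeError):
            geodesics(g, 0)


def random_connected(seed):
    from helpers import random_connected_graph

    return random_connected_graph(np.random.default_rng(seed))


def test_polyline_length_rejects_non_king_moves():
    with pytest.raises(ValueError):
        polyline_length([(0, 0), (0, 2)])
    assert polyline_length([(0, 0), (1, 1), (1, 2)]) == pytest.approx(SQRT2 + 1)


def test_plantgraph_json_roundtrip():
    skel, _ = fx.make_skeleton_fixture(fx.y_tree_spec())
    g = build_graph(skel)
    from shootscan.skeletongraph import PlantGraph

    g2 = PlantGraph.from_json(g.to_json())
    assert [n.id for n in g2.nodes] == [n.id for n in g.nodes]
    assert g2.total_length() == pytest.approx(g.total_length())
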