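"""Vectorial graph extraction: classification, tracing, cleanup, meshes."""

import math

import numpy as np
import pytest

from angioquant.graph import (
    Edge,
    Extremity,
    GraphParams,
    Junction,
    NetworkGraph,
    assemble_graph,
    build_graph,
    build_junctions,
    classify_anchorage,
    classify_pixels,
    fuse_close_junctions,
    prune_small_branches,
    remove_small_isolated,
)
from angioquant.segmentation import Skeleton
from angioquant.spheres import Circle


def sk_from_pixels(pts, shape=(64, 64), circles=()):
    px = np.zeros(shape, dtype=bool)
    for y, x in pts:
        px[y, x] = True
    return Skeleton(pixels=px, source_circles=tuple(circles))


def hline(y, x0, x1):
    return [(y, x) for x in range(x0, x1 + 1)]


def vline(x, y0, y1):
    return [(y, x) for y in range(y0, y1 + 1)]


# ---------------------------------------------------------------------------
# Pixel classification
# ---------------------------------------------------------------------------

def test_all_256_neighborhoods_match_brute_force():
    """Exhaustive 3x3 neighborhood classification against direct counting."""
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]
    for config in range(256):
        img = np.zeros((5, 5), dtype=bool)
        img[2, 2] = True
        n_set = 0
        for bit, (dy, dx) in enumerate(offsets):
            if config >> bit & 1:
                img[2 + dy, 2 + dx] = True
                n_set += 1
        nodes, ends = classify_pixels(img)
        assert ((2, 2) in nodes) == (n_set >= 3)
        assert ((2, 2) in ends) == (n_set == 1)


def test_plus_shape_center_nodes_merge_into_one_junction():
    # the crossing pixel and its four axial neighbors all have >= 3
    # neighbors (diagonal adjacency); their dots overlap into one junction
    pts = hline(10, 6, 14) + vline(10, 6, 14)
    nodes, ends = classify_pixels(sk_from_pixels(pts))
    assert (10, 10) in nodes
    assert all(abs(y - 10) + abs(x - 10) <= 1 for y, x in nodes)
    assert sorted(ends) == [(6, 10), (10, 6), (10, 14), (14, 10)]
    assert len(build_junctions(nodes, GraphParams(), (64, 64))) == 1


def test_straight_line_has_two_extremities_no_nodes():
    nodes, ends = classify_pixels(sk_from_pixels(hline(5, 10, 19)))
    assert nodes == []
    assert ends == [(5, 10), (5, 19)]


# ---------------------------------------------------------------------------
# Junction construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("nodes,expected", [
    ([(10, 10), (10, 11), (11, 10), (11, 11)], 1),   # adjacent cluster
    ([(10, 10), (10, 40)], 2),                        # far apart
    ([(10, 10), (10, 15)], 1),                        # 5 px: disks overlap
    ([(10, 10), (10, 16)], 1),                        # 6 px: still overlap
])
def test_node_dot_merging(nodes, expected):
    junctions = build_junctions(nodes, GraphParams(), (64, 64))
    assert len(junctions) == expected


# ---------------------------------------------------------------------------
# Edge tracing
# ---------------------------------------------------------------------------

def test_y_shape_traces_one_junction_three_branches():
    pts = (vline(30, 30, 50)                       # stem down from center
           + [(30 - k, 30 - k) for k in range(1, 15)]
           + [(30 - k, 30 + k) for k in range(1, 15)])
    pts.append((30, 30))
    g = assemble_graph(sk_from_pixels(pts, (64, 64)), GraphParams())
    kinds = sorted(e.kind for e in g.edges.values())
    assert len(g.junctions) == 1
    assert kinds == ["branch", "branch", "branch"]


def test_h_shape_traces_two_junctions_one_segment_four_branches():
    pts = (vline(10, 2, 22) + vline(24, 2, 22) + hline(12, 11, 23))
    g = assemble_graph(sk_from_pixels(pts, (32, 40)), GraphParams())
    kinds = sorted(e.kind for e in g.edges.values())
    assert len(g.junctions) == 2
    assert kinds == ["branch", "branch", "branch", "branch", "segment"]


def test_diagonal_line_is_isolated_with_sqrt2_steps():
    pts = [(5 + k, 5 + k) for k in range(10)]
    g = assemble_graph(sk_from_pixels(pts, (32, 32)), GraphParams())
    (e,) = g.edges.values()
    assert e.kind == "isolated"
    assert e.length == pytest.approx(9 * math.sqrt(2))


def test_every_free_pixel_belongs_to_exactly_one_polyline():
    # pixel conservation on a branched figure: skeleton pixels outside
    # junction blobs partition into edge polylines
    pts = (vline(20, 2, 38) + hline(20, 20, 38) + [(20 - k, 20 - k) for k in range(1, 12)])
    sk = sk_from_pixels(pts, (48, 48))
    g = assemble_graph(sk, GraphParams())
    blob = set()
    for j in g.junctions.values():
        blob |= set(j.blob_pixels)
    free = {tuple(p) for p in np.argwhere(sk.pixels)} - blob
    seen = []
    for e in g.edges.values():
        seen.extend(map(tuple, e.polyline))
    assert sorted(seen) == sorted(free)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def cross_pts(cy, cx, arm):
    return ([(cy, x) for x in range(cx - arm, cx + arm + 1)]
            + [(y, cx) for y in range(cy - arm, cy + arm + 1)])


def two_junction_graph(sep):
    """Two 3-armed junctions joined by a horizontal bar of length sep."""
    pts = set()
    for cx in (20, 20 + sep):
        pts.update([(20, x) for x in range(cx - 1, cx + 2)])
        pts.update([(y, cx) for y in range(8, 33)])       # vertical arms
    pts.update((20, x) for x in range(20, 21 + sep))      # connecting bar
    return sk_from_pixels(sorted(pts), (48, 48 + sep))


def test_close_junction_pair_fuses_and_preserves_arms():
    g = assemble_graph(two_junction_graph(15), GraphParams())
    assert len(g.junctions) == 2
    n_edges = len(g.edges)
    g = fuse_close_junctions(g, GraphParams())
    assert len(g.junctions) == 1
    assert len(g.edges) == n_edges - 1          # only the bar disappeared
    g.check_invariants()


def test_distant_junction_pair_does_not_fuse():
    g = assemble_graph(two_junction_graph(25), GraphParams())
    g = fuse_close_junctions(g, GraphParams())
    assert len(g.junctions) == 2


def test_junction_chain_fuses_transitively():
    pts = set()
    for cx in (20, 32, 44):
        pts.update((y, cx) for y in range(8, 33))
    pts.update((20, x) for x in range(20, 45))
    g = assemble_graph(sk_from_pixels(sorted(pts), (48, 72)), GraphParams())
    assert len(g.junctions) == 3
    g = fuse_close_junctions(g, GraphParams())
    assert len(g.junctions) == 1
    g.check_invariants()


def test_fusion_is_idempotent_at_fixed_point():
    g = assemble_graph(two_junction_graph(15), GraphParams())
    g = fuse_close_junctions(g, GraphParams())
    before = {k: (e.kind, e.length) for k, e in g.edges.items()}
    g = fuse_close_junctions(g, GraphParams())
    assert {k: (e.kind, e.length) for k, e in g.edges.items()} == before


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def test_small_spur_pruned_and_junction_dissolved():
    pts = hline(20, 5, 45) + vline(25, 17, 19)     # 3-px spur off a line
    g = assemble_graph(sk_from_pixels(pts, (40, 56)), GraphParams())
    assert len(g.junctions) == 1
    g = prune_small_branches(g, GraphParams())
    assert len(g.junctions) == 0
    (e,) = g.edges.values()
    assert e.kind == "isolated"


def test_branch_of_exactly_threshold_length_is_kept():
    # boundary convention, strict < threshold: a 10-px terminal extension
    # survives pruning, a 9-px one does not
    def synthetic(spur_len):
        g = NetworkGraph(shape=(64, 64))
        g.junctions[0] = Junction(id=0, member_dots=((30, 30),),
                                  blob_pixels=frozenset({(30, 30)}),
                                  centroid=(30.0, 30.0))
        g.extremities = {0: Extremity(id=0, y=30, x=5),
                         1: Extremity(id=1, y=30 - spur_len, x=30)}
        g.edges[0] = Edge(0, "branch", [(30, x) for x in range(5, 30)], 24.0,
                          (("extremity", 0), ("junction", 0)))
        g.edges[1] = Edge(1, "branch",
                          [(30 - k, 30) for k in range(1, spur_len + 1)],
                          float(spur_len),
                          (("junction", 0), ("extremity", 1)))
        return prune_small_branches(g, GraphParams())

    kept = synthetic(10)
    assert sum(e.length for e in kept.edges.values()) > 30.0
    pruned = synthetic(9)
    assert sum(e.length for e in pruned.edges.values()) == pytest.approx(24.0)


def test_comb_teeth_removed_in_one_fixed_point_run():
    pts = set(hline(20, 5, 60))
    for x in (20, 28, 36, 44, 52):
        pts.update(vline(x, 16, 19))
    g = assemble_graph(sk_from_pixels(sorted(pts), (40, 72)), GraphParams())
    g = prune_small_branches(g, GraphParams())
    assert len(g.junctions) == 0
    (e,) = g.edges.values()
    assert e.polyline[0][0] == 20 and e.polyline[-1][0] == 20
    g.check_invariants()


def test_pruning_is_idempotent_at_fixed_point():
    pts = set(hline(20, 5, 60))
    for x in (20, 36):
        pts.update(vline(x, 16, 19))
    g = assemble_graph(sk_from_pixels(sorted(pts), (40, 72)), GraphParams())
    g = prune_small_branches(g, GraphParams())
    snapshot = {k: (e.kind, e.length) for k, e in g.edges.items()}
    g = prune_small_branches(g, GraphParams())
    assert {k: (e.kind, e.length) for k, e in g.edges.items()} == snapshot


# ---------------------------------------------------------------------------
# Anchorage
# ---------------------------------------------------------------------------

def radial_skeleton(circle, angle_deg, length, shape=(128, 128)):
    th = math.radians(angle_deg)
    pts = []
    for r in np.arange(circle.radius + 0.5, circle.radius + length, 0.7):
        y = int(round(circle.cy + r * math.sin(th)))
        x = int(round(circle.cx + r * math.cos(th)))
        pts.append((y, x))
    return pts


def test_radial_sprout_gets_anchorage_junction():
    c = Circle(cy=64, cx=64, radius=25)
    pts = sorted(set(radial_skeleton(c, 0, 35)))
    g = build_graph(sk_from_pixels(pts, (128, 128), circles=[c]),
                    GraphParams(), mode="FBA")
    anchors = [j for j in g.junctions.values() if j.is_anchorage]
    assert len(anchors) == 1
    assert sum(1 for j in g.junctions.values() if not j.is_anchorage) == 0
    (e,) = g.edges.values()
    assert e.kind == "branch"


def test_residual_rim_arc_is_deleted_as_circle_piece():
    c = Circle(cy=64, cx=64, radius=25)
    pts = set()
    for a in np.arange(0, 120, 1.0):
        th = math.radians(a)
        pts.add((int(round(64 + 25 * math.sin(th))),
                 int(round(64 + 25 * math.cos(th)))))
    g = build_graph(sk_from_pixels(sorted(pts), (128, 128), circles=[c]),
                    GraphParams(), mode="FBA")
    assert len(g.edges) == 0


def test_interior_junction_far_from_rim_is_not_anchorage():
    c = Circle(cy=200, cx=30, radius=20)
    pts = cross_pts(40, 40, 10)
    g = NetworkGraph(shape=(256, 256))
    g = assemble_graph(sk_from_pixels(sorted(set(pts)), (256, 256)), GraphParams())
    g = classify_anchorage(g, (c,))
    assert all(not j.is_anchorage for j in g.junctions.values())


# ---------------------------------------------------------------------------
# Isolated elements
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_pixels,kept", [(10, False), (11, True)])
def test_isolated_element_size_boundary(n_pixels, kept):
    # n axial pixels have path length n-1: 10 px -> length 9 (removed),
    # 11 px -> length 10 (kept, strict <)
    g = assemble_graph(sk_from_pixels(hline(10, 5, 4 + n_pixels), (32, 32)),
                       GraphParams())
    g = remove_small_isolated(g, GraphParams())
    assert bool(g.edges) == kept


def test_short_branch_untouched_by_isolated_filter():
    g = NetworkGraph(shape=(32, 32))
    g.junctions[0] = Junction(id=0, member_dots=((10, 10),),
                              blob_pixels=frozenset({(10, 10)}),
                              centroid=(10.0, 10.0))
    g.extremities[0] = Extremity(id=0, y=10, x=18)
    g.edges[0] = Edge(0, "branch", [(10, x) for x in range(11, 19)], 8.0,
                      (("junction", 0), ("extremity", 0)))
    g = remove_small_isolated(g, GraphParams())
    assert 0 in g.edges


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def grid_skeleton(lines_y, lines_x, shape):
    pts = set()
    for y in lines_y:
        pts.update(hline(y, lines_x[0], lines_x[-1]))
    for x in lines_x:
        pts.update(vline(x, lines_y[0], lines_y[-1]))
    return sk_from_pixels(sorted(pts), shape)


def test_2x2_grid_has_four_meshes_with_expected_areas():
    sk = grid_skeleton([10, 35, 60], [10, 35, 60], (80, 80))
    g = build_graph(sk, GraphParams(), mode="ETFA")
    assert len(g.meshes) == 4
    for m in g.meshes:
        assert m.area == pytest.approx(24 * 24, rel=0.15)


def test_tree_has_no_meshes():
    pts = vline(20, 5, 40) + hline(20, 20, 40)
    g = build_graph(sk_from_pixels(pts, (48, 48)), GraphParams(), mode="ETFA")
    assert g.meshes == []


def test_square_loop_mesh_area_is_interior_of_walls():
    sk = grid_skeleton([10, 109], [10, 109], (128, 128))
    g = build_graph(sk, GraphParams(), mode="ETFA")
    assert len(g.meshes) == 1
    assert g.meshes[0].area == pytest.approx(98 * 98, rel=0.01)
    assert g.cyclomatic_number() == 1


def test_mesh_count_equals_cyclomatic_number_on_grids():
    for (ys, xs) in [([10, 35, 60], [10, 35, 60, 85]),
                     ([10, 40], [10, 40, 70, 100, 130])]:
        shape = (max(ys) + 20, max(xs) + 20)
        g = build_graph(grid_skeleton(ys, xs, shape), GraphParams(), mode="ETFA")
        assert len(g.meshes) == g.cyclomatic_number()
        g.check_invariants()


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def test_graph_json_round_trip_is_lossless():
    sk = grid_skeleton([10, 35, 60], [10, 35, 60], (80, 80))
    g = build_graph(sk, GraphParams(), mode="ETFA")
    doc = g.to_json()
    g2 = NetworkGraph.from_json(doc)
    assert g2.to_json() == doc
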