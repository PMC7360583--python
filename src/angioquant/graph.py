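"""Vectorial modeling of capillary skeletons.

The one-pixel skeleton is converted into the object model used for
morphometry: *node* pixels (>= 3 neighbors) are stamped with 7-px disks
whose overlapping blobs form *junctions*; pixels with one neighbor are
*extremities*; the paths between terminals become *branches*
(junction-extremity), *segments* (junction-junction) or *isolated
elements* (extremity-extremity).  Close junctions are fused, artifactual
small branches are pruned iteratively, junctions on a bead circle become
*anchorage junctions*, small isolated elements are dropped, and in
tube-formation mode the closed areas enclosed by segments are detected as
*meshes*.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from .segmentation import MIN_HOLE_AREA, Skeleton
from .spheres import Circle

__all__ = [
    "GraphParams",
    "Junction",
    "Extremity",
    "Edge",
    "Mesh",
    "NetworkGraph",
    "classify_pixels",
    "build_junctions",
    "trace_edges",
    "fuse_close_junctions",
    "prune_small_branches",
    "classify_anchorage",
    "remove_small_isolated",
    "detect_meshes",
    "build_graph",
]

log = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)
_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
            (0, 1), (1, -1), (1, 0), (1, 1)]

# An edge endpoint (or junction centroid) within this distance of a circle
# ring is considered to lie on the bead boundary.
RING_TOL = 2.0
# Promotion to anchorage tolerates slightly more: the clearing cut and the
# rasterized ring each contribute about a pixel of slack.
PROMOTE_TOL = 3.5
# Two edges leaving a junction more than this many degrees apart run
# "straight through" it; a short leaf there is a spur, not a bifurcation.
THROUGH_ANGLE_DEG = 155.0
# Edges with at least this fraction of pixels on a ring are residual arcs
# of the bead circle itself and are deleted.
CIRCLE_PIECE_FRACTION = 0.8


@dataclass(frozen=True)
class GraphParams:
    """Vectorization tunables (all in pixels).

    ``node_dot_diameter``: diameter of the disk stamped on each node pixel
    (7, so that skeletonization artifacts around a bifurcation merge into
    one junction).  ``junction_fusion_distance``: junctions closer than
    this joined by a shorter segment are fused (20, below the length of
    two aligned endothelial cells).  ``min_object_size``: isolated
    elements shorter than this are discarded (10, the minimum size of an
    isolated cell).  ``prune_min_branch``: branches shorter than this are
    pruned iteratively (10).
    """

    node_dot_diameter: float = 7.0
    junction_fusion_distance: float = 20.0
    min_object_size: float = 10.0
    prune_min_branch: float = 10.0

    def __post_init__(self) -> None:
        for name in ("node_dot_diameter", "junction_fusion_distance",
                     "min_object_size", "prune_min_branch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class Junction:
    id: int
    member_dots: tuple[tuple[int, int], ...]   # constituent node pixels
    blob_pixels: frozenset[tuple[int, int]]    # union of stamped disks
    centroid: tuple[float, float]              # (y, x), mean of member dots
    is_anchorage: bool = False
    circle_index: int | None = None            # bead it anchors on, if any


@dataclass
class Extremity:
    id: int
    y: int
    x: int


@dataclass
class Edge:
    """A skeleton path between two terminals.

    ``kind`` is ``"branch"`` (junction + extremity), ``"segment"`` (two
    junctions, possibly a self-loop) or ``"isolated"`` (two extremities).
    ``endpoints`` are ``("junction", id)`` / ``("extremity", id)`` refs in
    polyline order; ``length`` accumulates 1 per axial and sqrt(2) per
    diagonal step along the polyline.
    """

    id: int
    kind: str
    polyline: list[tuple[int, int]]
    length: float
    endpoints: tuple[tuple[str, int], tuple[str, int]]


@dataclass
class Mesh:
    id: int
    area: int
    boundary_edge_ids: tuple[int, ...]


def _polyline_length(polyline) -> float:
    total = 0.0
    for (y0, x0), (y1, x1) in zip(polyline, polyline[1:]):
        total += math.sqrt(2.0) if (y0 != y1 and x0 != x1) else 1.0
    return total


def _edge_kind(ep0: tuple[str, int], ep1: tuple[str, int]) -> str:
    kinds = sorted((ep0[0], ep1[0]))
    if kinds == ["junction", "junction"]:
        return "segment"
    if kinds == ["extremity", "junction"]:
        return "branch"
    return "isolated"


@dataclass
class NetworkGraph:
    """The vectorial model of one skeleton (junctions, edges, meshes)."""

    shape: tuple[int, int]
    junctions: dict[int, Junction] = field(default_factory=dict)
    extremities: dict[int, Extremity] = field(default_factory=dict)
    edges: dict[int, Edge] = field(default_factory=dict)
    meshes: list[Mesh] = field(default_factory=list)
    circles: tuple[Circle, ...] = ()
    calibration: float | None = None   # pixels per micron, optional

    # -- bookkeeping ----------------------------------------------------

    def degree(self, junction_id: int) -> int:
        d = 0
        for e in self.edges.values():
            for kind, ref in e.endpoints:
                if kind == "junction" and ref == junction_id:
                    d += 1
        return d

    def incident_edges(self, kind: str, ref: int) -> list[int]:
        out = []
        for eid in sorted(self.edges):
            for k, r in self.edges[eid].endpoints:
                if k == kind and r == ref:
                    out.append(eid)
                    break
        return out

    def next_edge_id(self) -> int:
        return max(self.edges, default=-1) + 1

    def next_junction_id(self) -> int:
        return max(self.junctions, default=-1) + 1

    def check_invariants(self) -> None:
        """Referential integrity and the degree handshake identity."""
        degree_sum = 0
        incidences = 0
        for e in self.edges.values():
            for kind, ref in e.endpoints:
                table = self.junctions if kind == "junction" else self.extremities
                if ref not in table:
                    raise AssertionError(f"edge {e.id} dangling {kind} ref {ref}")
                if kind == "junction":
                    incidences += 1
        for jid in self.junctions:
            degree_sum += self.degree(jid)
        if degree_sum != incidences:
            raise AssertionError("handshake identity violated")

    def to_networkx(self) -> nx.MultiGraph:
        """Combinatorial view: junction/extremity nodes, one edge per path."""
        g = nx.MultiGraph()
        for jid in self.junctions:
            g.add_node(("junction", jid))
        for xid in self.extremities:
            g.add_node(("extremity", xid))
        for eid in sorted(self.edges):
            e = self.edges[eid]
            g.add_edge(e.endpoints[0], e.endpoints[1], key=eid,
                       length=e.length, kind=e.kind)
        return g

    def cyclomatic_number(self) -> int:
        g = self.to_networkx()
        if g.number_of_nodes() == 0:
            return 0
        return (g.number_of_edges() - g.number_of_nodes()
                + nx.number_connected_components(g))

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "calibration": self.calibration,
            "circles": [c.to_dict() for c in self.circles],
            "junctions": [
                {"id": j.id,
                 "member_dots": [list(d) for d in j.member_dots],
                 "centroid": list(j.centroid),
                 "is_anchorage": j.is_anchorage,
                 "circle_index": j.circle_index}
                for j in (self.junctions[k] for k in sorted(self.junctions))
            ],
            "extremities": [
                {"id": x.id, "y": x.y, "x": x.x}
                for x in (self.extremities[k] for k in sorted(self.extremities))
            ],
            "edges": [
                {"id": e.id, "kind": e.kind,
                 "polyline": [list(pt) for pt in e.polyline],
                 "length": e.length,
                 "endpoints": [list(ep) for ep in e.endpoints]}
                for e in (self.edges[k] for k in sorted(self.edges))
            ],
            "meshes": [
                {"id": m.id, "area": m.area,
                 "boundary_edge_ids": list(m.boundary_edge_ids)}
                for m in self.meshes
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkGraph":
        g = cls(shape=tuple(d["shape"]), calibration=d.get("calibration"))
        g.circles = tuple(Circle(**c) for c in d.get("circles", []))
        for j in d.get("junctions", []):
            dots = tuple(tuple(p) for p in j["member_dots"])
            g.junctions[j["id"]] = Junction(
                id=j["id"], member_dots=dots,
                blob_pixels=_blob_from_dots(dots, g.shape),
                centroid=tuple(j["centroid"]),
                is_anchorage=j["is_anchorage"],
                circle_index=j.get("circle_index"))
        for x in d.get("extremities", []):
            g.extremities[x["id"]] = Extremity(id=x["id"], y=x["y"], x=x["x"])
        for e in d.get("edges", []):
            g.edges[e["id"]] = Edge(
                id=e["id"], kind=e["kind"],
                polyline=[tuple(pt) for pt in e["polyline"]],
                length=e["length"],
                endpoints=tuple((ep[0], ep[1]) for ep in e["endpoints"]))
        for m in d.get("meshes", []):
            g.meshes.append(Mesh(id=m["id"], area=m["area"],
                                 boundary_edge_ids=tuple(m["boundary_edge_ids"])))
        return g

    @classmethod
    def from_json(cls, s: str) -> "NetworkGraph":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Pixel classification
# ---------------------------------------------------------------------------

def neighbor_counts(pixels: np.ndarray) -> np.ndarray:
    """Number of foreground 8-neighbors of every pixel."""
    return ndi.correlate(pixels.astype(np.uint8), _NEIGHBOR_KERNEL,
                         mode="constant", cval=0)


def classify_pixels(sk: Skeleton | np.ndarray):
    """Split skeleton pixels into node pixels and extremities.

    A pixel with >= 3 foreground 8-neighbors is a node (the minimal
    bifurcation unit); exactly one neighbor makes an extremity; two makes
    an ordinary path pixel.  Isolated single pixels are dropped.
    Returns ``(nodes, extremities)`` as lists of (y, x), sorted.
    """
    px = sk.pixels if isinstance(sk, Skeleton) else np.asarray(sk, dtype=bool)
    counts = neighbor_counts(px)
    nodes = [(int(y), int(x)) for y, x in np.argwhere(px & (counts >= 3))]
    ends = [(int(y), int(x)) for y, x in np.argwhere(px & (counts == 1))]
    return sorted(nodes), sorted(ends)


# ---------------------------------------------------------------------------
# Junction construction
# ---------------------------------------------------------------------------

def _stamp_disk(center: tuple[int, int], diameter: float,
                shape: tuple[int, int]) -> list[tuple[int, int]]:
    r = diameter / 2.0
    ri = int(math.floor(r))
    y0, x0 = center
    out = []
    for dy in range(-ri, ri + 1):
        for dx in range(-ri, ri + 1):
            if dy * dy + dx * dx <= r * r + 1e-9:
                y, x = y0 + dy, x0 + dx
                if 0 <= y < shape[0] and 0 <= x < shape[1]:
                    out.append((y, x))
    return out


def _blob_from_dots(dots, shape, diameter: float = 7.0) -> frozenset:
    blob: set[tuple[int, int]] = set()
    for d in dots:
        blob.update(_stamp_disk(tuple(d), diameter, shape))
    return frozenset(blob)


def build_junctions(nodes, p: GraphParams,
                    shape: tuple[int, int]) -> list[Junction]:
    """Stamp a disk on every node pixel; overlapping blobs are junctions.

    The 7-px dots absorb the cluster of node pixels that thinning
    produces around a single biological bifurcation, so each blob of
    overlapping dots is one junction.  The centroid is the mean of the
    member node pixels.
    """
    if not nodes:
        return []
    canvas = np.zeros(shape, dtype=bool)
    dot_pixels = {}
    for node in nodes:
        px = _stamp_disk(tuple(node), p.node_dot_diameter, shape)
        dot_pixels[tuple(node)] = px
        for yx in px:
            canvas[yx] = True
    labels, n = ndi.label(canvas, structure=_STRUCT8)
    members: dict[int, list] = {i: [] for i in range(1, n + 1)}
    for node in nodes:
        members[int(labels[tuple(node)])].append(tuple(node))
    junctions = []
    for jid, lab in enumerate(sorted(members)):
        dots = sorted(members[lab])
        blob = frozenset((int(y), int(x)) for y, x in np.argwhere(labels == lab))
        cy = float(np.mean([d[0] for d in dots]))
        cx = float(np.mean([d[1] for d in dots]))
        junctions.append(Junction(id=jid, member_dots=tuple(dots),
                                  blob_pixels=blob, centroid=(cy, cx)))
    return junctions


# ---------------------------------------------------------------------------
# Edge tracing
# ---------------------------------------------------------------------------

def _order_open_path(pixels: set, start) -> list:
    """Walk an open path of degree-<=2 pixels from one end to the other."""
    path = [start]
    seen = {start}
    current = start
    while True:
        nxt = None
        for dy, dx in _OFFSETS:
            cand = (current[0] + dy, current[1] + dx)
            if cand in pixels and cand not in seen:
                nxt = cand
                break
        if nxt is None:
            return path
        path.append(nxt)
        seen.add(nxt)
        current = nxt


def trace_edges(sk: Skeleton | np.ndarray, junctions: list[Junction],
                extremities) -> tuple[list[Edge], dict]:
    """Trace the skeleton paths between terminals and classify them.

    Skeleton pixels not covered by a junction blob form simple paths or
    cycles; each open path is attached at either end to the junction blob
    that covers its missing skeleton neighbor, or terminates at an
    extremity.  Cycles with no junction become a self-loop segment on a
    synthetic junction.  Returns the edges and a registry mapping
    ``("extremity", id)``/``("junction", id)`` refs to objects (including
    any synthetic junctions created for node-free loops).
    """
    px = sk.pixels if isinstance(sk, Skeleton) else np.asarray(sk, dtype=bool)
    shape = px.shape
    jlabel = np.full(shape, -1, dtype=np.int64)
    for j in junctions:
        for yx in j.blob_pixels:
            jlabel[yx] = j.id
    ext_ids = {}
    ext_list = []
    for i, e in enumerate(sorted(tuple(e) if not isinstance(e, Extremity)
                                 else (e.y, e.x) for e in extremities)):
        ext_ids[e] = i
        ext_list.append(Extremity(id=i, y=e[0], x=e[1]))

    free = px & (jlabel < 0)
    labels, n = ndi.label(free, structure=_STRUCT8)
    counts_free = ndi.correlate(free.astype(np.uint8), _NEIGHBOR_KERNEL,
                                mode="constant", cval=0)
    counts_all = neighbor_counts(px)

    synthetic: list[Junction] = []
    next_jid = max((j.id for j in junctions), default=-1) + 1
    edges: list[Edge] = []

    def terminal_for(end: tuple[int, int]):
        # Junction attachment goes through skeleton connectivity: only a
        # skeleton neighbor covered by a blob attaches the path.
        best = None
        for dy, dx in _OFFSETS:
            y, x = end[0] + dy, end[1] + dx
            if 0 <= y < shape[0] and 0 <= x < shape[1] and px[y, x]:
                jid = int(jlabel[y, x])
                if jid >= 0 and (best is None or jid < best):
                    best = jid
        if best is not None:
            return ("junction", best)
        if counts_all[end] <= 1:
            if end not in ext_ids:
                # terminal created by blob coverage quirks: register it
                ext_ids[end] = len(ext_list)
                ext_list.append(Extremity(id=ext_ids[end], y=end[0], x=end[1]))
            return ("extremity", ext_ids[end])
        return None

    for lab in range(1, n + 1):
        comp_pixels = {(int(y), int(x)) for y, x in np.argwhere(labels == lab)}
        ends = sorted(pt for pt in comp_pixels if counts_free[pt] <= 1)
        if len(comp_pixels) == 1:
            # single free pixel: may join two junctions, or hang off one
            pt = next(iter(comp_pixels))
            jids = sorted({int(jlabel[pt[0] + dy, pt[1] + dx])
                           for dy, dx in _OFFSETS
                           if 0 <= pt[0] + dy < shape[0]
                           and 0 <= pt[1] + dx < shape[1]
                           and px[pt[0] + dy, pt[1] + dx]
                           and jlabel[pt[0] + dy, pt[1] + dx] >= 0})
            if len(jids) >= 2:
                ep0, ep1 = ("junction", jids[0]), ("junction", jids[1])
            elif len(jids) == 1 and counts_all[pt] >= 2:
                ep0 = ep1 = ("junction", jids[0])
            elif len(jids) == 1:
                # pt has one neighbor (the blob) -> pt itself is the tip
                if pt not in ext_ids:
                    ext_ids[pt] = len(ext_list)
                    ext_list.append(Extremity(id=ext_ids[pt], y=pt[0], x=pt[1]))
                ep0, ep1 = ("junction", jids[0]), ("extremity", ext_ids[pt])
            elif counts_all[pt] == 0:
                continue  # isolated single pixel: dropped
            else:
                continue
            eid = len(edges)
            edges.append(Edge(id=eid, kind=_edge_kind(ep0, ep1),
                              polyline=[pt], length=0.0,
                              endpoints=(ep0, ep1)))
            continue
        if not ends:
            # node-free closed loop: synthesize a junction at its first pixel
            start = min(comp_pixels)
            polyline = _order_open_path(comp_pixels - {start}, _first_neighbor(
                start, comp_pixels))
            polyline = [start] + polyline + [start]
            j = Junction(id=next_jid, member_dots=(start,),
                         blob_pixels=frozenset({start}),
                         centroid=(float(start[0]), float(start[1])))
            synthetic.append(j)
            log.info("closed loop with no node at %s: synthetic junction %d",
                     start, j.id)
            eid = len(edges)
            edges.append(Edge(id=eid, kind="segment", polyline=polyline,
                              length=_polyline_length(polyline),
                              endpoints=(("junction", j.id),
                                         ("junction", j.id))))
            next_jid += 1
            continue
        polyline = _order_open_path(comp_pixels, ends[0])
        ep0 = terminal_for(polyline[0])
        ep1 = terminal_for(polyline[-1])
        if ep0 is None or ep1 is None:
            # a path pixel adjacent to nothing traceable: skip defensively
            log.warning("untraceable path end near %s", polyline[0])
            continue
        eid = len(edges)
        edges.append(Edge(id=eid, kind=_edge_kind(ep0, ep1),
                          polyline=polyline,
                          length=_polyline_length(polyline),
                          endpoints=(ep0, ep1)))

    registry = {"junctions": list(junctions) + synthetic,
                "extremities": ext_list}
    return edges, registry


def _first_neighbor(pt, pixels):
    for dy, dx in _OFFSETS:
        cand = (pt[0] + dy, pt[1] + dx)
        if cand in pixels:
            return cand
    return pt


def assemble_graph(sk: Skeleton, p: GraphParams) -> NetworkGraph:
    """classify -> junctions -> edges, packed into a NetworkGraph."""
    nodes, ends = classify_pixels(sk)
    junctions = build_junctions(nodes, p, sk.shape)
    edges, registry = trace_edges(sk, junctions, ends)
    g = NetworkGraph(shape=sk.shape, circles=tuple(sk.source_circles))
    for j in registry["junctions"]:
        g.junctions[j.id] = j
    for x in registry["extremities"]:
        g.extremities[x.id] = x
    for e in edges:
        g.edges[e.id] = e
    _drop_unused_terminals(g)
    return g


def _drop_unused_terminals(g: NetworkGraph) -> None:
    used_j, used_x = set(), set()
    for e in g.edges.values():
        for kind, ref in e.endpoints:
            (used_j if kind == "junction" else used_x).add(ref)
    for jid in [j for j in g.junctions if j not in used_j]:
        del g.junctions[jid]
    for xid in [x for x in g.extremities if x not in used_x]:
        del g.extremities[xid]


# ---------------------------------------------------------------------------
# Junction fusion
# ---------------------------------------------------------------------------

def fuse_close_junctions(g: NetworkGraph, p: GraphParams) -> NetworkGraph:
    """Fuse junction pairs joined by short segments.

    While a segment shorter than ``junction_fusion_distance`` joins two
    distinct junctions whose centroids are closer than that distance, the
    pair is merged (dot-weighted mean centroid), the segment removed and
    the other incident edges reattached; such short spans are below the
    length of two aligned cells and represent a single bifurcation.
    Shortest segment first, ties broken by edge id, to a fixed point.
    """
    d = p.junction_fusion_distance
    while True:
        candidates = []
        for eid in sorted(g.edges):
            e = g.edges[eid]
            if e.kind != "segment" or e.length >= d:
                continue
            (k0, j0), (k1, j1) = e.endpoints
            if j0 == j1:
                # a short self-loop is a junction touching itself (a mask
                # artifact around a bifurcation): drop it
                del g.edges[eid]
                continue
            c0 = g.junctions[j0].centroid
            c1 = g.junctions[j1].centroid
            if math.hypot(c0[0] - c1[0], c0[1] - c1[1]) < d:
                candidates.append((e.length, eid, j0, j1))
        if not candidates:
            return g
        _, eid, j0, j1 = min(candidates)
        absorbed = tuple(g.edges[eid].polyline)
        del g.edges[eid]
        _merge_junctions(g, j0, j1, extra_pixels=absorbed)


def _merge_junctions(g: NetworkGraph, j0: int, j1: int,
                     extra_pixels=()) -> int:
    """Merge junction ``j1`` into ``j0`` (lower id kept); reattach edges.

    ``extra_pixels`` (e.g. the polyline of a contracted segment) are
    absorbed into the merged blob so the junction geometry stays
    connected.
    """
    keep, drop = min(j0, j1), max(j0, j1)
    jk, jd = g.junctions[keep], g.junctions[drop]
    dots = tuple(sorted(set(jk.member_dots) | set(jd.member_dots)))
    cy = float(np.mean([pt[0] for pt in dots]))
    cx = float(np.mean([pt[1] for pt in dots]))
    g.junctions[keep] = Junction(
        id=keep, member_dots=dots,
        blob_pixels=jk.blob_pixels | jd.blob_pixels
        | frozenset(tuple(pt) for pt in extra_pixels),
        centroid=(cy, cx),
        is_anchorage=jk.is_anchorage or jd.is_anchorage,
        circle_index=jk.circle_index if jk.circle_index is not None
        else jd.circle_index)
    del g.junctions[drop]
    for other in list(g.edges.values()):
        eps = tuple(("junction", keep) if ep == ("junction", drop) else ep
                    for ep in other.endpoints)
        if eps != other.endpoints:
            g.edges[other.id] = replace(other, endpoints=eps,
                                        kind=_edge_kind(*eps))
    return keep


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def _bridge(p0, p1) -> list[tuple[int, int]]:
    rr, cc = draw_line(p0[0], p0[1], p1[0], p1[1])
    return list(zip(rr.tolist(), cc.tolist()))


def _concat_through(e0: Edge, e1: Edge, jid: int) -> tuple[list, float]:
    """Join two polylines across the dissolved junction ``jid``."""
    p0 = e0.polyline if e0.endpoints[1] == ("junction", jid) else e0.polyline[::-1]
    p1 = e1.polyline if e1.endpoints[0] == ("junction", jid) else e1.polyline[::-1]
    bridge = _bridge(p0[-1], p1[0])
    merged = p0 + bridge[1:-1] + p1
    return merged, _polyline_length(merged)


def prune_small_branches(g: NetworkGraph, p: GraphParams) -> NetworkGraph:
    """Iteratively remove artifactual small branches.

    Branches shorter than ``prune_min_branch`` are deleted; a junction
    left with degree 2 dissolves and its two edges concatenate (and are
    re-classified by their new endpoints); a junction left with degree 1
    degrades into an extremity at its centroid; degree-0 junctions and
    orphan extremities disappear.  Runs to a fixed point, so spurs
    exposed by an earlier pass are removed too.  Short branches whose
    free end sits on a bead circle are kept: they are sprout anchor
    stubs, not artifacts.
    """

    promoted = any(j.is_anchorage for j in g.junctions.values())

    def anchored(e: Edge) -> bool:
        # before anchorage classification, leave rim-touching stubs alone:
        # they may be sprout bases whose cut end sits near the ring
        if not g.circles or promoted:
            return False
        for kind, ref in e.endpoints:
            if kind == "extremity" and ref in g.extremities:
                x = g.extremities[ref]
                if _nearest_ring((x.y, x.x), g.circles)[1] <= p.min_object_size:
                    return True
        return False

    def on_ring(j: Junction) -> bool:
        if not g.circles or promoted:
            return False
        pts = sorted(j.blob_pixels) or [j.centroid]
        return min(_nearest_ring(pt, g.circles)[1] for pt in pts) <= PROMOTE_TOL

    def direction_at(jid: int, eid: int, span: int = 12):
        """Unit chord of an edge's polyline as it leaves the junction."""
        e = g.edges[eid]
        if e.endpoints[0] == e.endpoints[1]:
            return None
        poly = e.polyline
        if e.endpoints[1] == ("junction", jid):
            poly = poly[::-1]
        p0 = poly[0]
        pt = poly[min(span, len(poly) - 1)]
        v = (pt[0] - p0[0], pt[1] - p0[1])
        n = math.hypot(*v)
        return (v[0] / n, v[1] / n) if n else None

    def through_hair(e: Edge) -> bool:
        """A leaf below the two-cell scale hanging off a junction whose
        other edges run straight through it is ribbon-boundary hair, not
        a bifurcation (a real fork opens well below 155 degrees)."""
        jids = [ref for kind, ref in e.endpoints if kind == "junction"
                and ref in g.junctions]
        if not jids:
            return False
        jid = jids[0]
        others = [oid for oid in g.incident_edges("junction", jid)
                  if oid != e.id
                  and g.edges[oid].length >= p.junction_fusion_distance]
        dirs = [d for d in (direction_at(jid, oid) for oid in others)
                if d is not None]
        cos_through = math.cos(math.radians(THROUGH_ANGLE_DEG))
        for i, da in enumerate(dirs):
            for db in dirs[i + 1:]:
                if da[0] * db[0] + da[1] * db[1] < cos_through:
                    return True
        return False

    changed = True
    while changed:
        changed = False
        for eid in sorted(g.edges):
            e = g.edges.get(eid)
            if e is None or e.kind != "branch":
                continue
            if e.length >= p.junction_fusion_distance or anchored(e):
                continue
            if e.length < p.prune_min_branch or through_hair(e):
                del g.edges[eid]
                changed = True
        # split tips: two short leaf branches leaving a junction in nearly
        # the same direction are a fishtail artifact of thinning a blunt
        # ribbon end (a real bifurcation opens much wider) — keep only
        # the longest leaf of such a pair

        def leaf_direction(jid: int, eid: int):
            e = g.edges[eid]
            for kind, ref in e.endpoints:
                if kind == "extremity" and ref in g.extremities:
                    x = g.extremities[ref]
                    c = g.junctions[jid].centroid
                    v = (x.y - c[0], x.x - c[1])
                    n = math.hypot(*v)
                    return (v[0] / n, v[1] / n) if n else None
            return None

        for jid in sorted(g.junctions):
            if jid not in g.junctions:
                continue
            inc = g.incident_edges("junction", jid)
            leaves = [eid for eid in inc
                      if g.edges[eid].kind == "branch"
                      and g.edges[eid].length < p.junction_fusion_distance
                      and not anchored(g.edges[eid])]
            if len(leaves) < 2 or len(inc) - len(leaves) > 1:
                continue
            dirs = {eid: leaf_direction(jid, eid) for eid in leaves}
            leaves = [eid for eid in leaves if dirs[eid] is not None]
            for i, ea in enumerate(leaves):
                for eb in leaves[i + 1:]:
                    if ea not in g.edges or eb not in g.edges:
                        continue
                    cosang = (dirs[ea][0] * dirs[eb][0]
                              + dirs[ea][1] * dirs[eb][1])
                    if cosang > math.cos(math.radians(45.0)):
                        drop = min((ea, eb),
                                   key=lambda eid: (g.edges[eid].length, eid))
                        del g.edges[drop]
                        changed = True
        if changed:
            _drop_unused_terminals(g)
        # dissolve / degrade junctions whose degree dropped (never those on
        # a bead ring: they are anchorage junctions in waiting)
        for jid in sorted(g.junctions):
            if g.junctions[jid].is_anchorage or on_ring(g.junctions[jid]):
                continue
            inc = g.incident_edges("junction", jid)
            deg = g.degree(jid)
            if deg == 0:
                del g.junctions[jid]
                changed = True
            elif deg == 2 and len(inc) == 2:
                e0, e1 = g.edges[inc[0]], g.edges[inc[1]]
                merged, length = _concat_through(e0, e1, jid)
                ep0 = e0.endpoints[0] if e0.endpoints[1] == ("junction", jid) \
                    else e0.endpoints[1]
                ep1 = e1.endpoints[1] if e1.endpoints[0] == ("junction", jid) \
                    else e1.endpoints[0]
                del g.edges[e1.id]
                g.edges[e0.id] = Edge(id=e0.id, kind=_edge_kind(ep0, ep1),
                                      polyline=merged, length=length,
                                      endpoints=(ep0, ep1))
                del g.junctions[jid]
                changed = True
            elif deg == 1:
                # junction degraded to a tree tip
                j = g.junctions[jid]
                y, x = int(round(j.centroid[0])), int(round(j.centroid[1]))
                xid = max(g.extremities, default=-1) + 1
                g.extremities[xid] = Extremity(id=xid, y=y, x=x)
                e0 = g.edges[inc[0]]
                eps = tuple(("extremity", xid) if ep == ("junction", jid)
                            else ep for ep in e0.endpoints)
                g.edges[e0.id] = replace(e0, endpoints=eps,
                                         kind=_edge_kind(*eps))
                del g.junctions[jid]
                changed = True
        _drop_unused_terminals(g)
    return g


# ---------------------------------------------------------------------------
# Anchorage junctions and isolated elements
# ---------------------------------------------------------------------------

def _nearest_ring(pt: tuple[float, float],
                  circles: tuple[Circle, ...]) -> tuple[int | None, float]:
    best, best_d = None, math.inf
    for i, c in enumerate(circles):
        d = abs(math.hypot(pt[0] - c.cy, pt[1] - c.cx) - c.radius)
        if d < best_d:
            best, best_d = i, d
    return best, best_d


def classify_anchorage(g: NetworkGraph,
                       circles: tuple[Circle, ...] | list[Circle] | None = None,
                       p: GraphParams | None = None) -> NetworkGraph:
    """Remove residual circle arcs and mark anchorage junctions.

    Edges running along a bead boundary (>= 80% of polyline pixels within
    2 px of a circle ring) are residual pieces of the circle itself and
    are deleted.  Terminals lying on a ring are where a sprout meets the
    bead: junctions there are flagged as anchorage junctions, extremities
    there are promoted to anchorage junctions, and incident edges are
    re-classified accordingly.  Anchorage junctions on the same circle
    closer than the junction-fusion distance are merged, consistent with
    the fusion rule for ordinary junctions.
    """
    p = p or GraphParams()
    circles = tuple(circles if circles is not None else g.circles)
    if not circles:
        log.warning("classify_anchorage called without circles; no-op")
        return g

    for eid in sorted(g.edges):
        e = g.edges[eid]
        on_ring = sum(1 for pt in e.polyline
                      if _nearest_ring(pt, circles)[1] <= RING_TOL)
        if e.polyline and on_ring / len(e.polyline) >= CIRCLE_PIECE_FRACTION:
            del g.edges[eid]
            log.debug("edge %d deleted as circle piece", eid)
    _drop_unused_terminals(g)

    for jid in sorted(g.junctions):
        j = g.junctions[jid]
        # the junction intercepts a circle when any pixel of its blob of
        # 7-px dots reaches the ring
        ci, dist = min((_nearest_ring(pt, circles) for pt in
                        sorted(j.blob_pixels) or [j.centroid]),
                       key=lambda t: t[1])
        if dist <= PROMOTE_TOL:
            g.junctions[jid] = replace(j, is_anchorage=True, circle_index=ci)

    for xid in sorted(g.extremities):
        x = g.extremities[xid]
        ci, dist = _nearest_ring((x.y, x.x), circles)
        if dist > PROMOTE_TOL:
            continue
        jid = g.next_junction_id()
        g.junctions[jid] = Junction(id=jid, member_dots=((x.y, x.x),),
                                    blob_pixels=frozenset({(x.y, x.x)}),
                                    centroid=(float(x.y), float(x.x)),
                                    is_anchorage=True, circle_index=ci)
        for eid in g.incident_edges("extremity", xid):
            e = g.edges[eid]
            eps = tuple(("junction", jid) if ep == ("extremity", xid) else ep
                        for ep in e.endpoints)
            g.edges[eid] = replace(e, endpoints=eps, kind=_edge_kind(*eps))
        del g.extremities[xid]

    # rim debris: anchored fragments that never get further from the ring
    # than the two-cell fusion scale are dirt stuck to the bead, not
    # sprouts
    nxg = g.to_networkx()
    for component in list(nx.connected_components(nxg)):
        dists = []
        has_anchor = False
        for kind, ref in component:
            if kind == "junction" and ref in g.junctions:
                j = g.junctions[ref]
                has_anchor = has_anchor or j.is_anchorage
                dists.append(_nearest_ring(j.centroid, circles)[1])
            elif kind == "extremity" and ref in g.extremities:
                x = g.extremities[ref]
                dists.append(_nearest_ring((x.y, x.x), circles)[1])
        if has_anchor and dists and max(dists) <= p.junction_fusion_distance:
            for u, v, k in nxg.subgraph(component).edges(keys=True):
                g.edges.pop(k, None)
            log.debug("rim debris component removed (%d terminals)",
                      len(component))
    _drop_unused_terminals(g)

    # merge anchorage junctions that crowd the same spot on a rim (a wide
    # sprout base can reach the ring with two tiny legs)
    merged = True
    while merged:
        merged = False
        anchors = [jid for jid in sorted(g.junctions)
                   if g.junctions[jid].is_anchorage]
        for a, b in ((a, b) for i, a in enumerate(anchors)
                     for b in anchors[i + 1:]):
            ja, jb = g.junctions[a], g.junctions[b]
            if ja.circle_index != jb.circle_index:
                continue
            dist = math.hypot(ja.centroid[0] - jb.centroid[0],
                              ja.centroid[1] - jb.centroid[1])
            if dist < p.junction_fusion_distance:
                bridge = _bridge((int(round(ja.centroid[0])),
                                  int(round(ja.centroid[1]))),
                                 (int(round(jb.centroid[0])),
                                  int(round(jb.centroid[1]))))
                _merge_junctions(g, a, b, extra_pixels=bridge)
                merged = True
                break
    return g


def remove_small_isolated(g: NetworkGraph, p: GraphParams) -> NetworkGraph:
    """Drop isolated elements shorter than ``min_object_size`` (strict <)."""
    for eid in sorted(g.edges):
        e = g.edges[eid]
        if e.kind == "isolated" and e.length < p.min_object_size:
            del g.edges[eid]
    _drop_unused_terminals(g)
    return g


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def detect_meshes(g: NetworkGraph,
                  sk: Skeleton | np.ndarray | None = None) -> list[Mesh]:
    """Closed areas enclosed by segments (tube-formation mode).

    Meshes are the connected components of the complement of the final
    vectorial skeleton — the retained edge polylines plus the junction
    blobs that join them — that do not touch the image border.  Working
    from the cleaned model rather than the raw thinned mask keeps the
    mesh count equal to the graph's cyclomatic number even after pruning
    and artifact-loop removal, and the one-pixel walls make the area
    independent of how thick the segmented ribbon was.
    """
    px = np.zeros(g.shape, dtype=bool)
    for e in g.edges.values():
        for (y, x) in e.polyline:
            if 0 <= y < g.shape[0] and 0 <= x < g.shape[1]:
                px[y, x] = True
    for j in g.junctions.values():
        for (y, x) in j.blob_pixels:
            px[y, x] = True
    background = ~px
    # walls are 8-connected, so faces are 4-connected regions
    labels, n = ndi.label(background, structure=ndi.generate_binary_structure(2, 1))
    border = np.zeros_like(px)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    outside = np.unique(labels[border & background])

    # map mesh component -> adjacent edges via edge polylines
    adjacency: dict[int, set[int]] = {}
    for eid in sorted(g.edges):
        for (y, x) in g.edges[eid].polyline:
            for dy, dx in _OFFSETS:
                yy, xx = y + dy, x + dx
                if 0 <= yy < px.shape[0] and 0 <= xx < px.shape[1]:
                    lab = int(labels[yy, xx])
                    if lab > 0:
                        adjacency.setdefault(lab, set()).add(eid)

    meshes = []
    mid = 0
    for lab in range(1, n + 1):
        if lab in outside:
            continue
        area = int(np.sum(labels == lab))
        if area < MIN_HOLE_AREA:
            # sub-cell pocket between a bridge and the wall it replaced,
            # not a capillary loop
            continue
        meshes.append(Mesh(id=mid, area=area,
                           boundary_edge_ids=tuple(sorted(adjacency.get(lab, ())))))
        mid += 1
    return meshes


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def build_graph(sk: Skeleton, p: GraphParams | None = None,
                mode: str = "ETFA") -> NetworkGraph:
    """Full vectorization: classify, stamp, trace, fuse, prune, then
    anchorage (FBA) or isolated-element filtering and meshes (ETFA)."""
    p = p or GraphParams()
    mode = mode.upper()
    if mode not in {"FBA", "ETFA"}:
        raise ValueError("mode must be 'FBA' or 'ETFA'")
    g = assemble_graph(sk, p)
    g = fuse_close_junctions(g, p)
    g = prune_small_branches(g, p)
    if mode == "FBA":
        if sk.source_circles:
            g = classify_anchorage(g, sk.source_circles, p)
            # promotion turns rim stubs into segments: fuse and prune once
            # more so the model reaches its fixed point
            g = fuse_close_junctions(g, p)
            g = prune_small_branches(g, p)
        g = remove_small_isolated(g, p)
    else:
        g = remove_small_isolated(g, p)
        g.meshes = detect_meshes(g)
    g.check_invariants()
    return g
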