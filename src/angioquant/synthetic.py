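"""Synthetic phase-contrast scenes with exact ground truth.

Renders the two assay geometries so every pipeline stage can be tested
without microscopy data:

* fibrin bead assay (FBA): dark microcarrier disks with a bright rim and
  radial sprouting trees anchored on the rim;
* tube formation assay (ETFA): a jittered polygonal tiling of filaments
  (the pseudo-capillary meshwork) with dangling branches and small
  isolated fragments.

Filaments are drawn with a difference-of-Gaussians ridge profile (bright
core flanked by darker bands), emulating the phase-contrast halo.  Scenes
carry multiplicative shading (meniscus-style uneven illumination) and
additive Gaussian noise.  Every render is deterministic given its spec;
the spec factories derive all geometry from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.special import expit
from skimage.draw import line as draw_line

from .spheres import Circle

__all__ = [
    "SproutPlan",
    "BeadPlan",
    "MeshGridPlan",
    "SceneSpec",
    "GroundTruth",
    "render_fba",
    "render_etfa",
    "render_scene",
    "random_fba_spec",
    "random_etfa_spec",
    "perturbation_suite",
]

# Ridge profile: intensity(d) = core * [exp(-d^2/2w1^2) - k exp(-d^2/2w2^2)]
RIDGE_CORE_SIGMA = 1.3
RIDGE_HALO_SIGMA = 4.0

BACKGROUND_LEVEL = 0.5
BEAD_INTERIOR_FACTOR = 0.5     # dark disk relative to background
RIM_AMPLITUDE = 0.35           # bright rim peak added just outside the disk
RIM_OFFSET = 1.5               # rim center relative to the disk radius
RIM_SIGMA = 1.2
FILAMENT_AMPLITUDE = 0.5


@dataclass(frozen=True)
class SproutPlan:
    """One radial sprout: a trunk, optionally bifurcating into two tips."""

    angle_deg: float
    trunk_length: float
    child_lengths: tuple[float, ...] = ()
    child_spread_deg: float = 30.0

    @property
    def bifurcates(self) -> bool:
        return len(self.child_lengths) == 2


@dataclass(frozen=True)
class BeadPlan:
    cy: float
    cx: float
    radius: float
    sprouts: tuple[SproutPlan, ...] = ()


@dataclass(frozen=True)
class MeshGridPlan:
    """Jittered rectangular tiling plus exterior spurs and loose fragments.

    ``jitter`` holds one (dy, dx) per vertex of the (rows+1) x (cols+1)
    lattice; ``spurs`` are (vertex_row, vertex_col, angle_deg, length)
    dangling branches attached at non-corner border vertices;
    ``fragments`` are (y, x, angle_deg, length) free-floating strokes.
    """

    origin: tuple[float, float]
    rows: int
    cols: int
    cell: float
    jitter: tuple[tuple[tuple[float, float], ...], ...] = ()
    spurs: tuple[tuple[int, int, float, float], ...] = ()
    fragments: tuple[tuple[float, float, float, float], ...] = ()

    def vertex(self, i: int, j: int) -> tuple[float, float]:
        dy, dx = self.jitter[i][j] if self.jitter else (0.0, 0.0)
        return (self.origin[0] + i * self.cell + dy,
                self.origin[1] + j * self.cell + dx)


@dataclass(frozen=True)
class SceneSpec:
    kind: str                      # "fba" | "etfa"
    height: int = 640
    width: int = 640
    beads: tuple[BeadPlan, ...] = ()
    grid: MeshGridPlan | None = None
    shading_amplitude: float = 0.2   # linear ramp 1 -+ amplitude across x
    noise_sigma: float = 0.04        # relative (signal-proportional) noise
    halo_strength: float = 0.45      # dark-flank weight of the ridge profile
    texture_density: float = 2e-4    # debris blobs per pixel (dirt and
    #                                  out-of-focus cells in the gel)
    texture_amplitude: float = 0.05
    seed: int = 0


@dataclass
class GroundTruth:
    """Exact geometry and object counts of a rendered scene."""

    circles: tuple[Circle, ...] = ()
    counts: dict = field(default_factory=dict)
    per_bead: list = field(default_factory=list)
    mesh_count: int = 0
    mesh_areas: tuple[float, ...] = ()
    centerline: np.ndarray | None = None
    filament_mask: np.ndarray | None = None

    def euler_check(self) -> bool:
        """V - E + F = 1 + C for the planned planar graph (F excl. outer)."""
        c = self.counts
        v = c.get("vertices", 0)
        e = c.get("graph_edges", 0)
        comps = c.get("components", 1)
        return v - e + self.mesh_count == comps


# ---------------------------------------------------------------------------
# Geometry -> raster
# ---------------------------------------------------------------------------

def _polylines_fba(spec: SceneSpec):
    """Centerline segments of every sprout, per bead."""
    segments = []
    for bead in spec.beads:
        for s in bead.sprouts:
            th = math.radians(s.angle_deg)
            d = (math.sin(th), math.cos(th))       # (dy, dx)
            p0 = (bead.cy + (bead.radius - 2.0) * d[0],
                  bead.cx + (bead.radius - 2.0) * d[1])
            p1 = (bead.cy + (bead.radius + s.trunk_length) * d[0],
                  bead.cx + (bead.radius + s.trunk_length) * d[1])
            segments.append((p0, p1))
            if s.bifurcates:
                for sign, clen in zip((-1.0, 1.0), s.child_lengths):
                    phi = th + sign * math.radians(s.child_spread_deg)
                    p2 = (p1[0] + clen * math.sin(phi),
                          p1[1] + clen * math.cos(phi))
                    segments.append((p1, p2))
    return segments


def _polylines_etfa(spec: SceneSpec):
    g = spec.grid
    segments = []
    for i in range(g.rows + 1):
        for j in range(g.cols + 1):
            if j < g.cols:
                segments.append((g.vertex(i, j), g.vertex(i, j + 1)))
            if i < g.rows:
                segments.append((g.vertex(i, j), g.vertex(i + 1, j)))
    for (i, j, ang, length) in g.spurs:
        p0 = g.vertex(i, j)
        th = math.radians(ang)
        segments.append((p0, (p0[0] + length * math.sin(th),
                              p0[1] + length * math.cos(th))))
    for (y, x, ang, length) in g.fragments:
        th = math.radians(ang)
        segments.append(((y, x), (y + length * math.sin(th),
                                  x + length * math.cos(th))))
    return segments


def _rasterize(segments, shape) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    for (y0, x0), (y1, x1) in segments:
        rr, cc = draw_line(int(round(y0)), int(round(x0)),
                           int(round(y1)), int(round(x1)))
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        canvas[rr[ok], cc[ok]] = True
    return canvas


def _ridge_field(centerline: np.ndarray, halo_strength: float) -> np.ndarray:
    d = ndi.distance_transform_edt(~centerline)
    core = np.exp(-d * d / (2 * RIDGE_CORE_SIGMA ** 2))
    halo = np.exp(-d * d / (2 * RIDGE_HALO_SIGMA ** 2))
    return core - halo_strength * halo


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene spec into a float image plus its ground truth."""
    if spec.kind == "fba":
        segments = _polylines_fba(spec)
        truth = _truth_fba(spec)
    elif spec.kind == "etfa":
        segments = _polylines_etfa(spec)
        truth = _truth_etfa(spec)
    else:
        raise ValueError("scene kind must be 'fba' or 'etfa'")

    shape = (spec.height, spec.width)
    img = np.full(shape, BACKGROUND_LEVEL, dtype=np.float64)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]

    for bead in spec.beads:
        dist = np.hypot(yy - bead.cy, xx - bead.cx)
        inside = expit(-(dist - bead.radius) / 0.8)
        img *= 1.0 - (1.0 - BEAD_INTERIOR_FACTOR) * inside
        rim = np.exp(-(dist - (bead.radius + RIM_OFFSET)) ** 2
                     / (2 * RIM_SIGMA ** 2))
        img += RIM_AMPLITUDE * rim

    centerline = _rasterize(segments, shape)
    img += FILAMENT_AMPLITUDE * _ridge_field(centerline, spec.halo_strength)

    rng = np.random.default_rng(spec.seed)
    if spec.texture_density:
        # faint gel debris, kept clear of the true structures so it never
        # merges with them and the planned object counts stay exact
        clear = ndi.distance_transform_edt(~centerline) > 25.0
        for bead in spec.beads:
            dist = np.hypot(yy - bead.cy, xx - bead.cx)
            clear &= dist > bead.radius + 25.0
        n_blobs = int(spec.texture_density * shape[0] * shape[1])
        ok_y, ok_x = np.nonzero(clear)
        if ok_y.size:
            picks = rng.integers(0, ok_y.size, size=n_blobs)
            for k in picks:
                by, bx = int(ok_y[k]), int(ok_x[k])
                s = float(rng.uniform(1.5, 3.0))
                amp = float(rng.uniform(-1, 1)) * spec.texture_amplitude
                r = int(3 * s)
                y0, y1 = max(by - r, 0), min(by + r + 1, shape[0])
                x0, x1 = max(bx - r, 0), min(bx + r + 1, shape[1])
                dy = yy[y0:y1, x0:x1] - by
                dx = xx[y0:y1, x0:x1] - bx
                img[y0:y1, x0:x1] += amp * np.exp(-(dy * dy + dx * dx)
                                                  / (2 * s * s))

    if spec.shading_amplitude:
        ramp = 1.0 + spec.shading_amplitude * (2.0 * xx / max(shape[1] - 1, 1)
                                               - 1.0)
        img *= ramp

    if spec.noise_sigma:
        # signal-proportional speckle, the high-count limit of shot noise
        img *= 1.0 + rng.normal(0.0, spec.noise_sigma, size=shape)

    img = np.clip(img, 0.0, None)
    truth.centerline = centerline
    truth.filament_mask = ndi.distance_transform_edt(~centerline) <= 2.0
    return img, truth


def render_fba(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    if spec.kind != "fba":
        raise ValueError("spec is not an FBA scene")
    return render_scene(spec)


def render_etfa(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    if spec.kind != "etfa":
        raise ValueError("spec is not an ETFA scene")
    return render_scene(spec)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _truth_fba(spec: SceneSpec) -> GroundTruth:
    per_bead = []
    totals = {"junctions": 0, "anchorage_junctions": 0, "branches": 0,
              "segments": 0, "extremities": 0, "isolated": 0}
    for bead in spec.beads:
        n_bif = sum(1 for s in bead.sprouts if s.bifurcates)
        n_tips = sum(2 if s.bifurcates else 1 for s in bead.sprouts)
        rec = {"AJN": len(bead.sprouts), "JN": n_bif,
               "branches": n_tips, "segments": n_bif, "extremities": n_tips}
        per_bead.append(rec)
        totals["anchorage_junctions"] += rec["AJN"]
        totals["junctions"] += rec["JN"]
        totals["branches"] += rec["branches"]
        totals["segments"] += rec["segments"]
        totals["extremities"] += rec["extremities"]
    # planar bookkeeping for the Euler self-check: each sprout is its own
    # component once the bead interior is cleared
    totals["vertices"] = (totals["anchorage_junctions"] + totals["junctions"]
                          + totals["extremities"])
    totals["graph_edges"] = totals["branches"] + totals["segments"]
    totals["components"] = totals["anchorage_junctions"]
    # the bead boundary includes the bright envelope: truth radius is the
    # rim midline, not the inner dark-disk edge
    circles = tuple(Circle(cy=b.cy, cx=b.cx, radius=b.radius + RIM_OFFSET)
                    for b in spec.beads)
    return GroundTruth(circles=circles, counts=totals, per_bead=per_bead)


def _shoelace(points) -> float:
    area = 0.0
    for (y0, x0), (y1, x1) in zip(points, points[1:] + points[:1]):
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


def _truth_etfa(spec: SceneSpec) -> GroundTruth:
    g = spec.grid
    rows, cols = g.rows, g.cols
    n_vertices = (rows + 1) * (cols + 1)
    n_grid_edges = rows * (cols + 1) + cols * (rows + 1)
    corners = 4 if (rows >= 1 and cols >= 1) else 0
    # a degree-2 corner vertex is a bend, not a junction: its two border
    # edges merge into one path
    junctions = max(n_vertices - corners, 0)
    segments = n_grid_edges - corners
    if rows == 1 and cols == 1:
        junctions, segments = 0, 1   # pure loop -> one self-loop segment
    kept_fragments = [f for f in g.fragments if f[3] >= 10.0]
    counts = {
        "junctions": junctions,
        "anchorage_junctions": 0,
        "segments": segments,
        "branches": len(g.spurs),
        "isolated": len(kept_fragments),
        "extremities": len(g.spurs) + 2 * len(kept_fragments),
        # planar bookkeeping for the Euler self-check
        "vertices": junctions + len(g.spurs) + 2 * len(kept_fragments)
        + (1 if rows == 1 and cols == 1 else 0),
        "graph_edges": segments + len(g.spurs) + len(kept_fragments),
        "components": 1 + len(kept_fragments),
    }
    areas = []
    for i in range(rows):
        for j in range(cols):
            quad = [g.vertex(i, j), g.vertex(i, j + 1),
                    g.vertex(i + 1, j + 1), g.vertex(i + 1, j)]
            areas.append(_shoelace(quad))
    return GroundTruth(counts=counts, mesh_count=rows * cols,
                       mesh_areas=tuple(areas))


# ---------------------------------------------------------------------------
# Randomized spec factories (all geometry derives from the seed)
# ---------------------------------------------------------------------------

def random_fba_spec(seed: int, n_beads: int | None = None,
                    size: int = 704, **overrides) -> SceneSpec:
    """A random 1-4 bead scene with well-separated sprouting trees.

    Beads sit on a 2x2 placement grid so trees from different beads never
    meet; sprout angles keep >= 50 degrees of separation, trunks are
    40-55 px, children 40-55 px at +-38-50 degrees — all edges comfortably
    above the pruning (10 px) and fusion (20 px) scales even after the
    few pixels of tip erosion that thinning causes.
    """
    rng = np.random.default_rng(seed)
    if n_beads is None:
        n_beads = int(rng.integers(1, 5))
    half = size // 2
    # fields are framed the way the assay is imaged: fewer beads means a
    # closer view, so bead and sprout sizes scale up and the structural
    # density the thresholds see stays comparable
    if n_beads == 1:
        cells = [(half, half)]
        jit, radius_rng, trunk_rng, child_rng = 25, (90, 110), (80, 110), (65, 90)
    elif n_beads == 2:
        c = 200
        cells = [(c, c), (size - c, size - c)] if rng.uniform() < 0.5 else \
            [(c, size - c), (size - c, c)]
        jit, radius_rng, trunk_rng, child_rng = 15, (55, 65), (45, 60), (40, 55)
    else:
        size = max(size, 960)
        q = size // 4
        cells = [(q, q), (q, 3 * q), (3 * q, q), (3 * q, 3 * q)]
        cells = [cells[int(i)] for i in rng.permutation(4)[:n_beads]]
        jit, radius_rng, trunk_rng, child_rng = 15, (55, 65), (45, 60), (40, 55)
    beads = []
    for cy0, cx0 in cells:
        cy = cy0 + float(rng.uniform(-jit, jit))
        cx = cx0 + float(rng.uniform(-jit, jit))
        radius = float(rng.uniform(*radius_rng))
        n_sprouts = int(rng.integers(4, 6))
        slot = 360.0 / n_sprouts
        base = float(rng.uniform(0, 360))
        sprouts = []
        for k in range(n_sprouts):
            angle = base + k * slot + float(rng.uniform(-0.12, 0.12) * slot)
            trunk = float(rng.uniform(*trunk_rng))
            if rng.uniform() < 0.5:
                children = (float(rng.uniform(*child_rng)),
                            float(rng.uniform(*child_rng)))
                spread = float(rng.uniform(35, 45))
                sprouts.append(SproutPlan(angle, trunk, children, spread))
            else:
                sprouts.append(SproutPlan(angle, trunk))
        beads.append(BeadPlan(cy=cy, cx=cx, radius=radius,
                              sprouts=tuple(sprouts)))
    return SceneSpec(kind="fba", height=size, width=size,
                     beads=tuple(beads), seed=seed, **overrides)


def random_etfa_spec(seed: int, n_cells: int | None = None,
                     size: int = 640, **overrides) -> SceneSpec:
    """A random jittered tiling with 1-12 meshes, spurs and fragments."""
    rng = np.random.default_rng(seed)
    if n_cells is None:
        n_cells = int(rng.integers(1, 13))
    # factor n_cells into rows x cols as squarely as possible
    best = (1, n_cells)
    for r in range(1, n_cells + 1):
        if n_cells % r == 0:
            c = n_cells // r
            if abs(r - c) < abs(best[0] - best[1]):
                best = (r, c)
    rows, cols = best
    # the canvas grows with the tiling so cells keep a realistic size
    # (pseudo-capillary meshes are imaged at high magnification)
    margin = 80.0
    cell = 170.0 if rows * cols <= 2 else (110.0 if rows * cols <= 6 else 90.0)
    width = max(size, int(cols * cell + 2 * margin))
    height = max(320, int(rows * cell + 2 * margin))
    oy = (height - rows * cell) / 2.0
    ox = (width - cols * cell) / 2.0
    jitter = tuple(
        tuple((float(rng.uniform(-5, 5)), float(rng.uniform(-5, 5)))
              for _ in range(cols + 1))
        for _ in range(rows + 1))
    spurs = []
    if rows >= 1 and cols >= 2:
        # dangling branches at non-corner bottom border vertices (the top
        # margin band is reserved for loose fragments)
        n_spurs = int(rng.integers(0, 3))
        choices = [(rows, j, 90.0) for j in range(1, cols)]
        for pick in rng.permutation(len(choices))[:n_spurs]:
            i, j, ang = choices[int(pick)]
            spurs.append((i, j, ang + float(rng.uniform(-20, 20)),
                          float(rng.uniform(25, 40))))
    fragments = []
    for k in range(int(rng.integers(0, 3))):
        length = float(rng.choice([5.0, 6.0, 18.0, 22.0]))
        y = float(rng.uniform(12, 35))
        x = float(rng.uniform(30, width - 60))
        fragments.append((y, x, float(rng.uniform(0, 180)), length))
    grid = MeshGridPlan(origin=(oy, ox), rows=rows, cols=cols, cell=cell,
                        jitter=jitter, spurs=tuple(spurs),
                        fragments=tuple(fragments))
    return SceneSpec(kind="etfa", height=height, width=width, grid=grid,
                     seed=seed, **overrides)


def perturbation_suite(spec: SceneSpec, perturbations=()):
    """Render the base spec under a list of field overrides.

    Each perturbation is a dict of ``SceneSpec`` field overrides; an empty
    list yields just the base render.
    """
    specs = [spec] if not perturbations else [replace(spec, **p)
                                              for p in perturbations]
    return [render_scene(s) for s in specs]
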