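"""Microcarrier bead detection for the fibrin bead assay.

A phase-contrast image of a Cytodex bead shows a dark disk with a bright
rim.  Detection proceeds in three stages: a coarse bead mask from
edge-enhanced thresholding, an interior mask that isolates one connected
component per bead (separating touching beads), and a least-squares circle
fit to each interior boundary, enlarged to account for the thickness of
the bead envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .raster import (
    DegenerateImageError,
    as_image,
    auto_threshold,
    binary_morphology,
    flatfield_correct,
    log_enhance,
    maximum_filter,
    variance_filter,
)

__all__ = [
    "Circle",
    "SphereDetectionParams",
    "coarse_sphere_mask",
    "interior_mask",
    "fit_spheres",
    "detect_spheres",
]

log = logging.getLogger(__name__)

# A fitted circle whose RMS boundary residual exceeds this fraction of its
# radius is rejected as non-circular clutter (dirt, crescents).
MAX_RESIDUAL_FRACTION = 0.25

# The trimmed fit must keep at least this fraction of the boundary pixels;
# shapes like crescents fit a clean circle to a minority arc and fail here.
MIN_INLIER_FRACTION = 0.7


@dataclass(frozen=True)
class Circle:
    """A fitted bead boundary: center (row, col), radius, RMS fit residual."""

    cy: float
    cx: float
    radius: float
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be strictly positive")
        if self.fit_residual < 0:
            raise ValueError("fit_residual must be non-negative")

    def distance_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel Euclidean distance from the circle center."""
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return np.hypot(yy - self.cy, xx - self.cx)

    def ring_mask(self, shape: tuple[int, int], tol: float = 1.0) -> np.ndarray:
        """Pixels within ``tol`` of the circle boundary."""
        return np.abs(self.distance_map(shape) - self.radius) <= tol

    def contains(self, y: float, x: float, margin: float = 0.0) -> bool:
        return bool(np.hypot(y - self.cy, x - self.cx) < self.radius + margin)

    def to_dict(self) -> dict:
        return {"cy": self.cy, "cx": self.cx, "radius": self.radius,
                "fit_residual": self.fit_residual}


@dataclass(frozen=True)
class SphereDetectionParams:
    """Tunables of the bead detector.

    ``sigma`` is the expected bead diameter (drives flat-field correction),
    ``edge_radius`` the apparent rim thickness (variance-filter radius).
    Components whose fitted diameter falls outside
    ``[min_diameter, max_diameter]`` are discarded as clutter; the fitted
    radius is enlarged by ``edge_thickness`` to cover the bead envelope.
    """

    sigma: float
    edge_radius: float = 4.0
    min_diameter: float | None = None
    max_diameter: float | None = None
    edge_thickness: float | None = None
    max_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.edge_radius <= 0:
            raise ValueError("sigma and edge_radius must be positive")
        if self.min_diameter is None:
            object.__setattr__(self, "min_diameter", 0.5 * self.sigma)
        if self.max_diameter is None:
            object.__setattr__(self, "max_diameter", 2.0 * self.sigma)
        if self.edge_thickness is None:
            object.__setattr__(self, "edge_thickness", self.edge_radius)
        if not 0 < self.min_diameter < self.max_diameter:
            raise ValueError("need 0 < min_diameter < max_diameter")


def coarse_sphere_mask(img, p: SphereDetectionParams) -> np.ndarray:
    """Coarse binary bead mask from edge-enhanced IsoData thresholding.

    flat-field correct -> log -> variance(edge_radius) -> IsoData ->
    close -> fill holes -> open -> fill holes.
    """
    img = as_image(img)
    if img.shape[0] <= p.sigma / 2 and img.shape[1] <= p.sigma / 2:
        raise ValueError("image too small for the configured bead diameter")
    lfc = flatfield_correct(img, p.sigma)
    enh = variance_filter(log_enhance(lfc), p.edge_radius)
    mask = auto_threshold(enh, "isodata")
    mask = binary_morphology(mask, "close")
    mask = binary_morphology(mask, "fill_holes")
    mask = binary_morphology(mask, "open")
    mask = binary_morphology(mask, "fill_holes")
    return mask


def interior_mask(img, coarse, p: SphereDetectionParams) -> np.ndarray:
    """One connected component per bead interior.

    The edge-enhanced image is subtracted from the coarse mask so that
    bead interiors (inside the mask, away from the rim response) stand
    out; a grayscale Maximum filter, Minimum threshold, hole filling and
    opening turn them into disjoint solid components even when bead rims
    touch.  Falls back to IsoData when the histogram is not bimodal.
    """
    img = as_image(img)
    coarse = np.asarray(coarse, dtype=bool)
    if not coarse.any():
        return np.zeros_like(coarse)
    lfc = flatfield_correct(img, p.sigma)
    enh = variance_filter(log_enhance(lfc), p.edge_radius)
    # scale the edge response by its own IsoData level so that "edge" sits
    # near 1 regardless of scene contrast; interiors then stand out as the
    # high mode of the difference image
    _, t_edge = auto_threshold(enh, "isodata", return_threshold=True)
    diff = coarse.astype(np.float64) - enh / max(t_edge, 1e-12)
    diff = np.maximum(diff, 0.0)
    diff = maximum_filter(diff, p.max_radius)
    try:
        mask = auto_threshold(diff, "minimum")
    except ValueError:
        log.warning("Minimum threshold not bimodal; falling back to IsoData")
        mask = auto_threshold(diff, "isodata")
    mask = binary_morphology(mask, "fill_holes")
    mask = binary_morphology(mask, "open")
    return mask


def _kasa_once(ys: np.ndarray, xs: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    a = np.column_stack([2 * xs, 2 * ys, np.ones_like(xs)])
    b = xs * xs + ys * ys
    (cx, cy, c), *_ = np.linalg.lstsq(a, b, rcond=None)
    r = float(np.sqrt(max(c + cx * cx + cy * cy, 1e-12)))
    return float(cy), float(cx), r, np.hypot(ys - cy, xs - cx) - r


def _kasa_fit(ys: np.ndarray, xs: np.ndarray
              ) -> tuple[float, float, float, float, float]:
    """Trimmed algebraic least-squares circle fit.

    Pixels more than 1.5 RMS deviations off the circle are discarded over
    up to three refits, so local dents (e.g. where a sprout base bites
    into a bead interior) do not bias the radius.  Returns
    ``(cy, cx, r, rms, inlier_fraction)``.
    """
    n0 = ys.size
    cy, cx, r, resid = _kasa_once(ys, xs)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    for _ in range(3):
        keep = np.abs(resid) <= max(1.5 * rms, 1.0)
        if keep.sum() < 6 or keep.all():
            break
        ys, xs = ys[keep], xs[keep]
        cy, cx, r, resid = _kasa_once(ys, xs)
        rms = float(np.sqrt(np.mean(resid ** 2)))
    return cy, cx, r, rms, ys.size / n0


def fit_spheres(interior, p: SphereDetectionParams) -> list[Circle]:
    """Fit a circle to each interior component's boundary pixels.

    Components with fitted diameter outside the plausible window, or with
    an RMS residual above ``0.25 * radius`` (non-circular clutter), are
    discarded.  Circles come back sorted by (cy, cx); each radius is
    enlarged by ``edge_thickness``.
    """
    interior = np.asarray(interior, dtype=bool)
    labels, n = ndi.label(interior, structure=np.ones((3, 3), dtype=bool))
    circles: list[Circle] = []
    for i in range(1, n + 1):
        comp = labels == i
        boundary = comp & ~ndi.binary_erosion(comp)
        ys, xs = np.nonzero(boundary)
        if ys.size < 6:
            continue
        cy, cx, r, rms, inlier = _kasa_fit(ys.astype(float), xs.astype(float))
        if rms > MAX_RESIDUAL_FRACTION * r or inlier < MIN_INLIER_FRACTION:
            log.debug("component %d rejected: residual %.2f, inliers %.0f%%",
                      i, rms, 100 * inlier)
            continue
        d = 2 * (r + p.edge_thickness)
        if not p.min_diameter <= d <= p.max_diameter:
            log.debug("component %d rejected: diameter %.1f outside window", i, d)
            continue
        circles.append(Circle(cy=cy, cx=cx, radius=r + p.edge_thickness,
                              fit_residual=rms))
    circles.sort(key=lambda c: (c.cy, c.cx))
    return circles


def detect_spheres(img, p: SphereDetectionParams) -> list[Circle]:
    """Full bead detection: coarse mask -> interior mask -> circle fits."""
    img = as_image(img)
    try:
        coarse = coarse_sphere_mask(img, p)
    except DegenerateImageError:
        raise
    except ValueError:
        return []
    if not coarse.any():
        return []
    inner = interior_mask(img, coarse, p)
    return fit_spheres(inner, p)
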