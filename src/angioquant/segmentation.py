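"""Capillary-network segmentation and skeletonization.

Thin pseudo-capillary structures are enhanced by band-pass filtering and
variance filtering (which folds the paired bright/dark halo bands of phase
contrast into one ridge), thresholded at the histogram mean, and smoothed
into a binary ribbon mask.  The mask is thinned to a one-pixel-wide,
8-connected skeleton.  In bead (FBA) mode the detected circles are filled
before thinning, components not anchored on any circle are dropped, and
circle interiors are cleared afterwards so that only the sprouting trees
remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .raster import (
    FilterParams,
    as_image,
    auto_threshold,
    binary_morphology,
    fft_bandpass,
    flatfield_correct,
    subtract_modal,
    variance_filter,
)
from .spheres import Circle

__all__ = ["Skeleton", "segment_network", "skeletonize_network"]

_STRUCT8 = np.ones((3, 3), dtype=bool)

# A skeleton component "touches" a circle when it has a pixel within this
# distance of the rasterized circle ring.
CIRCLE_CONTACT_TOL = 1.0

# Pixels strictly inside radius - CLEAR_MARGIN are erased when clearing a
# circle; the boundary ring survives for anchorage detection.
CLEAR_MARGIN = 0.5

# Mask holes smaller than one cell cross-section cannot be capillary
# loops; they are filled before thinning so they do not skeletonize into
# tiny cycles.
MIN_HOLE_AREA = 100.0


@dataclass(frozen=True)
class Skeleton:
    """One-pixel-wide, 8-connected skeleton plus its source circles."""

    pixels: np.ndarray
    source_circles: tuple[Circle, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "source_circles", tuple(self.source_circles))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def is_thin(self) -> bool:
        """No 2x2 block of the skeleton is fully foreground."""
        p = self.pixels
        return not np.any(p[:-1, :-1] & p[:-1, 1:] & p[1:, :-1] & p[1:, 1:])


def segment_network(img, p: FilterParams) -> np.ndarray:
    """Binary mask of the capillary network.

    flat-field correct -> band-pass(v1, v2) -> variance(2) ->
    subtract modal value -> Mean threshold -> close -> dilate.
    """
    img = as_image(img)
    lfc = flatfield_correct(img, p.sigma)
    bp = fft_bandpass(lfc, p.fft_v1, p.fft_v2)
    enh = subtract_modal(variance_filter(bp, p.tree_variance_radius))
    # 8-bit convention (macro heritage): the enhanced image is quantized
    # to 256 levels before thresholding, which keeps the Mean threshold
    # above the noise floor even in sparse fields
    peak = float(enh.max())
    if peak > 0:
        enh = np.round(enh * (255.0 / peak))
    mask = auto_threshold(enh, "mean")
    mask = binary_morphology(mask, "close")
    mask = binary_morphology(mask, "dilate")
    return mask


def _remove_2x2_blocks(sk: np.ndarray) -> np.ndarray:
    """Delete redundant pixels so no 2x2 block is fully foreground.

    A pixel in a solid 2x2 block can be removed without changing
    8-connectivity when its remaining 8-neighborhood stays connected;
    with a full 2x2 block the two diagonal partners always keep the
    neighborhood linked, so removal is safe.  Scan order is fixed for
    determinism.
    """
    sk = sk.copy()
    changed = True
    while changed:
        changed = False
        blocks = sk[:-1, :-1] & sk[:-1, 1:] & sk[1:, :-1] & sk[1:, 1:]
        ys, xs = np.nonzero(blocks)
        for y, x in zip(ys, xs):
            for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
                yy, xx = y + dy, x + dx
                if not sk[yy, xx]:
                    continue
                nb = sk[max(yy - 1, 0):yy + 2, max(xx - 1, 0):xx + 2].copy()
                cy, cx = min(yy, 1), min(xx, 1)
                nb[cy, cx] = False
                lab, n = ndi.label(nb, structure=_STRUCT8)
                if n <= 1:
                    sk[yy, xx] = False
                    changed = True
                    break
    return sk


def _fill_small_holes(mask: np.ndarray, max_area: float = MIN_HOLE_AREA) -> np.ndarray:
    labels, n = ndi.label(~mask, structure=ndi.generate_binary_structure(2, 1))
    if not n:
        return mask
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    outside = set(np.unique(labels[border]).tolist())
    sizes = ndi.sum_labels(~mask, labels, index=np.arange(1, n + 1))
    out = mask.copy()
    for lab in range(1, n + 1):
        if lab not in outside and sizes[lab - 1] < max_area:
            out[labels == lab] = True
    return out


def _thin(mask: np.ndarray) -> np.ndarray:
    sk = skeletonize(_fill_small_holes(mask))
    return _remove_2x2_blocks(sk)


def skeletonize_network(mask, circles: list[Circle] | tuple[Circle, ...] = ()) -> Skeleton:
    """Thin the network mask to a skeleton; apply bead-mode cleanup.

    With circles (FBA mode): each circle's disk is filled into the mask
    before thinning so rim responses merge with the bead; skeleton
    components not in contact with any circle ring are removed (floating
    debris is not a sprout); pixels strictly inside a circle are cleared,
    leaving one tree per sprout anchored at the rim.  Without circles
    (ETFA mode) the mask is thinned as-is.
    """
    mask = np.asarray(mask, dtype=bool)
    circles = tuple(circles)
    if not circles:
        return Skeleton(pixels=_thin(mask))

    filled = mask.copy()
    dist_maps = [c.distance_map(mask.shape) for c in circles]
    for c, dm in zip(circles, dist_maps):
        filled |= dm <= c.radius
    sk = _thin(filled)

    ring_zone = np.zeros_like(sk)
    for c, dm in zip(circles, dist_maps):
        ring_zone |= np.abs(dm - c.radius) <= 1.0 + CIRCLE_CONTACT_TOL
    labels, n = ndi.label(sk, structure=_STRUCT8)
    if n:
        touching = np.unique(labels[sk & ring_zone])
        keep = np.zeros(n + 1, dtype=bool)
        keep[touching] = True
        keep[0] = False
        sk &= keep[labels]

    for c, dm in zip(circles, dist_maps):
        sk &= ~(dm < c.radius - CLEAR_MARGIN)
    return Skeleton(pixels=sk, source_circles=circles)
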