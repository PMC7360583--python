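"""Pixel-level primitives shared by the bead and network pipelines.

Flat-field correction, variance filtering, FFT-style band-pass, histogram
auto-thresholds (IsoData / Minimum / Mean) and binary morphology.  All
operations act on plain 2-D ``numpy`` arrays: grayscale images are float
arrays of non-negative intensities, masks are boolean arrays of the same
shape as their source image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "FilterParams",
    "DegenerateImageError",
    "as_image",
    "flatfield_correct",
    "log_enhance",
    "variance_filter",
    "maximum_filter",
    "fft_bandpass",
    "subtract_modal",
    "auto_threshold",
    "binary_morphology",
    "disk_footprint",
]

# Relative floor used wherever a division or log would otherwise hit zero.
EPSILON_FRACTION = 1e-6

# Structure sizes v1/v2 of the band-pass are diameters of the smallest /
# largest structures to keep; the equivalent Gaussian sigma is smaller.
BANDPASS_SIGMA_PER_SIZE = 0.4

HISTOGRAM_BINS = 256


class DegenerateImageError(ValueError):
    """Raised when an image has no usable signal (e.g. all zeros)."""


@dataclass(frozen=True)
class FilterParams:
    """Filter scales for the network-segmentation pipeline.

    Parameters
    ----------
    sigma:
        Gaussian flat-field scale in pixels; set to the average bead
        diameter so that the estimated background varies more slowly than
        any object of interest.
    edge_radius:
        Variance-filter radius used for bead-edge enhancement, matched to
        the apparent thickness of the bead rim.
    max_radius:
        Radius of the grayscale Maximum filter applied to the interior
        difference image.
    tree_variance_radius:
        Variance-filter radius for capillary enhancement; the minimum size
        of cellular extensions to detect.
    fft_v1, fft_v2:
        Band-pass bounds in pixels: structures smaller than ``fft_v1`` or
        larger than ``fft_v2`` are suppressed.  ``fft_v2`` conventionally
        equals ``sigma``.
    """

    sigma: float
    edge_radius: float = 4.0
    max_radius: float = 2.0
    tree_variance_radius: float = 2.0
    fft_v1: float = 1.5
    fft_v2: float | None = None

    def __post_init__(self) -> None:
        v2 = self.sigma if self.fft_v2 is None else self.fft_v2
        object.__setattr__(self, "fft_v2", float(v2))
        for name in ("sigma", "edge_radius", "max_radius",
                     "tree_variance_radius", "fft_v1", "fft_v2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.fft_v1 >= self.fft_v2:
            raise ValueError("fft_v1 must be smaller than fft_v2")


def as_image(pixels) -> np.ndarray:
    """Validate and convert an array-like into a float64 intensity image."""
    img = np.asarray(pixels, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if img.shape[0] < 16 or img.shape[1] < 16:
        raise ValueError("image must be at least 16x16 pixels")
    if not np.all(np.isfinite(img)):
        raise ValueError("image intensities must be finite")
    if np.any(img < 0):
        raise ValueError("image intensities must be non-negative")
    return img


def _epsilon(img: np.ndarray) -> float:
    m = float(img.max())
    return EPSILON_FRACTION * m if m > 0 else EPSILON_FRACTION


def flatfield_correct(img, sigma: float) -> np.ndarray:
    """Divide an image by its own Gaussian blur to level uneven lighting.

    The blur at scale ``sigma`` (the average bead diameter) is an artificial
    flat field; dividing by it removes slowly varying illumination such as
    the meniscus shading of a culture well, leaving a unit-mean image.
    """
    img = as_image(img)
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    if not np.any(img > 0):
        raise DegenerateImageError("degenerate image: all pixels are zero")
    flat = ndi.gaussian_filter(img, sigma=sigma, mode="nearest")
    eps = _epsilon(img)
    return img / np.maximum(flat, eps)


def log_enhance(img) -> np.ndarray:
    """Log-transform intensities (with a relative epsilon floor at zero)."""
    img = as_image(img)
    return np.log(img + _epsilon(img))


def disk_footprint(radius: float) -> np.ndarray:
    """Boolean disk: pixels whose center distance is <= radius."""
    r = int(np.floor(radius))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    return (x * x + y * y) <= radius * radius + 1e-9


def variance_filter(img, radius: float) -> np.ndarray:
    """Local intensity variance in a circular neighborhood.

    Responds strongly at intensity edges and on thin objects, and merges
    the paired bright/dark halo bands of phase-contrast optics into a
    single ridge.  Borders are handled by edge replication.
    """
    img = np.asarray(img, dtype=np.float64)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    fp = disk_footprint(radius)
    kernel = fp.astype(np.float64) / fp.sum()
    mean = ndi.correlate(img, kernel, mode="nearest")
    mean_sq = ndi.correlate(img * img, kernel, mode="nearest")
    return np.maximum(mean_sq - mean * mean, 0.0)


def maximum_filter(img, radius: float) -> np.ndarray:
    """Grayscale maximum over a circular neighborhood."""
    return ndi.maximum_filter(np.asarray(img, dtype=np.float64),
                              footprint=disk_footprint(radius),
                              mode="nearest")


def fft_bandpass(img, v1: float, v2: float) -> np.ndarray:
    """Band-pass: keep structures between ``v1`` and ``v2`` pixels in size.

    Realized as a difference of two Gaussian low-passes (the frequency-
    domain equivalent of the classic FFT band-pass): the narrow blur
    removes structures smaller than ``v1``, subtracting the wide blur
    removes structures larger than ``v2``.  The output is approximately
    zero-mean; no offset is added.
    """
    img = np.asarray(img, dtype=np.float64)
    if v1 >= v2:
        raise ValueError("v1 must be smaller than v2")
    s1 = BANDPASS_SIGMA_PER_SIZE * v1
    s2 = BANDPASS_SIGMA_PER_SIZE * v2
    low1 = ndi.gaussian_filter(img, sigma=s1, mode="nearest")
    low2 = ndi.gaussian_filter(img, sigma=s2, mode="nearest")
    return low1 - low2


def _histogram(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        hi = lo + 1.0
    counts, edges = np.histogram(img, bins=HISTOGRAM_BINS, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(np.float64), centers


def subtract_modal(img) -> np.ndarray:
    """Subtract the histogram modal value (256 bins) and clip at zero.

    Removes the dominant background level so that only signal above the
    most frequent intensity survives.
    """
    img = np.asarray(img, dtype=np.float64)
    counts, centers = _histogram(img)
    mode = centers[int(np.argmax(counts))]
    return np.maximum(img - mode, 0.0)


def _threshold_mean(img: np.ndarray) -> float:
    return float(img.mean())


def _threshold_isodata(img: np.ndarray) -> float:
    # Fixed point of t = (mean(below) + mean(above)) / 2, iterated on the
    # raw intensities so the result is exactly affine-equivariant.
    values = img.ravel()
    if np.unique(values).size < 2:
        raise ValueError("IsoData threshold needs at least two distinct values")
    t = float(values.mean())
    for _ in range(500):
        below = values[values <= t]
        above = values[values > t]
        if below.size == 0 or above.size == 0:
            break
        t_new = 0.5 * (float(below.mean()) + float(above.mean()))
        if abs(t_new - t) < 1e-9 * max(1.0, abs(t)):
            t = t_new
            break
        t = t_new
    return t


def _threshold_minimum(img: np.ndarray) -> float:
    # Iteratively smooth the 256-bin histogram with a 3-bin moving average
    # until exactly two local maxima remain; threshold at the valley.
    if np.unique(img.ravel()).size < 2:
        raise ValueError("Minimum threshold needs at least two distinct values")
    counts, centers = _histogram(img)
    smooth = counts.copy()

    def n_maxima(h: np.ndarray) -> int:
        pad = np.concatenate(([-np.inf], h, [-np.inf]))
        return int(np.sum((pad[1:-1] > pad[:-2]) & (pad[1:-1] >= pad[2:])))

    for _ in range(10000):
        if n_maxima(smooth) <= 2:
            break
        smooth = np.convolve(smooth, np.ones(3) / 3.0, mode="same")
    else:
        raise ValueError("histogram not bimodal")
    if n_maxima(smooth) < 2:
        raise ValueError("histogram not bimodal")
    pad = np.concatenate(([-np.inf], smooth, [-np.inf]))
    peaks = np.nonzero((pad[1:-1] > pad[:-2]) & (pad[1:-1] >= pad[2:]))[0]
    lo, hi = int(peaks[0]), int(peaks[-1])
    between = smooth[lo:hi + 1]
    # the inter-mode minimum may be a flat plateau of empty bins; take its
    # middle bin so the threshold sits centrally in the valley
    minima = np.nonzero(between == between.min())[0]
    valley = lo + int(minima[len(minima) // 2])
    return float(centers[valley])


_THRESHOLD_METHODS = {
    "mean": _threshold_mean,
    "isodata": _threshold_isodata,
    "minimum": _threshold_minimum,
}


def auto_threshold(img, method: str, return_threshold: bool = False):
    """Binarize with a classic histogram auto-threshold.

    ``method`` is one of ``"isodata"`` (iterative intermeans), ``"minimum"``
    (valley of the smoothed bimodal histogram) or ``"mean"``.  Pixels
    strictly above the threshold are foreground; ties go to background.
    """
    img = np.asarray(img, dtype=np.float64)
    key = method.lower()
    if key not in _THRESHOLD_METHODS:
        raise ValueError(f"unknown threshold method: {method!r}")
    t = _THRESHOLD_METHODS[key](img)
    mask = img > t
    return (mask, t) if return_threshold else mask


_STRUCT3 = np.ones((3, 3), dtype=bool)


def binary_morphology(mask, op: str, radius: float | None = None) -> np.ndarray:
    """Binary morphology with a 3x3 structuring element by default.

    ``op`` is one of ``close``, ``open``, ``dilate``, ``erode``,
    ``fill_holes`` or ``maximum_filter`` (disk dilation of the given
    radius).  ``fill_holes`` fills background components not connected to
    the image border.
    """
    mask = np.asarray(mask, dtype=bool)
    struct = disk_footprint(radius) if radius is not None else _STRUCT3
    if op == "close":
        # Padded closing so dilation at the border does not leak past it.
        pad = struct.shape[0] // 2
        padded = np.pad(mask, pad, mode="constant")
        out = ndi.binary_erosion(ndi.binary_dilation(padded, struct), struct)
        return out[pad:-pad, pad:-pad]
    if op == "open":
        return ndi.binary_opening(mask, struct)
    if op == "dilate":
        return ndi.binary_dilation(mask, struct)
    if op == "erode":
        return ndi.binary_erosion(mask, struct)
    if op == "fill_holes":
        return ndi.binary_fill_holes(mask)
    if op == "maximum_filter":
        if radius is None:
            raise ValueError("maximum_filter needs a radius")
        return ndi.binary_dilation(mask, disk_footprint(radius))
    raise ValueError(f"unknown morphological operation: {op!r}")
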