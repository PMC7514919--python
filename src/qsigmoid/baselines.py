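"""Comparison enhancers: histogram equalization, gray-level slicing, Otsu.

These are the classical global techniques the q-sigmoid transforms are
benchmarked against.  All operate on :class:`~qsigmoid.core.GrayImage`,
preserve shape, and produce values in ``[0, level_ceiling]``.
"""

from __future__ import annotations

import numpy as np
from skimage import exposure

from .core import GrayImage

__all__ = ["histogram_equalize", "slicing", "otsu_threshold"]


def histogram_equalize(img: GrayImage, nbins: int = 256) -> GrayImage:
    """Classical cumulative-histogram equalization onto ``[0, L]``.

    The mapping is the image's empirical CDF scaled to the intensity ceiling,
    hence monotone non-decreasing: pixel ordering is preserved (up to bin
    quantization) while the output histogram is flattened.
    """
    if nbins < 2:
        raise ValueError(f"nbins must be >= 2, got {nbins}")
    out = exposure.equalize_hist(img.pixels, nbins=nbins)
    return GrayImage(out * img.level_ceiling, img.level_ceiling)


def slicing(
    img: GrayImage,
    low: "float | None" = None,
    high: "float | None" = None,
    mode: str = "clamp",
) -> GrayImage:
    """Gray-level slicing: map the window ``[low, high]`` linearly onto ``[0, L]``.

    Values outside the window saturate (``mode="clamp"``) or are zeroed
    (``mode="reject"``).  The default window is the 2nd-98th intensity
    percentile of the image, which discards the extreme tails the eye is
    least sensitive to.
    """
    if mode not in ("clamp", "reject"):
        raise ValueError(f"mode must be 'clamp' or 'reject', got {mode!r}")
    if low is None:
        low = float(np.percentile(img.pixels, 2.0))
    if high is None:
        high = float(np.percentile(img.pixels, 98.0))
    if not (0 <= low < high <= img.level_ceiling):
        raise ValueError(f"need 0 <= low < high <= {img.level_ceiling}, got ({low}, {high})")
    L = img.level_ceiling
    scaled = (img.pixels - low) / (high - low) * L
    if mode == "clamp":
        out = np.clip(scaled, 0.0, L)
    else:
        inside = (img.pixels >= low) & (img.pixels <= high)
        out = np.where(inside, np.clip(scaled, 0.0, L), 0.0)
    return GrayImage(out, L)


def otsu_threshold(img: GrayImage, nbins: int = 256) -> tuple[float, np.ndarray]:
    """Otsu's threshold over a fixed ``[0, L]``-anchored histogram.

    Intensities are binned by ``floor(v / L * (nbins - 1))`` — bit-exact
    across 8/16-bit inputs — and the threshold bin maximizes the
    between-class variance, ties broken toward the lower threshold.  Returns
    the threshold on the intensity scale and the mask of pixels >= threshold.
    A constant image has no two classes to separate and raises.
    """
    if nbins < 2:
        raise ValueError(f"nbins must be >= 2, got {nbins}")
    L = img.level_ceiling
    bins = np.floor(img.pixels / L * (nbins - 1)).astype(np.int64)
    np.clip(bins, 0, nbins - 1, out=bins)
    hist = np.bincount(bins.ravel(), minlength=nbins).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("image has fewer than 2 distinct quantized levels")
    p = hist / hist.sum()
    levels = np.arange(nbins, dtype=np.float64)
    w0 = np.cumsum(p)[:-1]  # weight of class {bins < t} for t = 1..nbins-1
    m0 = np.cumsum(p * levels)[:-1]
    w1 = 1.0 - w0
    mtot = float(np.sum(p * levels))
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        between = np.where(valid, w0 * w1 * (m0 / w0 - (mtot - m0) / w1) ** 2, -np.inf)
    t_bin = int(np.argmax(between)) + 1  # argmax takes the first (lowest) maximizer
    threshold = t_bin / (nbins - 1) * L
    return threshold, img.pixels >= threshold
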