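"""Evaluation statistics: convex-hull Err, AMBE, and the dilation-ring similarity.

Three statistics quantify how well an enhancement isolates a region of
interest:

* ``Err = 1 - A1 / A0`` compares the convex-hull area of the achieved region
  (A1) with that of the ground truth (A0); 0 is optimal, values can go
  negative when the achieved hull exceeds the truth hull.
* ``AMBE = |E(X) - E(Y)|`` is the absolute mean-brightness error between an
  input and an enhanced image; lower means brightness is better preserved.
* ``S(A, G)`` averages the Jaccard index of a segmentation A against the
  ground truth G with the fraction of the one-pixel outer ring of G left
  uncovered by A — the ring term penalizes segmentations that leak across
  the region boundary.

Region-extraction helpers (thresholding with optional largest-component
filtering) connect the pixelwise transforms to these region statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .core import GrayImage

__all__ = [
    "MetricRecord",
    "records_to_dataframe",
    "save_records",
    "default_threshold",
    "extract_region",
    "convex_hull_area",
    "err_measure",
    "ambe",
    "dilate",
    "similarity_S",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # canonical 3x3 structuring element


@dataclass(frozen=True)
class MetricRecord:
    """One named statistic value plus the configuration that produced it."""

    name: str
    value: float
    params: dict = field(default_factory=dict)
    source: str = ""


def records_to_dataframe(records: "list[MetricRecord]") -> pd.DataFrame:
    rows = [
        {"name": r.name, "value": r.value, "source": r.source, "params": json.dumps(r.params, sort_keys=True, default=str)}
        for r in records
    ]
    return pd.DataFrame(rows, columns=["name", "value", "source", "params"])


def save_records(records: "list[MetricRecord]", path: "str | Path") -> Path:
    """Serialize a record batch to CSV or JSON (by file suffix)."""
    path = Path(path)
    df = records_to_dataframe(records)
    if path.suffix.lower() == ".json":
        path.write_text(df.to_json(orient="records", indent=2) + "\n")
    else:
        df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# region extraction


def default_threshold(family: str, convention: str = "midpoint") -> float:
    """Extraction threshold for a transform family's codomain.

    ``midpoint`` thresholds halfway between the family's background level and
    the peak: 0.5 for families whose background tends to 0 (sigmoid,
    qsig_low), 0.75 for those tending to 1/2 (modified_sigmoid, qsig_high).
    ``display`` marks pixels whose rounded 8-bit rendering exceeds the
    rendered background level (level >= 1, resp. >= 129 out of 255), i.e. the
    region visibly brighter than background on an 8-bit display.
    """
    dark_background = family in ("sigmoid", "qsig_low")
    if convention == "midpoint":
        return 0.5 if dark_background else 0.75
    if convention == "display":
        return 0.5 / 255.0 if dark_background else 128.5 / 255.0
    raise ValueError(f"unknown convention {convention!r}; expected 'midpoint' or 'display'")


def extract_region(img: GrayImage, t: float = 0.5, largest_component: bool = False) -> np.ndarray:
    """Boolean mask of pixels with value >= ``t``.

    With ``largest_component=True`` only the largest 8-connected component is
    kept (ties broken by label order).  An empty mask is a valid result.
    """
    mask = img.pixels >= t
    if largest_component and mask.any():
        labels, n = ndimage.label(mask, structure=_EIGHT)
        if n > 1:
            sizes = np.bincount(labels.ravel())[1:]
            mask = labels == (1 + int(np.argmax(sizes)))
    return mask


# ---------------------------------------------------------------------------
# statistics


def convex_hull_area(mask: np.ndarray, method: str = "polygon") -> float:
    """Area of the convex hull of the centers of all true pixels (pixel^2).

    ``polygon`` (default) is the shoelace area of the hull polygon through
    pixel centers; degenerate masks (empty, single pixel, collinear) have
    zero polygon area.  ``pixel_count`` counts the pixels of the filled
    convex hull instead, as a discretized sensitivity variant.
    """
    mask = np.asarray(mask, dtype=bool)
    if method == "pixel_count":
        from skimage.morphology import convex_hull_image

        return float(convex_hull_image(mask).sum()) if mask.any() else 0.0
    if method != "polygon":
        raise ValueError(f"unknown method {method!r}")
    pts = np.argwhere(mask).astype(np.float64)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the polygon area
    except QhullError:
        return 0.0  # collinear points span no area


def err_measure(achieved: np.ndarray, truth: np.ndarray) -> float:
    """Convex-hull region error ``1 - A1 / A0``; 0 is optimal, not clamped."""
    a0 = convex_hull_area(truth)
    if a0 <= 0.0:
        raise ValueError("ground-truth hull area is zero; Err is undefined")
    return 1.0 - convex_hull_area(achieved) / a0


def ambe(X: GrayImage, Y: GrayImage) -> float:
    """Absolute mean brightness error ``|E(X) - E(Y)|``; symmetric."""
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    return float(abs(X.pixels.mean() - Y.pixels.mean()))


def dilate(mask: np.ndarray) -> np.ndarray:
    """Binary dilation by the full 3x3 structuring element (outside = false)."""
    return ndimage.binary_dilation(np.asarray(mask, dtype=bool), structure=_EIGHT)


def similarity_S(A: np.ndarray, G: np.ndarray) -> float:
    """Segmentation similarity: mean of the Jaccard index and the clean-ring fraction.

    ``S = (|A n G| / |A u G| + |ring n ~A| / |ring|) / 2`` where ``ring`` is
    the one-pixel outer ring ``dilate(G) - G``.  The ring term is ~1 when the
    segmentation does not leak across the ground-truth boundary, and lowers S
    when A bridges the region with its surroundings.
    """
    A = np.asarray(A, dtype=bool)
    G = np.asarray(G, dtype=bool)
    if A.shape != G.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {G.shape}")
    if not G.any():
        raise ValueError("ground truth is empty; S is undefined")
    ring = dilate(G) & ~G
    n_ring = int(ring.sum())
    if n_ring == 0:
        raise ValueError("ground truth fills the raster; the outer ring is empty")
    union = int((A | G).sum())
    jaccard = int((A & G).sum()) / union  # union >= |G| > 0
    clean = int((ring & ~A).sum()) / n_ring
    return 0.5 * (jaccard + clean)
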