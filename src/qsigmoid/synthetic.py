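"""Synthetic scenes: Gaussian phantom, noise series and speckled lesions.

The Gaussian phantom is the controlled test scene for the enhancement
experiments: a normalized 2-D Gaussian intensity profile (peak 1) whose
spread ``delta`` sets the size of the region of interest.  The default scene
is a 256x256 raster with the peak at pixel (175, 175) and ``delta = 30``
pixels; the ground-truth region is the disc of radius ``3 * delta`` around
the peak, clipped at the raster borders.

Noise-degraded copies of the phantom (additive Gaussian, parameterized by a
linear-power SNR) and ultrasound-like speckled-lesion scenes (a darker
ellipse under unit-mean multiplicative gamma speckle) make every metric and
experiment testable without external data.  All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .core import GrayImage

__all__ = [
    "GaussianSceneSpec",
    "gaussian_scene",
    "ground_truth_mask",
    "add_gaussian_noise",
    "noisy_phantom_series",
    "speckled_lesion_scene",
    "random_lesion_scenes",
    "write_fixture",
]


@dataclass(frozen=True)
class GaussianSceneSpec:
    """Geometry of the synthetic Gaussian phantom.

    ``delta`` is the spatial spread in pixels, read as a standard deviation
    by default; set ``delta_is_variance=True`` for the alternative reading
    (sigma = sqrt(delta)).
    """

    height: int = 256
    width: int = 256
    center: tuple[float, float] = (175.0, 175.0)
    delta: float = 30.0
    delta_is_variance: bool = False

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("raster must be at least 1x1")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        r, c = self.center
        if not (0 <= r <= self.height - 1 and 0 <= c <= self.width - 1):
            raise ValueError(f"center {self.center} lies outside the {self.height}x{self.width} raster")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.delta)) if self.delta_is_variance else float(self.delta)

    def _sq_dist(self) -> np.ndarray:
        r, c = np.mgrid[0 : self.height, 0 : self.width]
        return (r - self.center[0]) ** 2 + (c - self.center[1]) ** 2


def gaussian_scene(spec: GaussianSceneSpec = GaussianSceneSpec()) -> GrayImage:
    """Normalized 2-D Gaussian intensity profile; maximum exactly 1.

    Pixel value is ``exp(-d^2 / (2 sigma^2))`` with ``d`` the distance to the
    center, renormalized so the pixel nearest the center is exactly 1.
    """
    vals = np.exp(-spec._sq_dist() / (2.0 * spec.sigma**2))
    return GrayImage(vals / vals.max(), 1.0)


def ground_truth_mask(
    spec: GaussianSceneSpec = GaussianSceneSpec(), k: float = 3.0, mode: str = "disc"
) -> np.ndarray:
    """Ground-truth region of the phantom: the ``k * sigma`` disc (default).

    ``mode="disc"`` marks pixels within Euclidean distance ``k * sigma`` of
    the center (clipped at raster borders).  ``mode="intensity"`` is the
    threshold variant marking pixels with intensity >= exp(-k^2 / 2), provided
    for sensitivity analysis; on an unclipped raster the two coincide.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if mode == "disc":
        return spec._sq_dist() <= (k * spec.sigma) ** 2
    if mode == "intensity":
        return gaussian_scene(spec).pixels >= float(np.exp(-(k**2) / 2.0))
    raise ValueError(f"unknown mode {mode!r}; expected 'disc' or 'intensity'")


def add_gaussian_noise(img: GrayImage, snr: float, seed: int) -> GrayImage:
    """Add zero-mean Gaussian noise at the given linear-power SNR.

    The noise variance is ``mean(signal^2) / snr``; the result is clipped to
    ``[0, level_ceiling]``.  Identical (img, snr, seed) give identical output.
    """
    if not (snr > 0):
        raise ValueError(f"snr must be positive, got {snr!r}")
    rng = np.random.default_rng(seed)
    sd = float(np.sqrt(np.mean(img.pixels**2) / snr))
    noisy = np.clip(img.pixels + rng.normal(0.0, sd, img.pixels.shape), 0.0, img.level_ceiling)
    return GrayImage(noisy, img.level_ceiling)


def noisy_phantom_series(
    spec: GaussianSceneSpec = GaussianSceneSpec(),
    n: int = 100,
    snr_max: float = 100.0,
    seed: int = 0,
    truth_k: float = 3.0,
) -> list[tuple[GrayImage, np.ndarray, float]]:
    """Series of noise-degraded phantoms spanning SNR values up to ``snr_max``.

    SNR values are evenly spaced from 0 to ``snr_max``; the degenerate 0
    endpoint is replaced by the smallest positive value of the series.
    Returns ``(image, ground-truth mask, snr)`` triples.
    """
    if n < 2:
        raise ValueError("series needs at least 2 images")
    img = gaussian_scene(spec)
    truth = ground_truth_mask(spec, k=truth_k)
    snrs = np.linspace(0.0, snr_max, n)
    snrs[0] = snrs[1]
    return [(add_gaussian_noise(img, float(s), seed + i), truth, float(s)) for i, s in enumerate(snrs)]


def speckled_lesion_scene(
    height: int = 256,
    width: int = 256,
    lesion_center: tuple[float, float] = (128.0, 128.0),
    lesion_axes: tuple[float, float] = (40.0, 28.0),
    background_level: float = 0.6,
    lesion_level: float = 0.2,
    looks: int = 4,
    seed: int = 0,
) -> tuple[GrayImage, np.ndarray]:
    """Ultrasound-like fixture: a darker elliptical lesion under speckle.

    The noiseless scene is a piecewise-constant image (``background_level``
    outside, ``lesion_level`` inside the ellipse) multiplied by unit-mean
    gamma-distributed speckle with shape ``looks`` (larger = cleaner) and
    clipped to ``[0, 1]``.  Returns the image and the true lesion mask.  This
    emulates only the qualitative structure of ultrasound imagery, not its
    physics.
    """
    if not (0 <= lesion_level <= 1 and 0 <= background_level <= 1):
        raise ValueError("levels must lie in [0, 1]")
    if looks < 1:
        raise ValueError(f"looks must be >= 1, got {looks}")
    cr, cc = lesion_center
    ar, ac = lesion_axes
    if not (ar > 0 and ac > 0):
        raise ValueError("lesion axes must be positive")
    if not (0 <= cr - ar and cr + ar <= height - 1 and 0 <= cc - ac and cc + ac <= width - 1):
        raise ValueError("lesion ellipse extends outside the raster")
    r, c = np.mgrid[0:height, 0:width]
    mask = ((r - cr) / ar) ** 2 + ((c - cc) / ac) ** 2 <= 1.0
    scene = np.where(mask, lesion_level, background_level)
    rng = np.random.default_rng(seed)
    speckle = rng.gamma(shape=looks, scale=1.0 / looks, size=scene.shape)
    return GrayImage(np.clip(scene * speckle, 0.0, 1.0), 1.0), mask


def random_lesion_scenes(
    n: int, seed: int = 0, height: int = 128, width: int = 128, looks: int = 4
) -> list[tuple[GrayImage, np.ndarray]]:
    """Batch of lesion fixtures with jittered geometry and levels.

    Stand-in corpus for batch experiments; each scene gets an independent
    sub-seed derived from ``seed`` so the batch is reproducible.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        ar = float(rng.uniform(0.1, 0.2) * height)
        ac = float(rng.uniform(0.1, 0.2) * width)
        cr = float(rng.uniform(ar + 1, height - 2 - ar))
        cc = float(rng.uniform(ac + 1, width - 2 - ac))
        out.append(
            speckled_lesion_scene(
                height,
                width,
                (cr, cc),
                (ar, ac),
                background_level=float(rng.uniform(0.5, 0.7)),
                lesion_level=float(rng.uniform(0.1, 0.3)),
                looks=looks,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


def write_fixture(img: GrayImage, path: "str | Path", bit_depth: int = 8, **meta) -> Path:
    """Write a fixture image plus a JSON sidecar manifest for provenance.

    ``meta`` (e.g. spec parameters, seed, snr) is serialized next to the
    image as ``<name>.json``.  Returns the manifest path.
    """
    from .io import write_image  # deferred: io depends on core only

    path = Path(path)
    write_image(img, path, bit_depth=bit_depth)
    manifest = {"image": path.name, "bit_depth": bit_depth, "level_ceiling": img.level_ceiling}
    for key, val in meta.items():
        manifest[key] = asdict(val) if hasattr(val, "__dataclass_fields__") else val
    mpath = path.with_suffix(".json")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath
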