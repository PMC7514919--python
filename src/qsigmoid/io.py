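"""Reading and writing grayscale rasters (PNG/TIFF) as :class:`GrayImage`."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .core import GrayImage

__all__ = ["read_image", "write_image"]

_CEILINGS = {np.dtype(np.uint8): 255.0, np.dtype(np.uint16): 65535.0}


def read_image(path: "str | Path", normalize: bool = False) -> GrayImage:
    """Read a PNG/TIFF as a grayscale image.

    8-bit data gets ``level_ceiling`` 255 and 16-bit 65535; floating-point
    rasters are taken as already normalized (ceiling 1.0).  Multi-channel
    images collapse to grayscale only when all channels are identical.  With
    ``normalize=True`` intensities are rescaled onto ``[0, 1]`` by the level
    ceiling, so max-level pixels map to exactly 1.0.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):
            rgb = arr[..., :3]
            if not (np.array_equal(rgb[..., 0], rgb[..., 1]) and np.array_equal(rgb[..., 0], rgb[..., 2])):
                raise ValueError(f"{path}: multi-channel image is not grayscale; no collapse rule")
            arr = rgb[..., 0]
        else:
            raise ValueError(f"{path}: unsupported channel layout {arr.shape}")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D raster, got shape {arr.shape}")
    if arr.dtype in _CEILINGS:
        ceiling = _CEILINGS[arr.dtype]
    elif np.issubdtype(arr.dtype, np.floating):
        ceiling = 1.0
    else:
        raise ValueError(f"{path}: unsupported bit depth / dtype {arr.dtype}")
    img = GrayImage(arr.astype(np.float64), ceiling)
    return img.normalized() if normalize else img


def write_image(img: GrayImage, path: "str | Path", bit_depth: "int | None" = None) -> Path:
    """Write as 8- or 16-bit PNG/TIFF.

    Integer-valued data on a matching ceiling round-trips losslessly; data on
    ceiling 1.0 is scaled by ``2**bit_depth - 1``.  Default bit depth is 8
    unless the ceiling requires 16.
    """
    path = Path(path)
    if bit_depth is None:
        bit_depth = 16 if img.level_ceiling > 255.0 else 8
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    full = float(2**bit_depth - 1)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    scaled = np.rint(img.pixels / img.level_ceiling * full)
    iio.imwrite(path, np.clip(scaled, 0, full).astype(dtype))
    return path
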