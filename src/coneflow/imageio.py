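"""Grayscale image I/O: single-channel TIFF (float or integer) and PNG.

TIFF is the native interchange format (float32 preserves rendered
intensities exactly); PNG is written as 8-bit after rounding and
clipping to [0, 255].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_grayscale", "write_grayscale"]


def read_grayscale(path) -> np.ndarray:
    """Read a single-channel TIFF or PNG as a float array.

    Multi-channel images are rejected: quantitative inputs must be
    grayscale.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, "
                         f"got shape {arr.shape}")
    return arr.astype(float)


def write_grayscale(image: np.ndarray, path) -> None:
    """Write a 2-D array as float32 TIFF, or 8-bit PNG (clipped to
    [0, 255] and rounded)."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img.astype(np.float32))
    elif path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(
            np.clip(np.round(img), 0, 255).astype(np.uint8)
        ).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r}")
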