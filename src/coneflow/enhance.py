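"""Display-only enhancement of mosaic images.

The published grading workflow brightened, contrast-stretched and
sharpened mosaic images *after* grading, purely for visualization.  The
same convention holds here: :func:`enhance_for_display` output must
never be fed into detection or metrics.

Operator definitions ("increase X by N%" read multiplicatively):

* brightness +22%: multiply intensities by 1.22;
* contrast +11%: scale deviations from the (brightened) image mean by
  1.11;
* sharpness +37%: unsharp mask with amount 0.37 (Gaussian radius
  default 2 px);

applied in that order, then clipped to the valid range.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["enhance_for_display"]


def enhance_for_display(
    image: np.ndarray,
    brightness: float = 0.22,
    contrast: float = 0.11,
    sharpness: float = 0.37,
    radius_px: float = 2.0,
    value_range: tuple[float, float] = (0.0, 255.0),
) -> np.ndarray:
    """Brighten, contrast-stretch and sharpen a grayscale image for
    display.  Non-idempotent by construction; a constant image is only
    brightened (deviations from the mean are zero)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("enhance_for_display expects a 2-D grayscale image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    out = img * (1.0 + brightness)
    out = out.mean() + (out - out.mean()) * (1.0 + contrast)
    if sharpness > 0:
        out = out + sharpness * (out - ndimage.gaussian_filter(out, radius_px))
    return np.clip(out, value_range[0], value_range[1])
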