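"""Parafoveal vessel density and non-flow-region detection on en-face
angiogram masks.

Vessel density is the percentage of vessel pixels within a region,
with pixel membership decided by a center-in-region test (no
partial-pixel weighting).  The default region is the parafoveal
annulus: inner diameter 1 mm, outer diameter 3 mm, centered on the
fovea.  Non-flow regions are 8-connected components of the non-vessel
complement whose equivalent-circle diameter exceeds a threshold
(default 100 um); components touching the image border are field-of-view
edges, not lesions, and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AngioImage",
    "AnnulusSpec",
    "NonFlowRegion",
    "VesselDensityResult",
    "binarize",
    "vessel_density",
    "detect_nonflow",
    "annulus_membership",
]


@dataclass
class AngioImage:
    """En-face angiogram: grayscale or binary pixels, a um/px scale and
    the fovea center in pixel coordinates (x, y)."""

    pixels: np.ndarray
    um_per_px: float
    fovea_center: tuple[float, float]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("angiogram must be a 2-D array")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        h, w = px.shape
        cx, cy = self.fovea_center
        if not (-0.5 <= cx <= w - 0.5 and -0.5 <= cy <= h - 0.5):
            raise ValueError("fovea center must lie inside the image")
        self.pixels = px


@dataclass
class AnnulusSpec:
    """Parafoveal annulus: ring between the inner and outer diameters,
    centered on (x, y) in pixels.  Defaults are the 1 mm / 3 mm
    parafovea."""

    inner_diameter_um: float = 1000.0
    outer_diameter_um: float = 3000.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.inner_diameter_um < self.outer_diameter_um:
            raise ValueError("need 0 < inner diameter < outer diameter")


@dataclass
class NonFlowRegion:
    pixel_count: int
    area_um2: float
    equivalent_diameter_um: float
    centroid: tuple[float, float]  # (x_px, y_px)


@dataclass
class VesselDensityResult:
    region_name: str
    vessel_pixels: int
    region_pixels: int
    density_pct: float


def _is_binary(px: np.ndarray) -> bool:
    if px.dtype == bool:
        return True
    vals = np.unique(px)
    return vals.size <= 2 and np.isin(vals, (0, 1)).all()


def binarize(image, method: str = "otsu", **params) -> np.ndarray:
    """Extract a binary vessel mask from a grayscale angiogram.

    Methods: ``"fixed"`` (requires ``threshold``; vessel = pixel >=
    threshold), ``"otsu"`` (global Otsu), ``"local_mean"`` (adaptive
    local-mean threshold; optional ``block_size``, odd, default 51).
    Already-binary input is returned unchanged (as boolean) for any
    method.  All methods are deterministic.
    """
    px = image.pixels if isinstance(image, AngioImage) else np.asarray(image)
    if px.ndim != 2:
        raise ValueError("binarize expects a 2-D image")
    if not np.isfinite(px).all():
        raise ValueError("image contains non-finite values")
    if _is_binary(px):
        return px.astype(bool)
    if method == "fixed":
        if "threshold" not in params:
            raise ValueError("fixed method requires a 'threshold' parameter")
        return px >= float(params["threshold"])
    if method == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(px) == 0:
            raise ValueError(
                "Otsu threshold is undefined on a constant image; "
                "use method='fixed' with an explicit threshold"
            )
        return px >= threshold_otsu(px)
    if method == "local_mean":
        from skimage.filters import threshold_local

        block = int(params.get("block_size", 51))
        return px > threshold_local(px, block_size=block, method="mean")
    raise ValueError(f"unknown binarization method {method!r}")


def annulus_membership(shape: tuple[int, int], annulus: AnnulusSpec,
                       um_per_px: float) -> np.ndarray:
    """Boolean map of pixels whose centers fall inside the annulus."""
    h, w = shape
    cx, cy = annulus.center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    r_um = np.hypot(xx - cx, yy - cy) * um_per_px
    return (r_um >= annulus.inner_diameter_um / 2.0) & (
        r_um <= annulus.outer_diameter_um / 2.0
    )


def vessel_density(
    mask: np.ndarray,
    annulus: AnnulusSpec,
    um_per_px: float,
    region_name: str = "parafovea",
) -> VesselDensityResult:
    """Percentage of vessel pixels inside the annulus.

    Rejects an annulus whose outer circle extends beyond the image.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    cx, cy = annulus.center
    r_px = annulus.outer_diameter_um / 2.0 / um_per_px
    if (cx - r_px < -0.5 or cx + r_px > w - 0.5
            or cy - r_px < -0.5 or cy + r_px > h - 0.5):
        raise ValueError("annulus exceeds the image bounds")
    member = annulus_membership((h, w), annulus, um_per_px)
    region_pixels = int(member.sum())
    vessel_pixels = int((mask & member).sum())
    return VesselDensityResult(
        region_name=region_name,
        vessel_pixels=vessel_pixels,
        region_pixels=region_pixels,
        density_pct=100.0 * vessel_pixels / region_pixels,
    )


def detect_nonflow(
    mask: np.ndarray,
    um_per_px: float,
    min_diameter_um: float = 100.0,
) -> list[NonFlowRegion]:
    """Non-flow regions: 8-connected components of the non-vessel
    complement, border-touching components excluded, kept when the
    equivalent-circle diameter 2*sqrt(area/pi) exceeds
    ``min_diameter_um``.  Sorted by area, largest first."""
    mask = np.asarray(mask).astype(bool)
    complement = ~mask
    labels, n = ndimage.label(complement, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = np.unique(labels[border & complement])
    areas = ndimage.sum_labels(complement, labels, index=np.arange(1, n + 1))
    centroids = ndimage.center_of_mass(complement, labels, np.arange(1, n + 1))
    regions = []
    for lab in range(1, n + 1):
        if lab in touching:
            continue
        area_px = int(areas[lab - 1])
        area_um2 = area_px * um_per_px**2
        eq_diam = 2.0 * np.sqrt(area_um2 / np.pi)
        if eq_diam > min_diameter_um:
            row, col = centroids[lab - 1]
            regions.append(
                NonFlowRegion(
                    pixel_count=area_px,
                    area_um2=float(area_um2),
                    equivalent_diameter_um=float(eq_diam),
                    centroid=(float(col), float(row)),
                )
            )
    regions.sort(key=lambda r: r.pixel_count, reverse=True)
    return regions
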