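"""Cone-center point sets and their on-disk CSV format.

Coordinates are sub-pixel positions in units of pixels, origin at the
top-left pixel center, x rightward, y downward, 0-based.  Physical
distances are always derived through the stored micrometers-per-pixel
scale, never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = ["ConePointSet", "PointsCsvError", "read_points_csv", "write_points_csv"]


class PointsCsvError(ValueError):
    """Malformed or out-of-bounds coordinate CSV."""


@dataclass
class ConePointSet:
    """Cone center coordinates within a rectangular region of interest.

    Parameters
    ----------
    points
        Array of shape (n, 2) holding (x_px, y_px) sub-pixel coordinates.
    roi_width_px, roi_height_px
        Size of the region of interest in pixels.
    um_per_px
        Lateral scale in micrometers per pixel.
    """

    points: np.ndarray
    roi_width_px: int
    roi_height_px: int
    um_per_px: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x_px, y_px)")
        if self.roi_width_px <= 0 or self.roi_height_px <= 0:
            raise ValueError("ROI dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        bad = self._out_of_bounds_rows(pts)
        if bad.size:
            raise PointsCsvError(
                f"point(s) outside ROI bounds at row(s) {bad.tolist()}: "
                f"first offender {tuple(pts[bad[0]])}"
            )
        self.points = pts

    def _out_of_bounds_rows(self, pts: np.ndarray) -> np.ndarray:
        # the image of W x H pixels, origin at the top-left pixel center,
        # spans [-0.5, W-0.5] x [-0.5, H-0.5]
        w, h = self.roi_width_px, self.roi_height_px
        bad = (
            (pts[:, 0] < -0.5)
            | (pts[:, 0] > w - 0.5)
            | (pts[:, 1] < -0.5)
            | (pts[:, 1] > h - 0.5)
        )
        return np.nonzero(bad)[0]

    def __len__(self) -> int:
        return len(self.points)

    @property
    def points_um(self) -> np.ndarray:
        """Coordinates converted to micrometers."""
        return self.points * self.um_per_px

    def min_separation_px(self) -> float:
        """Smallest pairwise distance, in pixels (inf for < 2 points)."""
        if len(self.points) < 2:
            return float("inf")
        return float(pdist(self.points).min())

    def check_min_separation(self, min_separation_px: float = 2.0) -> None:
        """Raise if any two points are closer than ``min_separation_px``."""
        if self.min_separation_px() < min_separation_px:
            raise ValueError(
                f"points violate the minimum separation of {min_separation_px} px"
            )

    def same_frame(self, other: "ConePointSet") -> bool:
        return (
            self.roi_width_px == other.roi_width_px
            and self.roi_height_px == other.roi_height_px
            and np.isclose(self.um_per_px, other.um_per_px)
        )


def write_points_csv(points: ConePointSet, path) -> None:
    """Write a point set to CSV with ``#``-prefixed metadata lines.

    Layout: metadata (ROI size and scale), then a ``x_px,y_px`` header,
    then one row per point.  Round-trips to <= 1e-6 px.
    """
    lines = [
        f"# roi_width_px={points.roi_width_px}",
        f"# roi_height_px={points.roi_height_px}",
        f"# um_per_px={points.um_per_px!r}",
        "x_px,y_px",
    ]
    lines += [f"{x:.8f},{y:.8f}" for x, y in points.points]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_points_csv(
    path,
    roi_width_px: int | None = None,
    roi_height_px: int | None = None,
    um_per_px: float | None = None,
) -> ConePointSet:
    """Read a coordinate CSV written by :func:`write_points_csv`.

    Metadata in ``#`` header lines supplies the ROI geometry; explicit
    arguments override it (and are required if the file has no metadata).
    Out-of-bounds points and missing columns raise :class:`PointsCsvError`
    naming the offending row/field.
    """
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, val = line.lstrip("# ").split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            fields = [f.strip() for f in line.split(",")]
            if header is None:
                header = fields
                if header[:2] != ["x_px", "y_px"]:
                    raise PointsCsvError(
                        f"{path}: expected header 'x_px,y_px', got {line!r}"
                    )
                continue
            try:
                rows.append((float(fields[0]), float(fields[1])))
            except (ValueError, IndexError) as exc:
                raise PointsCsvError(f"{path}: bad row {lineno}: {line!r}") from exc
    if header is None:
        raise PointsCsvError(f"{path}: missing 'x_px,y_px' header")

    def _resolve(arg, key, cast):
        if arg is not None:
            return arg
        if key in meta:
            return cast(meta[key])
        raise PointsCsvError(f"{path}: no {key} metadata and none supplied")

    return ConePointSet(
        points=np.array(rows, dtype=float).reshape(len(rows), 2),
        roi_width_px=_resolve(roi_width_px, "roi_width_px", int),
        roi_height_px=_resolve(roi_height_px, "roi_height_px", int),
        um_per_px=_resolve(um_per_px, "um_per_px", float),
    )
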