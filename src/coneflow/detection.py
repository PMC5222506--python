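"""Cone-center detection in grayscale mosaic images, and scoring of
detections against ground truth.

The detector is the standard parameter-transparent approach for bright,
roughly equally spaced spots: Gaussian pre-smoothing, local intensity
maxima with a minimum-separation constraint and an intensity-quantile
floor, then sub-pixel refinement by a quadratic fit around each peak.
Default parameters are tied to the expected cone spacing (about 8 um at
2-3 degrees of eccentricity): smoothing SD 0.25x spacing — roughly a
matched filter for cone-sized spots; stronger smoothing merges the
maxima of hexagonally packed neighbors — and minimum separation 0.5x
spacing.

Manual correction of detections is supported by round-tripping
coordinates through the CSV format of :mod:`coneflow.points`: an edited
file can be fed back anywhere a detected point set is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .points import ConePointSet, read_points_csv, write_points_csv  # noqa: F401

__all__ = [
    "DetectionParams",
    "DetectionScore",
    "detect_cones",
    "score_detections",
]

_EXPECTED_SPACING_UM = 8.0


@dataclass
class DetectionParams:
    """Detector knobs, all in physical units.

    smooth_sigma_um   Gaussian pre-smoothing SD (0 disables smoothing).
    min_distance_um   minimum separation between accepted peaks.
    threshold_quantile  smoothed-intensity quantile below which peaks
                        are rejected.
    """

    smooth_sigma_um: float = 0.25 * _EXPECTED_SPACING_UM
    min_distance_um: float = 0.5 * _EXPECTED_SPACING_UM
    threshold_quantile: float = 0.1

    def __post_init__(self) -> None:
        if self.smooth_sigma_um < 0:
            raise ValueError("smooth_sigma_um must be >= 0")
        if self.min_distance_um <= 0:
            raise ValueError("min_distance_um must be > 0")
        if not 0 <= self.threshold_quantile <= 1:
            raise ValueError("threshold_quantile must be in [0, 1]")

    @classmethod
    def for_spacing(cls, spacing_um: float,
                    threshold_quantile: float = 0.1) -> "DetectionParams":
        """Defaults scaled to an expected cone spacing."""
        return cls(
            smooth_sigma_um=0.25 * spacing_um,
            min_distance_um=0.5 * spacing_um,
            threshold_quantile=threshold_quantile,
        )


@dataclass
class DetectionScore:
    n_true: int
    n_detected: int
    n_matched: int
    precision: float
    recall: float
    mean_localization_error_um: float


def _subpixel_offset(patch3: np.ndarray) -> float:
    """1-D quadratic-fit peak offset from the center of a 3-sample patch,
    clamped to [-0.5, 0.5]."""
    a, b, c = patch3
    denom = a - 2.0 * b + c
    if denom >= 0:  # flat or non-concave: keep the integer location
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


def detect_cones(
    image: np.ndarray,
    params: DetectionParams | None = None,
    um_per_px: float = 1.445,
) -> ConePointSet:
    """Detect cone centers as smoothed local maxima.

    Candidate peaks are local maxima of the smoothed image (3x3
    neighborhood) above the intensity-quantile threshold; they are
    accepted greedily in order of decreasing intensity — ties broken by
    smaller (y, x) — subject to the minimum separation; accepted peaks
    are refined to sub-pixel positions by per-axis quadratic fits.
    A constant image yields an empty point set.  Deterministic.
    """
    if params is None:
        params = DetectionParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_cones expects a 2-D grayscale image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    h, w = img.shape

    def _empty() -> ConePointSet:
        return ConePointSet(np.empty((0, 2)), w, h, um_per_px)

    if np.ptp(img) == 0:
        return _empty()

    sigma_px = params.smooth_sigma_um / um_per_px
    sm = ndimage.gaussian_filter(img, sigma_px) if sigma_px > 0 else img
    threshold = np.quantile(sm, params.threshold_quantile)

    is_max = sm == ndimage.maximum_filter(sm, size=3, mode="nearest")
    is_max &= sm > threshold
    rows, cols = np.nonzero(is_max)
    if rows.size == 0:
        return _empty()

    order = np.lexsort((cols, rows, -sm[rows, cols]))
    rows, cols = rows[order], cols[order]

    min_dist_px = params.min_distance_um / um_per_px
    accepted: list[tuple[int, int]] = []
    acc_arr = np.empty((rows.size, 2))
    n_acc = 0
    for r, c in zip(rows, cols):
        if n_acc:
            d2 = (acc_arr[:n_acc, 0] - r) ** 2 + (acc_arr[:n_acc, 1] - c) ** 2
            if d2.min() < min_dist_px**2:
                continue
        acc_arr[n_acc] = (r, c)
        n_acc += 1
        accepted.append((int(r), int(c)))

    pts = np.empty((len(accepted), 2))
    for i, (r, c) in enumerate(accepted):
        dx = dy = 0.0
        if 0 < c < w - 1:
            dx = _subpixel_offset(sm[r, c - 1:c + 2])
        if 0 < r < h - 1:
            dy = _subpixel_offset(sm[r - 1:r + 2, c])
        pts[i] = (c + dx, r + dy)
    pts[:, 0] = np.clip(pts[:, 0], -0.5, w - 0.5)
    pts[:, 1] = np.clip(pts[:, 1], -0.5, h - 0.5)
    return ConePointSet(pts, w, h, um_per_px)


def score_detections(
    detected: ConePointSet,
    truth: ConePointSet,
    tol_um: float = 3.0,
) -> DetectionScore:
    """Score detections by one-to-one greedy nearest-neighbor matching.

    Candidate pairs within ``tol_um`` are matched closest-first, each
    point used at most once.  Precision = matched/detected, recall =
    matched/true; the localization error is the mean matched pair
    distance in micrometers.
    """
    if not detected.same_frame(truth):
        raise ValueError("detected and truth point sets use different "
                         "ROI geometry or scale")
    um = truth.um_per_px
    tol_px = tol_um / um
    n_det, n_true = len(detected), len(truth)
    if n_det == 0 or n_true == 0:
        return DetectionScore(n_true, n_det, 0,
                              0.0 if n_det else 0.0, 0.0, float("nan"))

    tree = cKDTree(truth.points)
    pairs: list[tuple[float, int, int]] = []
    for i, p in enumerate(detected.points):
        for j in tree.query_ball_point(p, tol_px):
            d = float(np.hypot(*(p - truth.points[j])))
            pairs.append((d, i, j))
    pairs.sort()
    used_det: set[int] = set()
    used_true: set[int] = set()
    dists: list[float] = []
    for d, i, j in pairs:
        if i in used_det or j in used_true:
            continue
        used_det.add(i)
        used_true.add(j)
        dists.append(d)
    n_matched = len(dists)
    return DetectionScore(
        n_true=n_true,
        n_detected=n_det,
        n_matched=n_matched,
        precision=n_matched / n_det,
        recall=n_matched / n_true,
        mean_localization_error_um=(
            float(np.mean(dists)) * um if dists else float("nan")
        ),
    )
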