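"""Voronoi tessellation of cone centers and packing regularity metrics.

The cone mosaic is summarized by the Voronoi neighbor-count spectrum:
for each cone, the number of Voronoi cells sharing a positive-length
edge with its cell.  A dense, perfectly triangular mosaic gives six
neighbors everywhere; disorder (positional jitter, cone loss) shifts
mass toward 4-, 5-, 7- and 8-sided cells.

The heterogeneity packing index (HPi) condenses the spectrum into a
scalar that *decreases* as 4- and 8-sided cells appear at the expense of
6-sided ones.  The default formula is

    HPi = f6 - f4 - f8

over interior cells, where f_k is the fraction of interior cells with k
neighbors; it is 1 exactly when every interior cell is 6-sided and is
bounded in [-1, 1].  The formula is a named, replaceable strategy
(``hpi_formula`` argument) because different packing-index variants
circulate in the adaptive-optics literature.

Cells that are unbounded or whose polygon touches the region-of-interest
boundary are flagged non-interior and excluded from all metrics — the
standard guard against boundary-truncation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import QhullError, Voronoi

from .points import ConePointSet
from .synthetic import SyntheticMosaicConfig, generate_mosaic_points

__all__ = [
    "RoiSpec",
    "VoronoiCell",
    "PackingMetrics",
    "tessellate",
    "packing_metrics",
    "hpi_vs_disorder_curve",
    "render_tessellation",
    "HPI_FORMULAS",
]

#: Neighbor-count bucket for "9 or more".
MANY = 9

# Deterministic sub-nanometer perturbation applied before tessellation to
# break exactly-degenerate (cocircular) vertex configurations.  Keyed to
# the site index; never applied to user-facing coordinates.
_DEGENERACY_EPS_PX = 1e-9


def _hpi_f6_minus_f4_f8(fractions: Mapping[int, float]) -> float:
    return fractions[6] - fractions[4] - fractions[8]


HPI_FORMULAS: dict[str, Callable[[Mapping[int, float]], float]] = {
    "f6-f4-f8": _hpi_f6_minus_f4_f8,
}


@dataclass
class RoiSpec:
    """Rectangular region of interest for the tessellation.

    The image of ``width_px x height_px`` pixels, with the origin at the
    top-left pixel *center*, spans the rectangle
    ``[-0.5, width-0.5] x [-0.5, height-0.5]`` in pixel units; a cell is
    interior when its polygon lies strictly inside that rectangle.
    """

    width_px: int = 200
    height_px: int = 200
    um_per_px: float = 1.445
    eccentricity_deg: float | None = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("ROI dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the ROI rectangle, pixel units."""
        return (-0.5, self.width_px - 0.5, -0.5, self.height_px - 0.5)


@dataclass
class VoronoiCell:
    site: tuple[float, float]
    polygon: np.ndarray | None  # ordered (k, 2) vertex array; None if unbounded
    neighbor_count: int
    is_interior: bool


@dataclass
class PackingMetrics:
    """Neighbor-count spectrum and heterogeneity packing index of a mosaic.

    ``counts_by_neighbors`` maps k in {3, 4, 5, 6, 7, 8} plus the >= 9
    bucket (key 9) to interior-cell counts; ``fractions`` are the counts
    normalized by ``n_interior``.  3-sided and >= 9-sided cells appear in
    the spectrum but never in the HPi formula.
    """

    n_interior: int
    counts_by_neighbors: dict[int, int]
    fractions: dict[int, float]
    hpi: float
    formula: str = "f6-f4-f8"

    @property
    def mean_neighbor_count(self) -> float:
        total = sum(k * c for k, c in self._raw_counts.items())
        return total / self.n_interior

    # exact per-cell counts (>= 9 kept individually) for the mean
    _raw_counts: dict[int, int] = field(default_factory=dict, repr=False)


def tessellate(
    points: ConePointSet | np.ndarray,
    roi: RoiSpec | None = None,
) -> list[VoronoiCell]:
    """Voronoi-tessellate cone centers and classify each cell.

    One cell per site, in site order.  Two cells are neighbors when they
    share a Voronoi edge of positive length (vertex-only contact does
    not count; edges of unbounded cells count).  Cells that are
    unbounded or whose polygon is not strictly inside the ROI rectangle
    are flagged ``is_interior=False``.

    Raises ``ValueError`` for fewer than 4 sites or an all-collinear
    configuration (degenerate tessellation).
    """
    if isinstance(points, ConePointSet):
        pts = points.points
        if roi is None:
            roi = RoiSpec(points.roi_width_px, points.roi_height_px,
                          points.um_per_px)
    else:
        pts = np.asarray(points, dtype=float)
        if roi is None:
            raise ValueError("an RoiSpec is required for bare coordinate arrays")
    if len(pts) < 4:
        raise ValueError("tessellation needs at least 4 points")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate tessellation: all points are collinear")

    # deterministic degeneracy-breaking perturbation (<= 1e-9 px)
    idx = np.arange(len(pts), dtype=np.uint64)
    h1 = (idx * np.uint64(2654435761)) % np.uint64(2**32)
    h2 = (idx * np.uint64(2246822519) + np.uint64(97)) % np.uint64(2**32)
    jit = np.column_stack([h1, h2]).astype(float) / 2**32 - 0.5
    work = pts + _DEGENERACY_EPS_PX * jit

    try:
        vor = Voronoi(work)
    except QhullError as exc:
        raise ValueError(
            "degenerate tessellation (points collinear or coincident)"
        ) from exc

    n = len(pts)
    neighbor_sets: list[set[int]] = [set() for _ in range(n)]
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in verts:
            positive = True  # unbounded ridge: infinite length
        else:
            a, b = vor.vertices[verts[0]], vor.vertices[verts[1]]
            positive = float(np.hypot(*(a - b))) > 1e-9
        if positive:
            neighbor_sets[p].add(q)
            neighbor_sets[q].add(p)

    xmin, xmax, ymin, ymax = roi.bounds
    cells: list[VoronoiCell] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        bounded = len(region) >= 3 and -1 not in region
        polygon = None
        interior = False
        if bounded:
            polygon = vor.vertices[region]
            interior = bool(
                (polygon[:, 0] > xmin).all()
                and (polygon[:, 0] < xmax).all()
                and (polygon[:, 1] > ymin).all()
                and (polygon[:, 1] < ymax).all()
            )
        cells.append(
            VoronoiCell(
                site=(float(pts[i, 0]), float(pts[i, 1])),
                polygon=polygon,
                neighbor_count=len(neighbor_sets[i]),
                is_interior=interior,
            )
        )
    return cells


def packing_metrics(
    cells: Sequence[VoronoiCell],
    hpi_formula: str = "f6-f4-f8",
) -> PackingMetrics:
    """Neighbor-count spectrum and HPi over the interior cells.

    Raises ``ValueError`` when no cell is interior (enlarge the ROI or
    densify the mosaic).
    """
    interior = [c for c in cells if c.is_interior]
    if not interior:
        raise ValueError(
            "no interior Voronoi cells: every cell touches the ROI boundary; "
            "use a larger ROI or a denser mosaic"
        )
    n = len(interior)
    raw: dict[int, int] = {}
    for c in interior:
        raw[c.neighbor_count] = raw.get(c.neighbor_count, 0) + 1
    counts = {k: 0 for k in (3, 4, 5, 6, 7, 8, MANY)}
    for k, c in raw.items():
        counts[min(k, MANY)] += c
    fractions = {k: c / n for k, c in counts.items()}
    try:
        formula = HPI_FORMULAS[hpi_formula]
    except KeyError:
        raise ValueError(
            f"unknown HPi formula {hpi_formula!r}; known: {sorted(HPI_FORMULAS)}"
        ) from None
    metrics = PackingMetrics(
        n_interior=n,
        counts_by_neighbors=counts,
        fractions=fractions,
        hpi=float(formula(fractions)),
        formula=hpi_formula,
    )
    metrics._raw_counts = raw
    return metrics


def hpi_vs_disorder_curve(
    base: SyntheticMosaicConfig,
    jitter_grid: Iterable[float],
    dropout_grid: Iterable[float],
    n_seeds: int,
    hpi_formula: str = "f6-f4-f8",
):
    """Mean and SD of HPi over seeds for each (jitter, dropout) pair.

    Seeds are ``base.seed + k`` for k in range(n_seeds).  Returns a
    pandas DataFrame with columns jitter_sd_frac, dropout_frac,
    hpi_mean, hpi_sd, n_seeds.
    """
    import dataclasses

    import pandas as pd

    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    rows = []
    for jit in jitter_grid:
        for drop in dropout_grid:
            vals = []
            for k in range(n_seeds):
                cfg = dataclasses.replace(
                    base, jitter_sd_frac=float(jit), dropout_frac=float(drop),
                    seed=base.seed + k,
                )
                cells = tessellate(generate_mosaic_points(cfg))
                vals.append(packing_metrics(cells, hpi_formula).hpi)
            rows.append(
                {
                    "jitter_sd_frac": float(jit),
                    "dropout_frac": float(drop),
                    "hpi_mean": float(np.mean(vals)),
                    "hpi_sd": float(np.std(vals, ddof=1)),
                    "n_seeds": n_seeds,
                }
            )
    return pd.DataFrame(rows)


def render_tessellation(
    cells: Sequence[VoronoiCell],
    roi: RoiSpec,
    path=None,
    dpi: int = 150,
):
    """Draw the tessellation with cells shaded by neighbor count, dark
    (four neighbors) to light (eight neighbors); non-interior cells are
    left unshaded.  Returns the matplotlib figure; saves to ``path`` if
    given."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    fig, ax = plt.subplots(figsize=(5, 5), dpi=dpi)
    for cell in cells:
        if cell.polygon is None:
            continue
        if cell.is_interior:
            shade = np.clip((cell.neighbor_count - 4) / 4.0, 0.0, 1.0)
            color = (0.15 + 0.75 * shade,) * 3
        else:
            color = (1.0, 1.0, 1.0)
        ax.add_patch(
            MplPolygon(cell.polygon, closed=True, facecolor=color,
                       edgecolor="black", linewidth=0.4)
        )
    sites = np.array([c.site for c in cells])
    ax.plot(sites[:, 0], sites[:, 1], ".", color="tab:red", markersize=1.5)
    xmin, xmax, ymin, ymax = roi.bounds
    ax.set_xlim(xmin, xmax)
    ax.set_ylim(ymax, ymin)  # image convention: y downward
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
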