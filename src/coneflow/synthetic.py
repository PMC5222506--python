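"""Ground-truthed synthetic inputs for the whole pipeline.

Three generators, each a pure function of ``(config, seed)``:

* jittered triangular-lattice cone mosaics rendered as Gaussian spots
  (emulating averaged 1-degree adaptive-optics frames of the parafoveal
  cone mosaic, ~2-3 degrees of eccentricity);
* vessel-network-like binary angiograms with planted circular non-flow
  lesions of known diameter (emulating 3x3 mm en-face deep-plexus
  angiograms centered on the fovea);
* cohort tables with two groups (normal deep-plexus perfusion vs.
  non-flow) whose packing-index and vessel-density distributions follow
  configured normal laws.

The triangular lattice is the disorder-free reference: its Voronoi cells
are all hexagons, so the heterogeneity packing index of an unperturbed
mosaic is exactly 1.  Positional jitter and cone dropout are the two
disorder axes the downstream metrics must respond to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .points import ConePointSet

__all__ = [
    "SyntheticMosaicConfig",
    "SyntheticAngioConfig",
    "CohortSimConfig",
    "generate_mosaic",
    "generate_mosaic_points",
    "generate_angiogram",
    "generate_cohort",
    "lattice_sites",
]

# 289 um per degree of visual angle (16.7 mm focal length) over 200 px
# per degree gives 1.445 um/px for the mosaic images.
DEFAULT_UM_PER_PX_MOSAIC = 1.445


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class SyntheticMosaicConfig:
    """Parameters of the jittered-lattice cone-mosaic generator.

    Lengths are micrometers; ``jitter_sd_frac`` is the SD of isotropic
    positional noise as a fraction of the lattice spacing;
    ``dropout_frac`` is the probability of uniform cone deletion;
    ``lesion_dropouts`` lists (center_x_um, center_y_um, radius_um,
    dropout_prob) discs of clustered deletion.  Intensities are on the
    0-255 scale.
    """

    roi_width_px: int = 200
    roi_height_px: int = 200
    um_per_px: float = DEFAULT_UM_PER_PX_MOSAIC
    lattice_spacing_um: float = 8.0
    jitter_sd_frac: float = 0.05
    dropout_frac: float = 0.0
    lesion_dropouts: list[tuple[float, float, float, float]] = field(
        default_factory=list
    )
    spot_sigma_um: float = 2.0
    amplitude_mean: float = 150.0
    amplitude_cv: float = 0.10
    background_level: float = 20.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.roi_width_px > 0 and self.roi_height_px > 0,
                 "ROI dimensions must be positive")
        _require(self.um_per_px > 0, "um_per_px must be positive")
        _require(self.lattice_spacing_um > 0, "lattice spacing must be positive")
        _require(self.spot_sigma_um > 0, "spot sigma must be positive")
        _require(0 <= self.jitter_sd_frac, "jitter_sd_frac must be >= 0")
        _require(0 <= self.dropout_frac <= 1, "dropout_frac must be in [0, 1]")
        for les in self.lesion_dropouts:
            _require(len(les) == 4, "lesion = (cx_um, cy_um, radius_um, prob)")
            _require(les[2] > 0, "lesion radius must be positive")
            _require(0 <= les[3] <= 1, "lesion dropout prob must be in [0, 1]")
        _require(self.amplitude_cv >= 0 and self.noise_sd >= 0,
                 "amplitude_cv and noise_sd must be >= 0")
        spacing_px = self.lattice_spacing_um / self.um_per_px
        if spacing_px < 2.0:
            raise ValueError(
                f"lattice spacing of {spacing_px:.2f} px is unresolvable "
                "(< 2 px); increase spacing or decrease um_per_px"
            )


def lattice_sites(config: SyntheticMosaicConfig) -> np.ndarray:
    """Triangular-lattice site coordinates inside the ROI, in pixels.

    Rows are spaced ``spacing * sqrt(3)/2`` apart with alternate rows
    offset by half a spacing; the lattice is anchored half a spacing in
    from the origin.  A site is kept when its center lies within the
    full image extent ``[-0.5, width-0.5] x [-0.5, height-0.5]`` (pixel
    centers at integers): with this rule any lattice site missing at the
    image edge leaves its surrounding Voronoi cells provably crossing
    the region boundary, so a disorder-free lattice has exclusively
    six-sided interior cells.
    """
    spacing_px = config.lattice_spacing_um / config.um_per_px
    row_h = spacing_px * math.sqrt(3.0) / 2.0
    w, h = config.roi_width_px, config.roi_height_px
    pts = []
    j = 0
    y = row_h / 2.0
    while y <= h - 0.5:
        x0 = spacing_px / 2.0 + (spacing_px / 2.0 if j % 2 else 0.0)
        i_min = int(math.ceil((-0.5 - x0) / spacing_px))
        i_max = int(math.floor((w - 0.5 - x0) / spacing_px))
        if i_max >= i_min:
            xs = x0 + spacing_px * np.arange(i_min, i_max + 1)
            pts.append(np.column_stack([xs, np.full(xs.size, y)]))
        j += 1
        y = row_h / 2.0 + j * row_h
    if not pts:
        return np.empty((0, 2))
    return np.vstack(pts)


def generate_mosaic_points(config: SyntheticMosaicConfig) -> ConePointSet:
    """Ground-truth cone centers only (no rendering): lattice -> jitter ->
    clamp to ROI -> uniform dropout -> clustered (lesion) dropout."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pts = lattice_sites(config)
    spacing_px = config.lattice_spacing_um / config.um_per_px

    if config.jitter_sd_frac > 0 and len(pts):
        pts = pts + rng.normal(0.0, config.jitter_sd_frac * spacing_px, pts.shape)
        # clamp rather than drop so the dropout bookkeeping stays exact;
        # affected sites sit on the ROI edge, outside the interior metrics
        pts[:, 0] = np.clip(pts[:, 0], -0.5, config.roi_width_px - 0.5)
        pts[:, 1] = np.clip(pts[:, 1], -0.5, config.roi_height_px - 0.5)

    if config.dropout_frac > 0 and len(pts):
        keep = rng.random(len(pts)) >= config.dropout_frac
        pts = pts[keep]

    for cx_um, cy_um, radius_um, prob in config.lesion_dropouts:
        if not len(pts):
            break
        center_px = np.array([cx_um, cy_um]) / config.um_per_px
        r_px = radius_um / config.um_per_px
        inside = np.hypot(*(pts - center_px).T) <= r_px
        drop = inside & (rng.random(len(pts)) < prob)
        pts = pts[~drop]

    return ConePointSet(
        points=pts,
        roi_width_px=config.roi_width_px,
        roi_height_px=config.roi_height_px,
        um_per_px=config.um_per_px,
    )


def _render(points: ConePointSet, config: SyntheticMosaicConfig,
            rng: np.random.Generator) -> np.ndarray:
    h, w = config.roi_height_px, config.roi_width_px
    img = np.zeros((h, w), dtype=float)
    sigma_px = config.spot_sigma_um / config.um_per_px
    rad = int(math.ceil(4.0 * sigma_px))
    amps = config.amplitude_mean * (
        1.0 + config.amplitude_cv * rng.standard_normal(len(points))
    )
    amps = np.clip(amps, 0.0, None)
    for (x, y), a in zip(points.points, amps):
        c0, c1 = max(0, int(x) - rad), min(w, int(x) + rad + 1)
        r0, r1 = max(0, int(y) - rad), min(h, int(y) + rad + 1)
        xx = np.arange(c0, c1) - x
        yy = np.arange(r0, r1) - y
        img[r0:r1, c0:c1] += a * np.outer(
            np.exp(-yy**2 / (2 * sigma_px**2)),
            np.exp(-xx**2 / (2 * sigma_px**2)),
        )
    img += config.background_level
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, img.shape)
    np.clip(img, 0.0, 255.0, out=img)
    return img


def generate_mosaic(
    config: SyntheticMosaicConfig,
) -> tuple[ConePointSet, np.ndarray]:
    """Generate a cone mosaic: exact ground-truth centers plus a rendered
    grayscale image (sum of Gaussian spots + background + noise, clipped
    to [0, 255]).  Bit-identical for identical config and seed."""
    points = generate_mosaic_points(config)
    # second, independent stream for intensities so the point geometry is
    # unchanged by rendering parameters
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    image = _render(points, config, rng)
    return points, image


@dataclass
class SyntheticAngioConfig:
    """Parameters of the binary-angiogram generator.

    The vessel pattern is a thresholded smoothed Gaussian noise field
    whose threshold is chosen so the vessel fraction inside the default
    parafoveal annulus (1 mm inner / 3 mm outer diameter, image center)
    matches ``target_density_pct`` before lesion carving.
    ``lesion_specs`` lists (center_x_um, center_y_um, diameter_um)
    circular non-flow lesions carved to zero after thresholding.
    """

    image_size_px: int = 304
    um_per_px: float = 10.0
    target_density_pct: float = 55.0
    texture_scale_um: float = 25.0
    lesion_specs: list[tuple[float, float, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        _require(self.image_size_px > 0, "image_size_px must be positive")
        _require(self.um_per_px > 0, "um_per_px must be positive")
        _require(0 <= self.target_density_pct <= 100,
                 "target_density_pct must be in [0, 100]")
        _require(self.texture_scale_um > 0, "texture_scale_um must be positive")
        if self.lesion_specs and self.target_density_pct in (0.0, 100.0):
            raise ValueError(
                "lesions are undetectable against an empty/full field "
                "(target_density_pct of 0 or 100); use carve_lesion directly "
                "to plant lesions in a constant mask"
            )
        span_um = (self.image_size_px - 1) * self.um_per_px
        for cx, cy, diam in self.lesion_specs:
            _require(diam > 0, "lesion diameter must be positive")
            r = diam / 2.0
            _require(
                cx - r >= 0 and cy - r >= 0 and cx + r <= span_um and cy + r <= span_um,
                f"lesion at ({cx}, {cy}) um, diameter {diam} um, does not lie "
                "fully inside the image",
            )


def carve_lesion(mask: np.ndarray, center_x_um: float, center_y_um: float,
                 diameter_um: float, um_per_px: float) -> np.ndarray:
    """Zero all pixels whose centers fall inside the lesion disc.

    Idempotent: carving the same lesion twice yields the same mask.
    """
    s = mask.shape
    yy, xx = np.mgrid[0:s[0], 0:s[1]].astype(float)
    r_px = (diameter_um / 2.0) / um_per_px
    cx_px, cy_px = center_x_um / um_per_px, center_y_um / um_per_px
    inside = (xx - cx_px) ** 2 + (yy - cy_px) ** 2 <= r_px**2
    out = mask.copy()
    out[inside] = False
    return out


def generate_angiogram(
    config: SyntheticAngioConfig,
) -> tuple[np.ndarray, list[dict]]:
    """Generate a binary perfusion mask plus planted-lesion records.

    Returns (mask, lesions) where mask is a boolean array (True =
    vessel) and each lesion record carries the planted geometry and the
    number of pixels carved.
    """
    config.validate()
    # import here to avoid a cycle: angio also consumes synthetic outputs
    from .angio import AnnulusSpec, annulus_membership

    rng = np.random.default_rng(config.seed)
    s = config.image_size_px
    if config.target_density_pct >= 100.0:
        mask = np.ones((s, s), dtype=bool)
    elif config.target_density_pct <= 0.0:
        mask = np.zeros((s, s), dtype=bool)
    else:
        from scipy.ndimage import gaussian_filter

        field_ = gaussian_filter(
            rng.standard_normal((s, s)), config.texture_scale_um / config.um_per_px
        )
        center = ((s - 1) / 2.0, (s - 1) / 2.0)
        annulus = AnnulusSpec(center=center)
        outer_r_px = annulus.outer_diameter_um / 2.0 / config.um_per_px
        if outer_r_px > (s - 1) / 2.0 + 0.5:
            # small fields: calibrate density over the whole frame instead
            in_ann = np.ones((s, s), dtype=bool)
        else:
            in_ann = annulus_membership((s, s), annulus, config.um_per_px)
        thr = np.quantile(field_[in_ann], 1.0 - config.target_density_pct / 100.0)
        mask = field_ >= thr

    lesions: list[dict] = []
    for cx, cy, diam in config.lesion_specs:
        before = int(mask.sum())
        mask = carve_lesion(mask, cx, cy, diam, config.um_per_px)
        lesions.append(
            {
                "center_x_um": cx,
                "center_y_um": cy,
                "diameter_um": diam,
                "carved_px": before - int(mask.sum()),
            }
        )
    return mask, lesions


@dataclass
class CohortSimConfig:
    """Two-group cohort simulator (normal perfusion vs. non-flow).

    Group-wise packing-index and vessel-density values are drawn from
    normal distributions with the configured means and SDs; the defaults
    are the published group summaries of the study cohort this package
    models (densities in percent).  ``missing_density_count`` eyes of
    the non-flow group get an empty density cell, mirroring an eye
    imaged without angiography.
    """

    n_normal: int = 3
    n_nonflow: int = 8
    hpi_mean_normal: float = 0.431
    hpi_sd_normal: float = 0.002
    hpi_mean_nonflow: float = 0.358
    hpi_sd_nonflow: float = 0.013
    density_mean_normal: float = 60.14
    density_sd_normal: float = 2.91
    density_mean_nonflow: float = 50.21
    density_sd_nonflow: float = 5.21
    missing_density_count: int = 1
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_normal >= 2 and self.n_nonflow >= 2,
                 "need n >= 2 per group for statistics")
        for sd in (self.hpi_sd_normal, self.hpi_sd_nonflow,
                   self.density_sd_normal, self.density_sd_nonflow):
            _require(sd >= 0, "SDs must be >= 0")
        _require(0 <= self.missing_density_count <= self.n_nonflow,
                 "missing_density_count must be within the non-flow group")


def generate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate a cohort table in the study's per-eye schema.

    One row per eye; clinical covariates (age, diabetes duration, HbA1c,
    ...) are drawn from broad, group-independent distributions since the
    generator's contract concerns only the packing-index / density
    distributions and the missing-cell bookkeeping.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_normal + config.n_nonflow
    groups = ["normal_dcp"] * config.n_normal + ["dcp_nonflow"] * config.n_nonflow

    hpi = np.concatenate(
        [
            rng.normal(config.hpi_mean_normal, config.hpi_sd_normal, config.n_normal),
            rng.normal(config.hpi_mean_nonflow, config.hpi_sd_nonflow,
                       config.n_nonflow),
        ]
    )
    dens = np.concatenate(
        [
            rng.normal(config.density_mean_normal, config.density_sd_normal,
                       config.n_normal),
            rng.normal(config.density_mean_nonflow, config.density_sd_nonflow,
                       config.n_nonflow),
        ]
    )
    if config.missing_density_count:
        miss = n - 1 - np.arange(config.missing_density_count)
        dens[miss] = np.nan

    table = pd.DataFrame(
        {
            "case_id": np.arange(1, n + 1),
            "sex": rng.choice(["M", "F"], n),
            "age_y": np.round(rng.normal(45.0, 12.0, n)).clip(18, 85).astype(int),
            "dm_type": rng.choice([1, 2], n),
            "duration_y": np.round(rng.gamma(2.0, 6.0, n)).clip(1, 40).astype(int),
            "hba1c_pct": np.round(rng.normal(8.0, 1.5, n).clip(5.0, 14.0), 1),
            "study_eye": rng.choice(["Right", "Left"], n),
            "bcva": "20/20",
            "dr_stage": rng.choice(["NPDR", "PDR"], n),
            "laser": "None",
            "medication": "Insulin",
            "dcp_density_pct": dens,
            "hpi": hpi,
            "group": groups,
        }
    )
    return table
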