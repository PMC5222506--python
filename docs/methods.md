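# Methods

## The scientific setting

Cone photoreceptors in a healthy parafovea pack in a near-hexagonal
mosaic; on AOSLO images they appear as bright, roughly equally spaced
spots.  The deep capillary plexus (DCP) supplies part of the outer
retina's oxygen demand, and capillary non-perfusion ("non-flow") at
the DCP is suspected to disturb the overlying cone mosaic.  The
package quantifies both sides of this relationship: mosaic regularity
from cone coordinates, perfusion metrics from en-face angiogram masks,
and the group/correlation statistics that tie them together in a small
two-group cohort (eyes with vs. without DCP non-flow).

## Coordinate and unit conventions

Pixel coordinates are 0-based with the origin at the *center* of the
top-left pixel, x rightward, y downward.  An image of `W x H` pixels
therefore covers the rectangle `[-0.5, W-0.5] x [-0.5, H-0.5]`; points
are valid anywhere in this extent.  All physical quantities derive
from an explicit `um_per_px` scale.  The default mosaic scale, 1.445
µm/px, corresponds to 289 µm of retina per degree of visual angle
(16.7 mm focal length) imaged at 200 px per degree; it is configurable
everywhere.

## Voronoi packing metrics

`tessellate` wraps a standard Voronoi construction and classifies each
cell:

- **Neighbors** — two cells are neighbors when they share a Voronoi
  edge of positive length; vertex-only contact does not count; edges of
  unbounded cells count.  Exactly degenerate (cocircular) vertex
  configurations are broken by a deterministic perturbation of at most
  1e-9 px keyed to the site index, never applied to user-facing
  coordinates.
- **Interior** — a cell is interior when it is bounded and its polygon
  lies strictly inside the ROI rectangle.  All metrics use interior
  cells only, the standard guard against boundary-truncation bias.
  Fewer than 4 sites, or all-collinear sites, are rejected as a
  degenerate tessellation.

`packing_metrics` reports the neighbor-count spectrum (buckets 3–8 and
"9 or more") and the heterogeneity packing index

    HPi = f6 − f4 − f8

over interior cells, where `f_k` is the interior fraction with `k`
neighbors.  The index is 1 exactly when every interior cell is
six-sided, is bounded in [−1, 1], and decreases as 4- and 8-sided
cells appear.  Published descriptions of packing-index variants are
qualitative, so the formula is registered under a name
(`"f6-f4-f8"`) and is replaceable without touching the tessellation;
the cohort-level statistics operate on tabulated per-eye HPi values
and are independent of this choice.  3-sided and ≥9-sided cells count
in the spectrum but not in the formula.

A planar-graph fact anchors the scale: for a large random mosaic the
mean interior neighbor count approaches 6 (asserted within ±0.15 in
the tests), so HPi measures the *spread* of the spectrum around 6, not
its mean.

## Synthetic data: what it emulates, what it does not

The generators provide ground truth for every downstream stage; their
defaults describe the study conditions the package models.

**Mosaics.**  A triangular (hexagonal-packing) lattice is the
disorder-free reference, spacing 8 µm (parafoveal cone spacing at 2–3°
eccentricity) in a 200×200 px ROI at 1.445 µm/px.  Disorder enters on
two axes: isotropic Gaussian positional jitter (SD as a fraction of
spacing; default 0.05) and cone deletion, either uniform (probability
`dropout_frac`) or clustered inside lesion discs.  Jittered
coordinates are clamped to the image extent so dropout bookkeeping
stays exact; clamping affects only edge sites, which interior metrics
exclude.  Lattice sites are kept when their centers lie in the full
image extent; this makes the disorder-free mosaic's interior cells
exclusively six-sided (a missing edge neighbor places a Voronoi vertex
exactly at the missing-site position, outside the extent, so edge
cells are excluded rather than miscounted).  Rendering sums Gaussian
spots (SD 2 µm; per-cone amplitude 150 with CV 0.10 on a 0–255 scale)
over a background of 20, adds Gaussian read noise (SD 5) and clips to
[0, 255].  Point geometry and intensities use independent random
streams, so rendering parameters never perturb the ground-truth
coordinates.  Not emulated: eye-motion distortion, optical blur
anisotropy, photon (Poisson) noise — there is no photon-count
calibration to anchor it — rods, or reflectance fluctuation over time.
Passing tests therefore certify the geometry/metrics pipeline, not
detector robustness on clinical images.

**Angiograms.**  The vessel pattern is smoothed Gaussian noise
(correlation length 25 µm) thresholded at the quantile that yields the
target vessel fraction inside the default parafoveal annulus
(realized densities land well within ±2 percentage points of the
target).  Planted lesions are circular discs carved to zero after
thresholding (idempotent), with exact diameters recorded.  The default
field is 304 px at 10 µm/px, a 3 mm-class en-face slab in which the
3 mm annulus just fits.  The texture is *not* a vascular network —
no connectivity, branching or capillary-scale morphology — the
generator's contract is only the calibrated annulus density and the
carved lesions.
A degenerate target (0% or 100%) with lesions requested is rejected;
`carve_lesion` can plant lesions into explicit masks directly.

**Cohorts.**  Per-eye packing-index and vessel-density values are
drawn from group-wise normal distributions; the defaults are the
published group summaries of the 11-eye study cohort (normal
perfusion: HPi 0.431 ± 0.002, density 60.14 ± 2.91%; non-flow: HPi
0.358 ± 0.013, density 50.21 ± 5.21%), with one missing density cell
in the non-flow group mirroring the eye imaged without OCTA.  (The
published non-flow HPi dispersion matches the standard error of the
per-case values rather than their SD; the generator takes the printed
number at face value as a narrow-dispersion condition.)  Clinical
covariates are drawn from broad group-independent distributions and
carry no signal.

## Cone detection

Gaussian pre-smoothing (default SD 2 µm ≈ 0.25× expected spacing — a
matched filter for cone-sized spots; markedly stronger smoothing
merges the maxima of hexagonally packed neighbors), 3×3 local maxima
above an intensity-quantile floor (default 0.1), greedy acceptance in
decreasing-intensity order subject to a minimum separation (default
4 µm = 0.5× spacing; ties broken toward smaller (y, x)), then per-axis
quadratic sub-pixel refinement clamped to ±0.5 px.  A constant image
yields an empty point set.  Scoring matches detections to ground truth
one-to-one, closest pairs first, within a tolerance (default 3 µm).
On the low-noise synthetic reference (jitter 0.05, no dropout, noise
5% of spot amplitude) the defaults give precision 1.00 and recall
0.97 at 3 µm.  Manual correction is supported by editing the
coordinate CSV and feeding it back in place of detections.

## Angiographic metrics

Vessel density is the percentage of vessel pixels whose centers fall
inside the region (no partial-pixel weighting), with the parafovea as
the default region: annulus of 1 mm inner and 3 mm outer diameter
centered on the fovea.  Non-flow detection labels the non-vessel
complement with 8-connectivity, discards components touching the image
border (field-of-view edges, not lesions), and keeps components whose
equivalent-circle diameter `2*sqrt(area/pi)` exceeds the threshold
(default 100 µm), sorted by area.  "Diameter" of an irregular region
is deliberately the equivalent-circle diameter; maximum-inscribed-
circle or Feret definitions would need only a strategy swap in
`detect_nonflow`.  Grayscale inputs can be binarized by fixed
threshold, Otsu, or local-mean adaptive threshold; already-binary
inputs pass through unchanged, and Otsu on a constant image is
rejected with a pointer to the fixed method.  Because clinical
angiography binarization is proprietary, tabulated per-eye densities
are treated as given inputs and never recomputed from images.

## Cohort statistics

Group summaries use sample SD (n−1); missing values are dropped per
variable (the packaged table's non-flow group has n=7 for density,
n=8 for HPi).  Group comparisons use the pooled-variance Student t
with df = n1+n2−2 — on the packaged table this reproduces both
published p-values (0.016 density, 0.013 HPi), which Welch's variant
does not; Welch remains available via `equal_var=False`.  The Spearman
correlation uses average ranks for ties and a two-tailed p from the
t-approximation `t = r*sqrt((n−2)/(1−r²))`; an exact permutation p
(all n! orderings) is available for n ≤ 10.  `reproduce_table1`
recomputes every published summary and compares at the printed
precision (a mismatch is flagged, not silently tolerated).  Two known
inconsistencies in the published table are documented rather than
targeted: the non-flow HPi dispersion cell (SE, not SD) and the
narrative mean age (43.3; the per-case mean is 43.0 — the expected
values store the median, 43).

## Display enhancement

`enhance_for_display` brightens (×1.22), contrast-stretches
(deviations from the mean ×1.11) and sharpens (unsharp mask, amount
0.37, radius 2 px) in that order, clipping at the end.  The operators
are multiplicative readings of "increase by N%".  The function exists
for figure preparation only and is quarantined from every quantitative
path.

## Problem sizes and numerical choices

Test and acceptance runs use 200×200 px mosaics (≈1500 cones),
304×304 px angiograms, 20-seed Monte-Carlo sweeps for monotonicity
checks and 50 random instances (n ≤ 100) for the brute-force Voronoi
adjacency oracle — sizes chosen so the full suite completes in about a
minute while keeping every Monte-Carlo margin (3 SE bounds, ±0.15 on
the mean neighbor count) comfortably resolved.  Determinism is a
contract throughout: generators are pure functions of (config, seed),
detection and tessellation are deterministic, and pipeline reports are
byte-identical across repeated runs on the same inputs.

## Known limitations

- The HPi formula is one member of a family; only the tessellation and
  spectrum are formula-independent.
- The detector is tuned for bright-spot mosaics with a known expected
  spacing; it has no rod/cone discrimination and no handling of
  montage seams or reflectance dropout beyond what the threshold
  quantile absorbs.
- The synthetic angiogram is statistically, not morphologically,
  vessel-like; algorithms sensitive to vessel topology should not be
  validated against it.
- Cohort-level conclusions from the packaged table inherit its tiny
  sample (11 eyes, one missing density).
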