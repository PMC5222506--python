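# coneflow

Quantitative tools linking **cone photoreceptor mosaic regularity** to
**retinal capillary perfusion**, for researchers working with adaptive
optics scanning laser ophthalmoscopy (AOSLO) and OCT angiography
(OCTA) in diabetic retinopathy and related ischemic maculopathies.

The package implements, end to end:

- **Cone detection** — smoothed local-maxima spot detection with
  sub-pixel refinement, plus precision/recall scoring against ground
  truth and a CSV round-trip for manual correction of detections.
- **Voronoi packing metrics** — tessellation of cone centers, the
  neighbor-count spectrum `f_k` over interior cells, and the
  *heterogeneity packing index*

  ```
  HPi = f6 − f4 − f8
  ```

  which is 1 for a perfectly hexagonal mosaic and decreases as 4- and
  8-sided Voronoi cells appear at the expense of 6-sided ones (the
  formula is a named, replaceable strategy).
- **Angiographic metrics** — parafoveal vessel density (percentage of
  vessel pixels in the 1 mm / 3 mm annulus centered on the fovea) and
  detection of *non-flow regions*: avascular connected components with
  equivalent-circle diameter above 100 µm.
- **Cohort statistics** — per-group summaries, pooled two-sample
  t-tests and the Spearman rank correlation between HPi and deep
  capillary plexus (DCP) vessel density, with a packaged 11-eye
  per-case study table.
- **Synthetic data** — ground-truthed generators for jittered
  hexagonal cone mosaics (rendered as Gaussian-spot images), binary
  angiograms with planted circular non-flow lesions, and two-group
  cohort tables; every generator is a pure function of its config and
  seed.

## Worked example

```python
from coneflow import (SyntheticMosaicConfig, generate_mosaic,
                      detect_cones, DetectionParams,
                      score_detections, tessellate, packing_metrics)

cfg = SyntheticMosaicConfig(jitter_sd_frac=0.05, seed=1)   # 200x200 px, 1.445 um/px
truth, image = generate_mosaic(cfg)
detected = detect_cones(image, DetectionParams(), cfg.um_per_px)
print(score_detections(detected, truth, tol_um=3.0))
metrics = packing_metrics(tessellate(detected))
print(metrics.hpi, metrics.n_interior)
```

prints

```
DetectionScore(n_true=1533, n_detected=1490, n_matched=1490,
               precision=1.0, recall=0.972,
               mean_localization_error_um=0.445)
0.894 1341
```

i.e. on a lightly jittered synthetic mosaic of 1533 cones the detector
recovers 97% of them within 3 µm with no false detections, and the
detected mosaic's packing index is 0.894 over 1341 interior Voronoi
cells — close to the perfect
lattice's 1.0, far above heavily disordered mosaics (≈0.3, see
`examples/01_mosaic_hpi.py`).

The other example scripts cover the angiogram metrics
(`02_angiogram_metrics.py`), the packaged cohort statistics
(`03_cohort_statistics.py`) and the HPi-versus-disorder response
surface (`04_disorder_curve.py`).

A thin CLI mirrors the library:

```
coneflow simulate-mosaic --out-image m.tif --out-csv truth.csv --seed 1
coneflow detect-cones --image m.tif --out-csv detected.csv
coneflow voronoi-metrics --points detected.csv --render cells.png
coneflow vessel-density --mask angio.tif --um-per-px 10
coneflow reproduce-table1
```

## Layout

```
src/coneflow/      library (synthetic, detection, geometry, angio,
                   cohort, enhance, pipeline, cli)
src/coneflow/data/ packaged per-case study table + expected summaries
examples/          narrative scripts, one per capability
tests/             pytest suite incl. brute-force oracles
docs/methods.md    models, conventions, parameter choices, limitations
```
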