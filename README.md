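# phenorow

Computational phenotyping of spaced-plant field trials from multispectral
drone imagery and ground-vehicle ultrasonic height tracks.

Perennial ryegrass breeding programmes evaluate tens of thousands of
individually spaced plants, and destructive harvests or visual scores do
not scale. `phenorow` turns a georeferenced ortho-mosaic of such a trial
plus an RTK-logged ultrasonic sensor track into per-plant NDVI, plant
height and predicted dry-matter yield (DMY), then aggregates predictions
to plot level and validates them against measured harvests. A synthetic
trial generator with complete ground truth makes every stage testable
without any real imagery.

## The method

Given a multiband ortho-mosaic with red and near-infrared bands:

1. **Empirical-line calibration.** Reflectance panels of known
   reflectance (6, 11, 22, 33 %) calibrate each band by ordinary least
   squares, `reflectance = gain · DN + offset`, and
   `NDVI = (NIR − Red)/(NIR + Red)`.
2. **Perspective rectification.** Four corner ground-control points
   bound the trial; the enclosed quadrilateral is cropped and rotated
   upright so blocks and plant rows align with the image axes.
3. **Block and row segmentation by projection profiles.** Summing pixels
   along one axis gives a 1-D profile; a grayscale opening (line
   structuring element of length *feature*/2) followed by an erosion
   (length *feature*/3) and regional-minima extraction locates the
   bare-soil troughs that separate blocks (feature = expected row
   length) and then rows within each block (feature = expected plant
   width). Trough edges give deliberately under-estimated row boxes.
4. **Box growing.** The gap between vertically adjacent boxes is scanned
   from both ends, granting the brighter end row to its box until the
   remaining gap mass falls below the mean background intensity scaled
   by the remaining rows — recovering plants the erosion cut off.
5. **Plant counting by template matching.** A mean-of-samples template
   (20×20 px window, 4 px context ring) is swept over the image with
   zero-normalised cross-correlation; local maxima scoring ≥ 0.6 survive
   a 3 px non-maximum suppression, centres outside row boxes are
   discarded, and file-driven manual edits are applied.
6. **Per-plant polygons and traits.** Each row box is split at the
   midpoints between adjacent centres into per-plant rectangles; zonal
   statistics give each plant's NDVI, and UTM-projected sonar samples
   falling inside its polygon give its height
   (`height = mount_height − range`, median over samples).
7. **Biomass prediction.** With the combined predictor
   `NDVIsq_PH = NDVI² × height`, per-plant DMY in grams follows the
   seasonal linear model

   `g = (−4.62 + Δint_s) + (5.088 + Δslope_s) · NDVIsq_PH`

   with season offsets Δint = {0, +5.76, +16.86} and
   Δslope = {0, +1.49, +3.68} for winter and the two late-spring
   harvests. Plot DMY (kg) is the sum of its plants' grams / 1000;
   validation regresses measured on predicted and reports slope, R² and
   RMSE.

## Worked example

Simulate a small trial (4 entries × 3 blocks, 1,152 plants) and run the
whole workflow:

```bash
phenorow simulate --out-dir run --seed 7
phenorow run-all --out-dir run --seed 7 \
    --raster run/ortho.tif --gcps run/gcps.csv --panels run/panels.csv \
    --track run/track.csv --harvest run/harvest_plots.csv
```

with a `--config` YAML holding `n_entries: 4`, `n_reps: 3`,
`n_blocks: 3`, `harvest_noise_sd: 5.0`. The run prints per-stage counts:

```
calibrate: {'calibrated': True, 'clip_counts': {'red': 0, 'nir': 0}, ...}
segment: {'n_blocks': 3, 'n_rows': 36, 'rows_per_block': [12, 12, 12], ...}
detect: {'template_correlation': 0.97, 'n_candidates': 1152,
         'n_centers': 1152, 'n_polygons': 1152, 'n_empty_boxes': 0, ...}
extract: {'n_polygons': 1152, 'heights': True, ...}
predict: {'predicted': True, 'n_plants': 1152, 'n_plots': 12, ...}
validate: {'validated': True, 'n': 12, 'r2': 0.934, 'rmse_raw': 4.76, ...}
```

All 36 rows and all 1,152 plants are recovered (one polygon per plant,
96 predictions per plot); extracted heights equal the simulated truth,
and the plot-level regression of measured on predicted DMY reaches
R² = 0.93 under 5 g/plant harvest noise. `run/traits.csv` holds the
per-plant records, `run/predictions_plots.csv` the plot sums and
`run/validation.json` the regression report.

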