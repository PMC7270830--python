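# Methods

This note documents the models, parameters and numerical choices behind
`phenorow`, and what the synthetic benchmark does and does not show.

## Scope and data model

The package assumes a spaced-plant trial laid out on a regular grid:
rectangular blocks stacked along the image y-axis and separated by
bare-soil alleys, each block holding plant rows as parallel strips along
x. All pixel geometry is 0-based `(col, row)` with half-open rectangles
`[x0, x1) × [y0, y1)`, so adjacent regions partition exactly and no
pixel is ever counted twice. Rasters carry an affine geotransform, an
EPSG-coded projected CRS and a nodata value; GeoTIFF round-trips are
bit-exact. Polygons are found in rectified pixel space and exported in
world coordinates through the inverse homography and geotransform.

## Radiometric calibration

The empirical line is fitted with reflectance (percent) as the response
and digital number as the regressor, so applying it is a direct affine
map of the DN grid. The published description of the regression is
directionally ambiguous; fitting this direction keeps application
closed-form and the choice is invertible if a user needs the other
convention. Panel means can be 5 %-tail trimmed to resist edge pixels.
Out-of-range reflectance is clipped to [0, 1] and counted; nodata
propagates. NDVI pixels with a zero denominator become nodata (−9999).

## Profile segmentation

Structuring-element lengths derive from a single user parameter per
stage — the expected plant-row length for blocks, the expected plant
width for rows — as `floor(L/2)` for the opening and `floor(L/3)` for
the erosion, each forced odd (L → L−1 if even) so the centred morphology
is symmetric. Erosion and opening use border-clipped windows (equivalent
to nearest-value padding). Regional minima are maximal constant runs
strictly below both neighbours, with image borders counting as +∞; a
run spanning the whole profile is not a minimum. On plateaus the centre
is the lower median index, a deterministic tie-break.

Two robustness rules sit on top of the primitive when profiles come
from real-valued imagery:

* **Border troughs are discarded.** A minimum run touching the profile
  border reflects the crop boundary, not a gap between features, and
  would otherwise split off empty slivers when the field is cropped
  tightly.
* **Prominence filtering.** Soil noise produces multiple shallow minima
  inside one inter-row gap. Each trough's topographic prominence is
  computed from the processed profile and troughs below 10 % of the
  profile's dynamic range are dropped. The deepest trough of a real gap
  always has the adjacent row peaks as its ridges and survives; its
  noise-level neighbours do not.

Profiles are computed on NDVI + 1 (nodata → 0) so projections sum
non-negative mass; the shift is recorded.

## Box growing

The gap between two vertically linked boxes is described by its
row-wise-sum profile `f(1..n)`, the link width, and a background
threshold `t`. Ends are consumed toward the middle, brighter end first
(ties consume both), until the remaining mass is at most `t · width ·
remaining_rows`. Two readings of `remaining_rows` exist: `n − j + 1`,
which also counts rows already granted to the bottom box, and
`k − j + 1`, the rows still strictly between the growing edges. The
package implements both; the orchestration default is `k − j + 1`
(`variant="prose"`). The reason is empirical and structural: the
`n − j + 1` variant's threshold is inflated by every row the bottom box has already
absorbed, so bottom-edge growth stalls after one or two rows and plants
between blocks are stranded outside every box — on noiseless synthetic
renders it leaves 8–10 % of plants unassigned at any threshold, while
the `k − j + 1` reading assigns 100 % with zero overlaps. The printed
variant remains available as `variant="printed"` and is what the
hand-trace unit tests pin down. Both variants guarantee
`(j−1) + (n−k) ≤ n`, so grown boxes never overlap, and growth is
monotone non-increasing in `t`.

The background threshold defaults to the 25th percentile of pixels
outside all initial boxes. The outside region is exactly where
not-yet-assigned plants sit, so a plain mean is contaminated upward by
plant pixels; a low quantile lands inside the soil population. A slight
low bias is harmless (growth stops at soil level regardless) whereas an
over-estimate strands plants, so the estimator is deliberately biased
down. A user-supplied `t` overrides the estimate.

## Plant detection

Template matching uses zero-normalised cross-correlation — the standard
illumination-invariant correlation — with a template built as the
pixelwise mean of operator- or automatically-selected sample windows
(default 20×20 px plus a 4 px context ring, i.e. 28×28 effective). The
image is padded reflectively during matching so plants within half a
window of the crop border stay detectable. Strict local maxima with
score ≥ 0.6 pass a greedy non-maximum suppression at the 3 px tolerance
(higher score wins; ties go to the smaller (row, col)), implemented on
a hash grid so the scan is linear in candidate count. Centres outside
every grown row box are discarded; manual QC edits (`add`/`remove` with
pixel coordinates) are applied deterministically afterwards.

Row boxes are split at the rounded midpoints between consecutive
centres; cuts are clamped so each centre stays inside its own half-open
slice whenever the pixel grid allows (centres sharing a pixel cannot be
separated). First and last polygons extend to the box ends, so the
polygons always partition the box exactly. Expected-count enforcement is
off by default: a row may legitimately yield fewer polygons than
planted positions when plants die.

## Heights

RTK latitude/longitude is projected with a sixth-order Krüger-series
transverse Mercator (WGS84), accurate to well under a millimetre within
a zone; headings come from consecutive distinct fixes and stationary
duplicates inherit the last moving heading. Each sonar's position is the
antenna position plus its signed lateral offset along the right-hand
perpendicular. Samples are converted to `height = (mount − range) ×
100` cm, floored at zero (counted), and samples at or below 2 cm are
treated as ground echoes — the beam missing the crown — and dropped
with a count; without this filter the inter-plant soil returns drag
every median toward zero. The per-plant statistic is the median
(configurable mean), robust to residual outliers and invariant to
sample order and travel direction.

## Biomass model

Per-plant DMY is affine in the combined predictor per season with
winter as the reference level. Two coefficient modes are carried
because the winter equation, as calibrated, omits the predictor slope
that both late-spring equations carry: `reconstructed` (default) gives winter the
shared base slope 5.088 that the other seasons' offsets build on;
`as_printed` keeps the winter slope at exactly 1. The modes agree at
predictor 0 and the active mode is recorded in every output file. The
exact formula for the combined predictor is calibrated in a companion
field study rather than derivable here; the default `NDVI² ×
height_cm` is configurable (exponent and units) and the active
definition is written into `traits_meta.json`.

Model fitting is OLS on the full interaction design (intercept +
predictor + season dummies + predictor×season). Validation reports the
slope and intercept of measured-on-predicted, R² as the squared Pearson
correlation (sign-blind, hence the slope alongside), and RMSE both on
raw prediction error and on regression residuals, because field reports
frequently leave the convention unstated; both are exported so either
can be compared.

## Synthetic trial generator

The generator emulates the trial the workflow was built for: 50 entries
× 10 blocks in a randomized complete block design, 3 rows × 32 plants
per plot, 25 cm plant and 60 cm row spacing, 8 × 1.8 m plots, 2 cm/px
GSD, four reflectance panels (6/11/22/33 %), nine GCP markers in the
soil margins, and a six-sonar rig 0.6 m above ground. Choices not
determined by the trial design, fixed here once:

* **Plant canopies** are isotropic Gaussian reflectance blobs, radius =
  2σ, blob-peak NDVI equal to the plant's true NDVI (the pixel sampling
  the centre carries the exact peak). Default crown radius 0.12 m
  (diameter 0.24 m at 0.25 m spacing): spaced-plant trials are imaged
  while crowns are individually distinct — a 20×20 px matching window
  with a background context ring presupposes visible soil between
  plants — and merged canopies would make individual counting ill-posed
  for any correlation method.
* **Soil** NDVI is i.i.d. uniform in [0.05, 0.15]; plants are ≥ 0.4, so
  projection profiles always see trough contrast. Red and NIR
  reflectance are exact functions of NDVI with constant red+NIR sum, so
  the rendered bands invert to the NDVI truth identically; other bands
  are affine in NDVI. Panels and GCP markers are spectrally flat (NDVI
  0).
* **Entry effects.** Breeding entries differ genetically, so trait
  variance is split between entries and plants: per-entry mean NDVI and
  height are drawn uniformly, plants vary ±0.06 NDVI and ±6 cm around
  their entry mean within global ranges [0.4, 0.9] and [8, 40] cm.
  Without between-entry variance, replicate plots of a trial would
  differ only by sampling noise and plot-level validation would be
  measuring nothing.
* **Vehicle path**: one straight pass along every row line at 1 m/s,
  sampled at 10 Hz, serpentine direction; six sensors at lateral
  offsets (−0.75, −0.45, −0.15, 0, 0.30, 0.60) m. A sensor within a
  crown's radius returns `mount − height`; otherwise the mount height.
* **Block alleys** are 1 m of bare soil; a 3 m soil margin rings the
  field and hosts panels and markers. World placement is UTM zone 54
  south (a metre-based projected CRS covering 142° E).
* **Harvests** are generated from the seasonal model evaluated at the
  *true* predictor plus Gaussian noise; negative weights are kept by
  default (the model is linear and can go negative) so parameter
  recovery stays exact, with optional truncation recorded in the
  output.

Everything is deterministic per seed: layout, render, track and harvest
derive independent generators from the layout seed.

### What the synthetic benchmark shows — and what it does not

Passing on synthetic renders demonstrates that the geometry pipeline is
internally consistent: counts are conserved, every plant centre ends up
in exactly one grown box, polygons partition rows, zonal statistics and
height matching agree with ground truth, and the model layer recovers
its own coefficients. It does not demonstrate robustness to the
phenomena the renderer omits: perspective and stitching artefacts,
illumination gradients, wind-blown or lodged canopies, genuinely merged
neighbouring crowns, sonar beam-width effects, or GNSS drift. Results
on real imagery depend on those factors and on sensible parameter
choices (expected row length, plant width, match threshold).

## Problem sizes and runtime

The default test suite runs the complete workflow on a 4 × 3-block
trial (1,152 plants) and structural checks on the full 50 × 10 trial
(48,000 plants, ~4,800 × 4,750 px render); the full-trial segmentation
plus detection completes in well under a minute on one CPU, and
`scripts/acceptance.py` repeats it from scratch in a few minutes
including rendering and I/O.

## Known limitations

* Rows must be straight and axis-aligned after rectification; rotated
  or curved rows are out of scope.
* Overlapping-canopy instance separation is not attempted; the split is
  purely geometric between detected centres.
* The sonar model is a point sample, not a beam footprint.
* The consensus step selects among polygon sets by least area variance;
  with a single imaging date it degenerates to identity, which is how
  the end-to-end pipeline uses it.
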