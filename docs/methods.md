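# Methods

This note records the model, the conventions, and the design choices
behind `vegdyn`, in the order the pipeline applies them.

## Analysis surfaces

**Growing-season composite.** The annual value of a pixel is the median
of its valid monthly NDVI over May–September (configurable month set).
A pixel-year needs at least `min_valid_months` (default 3) valid months;
otherwise it is nodata. The median, not the mean, is used so single
anomalous months (cloud, snow) do not leak into the annual series.

**Period mean.** The multi-year arithmetic mean of the composite
(default minimum 15 valid years) feeds the 0.2 sparse-vegetation
threshold. NDVI below 0.2 is treated as sparse/non-vegetated; the
boundary value 0.2 itself counts as vegetated, because the sparse
classes are defined by *strictly* low NDVI.

**Focal CV.** Spatial heterogeneity is the coefficient of variation
s/m of the 9 composite values in a 3×3 window, assigned to the center
pixel, computed once per year from the annual composite. Conventions:

- *Sample* standard deviation (divisor n−1): the 9 values are a sample
  of the local surface.
- All 9 window values must be valid. The window is the statistical
  justification for the CV; a partial window changes the estimator.
  Consequently borders, masked pixels, and every window touching a
  masked pixel are nodata.
- Windows with mean ≤ 1e−6 are nodata: the ratio is numerically
  meaningless near a zero mean (NDVI can be negative over water/snow,
  so near-zero window means do occur).
- Masking (excluded land cover ∪ road/river buffers) happens *before*
  windowing, so a buffer pixel also invalidates its neighbours'
  windows. Buffer membership is center-in-buffer with a configurable
  distance per run (default 250 m, one pixel): linear features inflate
  local CV without reflecting vegetation structure.
- Order of operations: the composite is built first, then the CV — one
  heterogeneity value per pixel-year. The alternative (CV per month,
  then the growing-season median of monthly CVs) is available as
  `cv_order: monthly`; on noiseless scenes the two orders coincide
  exactly, and the annual order is the default because it defines one
  clean annual series per pixel.

## Trends and classification

Per-pixel ordinary least squares of the annual value on calendar year,
skipping nodata years; at least `max(3, min_valid_years)` valid years
are required. Significance is the two-sided t-test on the slope with
n−2 degrees of freedom. Numerical conventions:

- Sums are computed centered (about the per-pixel means of year and
  value), which makes a perfectly constant series yield slope exactly 0
  and residual exactly 0 rather than float dust.
- A zero-residual series with nonzero slope (noiseless line) reports
  p = 0; a constant series reports p = 1 — a flat line is never
  evidence of change.

Classification gates on *both* trends being significant at the same
alpha (default 0.05). Pixels with data that fail the gate are "not
significant"; pixels without valid trends or mean are nodata. The six
classes are the sign table in the README; it is exhaustive and mutually
exclusive for every dual-significant pixel (slope exactly 0 with
p < alpha cannot occur, since a zero slope implies p = 1).

Area summaries report each class as a share of the dual-significant
area (the headline convention) and, because the denominator convention
is ambiguous in practice, also as a share of the total valid area —
both columns appear in every proportion table. No multiple-testing
correction or spatial-autocorrelation adjustment is applied to the
per-pixel p-values; the maps are descriptive, as is standard for this
family of analyses.

## Driver attribution

**Correlations.** Pearson r of the annual response series (NDVI
composite, CV) with each annual driver per pixel, on the raw series
(no detrending), with the t-transform p-value. Summaries report the
share of valid area with p < alpha and, within it, the positive /
negative split (these two always sum to 100%).

**Stratified samples.** The random-forest observation unit is the
pixel-year: every (dual-significant pixel, year) pair contributes one
row of (response, six drivers). Strata are grassland type × class
(12 at most). Rows with any missing value are dropped, then strata
larger than the cap (default 10,000) are subsampled uniformly without
replacement with a fixed seed. Per-pixel temporal means are available
via `sample_unit: pixel` for sensitivity checks.

**Forests.** Per stratum and response: the tree count is selected from
the grid {100, 200, 300, 500, 800} by k-fold (default 5)
cross-validated mean squared error; all other hyperparameters are the
scikit-learn defaults with a fixed random state. The reported fit is
the out-of-bag R²; importances are mean decrease in impurity,
normalized to sum to 1. Strata under 50 rows or with a constant
response are skipped with a warning. Climate share = Pre + Temp + RH +
SPEI importances; human share = Graz + Pop.

## The synthetic scene

The generator exists to give every stage a ground-truth acceptance
surface. Monthly NDVI of a pixel in month m of year t (years from 0):

    v = (b + s·t) · (1 + o · (A + d·t)) + ε + η

with baseline b, NDVI trend s per year, a fixed zero-mean 3×3 offset
pattern o ∈ [−1, 1] tiled periodically, divergence amplitude A and
trend d per year, observation error ε ~ N(0, noise_sd) drawn
independently per monthly sample, and month-level jitter
η ~ N(0, noise_sd/2). Because the pattern is zero-mean with period 3,
every 3×3 window sees all nine offsets: the window mean is b + s·t
(NDVI trend = s) and the noiseless window CV is (A + d·t)·sd(pattern)
(CV trend sign = sign d). The two trends are therefore controlled
independently — each class of the sign table can be produced at will.
Independent per-observation error is the natural model of satellite
composite noise; the growing-season median then averages it down by
roughly √5.

Block parameter validation enforces, analytically over the simulated
horizon: sign consistency of (s, d) with the class label; baseline and
period-mean NDVI on the correct side of 0.2 for the sparse/vegetated
classes; the noiseless trajectory staying inside [0, 1] at the extreme
offsets; a non-negative divergence amplitude; and — the subtle one —
preservation of the NDVI trend sign at every offset (a strong
divergence trend can otherwise flip the trend of the o = −1 pixels,
so a noiseless scene would no longer classify to its own label).

The bundled demo scene is 120×120 pixels (250 m), 23 years, six 30×30
blocks (one per class) on a no-change background, with |s| of
0.003–0.004 per year — typical of multi-decadal grassland records —
and divergence trends sized by a design-time power analysis so every
class is detectable at the default noise_sd = 0.02. Two line features
(a road through the first block, a diagonal river) and a ~1% water
patch exercise the masking path; grassland type splits the grid into a
steppe and a meadow half, producing up to 12 attribution strata.

Drivers are generated on a 4× coarser grid (forcing the resampling
path) as mean + slope·t + N(0, sd) per coarse cell and year, then
aligned bilinearly — except population, which is rounded to whole
persons per cell and aligned by nearest neighbour, since it is a count
(this also yields the realistic large "unchanged" fraction under an
exact-zero slope rule). Defaults emulate a semi-arid alpine setting:
precipitation ~450 mm rising 1.5 mm/yr (sd 30), temperature ~0.5 °C
warming 0.03 °C/yr (sd 0.3), relative humidity ~55% (sd 2), SPEI ~0
(sd 0.5), grazing ~50 units declining 0.4/yr (sd 5), population ~10
persons/cell static (sd 0.15). An optional response link adds
Σ β_v · z_v (per-pixel z-scores of a driver) to the annual NDVI, so
attribution recovery is testable with a known dominant driver.

What the scene does **not** emulate: realistic spatial autocorrelation
of NDVI beyond the 3×3 pattern, cloud/QA gaps, phenological curvature
within the growing season, interannual climate memory, or any real
geography. Passing tests therefore demonstrate the correctness of the
computations and the internal consistency of the classification and
attribution logic, not performance on real archives.

## Problem sizes and runtime

The demo analyses and the acceptance runs scale the attribution stage
down — sample caps of ~300–1,500 rows and tree grids of {50, 100} with
3-fold selection — so a full pipeline run takes ~1.5 minutes and the
complete acceptance sweep ~5 minutes on one CPU. These are package
choices for the bundled scenes; library defaults (cap 10,000, grid up
to 800 trees, 5 folds) remain the full-scale settings.

## Known limitations

- Raster I/O is TIFF + JSON sidecar and GeoJSON only; no NetCDF or
  shapefile backends, and no reprojection (inputs must share a CRS).
- The CV is single-scale (3×3); no variogram or multi-scale texture.
- OLS significance assumes independent residuals; serially correlated
  NDVI series would need a Mann–Kendall or block-bootstrap variant.
- Mean-decrease-in-impurity importances are biased toward
  high-cardinality predictors; with six continuous drivers this is
  benign, and `attribution.permutation_check` provides a
  permutation-importance cross-check.
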