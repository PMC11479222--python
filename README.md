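# vegdyn

Vegetation-change assessment for grassland landscapes from NDVI time
series: instead of reading greenness trends alone, the pipeline pairs the
per-pixel NDVI trend with the trend of its *spatial heterogeneity* — the
coefficient of variation (CV = s/m) of NDVI within a 3×3 moving window —
to separate genuine recovery from degradation that hides behind greening,
and then attributes the detected changes to climatic and human drivers.

The package is aimed at remote-sensing ecologists working with
moderate-resolution (~250 m) monthly NDVI products over alpine or
semi-arid grasslands. Because real satellite archives are large and
external, the repository ships a fully labeled synthetic-scene generator
whose statistical structure matches what the analysis assumes; every
stage is tested against that ground truth.

## Method

1. **Composites.** For each year, the growing-season (May–September)
   median NDVI per pixel; the multi-year mean of these composites gives
   the sparse-vegetation mask side (mean NDVI < 0.2).
2. **Heterogeneity.** The CV (sample standard deviation over mean, 9
   window values, divisor *n*−1) of the annual composite in a 3×3 moving
   window. Pixels near roads/rivers (configurable buffer) and
   water/impervious/wetland/glacier land cover are masked first.
3. **Trends.** Per-pixel OLS of each annual series on calendar year,
   with a two-sided *t*-test (df = *n*−2) on the slope.
4. **Classification.** Pixels where *both* trends are significant
   (p < 0.05) are labeled by the sign pattern:

   | NDVI trend | CV trend | mean NDVI | class |
   |---|---|---|---|
   | + | − | any | improving |
   | + | + | < 0.2 | regrowing |
   | + | + | ≥ 0.2 | slight degradation |
   | − | + | any | medium degradation |
   | − | − | ≥ 0.2 | severe degradation |
   | − | − | < 0.2 | desertification |

5. **Attribution.** Per-pixel Pearson correlations of NDVI and CV with
   six annual drivers (Pre, Temp, RH, SPEI, Graz, Pop), and per-stratum
   random-forest regressions (strata = steppe/meadow × six classes,
   capped at 10,000 pixel-year samples, tree count chosen by
   cross-validation) reporting mean-decrease-in-impurity importances and
   out-of-bag R².

## Worked example

The numbered scripts under `analysis/` run the whole study on the
bundled synthetic scene (120×120 pixels at 250 m, 23 years, six labeled
blocks, observation noise sd 0.02):

```sh
python analysis/01_simulate_scene.py
python analysis/02_composites_heterogeneity.py
python analysis/03_trends_classification.py
python analysis/04_driver_attribution.py
```

Step 03 prints, for seed 1:

```
dual-significant: 4755 of 12518 valid pixels (38.0%)
             class  n_valid_interior  recovery_pct
         improving               568    100.000000
         regrowing               644     99.378882
slight_degradation               644     99.378882
medium_degradation               784    100.000000
severe_degradation               745     97.449664
   desertification               745     97.583893
```

38% of the valid area passes the dual-significance gate (the six truth
blocks plus noise-induced detections), and ≥97% of the interior pixels
of every block recover their generating class. Step 04's driver stage
reports, per stratum, the selected tree count, the out-of-bag fit and
normalized importances; with the default scene (drivers not linked to
NDVI) the climate/human split reflects only the drivers' own trends.
The same pipeline runs from a single YAML config via the `vegdyn`
command (`vegdyn run-all --config ...`), or stage by stage
(`simulate | composite | heterogeneity | trends | classify | drivers`).

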