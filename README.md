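# scalesdm

Multi-scale ensemble species distribution modeling (SDM) for presence-only
data: scale-of-effect selection by moving-window focal statistics, an
AUC-weighted ensemble of five learners, scenario projection with
climate-model averaging, habitat-change accounting, and minimum-convex-
polygon range diagnostics — all exercisable end-to-end on synthetic
landscapes with known ground truth.

## The problem

Species respond to environmental variables at characteristic spatial
scales: a ground-dwelling montane bird may react to forest cover averaged
over several kilometres while responding to human disturbance only
locally. Standard SDMs take every predictor at the native raster
resolution and so mis-specify these responses. This package implements the
multi-scale workflow used in recent pheasant habitat studies:

1. **Occurrence cleaning.** Presence records are dropped when they fall
   outside the species' range polygon, outside the plausible elevation band
   (± a 100 m buffer), or on land-cover classes the species does not use;
   the remainder is thinned to one record per 1-km cell.
2. **Scale of effect.** Every predictor is recomputed as a circular
   moving-window mean (continuous) or class fraction (categorical) at
   candidate radii r = 1…10 km. For each variable and radius, a Welch
   t-test compares presence and pseudo-absence values; the radius with the
   smallest p < 0.05 is that variable's characteristic scale, and variables
   with no significant radius are excluded. Collinear survivors
   (|Pearson r| > 0.7) are screened greedily in ascending p.
3. **Ensemble.** Five learners — GLM (logistic, linear + quadratic terms),
   GAM (spline features), a MaxEnt-style L1 logistic model, random forest,
   and gradient boosting — are fitted to presences vs n pseudo-absence sets
   and evaluated by repeated stratified k-fold cross-validation (AUC, TSS,
   continuous Boyce index). All runs with held-out AUC > 0.7 are combined
   by the AUC-weighted mean, w_i = AUC_i / Σ AUC_j. Suitability maps are
   binarized at the threshold maximizing sensitivity + specificity (maxSSS).
4. **Projection and change.** The ensemble is projected onto scenario
   stacks (warming offsets, precipitation scaling, forest-to-cropland
   conversion), averaged across climate-model realizations, binarized at
   the *current-time* threshold, and optionally constrained to a buffered
   range polygon (limited dispersal). Change is summarised per scenario as
   stable/gain/loss areas with

   `net change = 100 · (future − current) / current`
   `turnover = 100 · (gain + loss) / (current + gain)`

   plus per-cell trajectory ("time-step") maps with classes never / stable
   / expansion / contraction / fluctuation.
5. **Range dynamics.** 95% minimum convex polygons (drop the 5% of points
   farthest from the centroid, take the convex hull) for two occurrence
   periods, their mutual overlap, and the shift in occurrence-elevation
   distributions.

Because real inputs (GBIF records, 1-km climate and land-use grids) need
large downloads, the package ships a first-class synthetic-landscape
generator whose ground truth (true radii, response shapes) is known, so
every stage is testable: scale selection must recover the generating 7 km
forest radius, the fitted ensemble must correlate with the true
suitability surface, and all change accounting must satisfy its exact
identities.

## Worked example

`examples/02_scale_selection.py` generates the default synthetic world
(64×64 km, truth: forest effect at 7 km, temperature optimum 15 °C at
6 km, ruggedness optimum at 8 km), samples 150 presences and 2,000
background points, and runs the scale search:

```
variable     chosen km  p at chosen scale
tem_warmmon         10           6.61e-08
tri                 10           3.05e-02
footprint           10           9.45e-05
forest               7           2.50e-44
cropland             7           1.63e-26
retained after |r|>0.7 screen: forest, tem_warmmon, tri
```

The forest fraction is recovered at exactly its generating 7 km radius
with an overwhelming contrast (p ≈ 10⁻⁴⁴); weak, indirect variables sit at
larger radii with far weaker support, and the collinearity screen then
drops cropland (anti-correlated with forest) and footprint.
`examples/03_ensemble_model.py` continues to the fitted ensemble:

```
ensemble: 47/50 members above AUC 0.7
  AUC=0.945  TSS=0.760  Boyce=0.914
  maxSSS threshold = 0.593
```

and `examples/04_projection_change.py` projects it onto a warming scenario,
printing the change accounting (net change −32.8% by 2070 and −63.6% by
2100 under the mid-range pathway analog, turnover rising with warming).

The full chain — generation, cleaning, scale selection, screening, CV
ensemble, projection, dispersal variants, time-step maps, change tables,
range dynamics — runs from one seeded config:

```bash
scalesdm run --seed 1 --out my_run          # or: scalesdm run --config cfg.yaml
```

which writes CSV tables (scale profiles, model runs, ensemble summary,
importances, response curves, suitability bins, change accounting,
trajectory-class areas, range dynamics), ASCII-grid maps, and a manifest
with checksums. Re-running the same config reproduces every CSV
bit-identically.

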