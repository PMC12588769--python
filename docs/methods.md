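# Methods

This note records the models, defaults and numerical choices behind
`scalesdm`, and what the synthetic experiments do and do not demonstrate.

## The synthetic world

All development-time experiments run on a generated landscape rather than
real rasters. The generator's aim is statistical, not geographic realism:
it reproduces the dependence structure the multi-scale SDM workflow
assumes, with a known ground truth so recovery can be tested.

**Fields.** Every continuous layer starts from seeded white noise smoothed
by an isotropic Gaussian kernel whose sigma is the stated correlation
length (in cells), then standardised to exactly zero mean and unit
variance. Smoothing wraps toroidally, so fields are stationary without
edge attenuation; focal windows downstream are nevertheless truncated at
the grid border, as they would be on real data.

**Layers and couplings** (64×64 cells of 1 km by default):

| layer | construction | rationale |
|---|---|---|
| elevation | 2200 + 1000·field(L=10), floored at 50 m | broad montane relief |
| slope/aspect/northness/tri | Horn 8-neighbour finite differences; tri = mean \|Δz\| to 8 neighbours | the standard 1-km topography conventions; hand-checkable |
| annualtem | 20 − 6.5·elev/km + 1.2·field(L=8) | tropospheric lapse rate; temperature *must* fall with elevation |
| tem_warmmon / tem_coldmon | annualtem ± 10 plus small independent fields | warm/cold month offsets; the annual/warm pair is deliberately collinear (r > 0.9) so the correlation screen has work to do |
| temvar, prec_var | independent fields | variables with *no* true effect, so the no-contrast exclusion path is exercised |
| precipitation family | 1200 + 350·field(L=10) and derived wet/dry-month layers | plausible magnitudes; no true effect |
| land cover | quantile-pinned classes: 25% cropland (score biased toward low elevation with weight 0.3), then 45% forest among the rest (grain L=1) | see below |
| footprint | 20 − 8·z(elev) + 6·field(L=4), clipped to [0, 50] | disturbance concentrated at low elevation |

**True suitability** is logistic in a sum of focally aggregated responses:
unimodal (negative quadratic) in the 6 km warm-month temperature with
optimum 15 °C and width 7 °C, unimodal in the 8 km ruggedness (optimum 60,
width 120), and linear in the 7 km forest fraction with slope 30 centred
at the pinned 0.45 landscape prevalence. Presences are drawn with
replacement proportional to suitability, one point per drawn cell centre.

Two generator choices matter for scale identifiability and were fixed at
design time:

* **Fine land-cover grain (L = 1 cell).** Focal fractions at neighbouring
  radii share most of their window area, so their correlation is driven by
  window overlap; any coarse-scale component in the land-cover pattern
  inflates that correlation further and flattens the p-value profile
  across radii. A fine grain keeps the profile peaked at the generating
  radius.
* **Quantile-pinned prevalences.** Pinning forest at exactly 45% per seed
  lets the truth's linear term be centred at a fixed constant without
  per-seed saturation drift.

With these settings the 7 km forest radius is recovered in 86 of 100
seeds, with every failure at an adjacent radius (6 or 8 km) — the
behaviour expected of a t-profile over highly overlapping windows.

**What the synthetic world does not emulate:** real bioclimatic formulas,
anisotropic terrain, spatially biased sampling effort, coordinate error,
or temporal autocorrelation of records. Passing tests therefore show the
*method* behaves as specified under its own assumptions, not that any
real-data result is correct.

**Scenarios.** A future stack shifts temperature layers by a warming
offset, scales precipitation layers, and converts a fraction of forest
cells to cropland, drawn without replacement with weights 1/rank of
elevation (lowest first) — encoding the expectation that cropland pressure
climbs from below. Default scenario analogs span a low/medium/high
pathway (warming 1.5–6.0 °C, conversion 5–40% by the second period), and
three "climate model" realizations jitter the climate terms (±0.5 °C,
±3% precipitation) around each pathway before averaging.

## Focal statistics

Windows are circular: a neighbour belongs when the centre-to-centre
Euclidean distance is at most the radius, with no rounding of the distance
test (radius in cells = radius_km × 1000 / cell size). Nodata cells are
excluded from numerator and denominator alike, and windows truncate at the
border, so a cell's statistic is always the mean/fraction over its *valid*
neighbourhood. Radii below half a cell warn and act as radius 0. Both
operations are validated cell-by-cell against a double-loop enumeration
oracle, exactly for fractions and to 1e-10 for means.

## Scale selection and screening

The characteristic scale is chosen by a Welch (unequal-variance) t-test of
presence vs background values per radius — Welch rather than pooled
because the two samples are grossly unequal in size and variance. Only
radii with p < 0.05 are eligible; the minimum-p radius wins and ties go to
the smaller radius (parsimony). The collinearity screen is a greedy pass
in ascending chosen-p: a candidate is kept iff |r| ≤ 0.7 against every
already-kept variable, with correlations computed on a common seeded
sample of at most 50,000 jointly valid cells. The greedy order makes the
"retain the lower p" rule deterministic and transitive.

## The ensemble

Learner defaults (all seeded, one fit seed fanned per run from the
pipeline seed):

* **GLM** — standardised features + squares, ridge-logistic (C = 1).
* **GAM** — per-feature cubic B-spline basis (5 knots) + logistic.
* **MAXENT_LIKE** — standardised linear + quadratic + pairwise product
  features with L1 logistic (liblinear), the logistic-regression
  equivalent of a MaxEnt feature model.
* **RF** — 100 trees, min leaf 2.
* **XGB** — 100 trees, depth 3, learning rate 0.1, subsample 0.8.

Background rows are down-weighted so total presence and background weight
are equal; scores are probabilities in [0, 1]. Cross-validation partitions
presences and background separately (every fold keeps presences) with k = 5
folds and 3 repeats over 3 pseudo-absence sets by default, giving
5 × 3 × 3 × 5 = 225 runs. Held-out AUC uses the Mann–Whitney rank form with
half-credit ties; TSS is reported at the held-out maxSSS threshold; the
Boyce index uses 10 overlapping classes of width 10% of the landscape
score range and is the Spearman correlation of P/E against the class
midpoint (range [−1, 1]; with so few classes its *null* distribution has
sd ≈ 1/3, so single-run values are noisy and only its sign/magnitude
pattern is meaningful). All runs with AUC > 0.7 enter the ensemble with
weights AUC_i/ΣAUC; the ensemble is a convex combination, hence bounded by
member extrema. The maxSSS threshold searches the set of unique observed
scores and takes the smallest maximiser on ties.

Permutation importance is 1 − |Pearson r| between predictions on original
vs column-permuted features (5 seeded permutations); response curves sweep
one variable over its observed range with all others at their medians.

## Projection and change accounting

Scenario projection recomputes every retained variable's focal layer at
its chosen radius on the scenario stack, so projecting the current stack
reproduces the training-time map exactly. Climate-model realizations are
averaged cellwise *before* binarization; binarization is
threshold-inclusive (≥). Limited dispersal zeroes suitable cells whose
centres fall outside the range polygon buffered by a configurable
distance; on the 64-km synthetic grid the default buffer is 10 km (a
desk-scale analog of the ~110 km buffer used for real ranges; both are
configuration). Areas are suitable-cell counts × nominal cell area with no
latitude correction (metric grids). Net change and turnover keep full
precision internally; report-time rounding is half-away-from-zero to one
decimal. Trajectory classes generalise to any number of periods: a cell is
expansion (contraction) when its first→last transition is 0→1 (1→0) with
no reversal, fluctuation otherwise.

## Range dynamics

The 95% MCP drops ⌈0.05·n⌉ points farthest from the centroid of all points
(an epsilon guards the ceiling against float artifacts; ties at the
trimming rank drop the later record), then takes the convex hull; fewer
than 3 non-collinear survivors is an error. Elevation shifts prefer each
record's own elevation and fall back to the DEM at its cell; unresolvable
records are counted and reported rather than silently dropped.

## Pipeline defaults and problem sizes

The default synthetic run uses a 64×64 grid, 150 raw presences, 2,000
background points × 3 sets, radii 1–10 km, k = 5 × 3 repeats, and three
pathways × two periods × three climate realizations. The development
experiments use 20 seeds (scale recovery), 10 seeds (ensemble behaviour,
with a 30-presence/400-background holdout and 2 CV repeats), and a reduced
40×40 / 2-set / k = 3 configuration for the determinism audit; these sizes
give stable statistics while keeping a full run in the order of minutes on
one CPU.

## Known limitations

* Random (not spatially blocked) cross-validation, as in the motivating
  workflow; with spatially clustered records it is optimistic.
* The MaxEnt-style learner is a feature-expanded logistic model, not a
  re-implementation of any particular MaxEnt software's regularization
  path or its default feature classes.
* The Boyce estimator with 10 classes is noisy (see above); it is reported
  but never used for member selection.
* Scenario construction is stylised: uniform warming offsets and a single
  multiplicative precipitation factor, not downscaled climate fields.
* No habitat-connectivity or fragmentation analysis; change accounting is
  purely per-cell.
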