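# Methods

This note records the models and procedures the package implements, the
conventions it fixes where the underlying practice leaves them open, and
what the synthetic-data experiments do and do not demonstrate.

## Coordinates and projection

Occurrence coordinates are either geographic (decimal degrees) or planar
metric; autodetection treats anything inside [−180, 180] × [−90, 90] as
geographic, overridable with an explicit tag. Geographic records are
projected with a **spherical Lambert azimuthal equal-area projection
centred on the record centroid**, using the authalic Earth radius
(6 371 007.181 m). The choice is driven by what the downstream metrics
are: EOO and AOO are areas, and the azimuthal equal-area projection has
zero area distortion everywhere, while its distance distortion is
negligible at the scale of a species range centred on the projection
origin (the 1°-of-longitude check in the tests agrees with the WGS84
equatorial arc to ~0.1%). The forward/inverse spherical formulas are
implemented directly; no ellipsoidal machinery is needed at this accuracy
and scale.

## Range metrics

* **EOO** is the shapely convex-hull area of the metric sites, in km².
  Sites are records, or the centres of presence cells when the input is a
  raster (cell centres, not corners — a convention fixed here and exposed
  for comparison). When the hull area falls below the AOO of the same
  sites (one or two sites, collinear sites), the AOO is reported instead:
  an extent of occurrence cannot be smaller than the occupancy it
  contains.
* **AOO** counts distinct occupied cells of a 2 × 2 km grid **anchored at
  the metric origin (0, 0)** and multiplies by 4 km². No origin
  optimization is attempted, so results are bit-for-bit reproducible;
  assessors who want the IUCN "minimum AOO over grid shifts" refinement
  can shift the records themselves. Presence rasters are mapped to the
  2-km grid by the any-overlap rule (a presence cell marks every 2-km
  cell its footprint touches).
* **Elevation range** samples the DEM at record cells and errors, naming
  the offending record indices, if any record sits on NoData — snapping
  is deliberately a separate, explicit step.
* **Countries** are the names of user-supplied boundary polygons
  (GeoJSON, `name` property) covering at least one site; edge contact
  counts as inside, output is sorted for determinism.

## Record quality control

* **Snapping** (`move_to_valid`) replaces each record on a NoData or
  off-grid cell by the centre of the Euclidean-nearest data cell.
* **Outlier screening** standardizes the environmental values at the
  record cells per layer (zero mean, unit variance over the records —
  record-relative, not whole-raster, so the statistic describes the
  sample at hand), fits a full-rank PCA and reports each record's
  distance to the PC-space centroid; since a full-rank PCA is a rotation,
  this equals the distance in standardized variable space, which the
  tests exploit as an oracle. The default flag threshold is
  mean + 2·SD of the distances, a parameter rather than a doctrine:
  the intended use is "look carefully at these records", not automatic
  deletion. Zero-variance layers are dropped with a warning; flags are
  invariant to affine rescaling of any layer by construction.
* **Spatial thinning** sets the distance threshold to
  `proportion × max pairwise distance` (default proportion 0.1). Each of
  `runs` (default 100) randomized passes deletes a uniformly random
  member of a uniformly random violating pair until no violation
  remains; the pass retaining the most records wins, ties going to the
  earliest pass. This is a randomized heuristic for a maximum
  independent set, which is why restarts matter; on ≤10-point instances
  with 200 runs it attains the exhaustively enumerated optimum in >90%
  of instances. Note that with exactly two records no thinning can ever
  occur: the threshold is strictly below the only pairwise distance by
  construction.

## Habitat and model-based range maps

* **Patches** are connected components of the binary habitat raster
  under queen (8-neighbour) connectivity — the more permissive and more
  common ecological convention; the parameter is exposed for rook
  analyses. `map_habitat` returns the cells of every patch containing a
  record, optionally snapping off-habitat records to the nearest habitat
  cell first (for georeferencing error, not for genuinely lost
  subpopulations). Raw EOO/AOO are computed from the records as used
  (i.e. after the optional snap), modelled EOO/AOO from the occupied
  patches; using post-snap records keeps modelled AOO ≥ raw AOO whenever
  the records lie on habitat.
* **The distribution model** is an L1-penalized logistic regression of
  presences against a uniform random background sample on standardized
  linear + quadratic features — the penalized-regression formulation of
  the maxent model family, chosen over wrapping the external MaxEnt Java
  program to keep the pipeline a pure-Python, dependency-light, fully
  seedable unit. The regularization multiplier (default 1, i.e. C = 1)
  scales the L1 penalty; hinge features are omitted by default because
  the quadratic family already captures unimodal responses, the common
  case for climate predictors. The inner solver's internal shuffling is
  pinned so fits are bit-reproducible.
* **Ensembles** (default 100 runs; 10 in the desk-scale experiments
  below) each draw a fresh random 70/30 presence train/test split and a
  fresh background sample (default n = 1000), fit, predict the
  suitability raster, score test AUC (held-out presences vs held-out
  background, Mann–Whitney with ties at ½), and binarize at the
  training-data threshold maximizing sensitivity + specificity — a
  data-driven rule, exposed as a parameter, in place of a fixed 0.5.
* **Consensus and confidence limits.** The consensus marks cells where
  the weighted vote Σ wᵣ bᵣ / Σ wᵣ strictly exceeds 0.5 with
  wᵣ = max(0, AUCᵣ − 0.5)²; runs at or below chance therefore carry no
  weight, and an ensemble whose runs are all at chance is rejected as
  uninformative. Confidence-limit maps use **unweighted** run
  frequencies — ≥ 97.5% of runs for the lower limit, ≥ 2.5% for the
  upper — read literally from the consensus/CL convention this package
  follows; the weighting applies to the consensus only. EOO/AOO are
  attached to all three maps, giving an uncertainty interval on both
  metrics.

## Red List Index

Weights follow the standard ladder LC 0, NT 1, VU 2, EN 3, CR 4, EW 5,
EX 5 (Extinct in the Wild shares the top score), and the index for one
date is 1 − Σw/(5N). **Data Deficient species are excluded from both the
weight sum and N by default**, matching standard RLI practice; a
`dd_weight` option pins DD to a fixed weight instead. Bootstrap
confidence limits resample whole species rows with replacement to the
original N — row-wise resampling preserves the pairing of categories
across dates, without which the sign-of-change test would be
meaningless — and take the 2.5/97.5 percentiles over (default) 1000
replicates. A change between consecutive dates (first-vs-last is an
option) is significant when strictly more than 95% of replicate changes
share the sign of the observed change; an observed change of exactly
zero has no sign and is never significant, which also makes the test
exactly conservative on no-change tables. The sampled-RLI curve reports,
for each subsample size n, the 95th percentile of the worst-date
absolute deviation from the full-table index over random subsets without
replacement; both the quantile and the worst-date aggregation are
parameters, as no single convention exists.

## Synthetic data and what the experiments show

The fixtures module simulates the inputs at desk scale: 100 × 100 grids
of 1-km cells, quantitative layers as unit-variance Gaussian random
fields smoothed to a correlation length of ~8 cells, a 4-class
categorical land-cover layer, and an island mask (largest connected
landmass of a smoothed blob) providing NoData sea. Virtual species have
logistic suitability in the standardized layers with known coefficients
and a presence cutoff, so truth is available cell by cell.

Two standard set-ups are frozen:

* **`island_spider`** — 10 records of a single-island endemic with one
  record displaced into the sea, mirroring the shape of the classic
  worked example (few records, one obvious georeferencing error); it
  drives the QC and `map_easy` integration tests.
* **`recovery_setup`** — the distribution-modelling recovery experiment:
  coefficients (3, −2.5, 1.5), intercept −3 and cutoff 0.7 give a
  restricted species occupying roughly a fifth of the island (a
  realistic prevalence for a species under assessment; prevalence also
  bounds the achievable presence-vs-background AUC at ≈ 1 − p/2, so a
  widespread species could not exhibit high AUC even under a perfect
  model), sampled by 50 error-free records — a well-surveyed case.
  With 10 ensemble runs the experiment yields mean test AUC ≈ 0.9,
  consensus/truth Jaccard ≈ 0.8, and the true AOO inside the
  [lower-CL, upper-CL] interval in ≥ 80% of 20 replicate seeds.

What passing these experiments does **not** show: real occurrence data
carry detection bias, positional error correlated with terrain, and
non-logistic responses; real climate layers are far smoother and mutually
correlated in structured ways; and the virtual species satisfies the
model family by construction, so recovery here measures the pipeline's
correctness, not maxent's ecological adequacy.

## Numerical conventions

* Rasters are north-up; row 0 is the top row; cell (r, c) has centre
  (x₀ + (c+0.5)s, y₀ − (r+0.5)s). NoData is NaN in memory, −9999 in
  files (ESRI ASCII `NODATA_value`, GeoTIFF `GDAL_NODATA` tag).
* GeoTIFF georeferencing is written as raw ModelPixelScale/ModelTiepoint
  tags (square pixels only); ESRI ASCII values are written with `repr`
  so round trips are exact.
* Correlation pruning drops the layer with the highest mean absolute
  pairwise correlation, ties to the lowest index, until all |r| < 0.7
  (default).
* All randomness flows from explicit seeds; ensembles and multi-group
  bootstraps derive per-unit seeds from one master generator, so a
  single `--seed` makes every CLI subcommand byte-reproducible.
* Problem sizes in the test-suite experiments (10-run ensembles,
  20 replicate seeds, 100–200 bootstrap tables, 2^n enumeration only for
  n ≤ 10) are chosen as the smallest sizes at which the checked
  properties are statistically unambiguous.

## Known limitations

* Planar (spherical-equal-area) hull areas, not ellipsoidal geodesic
  areas; the difference is far below assessment-relevant precision.
* No alpha hulls, subpopulation/fragmentation statistics, temporal
  EOO/AOO trends, or phylogenetically weighted indices.
* The AOO grid is fixed at origin (0,0); no grid-shift minimization.
* KML export of a metric raster requires the projection that built the
  metric frame; rasters supplied already-projected by the user without
  one cannot be placed on the globe.
* Background sampling is uniform over data cells; no bias-file or
  target-group background correction.
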