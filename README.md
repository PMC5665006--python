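# redlisting

A Python toolkit for the quantitative side of IUCN Red List assessments:
geographic range metrics with confidence limits, occurrence-record quality
control, range mapping from habitat or from ensemble species distribution
models, and the Red List Index with bootstrap inference.

## Who it is for

Assessors and conservation biogeographers who have occurrence records
(longitude/latitude or planar metric coordinates) and, optionally,
environmental raster layers, and need the criterion-B quantities and maps
an assessment requires — reproducibly, from the command line or from
Python.

## What it computes

**Extent of Occurrence (EOO).** The planar area of the minimum convex
polygon around all known or predicted sites, in km². Geographic records
are first projected with a Lambert azimuthal equal-area projection centred
on the record centroid, so areas are undistorted. Degenerate hulls (one or
two sites, collinear sites) are floored at the AOO so EOO ≥ AOO always.

**Area of Occupancy (AOO).** 4 km² times the number of distinct occupied
cells of a fixed 2 × 2 km grid, the resolution IUCN mandates. Presence
rasters at other resolutions are mapped to the 2-km grid by the
any-overlap rule.

**Record QC.** `move_to_valid` snaps records off valid cells (e.g. in the
sea) to the nearest data cell; `detect_outliers` flags records whose
standardized environmental fingerprint is far from the PCA centroid
(default cutoff mean + 2·SD); `thin_records` removes records until no two
are closer than a fraction of the maximum pairwise distance, using random
restarts and keeping the run that retains the most records.

**Range maps.** `map_points` marks recorded cells; `map_habitat` returns
the union of habitat patches (8-neighbour connectivity) containing
records; `run_ensemble`/`consensus_map` fit an ensemble of maxent-style
models — L1-penalized logistic regression of presences against random
background on standardized linear + quadratic features — over random
70/30 presence splits. Per-run binary maps are combined into a consensus
(cell present iff the AUC-weighted vote Σ wᵣbᵣ/Σ wᵣ > 0.5, with
wᵣ = max(0, AUCᵣ − 0.5)²) and two-sided confidence-limit maps (present in
≥ 97.5% of runs → lower CL; ≥ 2.5% → upper CL), each with its own
EOO/AOO.

**Red List Index.** For category weights w (LC=0 … CR=4, EW=EX=5),
`RLI = 1 − Σw/(5N)` over the N assessable species. `rli_bootstrap`
resamples whole species rows to get 2.5/97.5-percentile limits and flags
a change between dates as genuine when > 95% of replicate changes share
its sign. `rli_multi` handles several groups; `rli_sampled` finds how many
species a Sampled Red List Index needs for a target error.

## Worked example

```python
import numpy as np
import pandas as pd
import redlisting as rl

# Red List Index for 5 species assessed in 2000 and 2010
table = pd.DataFrame({"2000": ["LC", "EN", "EX", "LC", "CR"],
                      "2010": ["LC", "EN", "EX", "CR", "EX"]})
print(rl.rli_point(table["2000"]), rl.rli_point(table["2010"]))
res = rl.rli_bootstrap(table, reps=10_000, seed=1)
print(res.to_frame().round(2))
```

prints

```
0.52 0.31999999999999995
       rli  lower  upper
date
2000  0.52   0.16   0.88
2010  0.32   0.04   0.68
```

The group deteriorated from 0.52 to 0.32 (1 would mean every species is
Least Concern, 0 that all are extinct), but with only five species the
bootstrap limits are wide and the decline is not flagged as significant.

Range metrics on records (metres, planar):

```python
recs = rl.OccurrenceSet(np.array([[0., 0.], [10_000., 0.],
                                  [10_000., 10_000.], [0., 10_000.]]), crs="metric")
print(rl.eoo(recs), rl.aoo(recs))   # 100.0 16.0  (km²)
```

The same operations are available from the shell — `redlisting eoo
--records occ.csv`, `redlisting map-sdm ... --seed 1`, `redlisting rli
--table cats.csv --reps 1000 --seed 1` — with every stochastic subcommand
bit-reproducible under a fixed `--seed`.

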