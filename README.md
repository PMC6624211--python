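# koalasight

Spatial point-process analysis of citizen-reported wildlife sightings
— cleaning, temporal decomposition, kernel density mapping, distance
covariates, and quantification of road-proximity reporting bias in
presence-only data.

## The problem

Incidental wildlife sightings reported by the public (the motivating
case: two decades of koala sightings across South-East Queensland)
cover far more ground than systematic surveys, but they are
presence-only and effort-biased: people report animals where people
already are, above all near roads.  Before such data can inform
distribution or population estimates, the biases have to be measured.
This package implements that measurement pipeline for ecologists and
biostatisticians working with sighting databases:

1. **ingest** — validate and clean record tables (coordinate/date
   checks, removal of non-live records and of same-day
   same-location repeat reports), attribute and reporter summaries;
2. **temporal** — monthly series, multi-year period aggregation, and
   classical additive decomposition into trend + seasonal + random;
3. **spatial summaries** — tabulations by distance-to-coast band,
   elevation class, and polygon attributes (land type, region);
4. **density** — fixed-bandwidth Gaussian kernel density surfaces
   (Scott's rule) on a 1 km² grid, classified into density categories;
5. **covariates** — exact Euclidean distance rasters to each road and
   habitat class;
6. **ppp inference** — the statistical core, treating sightings as an
   inhomogeneous Poisson process with intensity λ(u) = ρ(Z(u)):
   nonparametric ρ̂(z) with 95% bands, the Berman Z1 test
   Z1 = (S − nμ)/√(nσ²), area-ranked ROC/AUC, and maximum-likelihood
   fits of the log-linear model λ(u) = exp(α + β·Z(u)) via the
   Berman–Turner quadrature device, reporting exp(β) as the per-km
   intensity multiplier.

A synthetic-data module generates complete study systems (window,
roads, habitat, coastline, elevation, regions, seasonally and
demographically structured record tables with injected duplicate and
corrupt rows) from an inhomogeneous Poisson model with known α and β,
so every stage is testable with no external data.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
synthetic 17-year study (100 × 100 km window, sighting intensity
biased toward tertiary roads with β = −1 per km):

```sh
python analysis/01_simulate.py          # writes results/synthetic/
python analysis/02_clean_and_describe.py
python analysis/03_temporal_patterns.py
python analysis/04_density_maps.py
python analysis/05_distance_covariates.py
python analysis/06_bias_inference.py    # writes results/analysis/
```

Output of the cleaning and inference steps (seed 0):

```
cleaning: 2754 rows in -> 2278 retained (27 bad coordinates, 395 non-live, 54 duplicates)
sex unknown: 57% of sightings
...
covariate          Berman Z1         p    AUC  beta/km  decrease/km
...
primary                -0.22      0.83   0.49   -0.000        0.0%
tertiary              -41.20         0   0.80   -0.960        61.7%
...
strongest discrimination: tertiary (AUC 0.80); planted bias covariate was tertiary (true beta -1.0/km)
```

Reading the numbers: the cleaning report reconciles exactly against
the generator's injected noise; the Berman Z1 of −41 (negative:
sightings sit at *smaller* road distances than the window average)
and AUC of 0.80 single out the tertiary-road covariate the scenario
actually biased, and the fitted slope β̂ = −0.96/km recovers the
planted −1.0 — an estimated 62% drop in sighting density per km of
distance from a tertiary road.  Covariates with no planted effect sit
at AUC ≈ 0.5 with slopes near zero.

The same sequence is available as one call on real inputs or a
scenario file:

```sh
koalasight simulate --seed 0 --outdir data/
koalasight analyze --config run.yaml --outdir results/run
koalasight report --outdir results/run
```

or in Python via `koalasight.pipeline.run_pipeline(RunConfig(...))`.

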