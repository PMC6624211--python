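# Methods

`koalasight` implements the analysis pipeline used to assess the
quality and biases of long-running citizen-science wildlife sighting
programs, of which the South-East Queensland koala sighting database
is the motivating case: a record table of individually reported
animals is cleaned, summarised in time and space, smoothed into
density maps, and finally treated as a realisation of a spatial point
process whose intensity is tested and modelled against distance
covariates (distance to each road class and to each
habitat-suitability class).

## Data model and cleaning

A sighting record carries a calendar date, planar coordinates (km; any
lon/lat source must be projected before entry — projection is an
ingest precondition, not a pipeline stage), sex, age class, physical
location, report status and an optional reporter id.  `unknown` is an
explicit level of every categorical attribute, never a missing cell,
because shares of unknowns are themselves reported statistics.

Cleaning applies three exclusion rules, in order, each counted in a
`CleaningReport` that must reconcile exactly to the input row count:

1. rows with unparseable dates or coordinates outside the study
   window (read-time validation flags them; `drop_invalid` removes);
2. non-live records — hospital presentations, dead or euthanised
   animals are clinical events, not observation effort;
3. same-day same-location repeats: among rows sharing (x, y, date)
   exactly one is retained.  "Same location" means equality after
   rounding to 1 m (configurable); the retained row is the one with
   the lexicographically smallest id, a deterministic and auditable
   tie-break.  Rows flagged in a `multi_animal` column (when present)
   are exempt, since deliberate multi-animal sightings are recorded
   as separate incidents at one location; without the flag the
   same-day rule wins.

`filter_live` and `deduplicate` commute on the retained set (only the
attribution of exclusion counts differs) provided duplicate groups
share a status, which the synthetic generator guarantees and real
same-animal re-reports satisfy in practice.

## Temporal decomposition

Monthly counts are decomposed additively: trend = centred moving
average of order 12 (weights 1/24, ten of 1/12, 1/24), seasonal =
month-of-year means of the detrended series re-centred to sum to
zero, random = exact remainder.  This is the classical procedure
behind `decompose()` in base R (verified against
`statsmodels.tsa.seasonal_decompose` in the test suite).  Trend and
remainder are reported as undefined (NaN) in the first and last six
months rather than extrapolated.  At least 24 months are required so
every calendar month contributes a detrended value.

## Density surfaces

Sighting density is a raw anisotropic Gaussian KDE evaluated at the
centres of the 1 km² study cells, with per-axis bandwidth from
Scott's rule for d = 2, `sigma_i = n^(-1/6) sd_i`.  No edge
correction is applied: kernel mass crossing the window boundary is
lost, so densities within a few bandwidths of the edge are deflated;
the mass-conservation tests therefore use interior patterns.  Cells
are classified into {0, >0–1, >1–2, >2–3, >3} sightings/km² with a
numerical zero floor of 1e-9 (a floating KDE is never exactly zero),
and area shares are reported per analysis period.  Evaluation is at
cell centres, not cell-integrated: at 1 km cells against multi-km
bandwidths the difference is second order.  Grid placement (edges on
integer km anchored at the window origin) is a convention; category
shares carry a corresponding grid-placement tolerance when compared
across implementations.

## Distance covariates

Each covariate Z(u) is the exact Euclidean distance from a cell
centre to the nearest geometry of one feature class (point-to-segment
for roads, zero inside polygons for habitat), computed from the
vector geometry rather than a grid distance transform, so there is no
chamfer error.  Point sampling of a covariate raster is bilinear by
default — nearest-cell lookup at 1 km resolution quantises distances
onto a few levels when features align with the lattice, which is
poison for covariate-distribution estimators — and configurable to
nearest for strict pixel-image comparisons.

## Point-process inference

Sighting locations are modelled as an inhomogeneous Poisson process,
`lambda(u) = rho(Z(u))`.

**rhohat.** The nonparametric ratio estimator
`rho_hat(z) = (n/|W|) f_hat(z) / g_hat(z)`, with f_hat a Gaussian KDE
of covariate values at events and g_hat the area-weighted KDE of the
covariate over the window, both at the same bandwidth (Scott's 1-D
rule on the event values).  Three numerical choices matter:

* g_hat is computed from the *interpolated* covariate surface on a
  4x-refined subgrid (then binned at 1/4096 of the range), so
  numerator and denominator describe the same random variable;
* both densities use reflection at the covariate range boundaries,
  without which each loses up to half its kernel mass at the edges
  and the mass-balance identity `integral rho g |W| dz = n` fails;
* the pointwise 95% band comes from the Poisson delta method,
  `Var rho_hat(z) ~ sum_i K_h(z - Z_i)^2 / (|W| g_hat(z))^2`, i.e.
  treating the kernel-weighted event count at each z as Poisson.
  This matches the fixed-bandwidth "ratio" estimator; reproducing any
  particular reweighted variant's band construction is out of scope.

**Berman test.** Z1 = (S − n·mu)/sqrt(n·sigma²) with S the sum of
covariate values at events and mu, sigma² the area-weighted moments
of the covariate over the window; two-sided normal p-value.  The
sum-based Z1 (rather than the maximum-based Z2) is used, matching the
default of the reference spatstat implementation.

**ROC/AUC.** Area is ranked by the covariate (ascending distance for
distance covariates, i.e. predicted-high-intensity first) and the
captured event fraction plotted against the cumulative area fraction.
The AUC is computed in its probability-integral form
`P(Z_event < Z_cell) + 0.5 P(=)` with area-weighted cell values —
identical to the trapezoid area over the full threshold union, exact
under orientation reversal (AUC -> 1 − AUC), and exactly equal to a
brute-force rank comparison on discrete grids.

**Log-linear model.** `lambda(u) = exp(alpha + beta·Z(u))` is fitted
by maximum likelihood via the Berman–Turner device: quadrature points
are the events plus an `n_dummy x n_dummy` dummy grid (default 80,
the conventional size), counting weights `w = tile area / points in
tile`, and a weighted Poisson GLM with log link on responses 1/w
(events) and 0 (dummy), solved by statsmodels.  Standard errors come
from the GLM Fisher information, which coincides with the
point-process information.  `exp(beta)` is the per-km intensity
multiplier and `100(1 − exp(beta))` the per-km percent decrease; a
slope magnitude above 50/km trips a unit-misuse guard (a covariate
accidentally in metres).  Multiple covariates are supported
additively, but the per-covariate fit is the documented default.  For
a single monotone covariate the fitted model's AUC coincides with the
raw covariate's AUC, so either reading of "model AUC" gives the same
number.

Counting-weight quadrature is known to carry an O(spacing) bias when
the covariate has kinks (distance fields do, along the features):
tiles containing an event evaluate part of the integral at the event
location, which sits preferentially where intensity is locally high.
The slope-recovery study therefore uses a 160² dummy grid, at which
the residual quadrature error (~0.006 on beta) is well below the
sampling standard error (~0.022) at its event count; the quadrature
convergence test uses a smooth covariate, where successive doublings
move beta by under 1e-3.

## Synthetic study systems

The generator fabricates a full study system on a rectangular planar
window: random road chords per class, disc-shaped habitat patches, a
coastline along the eastern edge, a westward-rising elevation ramp
(coastal plain to inland range, max 1,280 m), a grid of named
regions, and sighting locations from an inhomogeneous Poisson process
`lambda(u) = exp(alpha + beta Z(u))` simulated by thinning (exact for
bounded intensity; the covariate is evaluated through the same
bilinear surface the estimators see, so recovery tests are exactly
specified).  Records get dates from a 12-month seasonal profile
peaking in September–October (the austral-spring breeding season),
sex 57% unknown with the remainder split evenly, mostly-adult age and
mostly-in-tree location shares, a live/injured/dead/euthanised status
mix (85/6/7/2% — the excluded-record mix is not a published quantity;
this is a package choice), and reporter ids drawn uniformly from a
per-year pool of 550.  Reporter heterogeneity is configurable, not
calibrated: no quantitative reporter distribution is published.
Duplicate rows copy (x, y, date, status) from live records with other
attributes redrawn — a same-day duplicate report of the same animal
is by construction a live re-sighting, which also makes the injected
count exactly recoverable by the cleaning stage; corrupt rows get
coordinates displaced outside the window.  One scenario seed feeds a
splittable `SeedSequence`; every stage draws from its own child
stream, so all outputs are bit-reproducible.

The default scenario is a scaled-down analogue of a 17-year
state-scale program: a 100 x 100 km window (the real study area is
57,780 km²) with ~2,500–3,000 sightings, sized so the full pipeline
and its tests run in seconds while leaving every estimator in its
asymptotic regime.  What the generator does *not* emulate: koala
movement or home ranges, detectability beyond the log-linear covariate
link, reporter clustering in space, land-use change over time, or
coastal concentration of sightings (the synthetic coast covariate is
independent of the planted road bias).  Passing recovery tests
therefore demonstrate estimator correctness under the stated model,
not robustness to the messiness of real sighting data.

## Validation studies

`koalasight.validation` fixes four reference studies (layouts chosen
once; intercepts solved from the discretised intensity integral to
hit target event counts):

* **Berman type-I error** — 1,000 CSR patterns (E n = 300) on
  100 x 100 km against distance to a central road; rejection rate at
  the 5% level.
* **PPM slope recovery** — 200 patterns from beta = −1/km
  (E n = 3,000, roads every 10 km); mean slope estimate and empirical
  95% CI coverage.
* **rhohat recovery** — one pattern from rho(z) = exp(2 − 3z)
  (E n ~ 2,000, roads every 4 km on 40 x 40 km at 0.25 km cells,
  covariate range ~[0, 2] km); median relative error over the central
  80% of the range.
* **AUC null calibration** — 100 CSR patterns (E n = 5,000) against
  an independent covariate; mean AUC and the exactness of the
  orientation flip.

`scripts/acceptance.py` reruns all four plus one end-to-end synthetic
pipeline and writes every quantity to JSON; the test suite asserts
the same properties at fixed seeds.

## Known limitations

* No edge-corrected KDE and no inhomogeneous summary functions
  (K/pair correlation) — not part of this pipeline.
* The Berman–Turner counting-weight bias above, inherent to the
  quadrature scheme at coarse dummy grids.
* Distance-band and polygon tabulations fix one interval convention
  ([a, b), boundary points inside); results near band edges shift by
  one band under the opposite convention.
* Real-data reproduction of published headline values (AUCs, per-km
  decreases, area-share tables) requires the original sighting
  database and state GIS layers; nothing in this package downloads
  them.
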