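# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `ddxburden`, and what the synthetic-basin tests do and do
not demonstrate about real survey data.

## Chronology

All cores are synchronized on a single event horizon: the depth of maximum
DDT concentration, dated to 1955 (peak industrial discharge, independently
corroborated by radiometric chronologies in basins of this kind). The age
model is linear through (0 cm, sampling year) and (z_peak, 1955) and is
extrapolated below the peak with the same slope. Choices:

* the peak is located on **total DDT** (both isomers summed) — 4,4′
  dominates technical DDT and the sum is robust to isomer noise;
* the peak depth is the **midpoint of the argmax slice** (slices are the
  measurement resolution); ties break toward the shallower slice;
* pre-1950 material (mixed downward by bioturbation or cm-scale blending)
  keeps its model-assigned age. No mixing or compaction correction is
  applied; the model is a first-order synchronization device, not a burial
  model.

Decadal binning maps each slice's depth interval to a year interval and
assigns it to decades in proportion to overlapping thickness. The default
statistic is the thickness-weighted mean concentration; a thickness-
integrated "sum" variant is exposed because either reading is defensible
for time-slice maps.

## Inventories

Dry-weight concentrations are converted to areal mass with a two-phase
(solid grains + porewater) model: `ρ_wet = 1/(TS/ρ_grain + (1−TS)/ρ_w)`,
dry bulk density `ρ_db = TS·ρ_wet`. Defaults: grain density
2.5832 ± 0.0049 g/cm³ (basin-composite measurement), porewater
1.025 g/cm³ (seawater). This is the only dimensionally consistent way to
combine per-slice % total solids with a single grain density; it neglects
gas voids and salt correction.

Profiles are integrated over 1-cm layers to 30 cm. Values at unmeasured
depths are linearly interpolated between slice midpoints; beyond the
outermost midpoints the nearest measured value is extended **constantly**
(linear extrapolation can go negative; the unmeasured deep intervals are
low-concentration, so the policy has little leverage). Missing % total
solids in a slice is filled from neighboring slices, or a basin default of
0.35 with a logged warning. Refining the grid to 0.5 cm changes smooth-
profile inventories by <0.5% (tested).

Mini piston cores (vertically integrated 0–12 cm, sometimes 12–24 cm
composites, taken in triplicate) are stored as interval-mean
concentrations, converted with the station's mean ρ_db over the interval,
and scaled to full 0–30 cm inventories using the sliced profile's DDX
fractions f₁/f₂/f₃ per depth interval: with only 0–12 cm sampled, the
scaled inventory is (areal content)/f₁; with both intervals,
(sum)/(f₁+f₂). A station whose reference profile holds no mass in the
sampled interval cannot be scaled and is flagged.

## Natural-neighbor interpolation

Sibson weights are the Voronoi-cell areas a query steals upon insertion.
Two routes are implemented:

* **geometric (exact)** — every cell, including the inserted query's, is
  built by clipping a large box with perpendicular-bisector half-planes
  (sites sorted by distance, with an early stop once no remaining bisector
  can cut the current polygon); stolen areas are convex-polygon
  intersections. Direct half-plane clipping avoids the cocircular-site
  degeneracies of incremental Delaunay construction, so no symbolic
  perturbation is needed. Exactness at sites, Σw = 1 (to 1e-9), linear
  precision, and ≤1-percentage-point agreement with an independent
  discrete oracle (rasterized Voronoi area counting) are all under test.
* **discrete (rasterized)** — every fine-raster pixel knows its nearest
  site; a query steals the pixels closer to it than to their sites. The
  per-query counting form is the test oracle. A numba-compiled whole-grid
  form inverts the loop (each pixel "splats" its site's value onto all
  grid cells that would steal it) and makes the tens of thousands of
  surface evaluations inside the jackknife tractable; its raster extends a
  margin (default 30% of the grid dimension; 15% inside the resampling
  loops) beyond the grid so boundary queries keep their full stolen
  regions.

Queries outside the station hull have no bounded inserted cell. The
default policy masks such cells and reports the masked fraction (warning
above 20%); a "nearest" policy fills them with the nearest station's value
for full-polygon maps and is flagged as extrapolation. Interpolated values
are convex combinations of the data, hence bounded by the data range.

Grid resolution defaults to 250 m (~13 000 cells for an 814 km² basin);
burden means change negligibly down to 125 m because the integral is an
average. The resampling procedures use 500–1000 m grids.

## Uncertainty procedure 1: jackknife–bootstrap

Stations are randomly partitioned into N disjoint near-equal subsets
(sizes differ by ≤1); each subset is interpolated and integrated to its
own mean-inventory estimate, and σ is the sample standard deviation
(ddof = 1) across the N estimates. This is repeated B times (default
1000) for each N in 2…9, the per-N mean σ is fitted with an ordinary
least-squares quadratic in N, and the fit is evaluated at N = 1 — never
below — as the uncertainty of the all-station estimate. Per-iteration σ
values are retained (their per-N distributions give the standard error of
each mean σ). A partition producing a collinear subset is redrawn (at
most 100 times, logged). Partitions require 3N ≤ n_stations so every
subset supports a surface.

The fit uses per-N **means** of σ rather than the pooled per-iteration
values; with equal B per N the two give the same least-squares solution,
and the means are the natural summary of the bootstrap distributions.

## Uncertainty procedure 2: Monte Carlo patchiness propagation

At stations with triplicate mini-cores, the sliced core and the three
scaled replicates are four measurements of the same site; their
cross-section-weighted mean and weighted standard deviation define a
Normal site distribution. Weights default to 12:1:1:1 (the sliced core's
cross-section is ~12× a mini core's); exact areas may be supplied. The
weighted SD uses the **reliability-weight (unbiased) form**
`√(Σw(x−x̄)² / (V₁ − V₂/V₁))`, which reduces to the ordinary ddof = 1
sample SD for equal weights; the frequency-weight form is available
behind a flag. Stations without triplicates get a relative SD equal to
the mean relative SD of the triplicate stations (56.5% is the fallback
constant when no triplicates exist at all).

Each of 1000 iterations draws every site from Normal(mean, sd) —
negative draws are redrawn, since negative inventories are unphysical;
this truncation skews the mean upward slightly and its direction is
asserted in tests — then interpolates and integrates. Because the grid
geometry is fixed, the Sibson weight matrix is computed once with the
exact interpolator and each iteration is a matrix product. The estimate
is the mean and SD of the iterated totals, reproducible bit-for-bit from
the seed.

## Spatial autocorrelation

The correlogram statistic is Moran's I with binary distance-class
weights, the standard correlogram convention (the statistic behind the
qualitative "autocorrelation declines with distance" observation is an
interpretation; no specific formula is canonical for such statements).
Default bins: 8 equal-width classes to half the maximum pairwise
distance. One-sided p-values come from value permutations
(p = (1 + #{I_perm ≥ I}) / (B + 1)); they are uniform under the null
(tested by KS over simulated datasets).

## Synthetic basin generator

The generator emulates the structure the analysis assumes, with known
ground truth:

* a 40.7 × 20 km rectangle (814 km²), 54 stations on a jittered grid;
* DDT latent field: 150 µg/kg background + a NE–SW Gaussian ridge
  (3000 µg/kg, 4 km width) + a Gaussian hotspot (52 000 µg/kg, 1.2 km
  radius) at the western periphery. One station is snapped onto the
  hotspot center — a survey that knows a dumpsite targets it, and the
  observed >50 000 µg/kg maximum requires that it be sampled;
* DDD = 0.4 × the DDT field (in-situ dechlorination product);
* DDE: 100 µg/kg background + a 1200 µg/kg band + a 2500 µg/kg gradient
  decaying (5 km e-folding) from the northern shelf edge, where the
  adjacent contaminated shelf feeds ongoing deposition. Amplitudes were
  set so DDE carries roughly half the DDX burden, with DDT > DDD making
  up the rest, the composition such basins show;
* depth structure: DDT/DDD Gaussian peaks (σ = 1.8 cm) at a per-station
  peak depth uniform in 5–9 cm; DDE broader (σ = 4 cm) with a surface
  tail (recent deposition). Slices are 2-cm composites (sub-slice
  quadrature), % total solids ramps 0.25 → 0.45 over 30 cm;
* noise: one mean-preserving lognormal **patch factor per core (or
  mini-core replicate)**, driven by a single shared deviate across
  analytes with analyte-specific CVs (DDT/DDD 56.5%, DDE 20%), plus a
  smaller per-slice jitter (15% of the CV). The shared deviate makes the
  replicate that is high in DDT also high in DDE — the one-high-replicate
  pattern real triplicates show — and makes triplicate spread reproduce
  the configured CV (tested by pooled log-scale variance);
* an optional downward-smearing kernel emulates pre-peak (1940s) presence
  from bioturbation; off by default.

Ground truth integrates the noise-free latent field by dense quadrature
(≤50 m cells, 0.05 cm depth steps) using the central peak depth; the
per-station peak-depth jitter conserves the depth-integral, so it does
not bias the truth.

What the generator does **not** emulate: bathymetric steering of
deposition, compaction gradients, correlated (non-white) station noise,
detection limits and censoring, and any spatial structure in % total
solids beyond the depth ramp. Passing tests demonstrate the procedures'
internal calibration under these idealized conditions, not field
accuracy.

A note on bias the tests make visible: because the hotspot is narrower
than the station spacing and is sampled at its peak, natural-neighbor
interpolation spreads the peak value over the hotspot station's whole
neighborhood and the point estimate exceeds the ground truth by ~10–25%
depending on the seed. That is a property of interpolating under-resolved
hotspots, not an implementation artifact; the jackknife σ at N = 1
brackets it, and the Monte Carlo ±3σ covers the truth in ≥99% of seeded
experiments because the triplicate-derived site SDs carry the same
patchiness that drives the bias.

## Problem sizes in the test suite

The statistical acceptance checks run scaled-down but statistically
meaningful configurations chosen as a deliberate accuracy/effort
trade-off: jackknife stability at B = 200 (seed pairs agree within 10%),
Monte Carlo coverage over 200 basins at 60 iterations on a 1-km grid,
end-to-end recovery over 100 basins with B = 15 jackknives. Monotonicity
of mean σ in N is asserted within twice the bootstrap standard error of
each mean, the precision B = 200 supports.

## Known limitations

* The geometric interpolator is O(n) per query with small constants; for
  thousands of sites a Delaunay-walk implementation would be preferable.
* The equirectangular lon/lat helper is adequate only at basin scale.
* Age models assume constant accumulation between anchor points and
  ignore compaction.
* The mini-core scaling assumes the sliced profile's depth partition of
  DDX applies to the mini-cores' patch; patchiness that changes the depth
  *shape*, not just the amount, violates this.
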