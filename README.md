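# ddxburden

Basin-scale burden analysis for DDT and its breakdown products in marine
sediments.

Decades of offshore waste disposal left DDT-family contamination spread
across deep coastal basins. Surveys of such basins collect sediment cores
at tens of stations, slice them at cm resolution, and quantify the six
DDX congeners (2,4′- and 4,4′- isomers of DDT, DDD and DDE, collectively
"DDX") in each slice. `ddxburden` turns those depth-resolved concentration
profiles into the quantities such a survey reports:

* **chronologies** — per-core linear age–depth models anchored at the
  peak-DDT horizon (≡ 1955, the era of peak industrial discharge), and
  decadal binning of concentrations for time-slice maps;
* **areal inventories** — mass per unit seabed area over the top 30 cm
  (mg/m²), converting dry-weight concentrations with site-specific % total
  solids and a basin grain density via a two-phase sediment model;
* **interpolated surfaces and total burden** — natural-neighbor (Sibson)
  interpolation of station inventories onto a grid clipped to the study
  polygon, integrated to a basin total in tonnes;
* **uncertainty** — two resampling procedures: a jackknife–bootstrap that
  partitions stations into N = 2…9 subsets, measures the spread of
  subset burden estimates, and extrapolates the σ-versus-N trend to N = 1
  with a quadratic fit; and a Monte Carlo that propagates cm-scale
  patchiness measured by triplicate mini piston cores (cross-section-
  weighted site distributions, 1000 interpolation draws);
* **spatial statistics** — Moran's I correlograms of station inventories
  with permutation p-values;
* **a synthetic basin generator** with known ground truth (NE–SW
  concentration band, a >50 000 µg/kg hotspot, a shelf-edge DDE gradient,
  multiplicative lognormal patchiness), so the whole pipeline is testable
  end-to-end.

## The core computation

For each station the top-30-cm inventory of congener *c* is

```
I_c = Σ_z  C_c(z) · ρ_db(z) · Δz · 0.01        [mg/m²]
ρ_db = TS · ρ_wet,   ρ_wet = 1 / (TS/ρ_grain + (1−TS)/ρ_water)
```

with `C_c` in µg/kg dry, 1-cm layers to 30 cm (gaps filled by linear
interpolation between slice midpoints), `TS` the dry-mass fraction,
`ρ_grain = 2.5832 g/cm³` and `ρ_water = 1.025 g/cm³`. Station inventories
are interpolated with Sibson weights — the areas a query point steals from
each station's Voronoi cell upon insertion — and the basin burden is

```
T = mean(inventory over in-polygon cells) · A · 10⁻⁹    [tonnes]
```

## Worked example

```python
import numpy as np
import ddxburden as d

stations, truth, area = d.generate_basin(d.BasinConfig(seed=1))
invs = {s.id: d.areal_inventory(s.profile, station_id=s.id) for s in stations}
xy   = np.array([(s.x, s.y) for s in stations])
vals = np.array([invs[s.id].inventory["ddx"] for s in stations])

surf  = d.interpolate_surface(xy, vals, area, resolution=500)
point = d.integrate_burden(surf, area)
jk    = d.sigma_trend(xy, vals, area,
                      d.JackknifeConfig(bootstrap_iters=200, seed=2,
                                        resolution=750))
dists  = d.site_distributions(stations, invs)
mc, _  = d.monte_carlo_burden(dists, xy, area,
                              d.McConfig(iterations=1000, seed=3,
                                         resolution=750))

print(f"mean inventory {point.mean_inventory:.1f} mg/m^2 "
      f"-> burden {point.total:.1f} t (truth {truth.burden['ddx']:.1f} t)")
print(f"jackknife sigma at N=1: {jk.sigma_at_1:.1f} mg/m^2")
print(f"Monte Carlo: {mc.total:.1f} +/- {mc.sigma:.1f} t")
```

prints (54 stations over an 814 km² basin):

```
mean inventory 118.8 mg/m^2 -> burden 96.7 t (truth 76.2 t)
jackknife sigma at N=1: 49.3 mg/m^2
Monte Carlo: 98.3 +/- 15.2 t
```

The point estimate sits above the ground truth because one station samples
the peak of a hotspot narrower than the station spacing, and the
interpolation spreads that peak over the station's whole natural-neighbor
region — exactly the hotspot sensitivity that motivates the two resampling
procedures. The jackknife σ at N = 1 (the uncertainty assigned to the
all-station estimate) comfortably brackets the truth; the Monte Carlo mean
exceeds the point estimate slightly because negative inventory draws are
redrawn.

A command-line interface mirrors the stages
(`ddxburden simulate|agemodel|inventory|surface|burden|jackknife|montecarlo|correlogram|report`);
`report` chains the whole pipeline into one `summary.json`.

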