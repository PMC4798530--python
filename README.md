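# lucarbon

Tier 3 carbon bookkeeping for net CO₂ emissions from land-use change.

National greenhouse-gas inventories often treat forest as either intact or
permanently cleared. Real landscapes are messier: forests are cleared,
degraded by logging and fire, abandoned and regrown, and both aboveground
and soil carbon respond gradually. `lucarbon` implements the spatially
explicit bookkeeping approach (IPCC "Tier 3") for exactly this setting: a
10×10 km pixel grid observed at decadal epochs (1990/2000/2010), with
per-pixel forest type, biomass and soil-carbon densities, stepped through
annual sub-pixel cohorts. It is aimed at researchers estimating national or
regional land-use-change emissions from coarse land-cover time series.

## The model

**Equilibrium stocks.** Mature aboveground carbon per forest type
`v` is `CAP_v = f_C · q_p(B_v)`, the `p`-th percentile (50 baseline, 25 in
sensitivity) of the intact-pixel biomass distribution times the carbon
fraction `f_C = 0.5`. Root carbon is `R = CAP_v · r_v` with a per-type
root:shoot ratio; cropland/pasture hold 5 tC/ha aboveground.

**Regrowth.** Aboveground carbon of regrowth of age `a` follows a logistic

```
CAR_{v,a} = CAP_v / (1 + exp(α_v − β_v a))
```

with `(α_v, β_v)` solved in closed form from two boundary conditions:
`CAR_{v,0} = 5 tC/ha` and `CAR_{v,t99} = 0.99 CAP_v`, where `t99` is
40 years for humid and 35 for dry/seasonal forest.

**Soil carbon.** Under agriculture, soil organic carbon (top 100 cm) falls
linearly by 25% of its undisturbed value over 20 years, then stays flat;
after abandonment it recovers linearly at half the decomposition slope
(full recovery in 40 years). Converting forest to pasture or other
vegetation leaves soil carbon intact.

**Degraded forest.** Forest observed as regrowth without prior clearing is
degraded, not regenerating: it is assigned the carbon of 25-year-old
regrowth (≈85% of mature carbon; 15 years ≈45% in the severe variant),
soil untouched.

**Bookkeeping.** Each decadal transition converts one tenth of the
transitioning area in each year of the decade (timing within the decade is
unobserved). Net flux is mass balance: `(stock_start − stock_end) · 44/12`
tCO₂, emission positive. A Tier 1 comparator — average annual forest loss ×
mean carbon density × 44/12 — and a seven-scenario sensitivity engine
(percentile choice, pasture share, soil-loss fraction, degradation
severity, erosion from static land, mature-forest sink) sit on top.

Because the national GIS inputs are not redistributable, the package ships
a synthetic landscape generator whose national-like preset reproduces the
published aggregate structure: forest cover scaling as 56.8 → 55.0 → 52.6
Mha and share-weighted mean intact carbon of 114 tC/ha.

## Worked example

```python
import lucarbon as lc

cfg = lc.gen_national_like(n_pixels=400, seed=42)
grid, biomass, admin = lc.gen_landscape(cfg)

params = lc.build_params({}, biomass)          # CAPs + calibrated curves
result = lc.run_grid(grid, params)             # the Tier 3 engine
print(lc.summary_table(result.pixels, admin).round(2).to_string(index=False))
```

```
   period  total_tco2  avg_annual_tco2  mid_period_population  per_capita_tco2  mid_period_gdp_thousand_bs  per_gdp_kg_bs
1990-2000 41005560.32       4100556.03              6987201.0             0.59                  18626778.0           0.22
2000-2010 80566878.31       8056687.83              8873150.0             0.91                  26657738.0           0.30
```

Each row is one decade on the 400-pixel (4 Mha of simulated territory)
synthetic landscape: total and average-annual net CO₂ emissions from
land-use change, and the per-capita (tCO₂/person/yr) and per-GDP (kg CO₂
per 1990 Boliviano) rates against the mid-period denominators. Emissions
roughly double between decades because clearing accelerates in the second
transition matrix. Absolute magnitudes are far below the national
estimates simply because the grid covers ~4% of the national area; the
within-run structure (mass balance, scenario ordering, departmental
shares) is what the package reproduces. The Tier 1 comparator from the
published decade-two inputs:

```python
lc.tier1(2_431_200, 0, mean_agc=114.0, years=10)   # 101,624,160 tCO2/yr
```

A shell interface mirrors the library (`lucarbon synth | validate | run |
scenarios | tier1 | curves`); `lucarbon run config.yaml --outdir out/`
writes the pixel, department, municipality, scenario and summary tables
plus a manifest with config and output digests.

## Layout

- `src/lucarbon/params.py` — CAP estimation, logistic calibration, parameter assembly
- `src/lucarbon/dynamics.py` — regrowth curve, inverse age, soil-carbon stepper
- `src/lucarbon/bookkeeping.py` — the cohort engine (pixels → annual fluxes)
- `src/lucarbon/scenarios.py` — sensitivity variants, static-land fluxes, Tier 1
- `src/lucarbon/reporting.py` — admin aggregation, per-capita/per-GDP, classification
- `src/lucarbon/synth.py` — synthetic landscape generator and national-like preset
- `src/lucarbon/pipeline.py`, `cli.py` — end-to-end runs and the CLI

See `docs/methods.md` for modelling assumptions, defaults and limitations.
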