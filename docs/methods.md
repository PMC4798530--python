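# Methods

## Model

`lucarbon` is a bookkeeping (stock-difference) model of land-use-change
carbon. The unit of account is the cohort: a sub-pixel area fraction
sharing a land-cover class, conversion year, regrowth age and soil-carbon
history. Pixels are observed at three epochs (1990, 2000, 2010) in five
satellite classes — forest, regrowth, agriculture, other vegetation,
non-vegetated — and the engine expands each decadal class change into
annual conversion events, steps every cohort through closed-form carbon
curves, and reports the annual net CO₂ flux as the change in total stock
(shoots + roots + soil) times 44/12, emission positive.

Key assumptions, in the order the method applies them:

- **One predominant forest type per pixel.** Mature aboveground carbon
  (CAP, tC/ha) is a property of the type, estimated as carbon fraction
  (0.5) times a percentile of the intact-pixel biomass distribution —
  the 50th at baseline, computed by linear interpolation between closest
  ranks (the standard numerical-library rule; recorded in config since no
  convention is canonical).
- **Logistic aboveground regrowth.** `CAR(a) = CAP/(1+exp(α−βa))`, with
  `(α, β)` solved exactly from `CAR(0) = 5 tC/ha` (the cropland/pasture
  level) and `CAR(t99) = 0.99·CAP`, `t99` = 40 y (humid) or 35 y
  (dry/seasonal). Curves are evaluated at integer ages; time is discrete
  in whole years, matching the decadal observation granularity. Per-type
  `α, β` overrides are accepted so externally published curve parameters
  can be dropped in; with the two-point calibration, 15-year regrowth
  holds ≈45% of CAP (published severe-degradation figures based on
  slightly different curve parameters sit near 41%).
- **Clearing is instantaneous aboveground.** Conversion to agriculture
  drops aboveground carbon to 5 tC/ha in the conversion year. Root carbon
  tracks aboveground carbon through a constant root:shoot ratio (defaults
  0.24 humid / 0.28 dry, overridable): released with the shoots at
  clearing, rebuilt along the logistic. No root-specific decay curve is
  modelled; a gradual root pool is the natural config extension point.
- **Linear soil dynamics.** Under agriculture, soil organic carbon (top
  100 cm) declines by `soc_loss_frac` (0.25) of its undisturbed value
  linearly over `soc_loss_horizon` (20 y), then is constant; recovery
  runs at half that slope, so any tillage episode takes exactly twice as
  long to undo. Re-clearing resumes decomposition from the current level,
  not the map value. Conversion to pasture (scenario) or other vegetation
  leaves soil intact; vegetated classes recover any standing deficit;
  bare land is frozen.
- **Degradation by history.** Forest observed as regrowth that was never
  cleared is degraded forest: aboveground carbon of 25-year regrowth
  (15 y in the severe variant), soil intact. Degraded land observed as
  regrowth again stays at that level; observed as forest, it climbs the
  logistic from its equivalent age. Land reaching forest/regrowth from
  agriculture or other vegetation is seeded at the equivalent age of its
  current carbon, which avoids fictitious instantaneous uptake on the
  "odd" satellite transitions (e.g. other vegetation → forest).
- **Within-decade timing is unobserved**, so one tenth of a transitioning
  area converts in each year of the decade (a midpoint rule is available
  in config). Events apply at the end of each simulated year, after aging
  and soil stepping, so a slice cleared in year `k` accrues `10−k` years
  of soil decomposition within the decade — this makes the engine exactly
  equal to the analytic uniform-cohort sum the tests check it against.
- **Never-forested pixels carry zero land-use-change flux**; they still
  contribute to the erosion adjustment, which is accounted separately.

## Scenarios

Seven named scenario specifications cover the sensitivity set: baseline;
25th-percentile CAP ("clearing less dense forest first"); 20% pasture
share with intact soil; 35% soil loss ("aggressive agriculture"); 15-year
degradation ("severely degraded"); soil-erosion emissions from static
non-forested land (80% of that area losing 1% of soil carbon per year, of
which 1.5% oxidises to CO₂; the stock depletes year-on-year by default,
with a constant-stock mode provided since either reading is defensible —
they differ by <5% over a decade); and a mature-forest sink (static
forest gains 4% of CAP·(1+root:shoot) per decade, linearly per year). The
erosion and sink fluxes are computed per pixel and period from the cover
columns and added to the engine's national totals; the engine itself
remains a pure land-use-change ledger. The Tier 1 comparator is the
committed-emissions closed form: mean annual mature-forest loss × mean
aboveground carbon density × 44/12, ignoring regrowth, degradation and
soil.

## Synthetic landscapes

The generator emulates the statistical structure of the study inputs, not
their geography: per-type intact biomass is lognormal around a configured
median (log-sd 0.30, a right-skewed spread comparable to intact-forest
biomass distributions); soil carbon is uniform on 30–140 tC/ha; covers
evolve by independent per-pixel sampling from decadal transition
matrices; departments and municipalities partition pixels with configured
weights and carry mid-period population and GDP. The national-like preset
encodes a gross-flow table whose expected forest areas scale exactly to
the 56.8 → 55.0 → 52.6 Mha national trajectory (0.37%/yr average loss)
and whose nine forest-type shares and median biomasses give a
share-weighted mean intact carbon of 114 tC/ha; its population and GDP
are the published national mid-period figures split across departments by
plausible fixed shares.

What the generator deliberately omits: spatial autocorrelation of
clearing, mixed pixels at observation time (sub-pixel mixing arises only
through the engine's cohorts), classification error, and any correlation
between biomass and deforestation risk. Passing tests therefore
demonstrate correctness of the accounting and the direction/magnitude
structure of the scenario engine, not agreement with national absolute
totals, which depend on the unreleased GIS grid.

Initial 1990 state (fallow age structure unobserved): regrowth pixels are
ten equal cohorts aged 1–10; agricultural pixels are assumed 10 years
into tillage (soil at 87.5% of reference); both are config options, as is
starting mature forest at the pixel's mapped carbon instead of CAP.

## Numerical choices

- Area fractions are conserved to 1e-9 within every pixel-year and checked;
  per-decade mass balance (flux = Δstock·44/12) holds to 1e-9 relative.
- The inverse regrowth curve clamps: carbon ≤ the age-0 value maps to age
  0, ≥ 99% of CAP maps to t99; round-trips are exact to 1e-6 years.
- Classification uses an inclusive ±10 tCO₂/km²/yr neutral band and an
  inclusive −1 tCO₂/person/yr municipal-sink threshold (inclusivity is a
  package decision; the bands themselves are the study's).
- Everything is deterministic given the config and seed; reruns are
  bit-identical and the pipeline manifest records config and output
  digests.
- Default test problem sizes (250–1,000 pixels) keep the whole suite
  under a few seconds while leaving sampling noise well inside the
  asserted tolerances (binomial/percentile checks use ≥2 s.e. bands).

## Limitations

- No litter or deadwood pools, no sub-annual dynamics, no fire/logging
  attribution of degradation — outside the model's scope.
- Root carbon has no independent dynamics; its release and rebuild are
  slaved to aboveground carbon.
- Erosion restarts from the reference soil stock each decade rather than
  carrying depletion across periods (the decade totals differ
  negligibly at the configured 1%/yr rate).
- The synthetic national preset reproduces aggregate structure, not
  spatial pattern; departmental results on synthetic grids are
  illustrative only.
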