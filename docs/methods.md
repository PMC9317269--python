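# Methods

## Scope and model

`paddyval` values ten ecosystem services of an integrated rice–fish–duck
terrace system, tagged with CICES V5.1 sections (Provisioning, Regulation
& Maintenance, Cultural). Each service is a closed-form product of
scenario parameters; there is no process simulation. Emission fluxes,
evaporation, infiltration and uptake rates are inputs taken from
monitoring or literature, not modelled. All values are computed per
hectare first and scaled by the site area once, so every component is
exactly linear in area.

### Valuation methods by service

* **Provisioning (V1), market price.** Gross revenue of rice, fish, duck
  and egg output. Deliberately gross: input costs (seed, feed, labour)
  are a farm-profit question, not a service value. Ducks and eggs are
  ordinary `ProductSpec`s with count units (the bundled scenario lists
  drakes, 150/hm², and female ducks, 225/hm², separately; the engine sums
  them), keeping V1 a single homogeneous sum.
* **Gas regulation (V2), afforestation cost + GWP.** Credit side: carbon
  in fixed CO₂ (Tr·a·b·M_C) priced at the afforestation cost C_C
  (327.32 CNY/t C, 2020), plus released O₂ (Tr·a·c) at the industrial
  oxygen price (1072.21 CNY/t). Debit side: season CH₄ and CO₂ emissions
  converted to CO₂-equivalent at GWP d = 24.5 kg CO₂-eq/kg CH₄ — the
  study-area convention, configurable where users prefer an IPCC AR
  value — then priced through the same carbon-cost chain. The three terms
  are netted unrounded; the net is allowed to be negative and typically is.
* **Climate regulation (V3), replacement cost.** Seasonal cooling
  evaporation Qt = E·Tn (mm) converted to standard coal at e = 30.57 t
  per 50 mm per hm². The parameter is stored exactly in its per-50-mm
  form and the /50 applied inside the operation, so the t/hm² coal figure
  is an inspectable intermediate.
* **Air purification (V4), replacement cost.** Σ(flux × removal cost)
  over dust, SO₂, HF, NOx, at source-year prices, carried to the
  valuation year by a price-index ratio. A published already-adjusted
  per-area value can be supplied instead and takes precedence.
* **Pest control (V5) and biodiversity (V6), flat per-area rates.** V5 is
  the avoided pesticide spend relative to monoculture (hence zero in the
  monoculture baseline by construction); V6 is the equivalence-factor
  biodiversity value (factor 0.21 of baseline grain income, supplied
  already price-adjusted).
* **Water regulation (V7), replacement cost.** Infiltration f × standing-
  water days × agricultural water tariff × area.
* **Soil conservation (V8), fertilizer replacement.** Nutrient stock of
  the tillage layer (depth × bulk density × Σ(SOM+TN+TP+TK)) priced at
  fertilizer cost, with explicit unit bookkeeping (hm² → m², g/cm³ →
  kg/m³, g/kg → mass fraction).
* **Soil organic accumulation (V9), carbon budget.** Input
  I_soc = N_t·5·C_r + N_s·0.11·C_s (the ×5 expands measured root biomass
  to the whole root system; 11% is the straw fraction returned to the
  field); output O_soc = R_CO₂·0.27 + R_CH₄·0.75 (carbon fractions of the
  two gases); balance priced at the pure-carbon organic fertilizer price.
  B_soc + O_soc = I_soc holds exactly.
* **Cultural (V10), simulated market.** Either the festival-visitor share
  of annual tourism revenue, (N_rff/N_tour)·R_z, or a published per-area
  landscape-tourism unit value × area. The bundled scenario uses the unit
  value (17,262 CNY/hm²) because the revenue-partition inputs are not
  separately available.

## Monetary conventions

The canonical internal unit is plain CNY as a double; 万 (10⁴), million
and billion exist only at the reporting boundary. Source material in this
domain mixes all four scales and contains scale slips, so the engine never
stores a scaled number. Rescaling round trips are exact to one ulp
(the factors are powers of ten, not of two). Rounding to 2 decimals in 万
happens only in the CSV report writer; JSON reports carry full precision.
Every `Money` carries a price reference year; combining different years
raises, and price-index ratios (config constants, since published indices
are usually only available as before/after value pairs) are the only way
to move between years. Chained adjustment is multiplicative.

## Overrides and provenance

Three reported quantities in the bundled scenario are not reproducible
from their own published formula inputs, so the config carries them as
explicit, named overrides and the run log records the path used per
component:

* **GHG totals.** The monitored season totals (585,315 kg CH₄;
  788,577,460 kg CO₂) imply effective emission periods of ≈131 and ≈158
  days, not the 180-day growing period the flux product A·D·g would use.
  The engine supports both paths; the fixture uses the monitored totals so
  downstream values match the study, and the flux path remains for new
  sites.
* **Soil conservation.** The literal formula gives ≈367,254 CNY/hm²
  (≈4.91 billion CNY over the site), irreconcilable with the reported
  component value of 58.5764 万. The engine always reports the
  literal-formula value and the fixture aggregates the reported override,
  keeping the headline total reproducible while exposing the inconsistency.
* **Soil organic accumulation.** The formula yields ≈73.70 million CNY;
  the reported component is 7562.99 万 (≈75.63 million, ≈2.6% higher, with
  no stated reconciliation). Same override mechanism.

One deliberate unit decision: the water-infiltration rate is stored in
m³/(hm²·d). Literature tables quote "7.22 mm/d", but only the
m³/(hm²·d) reading reproduces the reported 3.09 million CNY water value
(the mm/d reading is exactly 10× larger). Configs must name the unit
(`m3_per_hm2_day` or `mm_per_day`); mm/d inputs are converted (×10) at
load time. Likewise the CO₂ carbon fraction is stored as the conventional
rounded 0.2727 rather than 12/44 at full precision, matching the worked
example bit for bit; both are configurable.

## Aggregation and comparison

`aggregate` sums components sharing one reference year and computes
percentage shares; negative components produce negative shares (gas
regulation: −0.58% in the bundled scenario). `compare_scenarios`
differences two valuations with identical labels; the added proportion is
added/baseline (default) or added/new — published comparison tables mix
the two conventions without saying so, hence the convention is explicit
in the API and named in every report row. The monoculture baseline ships
as reported per-service values only, because no independent parameter set
for it is available; re-deriving it from first principles is out of scope.
The reported provisioning added-proportion of 208.66% is arithmetically
inconsistent with its own row (132,997.8/43,088.88 ≈ 308.7%) and is not
reproduced under either convention; the engine reports the arithmetic.

## Synthetic survey

The generator emulates a ~100-household questionnaire survey: thirteen
observables (plot area, four yields/stock counts, four prices, four soil
nutrient contents) drawn independently per household from truncated-normal
(or mean-matched lognormal) distributions whose locations are the scenario
parameter means. Defaults: n = 100 households, CV = 0.10 for every
observable — the source survey reports only means, so dispersion is a
modelling knob chosen as typical smallholder between-farm variability, and
is never presented as an observed quantity. Mean plot area defaults to
1 hm², a typical smallholder terrace holding; it does not enter per-area
estimation. Prices vary per household (local market variation), but the
estimator aggregates as mean yield × mean price, matching how survey means
feed a per-area valuation (not the mean of per-household products, which
would differ under yield–price correlation; none is modelled).

Estimation is the unweighted household mean with nonparametric bootstrap
95% intervals (default 1000 resamples, seeded). Parameter recovery at the
survey's own size (CV = 0.10, n = 100) keeps the estimated per-area
provisioning value within 5% of truth in ≥95% of 200 seeded replicates,
and mean absolute error shrinks ~1/√n across n = 100/1,000/10,000.
The generator does not model survey weights, nonresponse, correlation
between observables, or any socioeconomic covariates (placeholder fields
only), so passing tests demonstrate estimator correctness under clean
sampling noise — not robustness to real survey pathologies.

## Numerical choices and problem sizes

* All intermediate math is unrounded double precision; tolerances in the
  test suite are 1e-9 relative for formula-oracle equivalence and 0.1%
  (0.5% for the internally inconsistent air per-area figure) against
  reported study values.
* Degenerate inputs: zero area, zero days, zero fluxes and zero rates all
  propagate to exact zeros; an empty product list, by contrast, is an
  error (a provisioning valuation of nothing is a config mistake).
* Zero-truncation of normal draws is by rejection resampling — bias is
  negligible at the default CV and the sample mean stays at the location.
* Zero denominators in comparison proportions yield `None` (rendered as a
  missing value), not an exception, since a zero-valued baseline row is
  legitimate.
* Problem sizes: the valuation itself is closed-form over ten components
  (milliseconds); property suites use 100 random parameter draws; survey
  checks use 200 replicates of 100 households plus single runs at up to
  10,000 households. The whole suite completes in a few seconds.

## Known limitations

* No mechanistic flux, water-balance or nitrogen modelling; all rates are
  exogenous.
* Single currency (CNY); no exchange-rate handling — published USD
  equivalences for this system are internally inconsistent and are not
  reproduced.
* Price-index ratios are config constants, not a CPI time-series lookup.
* The monoculture baseline is only as good as its reported component
  values; no uncertainty is attached to the comparison.
* CICES tagging is at section level only (Provisioning / Regulation &
  Maintenance / Cultural), not the full class hierarchy.
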