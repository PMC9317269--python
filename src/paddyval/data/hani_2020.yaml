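# Honghe Hani terraces integrated rice-fish-duck system, 2020 prices.
# All parameters are survey/monitoring/literature constants for the study
# area; overrides carry reported totals that the simple formulas do not
# reproduce (monitored GHG totals; reported soil component values).
metadata:
  name: hani_rice_fish_duck_2020
  valuation_year: 2020
  currency: CNY

site:
  area_hm2: 13373.33
  growing_period_days: 180
  hot_days: 60
  standing_water_days: 160

products:
  - {name: red_rice, yield_per_hm2: 5370, yield_unit: kg, unit_price_cny: 6.0}
  - {name: common_carp, yield_per_hm2: 750, yield_unit: kg, unit_price_cny: 50.0}
  - {name: duck_eggs, yield_per_hm2: 21600, yield_unit: count, unit_price_cny: 2.0}
  - {name: drakes, yield_per_hm2: 150, yield_unit: count, unit_price_cny: 50.0}
  - {name: female_ducks, yield_per_hm2: 225, yield_unit: count, unit_price_cny: 50.0}

gas:
  rice_yield_t: 73600          # total red-rice output of the prefecture's terraces
  economic_coefficient: 0.5
  co2_per_rice: 1.63           # g CO2 fixed per g rice dry matter
  o2_per_rice: 1.19            # g O2 released per g rice dry matter
  carbon_fraction: 0.2727      # C mass fraction of CO2
  gwp_ch4: 24.5                # kg CO2-eq per kg CH4
  afforestation_cost_cny_per_t_c: 327.32
  oxygen_cost_cny_per_t: 1072.21
  ch4_flux_kg_per_hm2_day: 0.334
  rice_co2_flux_kg_per_hm2_day: 272.04
  soil_co2_flux_kg_per_hm2_day: 102.35
  # monitored season totals; the area x days x flux product does not
  # reproduce them, so they are applied as an explicit override
  ghg_totals_override: {ch4_kg: 585315, co2_kg: 788577460}

climate:
  evaporation_mm_per_day: 3.83
  coal_t_per_50mm_hm2: 30.57
  coal_price_cny_per_t: 600

air:
  dust: {flux_kg_per_hm2_yr: 33200, cost_cny_per_kg: 0.18}
  so2:  {flux_kg_per_hm2_yr: 45,    cost_cny_per_kg: 1.44}
  hf:   {flux_kg_per_hm2_yr: 0.57,  cost_cny_per_kg: 0.83}
  nox:  {flux_kg_per_hm2_yr: 33.3,  cost_cny_per_kg: 0.76}
  source_year: 2004
  adjusted_per_area_override: {value_cny_per_hm2: 8968.61, year: 2020}

pest:
  rate_cny_per_hm2_yr: 375.0   # half the monoculture pesticide spend

biodiversity:
  rate_cny_per_hm2_yr: 911.98  # equivalence-factor value, 2020 prices

water:
  infiltration: 7.22
  infiltration_unit: m3_per_hm2_day
  price_cny_per_m3: 0.2

soil:
  tillage_depth_m: 0.2
  bulk_density_g_cm3: 1.09
  som_g_kg: 44.61
  tn_g_kg: 1.32
  tp_g_kg: 0.43
  tk_g_kg: 14.9
  fertilizer_price_cny_per_kg: 2.75
  reported_value_override_cny: 585764.0    # reported component value (58.5764 wan)

carbon:
  root_biomass_kg_per_hm2: 2100
  root_carbon_fraction: 0.346
  straw_biomass_kg_per_hm2: 12400
  straw_carbon_fraction: 0.414
  root_multiplier: 5.0
  straw_return_fraction: 0.11
  annual_co2_kg_per_hm2: 2123.63
  annual_ch4_kg_per_hm2: 29.64
  co2_to_c: 0.27
  ch4_to_c: 0.75
  soc_price_cny_per_kg_c: 1.53
  reported_value_override_cny: 75629900.0  # reported component value (7562.99 wan)

cultural:
  unit_value_cny_per_hm2: 17262  # landscape-tourism unit value from yearbook data

price_indices:
  - {name: air_removal_costs, source_year: 2004, target_year: 2020, ratio: 1.4784170408614064}
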