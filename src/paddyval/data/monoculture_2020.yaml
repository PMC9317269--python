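# Rice-monoculture baseline for the same study area, 2020 prices.
# The underlying parameter set of the baseline is not available; only its
# reported per-service values (in wan = 10^4 CNY) are, so the scenario is
# carried as printed component values.  Pest control is zero by definition:
# the avoided-pesticide value is measured relative to this baseline.
reference_year: 2020
components_wan:
  provisioning: 43088.88
  gas_regulation: -2989.391585
  climate_regulation: 112737.17
  air_purification: 11994.02
  pest_control: 0.0
  biodiversity: 1219.62
  water_regulation: 308.98
  soil_conservation: 60.36
  soil_organic_accumulation: 7562.99
  cultural: 9789.28
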