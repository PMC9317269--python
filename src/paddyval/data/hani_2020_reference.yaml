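# Reported per-service values (wan = 10^4 CNY, 2020) for the integrated
# system, used by `paddyval check` to show computed-vs-reported diffs.
reference_year: 2020
components_wan:
  provisioning: 176086.68
  gas_regulation: -1936.02
  climate_regulation: 112737.17
  air_purification: 11994.02
  pest_control: 501.50
  biodiversity: 1219.62
  water_regulation: 308.98
  soil_conservation: 58.5764
  soil_organic_accumulation: 7562.99
  cultural: 23085.33
total_wan: 331619.5452
shares_pct:
  provisioning: 53.10
  gas_regulation: -0.58
  climate_regulation: 34.00
  air_purification: 3.62
  pest_control: 0.15
  biodiversity: 0.37
  water_regulation: 0.09
  soil_conservation: 0.02
  soil_organic_accumulation: 2.28
  cultural: 6.96
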