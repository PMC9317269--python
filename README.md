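# paddyval

Ecosystem-services valuation for integrated rice–fish–duck terrace farming.

Agro-ecological systems like the Honghe Hani rice terraces (Yunnan, China)
produce far more than rice: fish and duck products, evaporative cooling,
air purification, groundwater recharge, soil nutrient retention, carbon
accumulation, biodiversity, and a world-heritage cultural landscape.
`paddyval` is a small, config-driven engine that turns the standard
valuation methods for these services — market price, replacement cost,
afforestation cost, global-warming-potential accounting, and the
equivalence-factor method — into a tested, reproducible pipeline, for
researchers and policy analysts who need per-service values, totals,
percentage shares, and integrated-versus-monoculture comparisons from a
single declarative scenario file.

## The model

Ten service values are computed for a site of area *A* (hm²) and summed:

| # | Service (CICES section) | Formula |
|---|---|---|
| V1 | Provisioning (Provisioning) | Σᵢ yieldᵢ·priceᵢ·A |
| V2 | Gas regulation (R&M) | Tr·a·b·M_C·C_C + Tr·a·c·C_O − GT_CO₂·M_C·C_C |
| V3 | Climate regulation (R&M) | E·Tn·(e/50)·P_coal·A |
| V4 | Air purification (R&M) | (Σ Q_pollutant·P_removal, price-adjusted)·A |
| V5 | Pest control (R&M) | Q_p·A |
| V6 | Biodiversity (R&M) | P_WC·A |
| V7 | Water regulation (R&M) | f·T_w·P_W·A |
| V8 | Soil conservation (R&M) | A·ST·SBD·Σ(SOM+TN+TP+TK)·P_F |
| V9 | Soil organic accumulation (R&M) | (I_soc − O_soc)·P_soc·A |
| V10 | Cultural (Cultural) | (N_rff/N_tour)·R_z, or unit value × A |

where GT_CO₂ = (G_CO₂ + d·G_CH₄)/1000 converts CH₄ and CO₂ emissions to
tonnes of CO₂-equivalent at GWP *d*, and the soil carbon budget is
I_soc = N_t·5·C_r + N_s·0.11·C_s, O_soc = R_CO₂·0.27 + R_CH₄·0.75.
Gas regulation may be negative (paddy CH₄ emissions usually exceed the
fixation-plus-release credit). All arithmetic is carried in plain CNY at
full precision; 万 (wàn = 10⁴ CNY), million and billion exist only at the
reporting boundary. See `docs/methods.md` for assumptions and parameters.

A synthetic household-survey module generates questionnaire-style records
(yields, prices, stocking counts, soil nutrients) whose population means
equal the scenario parameters, and estimates parameters back from them
with bootstrap intervals — so the full survey → estimate → valuate
pipeline is testable without any real microdata.

## Worked example

The bundled scenario `src/paddyval/data/hani_2020.yaml` describes the
13,373.33 hm² Hani terraces integrated system at 2020 prices. Running

```sh
paddyval check
```

computes all ten services and diffs them against the reported study values
(in 万 CNY):

```
service                         computed_wan    reported_wan  diff_pct
provisioning                       176086.64       176086.68   -0.000%
gas_regulation                      -1936.02        -1936.02   -0.000%
climate_regulation                 112736.95       112737.17   -0.000%
air_purification                    11994.02        11994.02   -0.000%
pest_control                          501.50          501.50   -0.000%
biodiversity                         1219.62         1219.62    0.000%
water_regulation                      308.98          308.98   -0.001%
soil_conservation                      58.58           58.58    0.000%
soil_organic_accumulation            7562.99         7562.99    0.000%
cultural                            23085.04        23085.33   -0.001%
total                              331618.29       331619.55   -0.000%
largest component deviation: 0.001%
```

The total, ≈ 3.316 billion CNY, splits 53.10% provisioning, 34.00%
climate regulation and 6.96% cultural services; the gas-regulation share
is −0.58% because emissions outweigh fixation. From the library:

```python
import paddyval as pv
from paddyval import data

cfg = pv.load_config(data.fixture_path(data.HANI_2020))
v = pv.run_valuation(cfg)
print(f"{v.total.amount/1e9:.3f} billion CNY")   # 3.316 billion CNY
print(f"{v.shares_pct['provisioning']:.2f}%")    # 53.10%

mono = pv.load_printed_valuation(data.fixture_path(data.MONOCULTURE_2020))
cmp_ = pv.compare_scenarios(v, mono)             # added/baseline convention
print(f"{cmp_.rows['cultural'].added_proportion_pct:.2f}%")  # 135.82%
```

Other commands: `paddyval run --config <yaml> --out <dir>` (CSV + JSON
report), `paddyval compare --config-a <yaml> --config-b <yaml>`, and
`paddyval synth --n 100 --seed 42 --out survey.csv` for synthetic survey
data.

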