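"""Scenario configuration: schema, loading, validation, and the full run.

A scenario is one YAML document holding every parameter of the ten service
valuations, with explicit units in the field names (the literature on
paddy-system valuation mixes mm/d with m³/(hm²·d) and CNY with 万, so
silent-unit configs are rejected by design: unknown keys fail validation).

Reported-value overrides are explicit, named fields.  Where a published
component value cannot be reproduced from the published formula inputs
(monitored gas totals, reported soil figures), the override carries the
reported number and the run log records which path — formula or override —
produced each component.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import cultural as cultural_mod
from . import regulation as reg
from .cultural import (
    CICES_CULTURAL,
    CICES_PROVISIONING,
    CICES_REGULATION,
    CulturalParams,
    ServiceValuation,
    aggregate,
    cultural_value,
)
from .provisioning import ProductSpec, SiteProfile, provisioning_value
from .units import Money, PriceIndexRatio

logger = logging.getLogger("paddyval")

#: Canonical service labels, in reporting order, with CICES section tags.
SERVICE_LABELS: tuple[tuple[str, str], ...] = (
    ("provisioning", CICES_PROVISIONING),
    ("gas_regulation", CICES_REGULATION),
    ("climate_regulation", CICES_REGULATION),
    ("air_purification", CICES_REGULATION),
    ("pest_control", CICES_REGULATION),
    ("biodiversity", CICES_REGULATION),
    ("water_regulation", CICES_REGULATION),
    ("soil_conservation", CICES_REGULATION),
    ("soil_organic_accumulation", CICES_REGULATION),
    ("cultural", CICES_CULTURAL),
)

CICES_TAGS: dict[str, str] = dict(SERVICE_LABELS)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MetadataCfg(_Model):
    name: str
    valuation_year: int
    currency: Literal["CNY"] = "CNY"


class SiteCfg(_Model):
    area_hm2: float = Field(gt=0)
    growing_period_days: float = Field(gt=0)
    hot_days: float = Field(gt=0)
    standing_water_days: float = Field(gt=0)

    def to_domain(self) -> SiteProfile:
        return SiteProfile(
            self.area_hm2, self.growing_period_days, self.hot_days, self.standing_water_days
        )


class ProductCfg(_Model):
    name: str
    yield_per_hm2: float = Field(ge=0)
    yield_unit: Literal["kg", "count"]
    unit_price_cny: float = Field(ge=0)

    def to_domain(self) -> ProductSpec:
        return ProductSpec(self.name, self.yield_per_hm2, self.unit_price_cny)


class GhgTotalsCfg(_Model):
    ch4_kg: float = Field(ge=0)
    co2_kg: float = Field(ge=0)


class GasCfg(_Model):
    rice_yield_t: float = Field(ge=0)
    economic_coefficient: float = Field(gt=0)
    co2_per_rice: float = Field(ge=0)
    o2_per_rice: float = Field(ge=0)
    carbon_fraction: float = Field(gt=0, lt=1)
    gwp_ch4: float = Field(ge=0)
    afforestation_cost_cny_per_t_c: float = Field(ge=0)
    oxygen_cost_cny_per_t: float = Field(ge=0)
    ch4_flux_kg_per_hm2_day: float = Field(ge=0, default=0.0)
    rice_co2_flux_kg_per_hm2_day: float = Field(ge=0, default=0.0)
    soil_co2_flux_kg_per_hm2_day: float = Field(ge=0, default=0.0)
    ghg_totals_override: Optional[GhgTotalsCfg] = None

    def to_domain(self) -> reg.GasParameters:
        return reg.GasParameters(
            rice_yield_t=self.rice_yield_t,
            economic_coeff_a=self.economic_coefficient,
            co2_per_rice_b=self.co2_per_rice,
            o2_per_rice_c=self.o2_per_rice,
            carbon_fraction_mc=self.carbon_fraction,
            gwp_ch4_d=self.gwp_ch4,
            afforestation_cost_cny_per_t_c=self.afforestation_cost_cny_per_t_c,
            oxygen_cost_cny_per_t=self.oxygen_cost_cny_per_t,
            ch4_flux_kg_per_hm2_day=self.ch4_flux_kg_per_hm2_day,
            rice_co2_flux_kg_per_hm2_day=self.rice_co2_flux_kg_per_hm2_day,
            soil_co2_flux_kg_per_hm2_day=self.soil_co2_flux_kg_per_hm2_day,
        )


class ClimateCfg(_Model):
    evaporation_mm_per_day: float = Field(gt=0)
    coal_t_per_50mm_hm2: float = Field(gt=0)
    coal_price_cny_per_t: float = Field(gt=0)

    def to_domain(self) -> reg.ClimateParameters:
        return reg.ClimateParameters(
            self.evaporation_mm_per_day, self.coal_t_per_50mm_hm2, self.coal_price_cny_per_t
        )


class PollutantCfg(_Model):
    flux_kg_per_hm2_yr: float = Field(ge=0)
    cost_cny_per_kg: float = Field(ge=0)


class AirOverrideCfg(_Model):
    value_cny_per_hm2: float = Field(ge=0)
    year: int


class AirCfg(_Model):
    dust: PollutantCfg
    so2: PollutantCfg
    hf: PollutantCfg
    nox: PollutantCfg
    source_year: int
    adjusted_per_area_override: Optional[AirOverrideCfg] = None

    def to_domain(self) -> reg.AirPollutantSpec:
        return reg.AirPollutantSpec(
            dust_flux=self.dust.flux_kg_per_hm2_yr,
            so2_flux=self.so2.flux_kg_per_hm2_yr,
            hf_flux=self.hf.flux_kg_per_hm2_yr,
            nox_flux=self.nox.flux_kg_per_hm2_yr,
            dust_cost=self.dust.cost_cny_per_kg,
            so2_cost=self.so2.cost_cny_per_kg,
            hf_cost=self.hf.cost_cny_per_kg,
            nox_cost=self.nox.cost_cny_per_kg,
            source_year=self.source_year,
            adjusted_per_area_cny_per_hm2=(
                self.adjusted_per_area_override.value_cny_per_hm2
                if self.adjusted_per_area_override
                else None
            ),
        )


class RateCfg(_Model):
    rate_cny_per_hm2_yr: float


class WaterCfg(_Model):
    infiltration: float = Field(gt=0)
    infiltration_unit: Literal["m3_per_hm2_day", "mm_per_day"]
    price_cny_per_m3: float = Field(gt=0)

    def to_domain(self) -> reg.WaterParameters:
        if self.infiltration_unit == "mm_per_day":
            return reg.WaterParameters.from_mm_per_day(self.infiltration, self.price_cny_per_m3)
        return reg.WaterParameters(self.infiltration, self.price_cny_per_m3)


class SoilCfg(_Model):
    tillage_depth_m: float = Field(gt=0)
    bulk_density_g_cm3: float = Field(gt=0)
    som_g_kg: float = Field(ge=0)
    tn_g_kg: float = Field(ge=0)
    tp_g_kg: float = Field(ge=0)
    tk_g_kg: float = Field(ge=0)
    fertilizer_price_cny_per_kg: float = Field(ge=0)
    reported_value_override_cny: Optional[float] = None

    def to_domain(self) -> reg.SoilProfile:
        return reg.SoilProfile(
            self.tillage_depth_m, self.bulk_density_g_cm3,
            self.som_g_kg, self.tn_g_kg, self.tp_g_kg, self.tk_g_kg,
            self.fertilizer_price_cny_per_kg,
        )


class CarbonCfg(_Model):
    root_biomass_kg_per_hm2: float = Field(ge=0)
    root_carbon_fraction: float = Field(ge=0, le=1)
    straw_biomass_kg_per_hm2: float = Field(ge=0)
    straw_carbon_fraction: float = Field(ge=0, le=1)
    root_multiplier: float = Field(gt=0, default=5.0)
    straw_return_fraction: float = Field(ge=0, le=1, default=0.11)
    annual_co2_kg_per_hm2: float = Field(ge=0)
    annual_ch4_kg_per_hm2: float = Field(ge=0)
    co2_to_c: float = Field(gt=0, lt=1, default=0.27)
    ch4_to_c: float = Field(gt=0, lt=1, default=0.75)
    soc_price_cny_per_kg_c: float = Field(ge=0)
    reported_value_override_cny: Optional[float] = None

    def to_domain(self) -> reg.CarbonBudgetParams:
        return reg.CarbonBudgetParams(
            root_biomass_kg_per_hm2=self.root_biomass_kg_per_hm2,
            root_carbon_fraction=self.root_carbon_fraction,
            straw_biomass_kg_per_hm2=self.straw_biomass_kg_per_hm2,
            straw_carbon_fraction=self.straw_carbon_fraction,
            root_multiplier=self.root_multiplier,
            straw_return_fraction=self.straw_return_fraction,
            annual_co2_kg_per_hm2=self.annual_co2_kg_per_hm2,
            annual_ch4_kg_per_hm2=self.annual_ch4_kg_per_hm2,
            co2_to_c=self.co2_to_c,
            ch4_to_c=self.ch4_to_c,
            soc_price_cny_per_kg_c=self.soc_price_cny_per_kg_c,
        )


class CulturalCfg(_Model):
    unit_value_cny_per_hm2: Optional[float] = None
    festival_visitors: Optional[float] = None
    total_tourists: Optional[float] = None
    tourism_revenue_cny: Optional[float] = None

    def to_domain(self) -> CulturalParams:
        return CulturalParams(
            self.unit_value_cny_per_hm2,
            self.festival_visitors,
            self.total_tourists,
            self.tourism_revenue_cny,
        )


class PriceIndexCfg(_Model):
    name: str
    source_year: int
    target_year: int
    ratio: float = Field(gt=0)

    def to_domain(self) -> PriceIndexRatio:
        return PriceIndexRatio(self.source_year, self.target_year, self.ratio)


class ScenarioConfig(_Model):
    """Validated scenario document; the single input to :func:`run_valuation`."""

    metadata: MetadataCfg
    site: SiteCfg
    products: list[ProductCfg]
    gas: GasCfg
    climate: ClimateCfg
    air: AirCfg
    pest: RateCfg
    biodiversity: RateCfg
    water: WaterCfg
    soil: SoilCfg
    carbon: CarbonCfg
    cultural: CulturalCfg
    price_indices: list[PriceIndexCfg] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_products(self) -> "ScenarioConfig":
        if not self.products:
            raise ValueError("products list must not be empty")
        return self

    def overrides_in_effect(self) -> list[str]:
        out = []
        if self.gas.ghg_totals_override is not None:
            out.append("gas.ghg_totals_override")
        if self.air.adjusted_per_area_override is not None:
            out.append("air.adjusted_per_area_override")
        if self.soil.reported_value_override_cny is not None:
            out.append("soil.reported_value_override_cny")
        if self.carbon.reported_value_override_cny is not None:
            out.append("carbon.reported_value_override_cny")
        return out


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario YAML; log every override in effect."""
    raw = yaml.safe_load(Path(path).read_text())
    cfg = ScenarioConfig.model_validate(raw)
    for ov in cfg.overrides_in_effect():
        logger.info("scenario %s: override in effect: %s", cfg.metadata.name, ov)
    return cfg


def run_valuation(cfg: ScenarioConfig, use_overrides: bool = True) -> ServiceValuation:
    """Compute all ten service values, aggregate, and record provenance.

    ``use_overrides=False`` forces the pure formula path everywhere, which
    is useful for linearity checks and for sites without reported totals.
    """
    year = cfg.metadata.valuation_year
    site = cfg.site.to_domain()
    provenance: dict[str, str] = {}

    # V1 provisioning
    products = [p.to_domain() for p in cfg.products]
    v1, per_area = provisioning_value(products, site, year)
    provenance["provisioning"] = "formula"
    logger.info("provisioning: %.2f CNY/hm2 -> %.2f CNY (%.2f wan)", per_area, v1.amount, v1.amount / 1e4)

    # V2 block: gas regulation
    gas = cfg.gas.to_domain()
    vco2 = reg.co2_fixation_value(gas, year)
    vo2 = reg.o2_release_value(gas, year)
    if use_overrides and cfg.gas.ghg_totals_override is not None:
        totals = reg.GhgTotals(
            cfg.gas.ghg_totals_override.ch4_kg,
            cfg.gas.ghg_totals_override.co2_kg,
            source="printed_override",
        )
    else:
        totals = reg.ghg_totals_from_flux(gas, site)
    co2eq = reg.co2_equivalent_t(totals, gas.gwp_ch4_d)
    v2 = reg.ghg_emission_value(co2eq, gas, year)
    gas_net = reg.gas_regulation_net(vco2, vo2, v2)
    provenance["gas_regulation"] = (
        "formula+ghg_override" if totals.source == "printed_override" else "formula"
    )
    logger.info(
        "gas regulation: fixation %.2f + release %.2f - emissions %.2f = %.2f CNY (totals: %s)",
        vco2.amount, vo2.amount, v2.amount, gas_net.amount, totals.source,
    )

    # V3 climate
    qt, coal, v3 = reg.climate_regulation_value(cfg.climate.to_domain(), site, year)
    provenance["climate_regulation"] = "formula"
    logger.info("climate: Qt=%.2f mm, coal=%.4f t/hm2, V3=%.2f CNY", qt, coal, v3.amount)

    # V4 air purification
    air = cfg.air.to_domain()
    if not use_overrides:
        air = reg.AirPollutantSpec(
            air.dust_flux, air.so2_flux, air.hf_flux, air.nox_flux,
            air.dust_cost, air.so2_cost, air.hf_cost, air.nox_cost,
            source_year=air.source_year, adjusted_per_area_cny_per_hm2=None,
        )
    idx = None
    if air.adjusted_per_area_cny_per_hm2 is None:
        idx = _find_index(cfg, air.source_year, year)
    v4 = reg.air_purification_value(air, site, idx, year)
    provenance["air_purification"] = (
        "adjusted_override" if air.adjusted_per_area_cny_per_hm2 is not None else "formula+index"
    )

    # V5, V6 flat rates
    v5 = reg.area_rate_value(reg.AreaRateService("pest_control", cfg.pest.rate_cny_per_hm2_yr), site, year)
    v6 = reg.area_rate_value(
        reg.AreaRateService("biodiversity", cfg.biodiversity.rate_cny_per_hm2_yr), site, year
    )
    provenance["pest_control"] = provenance["biodiversity"] = "formula"

    # V7 water
    v7 = reg.water_regulation_value(cfg.water.to_domain(), site, year)
    provenance["water_regulation"] = "formula"

    # V8 soil conservation
    _, v8_formula = reg.soil_conservation_value(cfg.soil.to_domain(), site, year)
    if use_overrides and cfg.soil.reported_value_override_cny is not None:
        v8 = Money(cfg.soil.reported_value_override_cny, year)
        provenance["soil_conservation"] = "reported_override"
        logger.info(
            "soil conservation: using reported override %.2f CNY (formula gives %.2f)",
            v8.amount, v8_formula.amount,
        )
    else:
        v8 = v8_formula
        provenance["soil_conservation"] = "formula"

    # V9 soil organic accumulation
    carbon = cfg.carbon.to_domain()
    _, _, bsoc = reg.soil_carbon_balance(carbon)
    v9_formula = reg.soil_organic_value(bsoc, carbon.soc_price_cny_per_kg_c, site, year)
    if use_overrides and cfg.carbon.reported_value_override_cny is not None:
        v9 = Money(cfg.carbon.reported_value_override_cny, year)
        provenance["soil_organic_accumulation"] = "reported_override"
        logger.info(
            "soil organic accumulation: using reported override %.2f CNY (formula gives %.2f)",
            v9.amount, v9_formula.amount,
        )
    else:
        v9 = v9_formula
        provenance["soil_organic_accumulation"] = "formula"

    # V10 cultural
    v10 = cultural_value(cfg.cultural.to_domain(), site, year)
    provenance["cultural"] = "formula"

    values = {
        "provisioning": v1,
        "gas_regulation": gas_net,
        "climate_regulation": v3,
        "air_purification": v4,
        "pest_control": v5,
        "biodiversity": v6,
        "water_regulation": v7,
        "soil_conservation": v8,
        "soil_organic_accumulation": v9,
        "cultural": v10,
    }
    components = [(label, values[label], tag) for label, tag in SERVICE_LABELS]
    valuation = aggregate(components, provenance=provenance)
    logger.info(
        "scenario %s: total %.2f CNY (%.4f wan)",
        cfg.metadata.name, valuation.total.amount, valuation.total.amount / 1e4,
    )
    return valuation


def _find_index(cfg: ScenarioConfig, source_year: int, target_year: int) -> PriceIndexRatio:
    for p in cfg.price_indices:
        if p.source_year == source_year and p.target_year == target_year:
            return p.to_domain()
    raise ValueError(
        f"no price index from {source_year} to {target_year} in config "
        "(needed for the air-purification formula path)"
    )


def load_printed_valuation(path: str | Path) -> ServiceValuation:
    """Load a baseline scenario given only as reported per-service 万 values."""
    raw = yaml.safe_load(Path(path).read_text())
    return cultural_mod.valuation_from_printed(
        raw["components_wan"], CICES_TAGS, raw["reference_year"]
    )
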