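"""Regulation-and-maintenance service valuations (V2-V9).

Eight services are valued, mostly by the replacement-cost family of
methods:

* gas regulation — CO₂ fixation and O₂ release priced by the afforestation
  cost method, net of the CO₂-equivalent value of CH₄/CO₂ emissions (GWP
  accounting); the net may be negative;
* climate regulation — evaporative cooling priced as the standard coal
  needed to supply the same heat;
* air purification — pollutant uptake (dust, SO₂, HF, NOx) priced at
  removal cost, with a price-index adjustment to the valuation year;
* pest control and biodiversity — flat per-area replacement rates
  (avoided pesticide spend; equivalence-factor biodiversity value);
* water regulation — infiltration volume priced at the agricultural
  water tariff;
* soil conservation — the nutrient stock of the tillage layer priced at
  fertilizer cost;
* soil organic-carbon accumulation — an annual carbon budget
  (root + returned-straw inputs minus gaseous carbon losses) priced at the
  pure-carbon organic fertilizer price.

Every value is computed per hm² first and scaled by the site area once, so
all results are exactly linear in area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .provisioning import SiteProfile
from .units import Money, PriceIndexRatio, YearMismatchError


# ---------------------------------------------------------------------------
# gas regulation (V2 block)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class GasParameters:
    """Inputs for the gas-regulation block.

    rice_yield_t:       total rice yield of the evaluated area (t); the
                        photosynthesis terms scale with it.
    economic_coeff_a:   economic coefficient of rice (dimensionless, 0.5):
                        fraction of fixed biomass counted as economic yield.
    co2_per_rice_b:     g CO₂ fixed per g of rice dry matter (1.63, from the
                        photosynthesis stoichiometry).
    o2_per_rice_c:      g O₂ released per g of rice dry matter (1.19).
    carbon_fraction_mc: carbon mass fraction of CO₂ (0.2727 ≈ 12/44).
    gwp_ch4_d:          global-warming potential of CH₄ in kg CO₂-eq per kg
                        CH₄ (24.5 here; configurable).
    afforestation_cost_cny_per_t_c: cost of sequestering 1 t C by
                        afforestation (CNY/t C, 2020 prices).
    oxygen_cost_cny_per_t: industrial oxygen price (CNY/t O₂, 2020 prices).
    ch4_flux / rice_co2_flux / soil_co2_flux: mean emission fluxes in
                        kg/(hm²·d), used when gas totals are derived from
                        fluxes rather than supplied directly.
    """

    rice_yield_t: float
    economic_coeff_a: float = 0.5
    co2_per_rice_b: float = 1.63
    o2_per_rice_c: float = 1.19
    carbon_fraction_mc: float = 0.2727
    gwp_ch4_d: float = 24.5
    afforestation_cost_cny_per_t_c: float = 327.32
    oxygen_cost_cny_per_t: float = 1072.21
    ch4_flux_kg_per_hm2_day: float = 0.0
    rice_co2_flux_kg_per_hm2_day: float = 0.0
    soil_co2_flux_kg_per_hm2_day: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.carbon_fraction_mc < 1.0:
            raise ValueError(f"carbon fraction must lie in (0,1), got {self.carbon_fraction_mc}")
        for name in (
            "rice_yield_t", "economic_coeff_a", "co2_per_rice_b", "o2_per_rice_c",
            "gwp_ch4_d", "afforestation_cost_cny_per_t_c", "oxygen_cost_cny_per_t",
            "ch4_flux_kg_per_hm2_day", "rice_co2_flux_kg_per_hm2_day",
            "soil_co2_flux_kg_per_hm2_day",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"GasParameters.{name} must be >= 0")


@dataclass(frozen=True, slots=True)
class GhgTotals:
    """Annual greenhouse-gas emission totals for the whole site, in kg.

    ``source`` records whether the totals came out of the flux formula or
    were supplied directly (e.g. monitored totals that the simple
    area x days x flux product does not reproduce).
    """

    ch4_kg: float
    co2_kg: float
    source: Literal["computed_from_flux", "printed_override"] = "computed_from_flux"

    def __post_init__(self) -> None:
        if self.ch4_kg < 0 or self.co2_kg < 0:
            raise ValueError("GHG totals must be >= 0")


def co2_fixation_value(g: GasParameters, year: int = 2020) -> Money:
    """Value of CO₂ fixed by rice photosynthesis (afforestation cost method).

    VCO2 = Tr × a × b × Mc × C_afforestation, with Tr in t so the carbon
    tonnage meets the CNY/t C cost directly.
    """
    amount = (
        g.rice_yield_t
        * g.economic_coeff_a
        * g.co2_per_rice_b
        * g.carbon_fraction_mc
        * g.afforestation_cost_cny_per_t_c
    )
    return Money(amount, year)


def o2_release_value(g: GasParameters, year: int = 2020) -> Money:
    """Value of O₂ released by rice photosynthesis, priced as industrial oxygen.

    VO2 = Tr × a × c × C_oxygen.
    """
    amount = g.rice_yield_t * g.economic_coeff_a * g.o2_per_rice_c * g.oxygen_cost_cny_per_t
    return Money(amount, year)


def ghg_totals_from_flux(g: GasParameters, site: SiteProfile) -> GhgTotals:
    """Season GHG totals from mean daily fluxes: G = A × D × flux."""
    a_d = site.area_hm2 * site.growing_period_days
    return GhgTotals(
        ch4_kg=a_d * g.ch4_flux_kg_per_hm2_day,
        co2_kg=a_d * (g.rice_co2_flux_kg_per_hm2_day + g.soil_co2_flux_kg_per_hm2_day),
        source="computed_from_flux",
    )


def co2_equivalent_t(totals: GhgTotals, gwp_ch4_d: float) -> float:
    """Convert kg totals of CO₂ and CH₄ into tonnes of CO₂-equivalent."""
    return (totals.co2_kg + gwp_ch4_d * totals.ch4_kg) / 1000.0


def ghg_emission_value(co2_eq_t: float, g: GasParameters, year: int = 2020) -> Money:
    """Monetary debit of the CO₂-equivalent emissions, at afforestation cost.

    V2 = GTCO2 × Mc × C_afforestation.
    """
    return Money(co2_eq_t * g.carbon_fraction_mc * g.afforestation_cost_cny_per_t_c, year)


def gas_regulation_net(vco2: Money, vo2: Money, v2: Money) -> Money:
    """Net gas-regulation value: fixation + release − emission debit.

    The three terms are combined unrounded; the net is frequently negative
    for paddy systems because CH₄ emissions dominate.
    """
    return vco2 + vo2 - v2


# ---------------------------------------------------------------------------
# climate regulation (V3)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ClimateParameters:
    """Evaporative-cooling valuation inputs.

    evaporation_mm_per_day: mean daily open-water evaporation (mm/d).
    coal_t_per_50mm_hm2:    tonnes of standard coal whose combustion heat
                            equals the latent heat of evaporating 50 mm of
                            water over 1 hm² (stored exactly in this
                            per-50-mm form; the /50 is applied inside the
                            operation so the t/hm² intermediate is
                            inspectable).
    coal_price_cny_per_t:   market price of standard coal (CNY/t).
    """

    evaporation_mm_per_day: float
    coal_t_per_50mm_hm2: float = 30.57
    coal_price_cny_per_t: float = 600.0

    def __post_init__(self) -> None:
        for name in ("evaporation_mm_per_day", "coal_t_per_50mm_hm2", "coal_price_cny_per_t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ClimateParameters.{name} must be > 0")


def climate_regulation_value(
    c: ClimateParameters, site: SiteProfile, year: int = 2020
) -> tuple[float, float, Money]:
    """Cooling-effect valuation by the replacement-cost (standard coal) method.

    Returns ``(Qt, coal_per_hm2, V3)`` where Qt = E × Tn is the seasonal
    cooling evaporation (mm), ``coal_per_hm2`` the equivalent standard coal
    (t/hm²·yr), and V3 = coal_per_hm2 × P × A.
    """
    qt_mm = c.evaporation_mm_per_day * site.hot_days
    coal_per_hm2 = qt_mm * c.coal_t_per_50mm_hm2 / 50.0
    v3 = Money(coal_per_hm2 * c.coal_price_cny_per_t * site.area_hm2, year)
    return qt_mm, coal_per_hm2, v3


# ---------------------------------------------------------------------------
# air purification (V4)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class AirPollutantSpec:
    """Pollutant uptake fluxes and removal costs for the air-purification value.

    Fluxes are kg/(hm²·yr) absorbed by the paddy; costs are the engineering
    removal cost per kg.  The raw flux x cost sum is referenced to
    ``source_year`` prices and must be carried to the valuation year by a
    price index.  When a published already-adjusted per-area value exists it
    can be supplied as ``adjusted_per_area_cny_per_hm2`` and takes
    precedence.
    """

    dust_flux: float
    so2_flux: float
    hf_flux: float
    nox_flux: float
    dust_cost: float
    so2_cost: float
    hf_cost: float
    nox_cost: float
    source_year: int = 2004
    adjusted_per_area_cny_per_hm2: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "dust_flux", "so2_flux", "hf_flux", "nox_flux",
            "dust_cost", "so2_cost", "hf_cost", "nox_cost",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"AirPollutantSpec.{name} must be >= 0")

    def per_area_source_year(self) -> float:
        """Σ flux×cost in CNY/hm² at ``source_year`` prices."""
        return (
            self.dust_flux * self.dust_cost
            + self.so2_flux * self.so2_cost
            + self.hf_flux * self.hf_cost
            + self.nox_flux * self.nox_cost
        )


def air_purification_value(
    a: AirPollutantSpec,
    site: SiteProfile,
    idx: PriceIndexRatio | None = None,
    year: int = 2020,
) -> Money:
    """Air-purification value V4 = (ΣQᵢPᵢ, price-adjusted) × A.

    Either ``a.adjusted_per_area_cny_per_hm2`` must be set (already at the
    valuation year's prices) or a price-index ratio from ``a.source_year``
    to ``year`` must be supplied.
    """
    if a.adjusted_per_area_cny_per_hm2 is not None:
        per_area = a.adjusted_per_area_cny_per_hm2
    elif idx is not None:
        if idx.source_year != a.source_year or idx.target_year != year:
            raise YearMismatchError(
                f"air-purification index must run {a.source_year}->{year}, "
                f"got {idx.source_year}->{idx.target_year}"
            )
        per_area = a.per_area_source_year() * idx.ratio
    else:
        raise ValueError(
            "air purification needs either an adjusted per-area value or a "
            "price-index ratio for the raw flux x cost sum"
        )
    return Money(per_area * site.area_hm2, year)


# ---------------------------------------------------------------------------
# flat per-area services: pest control (V5), biodiversity (V6)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class AreaRateService:
    """A service valued as a flat annual rate per hm² (CNY/(hm²·yr)).

    Used for pest control (avoided pesticide cost) and for the
    equivalence-factor biodiversity value.  The sign is unconstrained.
    """

    label: str
    rate_cny_per_hm2_yr: float


def area_rate_value(s: AreaRateService, site: SiteProfile, year: int = 2020) -> Money:
    """V = rate × A."""
    return Money(s.rate_cny_per_hm2_yr * site.area_hm2, year)


# ---------------------------------------------------------------------------
# water regulation (V7)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class WaterParameters:
    """Groundwater-recharge valuation inputs.

    infiltration_m3_per_hm2_day: soil water infiltration rate, stored
        canonically in m³/(hm²·d).  Literature values quoted in mm/d convert
        as 1 mm/d = 10 m³/(hm²·d); use :meth:`from_mm_per_day` for those.
    water_price_cny_per_m3: agricultural water tariff.
    """

    infiltration_m3_per_hm2_day: float
    water_price_cny_per_m3: float = 0.2

    def __post_init__(self) -> None:
        if self.infiltration_m3_per_hm2_day <= 0:
            raise ValueError("infiltration rate must be > 0")
        if self.water_price_cny_per_m3 <= 0:
            raise ValueError("water price must be > 0")

    @classmethod
    def from_mm_per_day(cls, infiltration_mm_per_day: float, water_price_cny_per_m3: float = 0.2):
        # 1 mm over 1 hm² = 10 m³
        return cls(infiltration_mm_per_day * 10.0, water_price_cny_per_m3)


def water_regulation_value(w: WaterParameters, site: SiteProfile, year: int = 2020) -> Money:
    """V7 = f × Tw × Pw × A, with f in m³/(hm²·d) and Tw the standing-water days."""
    amount = (
        w.infiltration_m3_per_hm2_day
        * site.standing_water_days
        * w.water_price_cny_per_m3
        * site.area_hm2
    )
    return Money(amount, year)


# ---------------------------------------------------------------------------
# soil conservation (V8)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class SoilProfile:
    """Tillage-layer nutrient stock and its replacement pricing.

    tillage_depth_m:       cultivated topsoil thickness (m).
    bulk_density_g_cm3:    soil bulk density (g/cm³ ≡ t/m³).
    som/tn/tp/tk_g_kg:     organic matter, total N, total P, total K
                           contents (g per kg of soil).
    fertilizer_price_cny_per_kg: market fertilizer price (CNY/kg nutrient).
    """

    tillage_depth_m: float
    bulk_density_g_cm3: float
    som_g_kg: float
    tn_g_kg: float
    tp_g_kg: float
    tk_g_kg: float
    fertilizer_price_cny_per_kg: float

    def __post_init__(self) -> None:
        if self.tillage_depth_m <= 0 or self.bulk_density_g_cm3 <= 0:
            raise ValueError("tillage depth and bulk density must be > 0")
        nutrients = (self.som_g_kg, self.tn_g_kg, self.tp_g_kg, self.tk_g_kg)
        if any(x < 0 for x in nutrients):
            raise ValueError("nutrient contents must be >= 0")
        if sum(nutrients) >= 1000.0:
            raise ValueError("nutrient contents sum to >= 1000 g/kg, impossible mass fraction")

    def nutrient_sum_g_kg(self) -> float:
        return self.som_g_kg + self.tn_g_kg + self.tp_g_kg + self.tk_g_kg


def soil_conservation_value(
    s: SoilProfile, site: SiteProfile, year: int = 2020
) -> tuple[float, Money]:
    """Fertilizer-replacement value of the tillage-layer nutrient stock.

    V8 = A × ST × SBD × Σ(SOM+TN+TP+TK) × P_F, evaluated with consistent
    units: 1 hm² = 10,000 m², bulk density g/cm³ = 1000 kg/m³, nutrient
    contents g/kg = /1000 mass fraction.  Returns ``(per_area, V8)``.
    """
    soil_mass_kg_per_hm2 = 10_000.0 * s.tillage_depth_m * s.bulk_density_g_cm3 * 1000.0
    nutrient_kg_per_hm2 = soil_mass_kg_per_hm2 * s.nutrient_sum_g_kg() / 1000.0
    per_area = nutrient_kg_per_hm2 * s.fertilizer_price_cny_per_kg
    return per_area, Money(per_area * site.area_hm2, year)


# ---------------------------------------------------------------------------
# soil organic-carbon accumulation (V9)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class CarbonBudgetParams:
    """Annual per-hectare soil organic-carbon budget inputs.

    Carbon input is root biomass (times a root-system multiplier) plus the
    returned fraction of straw, each times its carbon content; output is
    the carbon in the CO₂ and CH₄ the field emits each year.

    root_biomass_kg_per_hm2:  rice root biomass (kg/hm²).
    root_carbon_fraction:     carbon mass fraction of roots.
    straw_biomass_kg_per_hm2: straw biomass (kg/hm²).
    straw_carbon_fraction:    carbon mass fraction of straw.
    root_multiplier:          whole-root-system multiplier applied to root
                              biomass (5).
    straw_return_fraction:    fraction of straw returned to the field (0.11).
    annual_co2_kg_per_hm2 / annual_ch4_kg_per_hm2: yearly gaseous losses.
    co2_to_c / ch4_to_c:      carbon fractions of CO₂ (0.27) and CH₄ (0.75).
    soc_price_cny_per_kg_c:   organic-fertilizer price per kg pure carbon.
    """

    root_biomass_kg_per_hm2: float
    root_carbon_fraction: float
    straw_biomass_kg_per_hm2: float
    straw_carbon_fraction: float
    root_multiplier: float = 5.0
    straw_return_fraction: float = 0.11
    annual_co2_kg_per_hm2: float = 0.0
    annual_ch4_kg_per_hm2: float = 0.0
    co2_to_c: float = 0.27
    ch4_to_c: float = 0.75
    soc_price_cny_per_kg_c: float = 1.53

    def __post_init__(self) -> None:
        for name in ("root_carbon_fraction", "straw_carbon_fraction", "straw_return_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"CarbonBudgetParams.{name} must lie in [0,1], got {v}")
        for name in ("root_biomass_kg_per_hm2", "straw_biomass_kg_per_hm2",
                     "annual_co2_kg_per_hm2", "annual_ch4_kg_per_hm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"CarbonBudgetParams.{name} must be >= 0")


def soil_carbon_balance(c: CarbonBudgetParams) -> tuple[float, float, float]:
    """Annual soil organic-carbon input, output and net balance (kg C/hm²).

    Isoc = Nt × 5 × Cr + Ns × 11% × Cs;  Osoc = RCO2 × 0.27 + RCH4 × 0.75;
    Bsoc = Isoc − Osoc.  ``Bsoc + Osoc == Isoc`` holds exactly.
    """
    isoc = (
        c.root_biomass_kg_per_hm2 * c.root_multiplier * c.root_carbon_fraction
        + c.straw_biomass_kg_per_hm2 * c.straw_return_fraction * c.straw_carbon_fraction
    )
    osoc = c.annual_co2_kg_per_hm2 * c.co2_to_c + c.annual_ch4_kg_per_hm2 * c.ch4_to_c
    return isoc, osoc, isoc - osoc


def soil_organic_value(
    bsoc_kg_per_hm2: float, soc_price_cny_per_kg_c: float, site: SiteProfile, year: int = 2020
) -> Money:
    """V9 = Bsoc × Psoc × A."""
    return Money(bsoc_kg_per_hm2 * soc_price_cny_per_kg_c * site.area_hm2, year)
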