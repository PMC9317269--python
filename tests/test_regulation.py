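"""Regulation-and-maintenance valuations V2-V9 against hand-checked values
and a spreadsheet-style re-evaluation oracle on random parameter draws."""

import numpy as np
import pytest

import paddyval as pv
from paddyval import (
    AirPollutantSpec,
    AreaRateService,
    CarbonBudgetParams,
    ClimateParameters,
    GasParameters,
    GhgTotals,
    PriceIndexRatio,
    SiteProfile,
    SoilProfile,
    WaterParameters,
)

SITE = SiteProfile(13373.33, 180, 60, 160)
GAS = GasParameters(
    rice_yield_t=73600, economic_coeff_a=0.5, co2_per_rice_b=1.63, o2_per_rice_c=1.19,
    carbon_fraction_mc=0.2727, gwp_ch4_d=24.5,
    afforestation_cost_cny_per_t_c=327.32, oxygen_cost_cny_per_t=1072.21,
    ch4_flux_kg_per_hm2_day=0.334, rice_co2_flux_kg_per_hm2_day=272.04,
    soil_co2_flux_kg_per_hm2_day=102.35,
)
MONITORED = GhgTotals(585_315, 788_577_460, source="printed_override")


class TestGasRegulation:
    def test_co2_fixation(self):
        assert pv.co2_fixation_value(GAS).amount / 1e6 == pytest.approx(5.35, rel=1e-3)

    def test_co2_fixation_linear_in_cost(self):
        doubled = GasParameters(
            rice_yield_t=73600, afforestation_cost_cny_per_t_c=2 * 327.32
        )
        base = GasParameters(rice_yield_t=73600, afforestation_cost_cny_per_t_c=327.32)
        assert pv.co2_fixation_value(doubled).amount == pytest.approx(
            2 * pv.co2_fixation_value(base).amount
        )

    def test_o2_release(self):
        assert pv.o2_release_value(GAS).amount / 1e6 == pytest.approx(46.95, rel=1e-3)

    def test_zero_yield_zeroes_photosynthesis_terms(self):
        g0 = GasParameters(rice_yield_t=0)
        assert pv.co2_fixation_value(g0).amount == 0.0
        assert pv.o2_release_value(g0).amount == 0.0

    def test_fixation_release_ratio_matches_closed_forms(self):
        # independent closed-form check: VO2/VCO2 = (c*Co)/(b*Mc*Cc)
        want = (1.19 * 1072.21) / (1.63 * 0.2727 * 327.32)
        got = pv.o2_release_value(GAS).amount / pv.co2_fixation_value(GAS).amount
        assert got == pytest.approx(want, rel=1e-12)

    def test_flux_totals_unit_area_day(self):
        t = pv.ghg_totals_from_flux(GAS, SiteProfile(1, 1, 60, 160))
        assert t.ch4_kg == pytest.approx(0.334)
        assert t.co2_kg == pytest.approx(374.39)

    def test_flux_totals_study_area(self):
        # the flux product path, distinct from the monitored totals
        t = pv.ghg_totals_from_flux(GAS, SITE)
        assert t.ch4_kg == pytest.approx(13373.33 * 180 * 0.334, rel=1e-12)
        assert t.source == "computed_from_flux"

    def test_zero_days_zero_totals(self):
        t = pv.ghg_totals_from_flux(GAS, SiteProfile(13373.33, 0, 60, 160))
        assert (t.ch4_kg, t.co2_kg) == (0.0, 0.0)

    def test_co2_equivalent_of_monitored_totals(self):
        assert pv.co2_equivalent_t(MONITORED, 24.5) == pytest.approx(802_917.69, rel=1e-6)

    def test_co2_equivalent_definition_limits(self):
        assert pv.co2_equivalent_t(GhgTotals(0, 0), 24.5) == 0.0
        # 1 t CH4 alone at GWP 24.5 is 24.5 t CO2-eq
        assert pv.co2_equivalent_t(GhgTotals(1000, 0), 24.5) == pytest.approx(24.5)
        # GWP 0 excludes CH4 entirely
        assert pv.co2_equivalent_t(MONITORED, 0.0) == pytest.approx(MONITORED.co2_kg / 1000)

    def test_emission_value(self):
        v2 = pv.ghg_emission_value(pv.co2_equivalent_t(MONITORED, 24.5), GAS)
        assert v2.amount / 1e6 == pytest.approx(71.67, rel=1e-3)

    def test_emission_value_hand_product(self):
        assert pv.ghg_emission_value(1000.0, GAS).amount == pytest.approx(
            1000.0 * 0.2727 * 327.32, rel=1e-12
        )

    def test_net_gas_regulation_is_negative(self):
        vco2, vo2 = pv.co2_fixation_value(GAS), pv.o2_release_value(GAS)
        v2 = pv.ghg_emission_value(pv.co2_equivalent_t(MONITORED, 24.5), GAS)
        net = pv.gas_regulation_net(vco2, vo2, v2)
        assert net.amount / 1e6 == pytest.approx(-19.36, rel=1e-3)

    def test_net_zero_when_emissions_equal_fixation_plus_release(self):
        vco2, vo2 = pv.co2_fixation_value(GAS), pv.o2_release_value(GAS)
        net = pv.gas_regulation_net(vco2, vo2, vco2 + vo2)
        assert net.amount == 0.0

    def test_net_with_emissions_halved(self):
        vco2, vo2 = pv.co2_fixation_value(GAS), pv.o2_release_value(GAS)
        v2 = pv.ghg_emission_value(pv.co2_equivalent_t(MONITORED, 24.5), GAS)
        net = pv.gas_regulation_net(vco2, vo2, 0.5 * v2)
        # hand arithmetic: fixation + release - half the emission debit
        assert net.amount == pytest.approx(
            vco2.amount + vo2.amount - v2.amount / 2, rel=1e-12
        )


class TestClimateRegulation:
    def test_cooling_and_coal_intermediates(self):
        qt, coal, _ = pv.climate_regulation_value(ClimateParameters(3.83), SITE)
        assert qt == pytest.approx(229.8, rel=1e-9)
        assert coal == pytest.approx(140.50, rel=1e-4)

    def test_total_value(self):
        _, _, v3 = pv.climate_regulation_value(ClimateParameters(3.83), SITE)
        assert v3.amount / 1e4 == pytest.approx(112_737.17, rel=1e-3)


class TestAirPurification:
    SPEC = AirPollutantSpec(
        dust_flux=33200, so2_flux=45, hf_flux=0.57, nox_flux=33.3,
        dust_cost=0.18, so2_cost=1.44, hf_cost=0.83, nox_cost=0.76,
        source_year=2004,
    )

    def test_per_area_flux_cost_sum(self):
        # the published per-area figure is internally inconsistent with its
        # own inputs by ~0.004%; match the formula to 0.5%
        assert self.SPEC.per_area_source_year() == pytest.approx(6066.36, rel=5e-3)
        assert self.SPEC.per_area_source_year() == pytest.approx(6066.5811, rel=1e-9)

    def test_total_from_adjusted_override(self):
        spec = AirPollutantSpec(
            33200, 45, 0.57, 33.3, 0.18, 1.44, 0.83, 0.76,
            source_year=2004, adjusted_per_area_cny_per_hm2=8968.61,
        )
        v4 = pv.air_purification_value(spec, SITE)
        assert v4.amount / 1e6 == pytest.approx(119.94, rel=1e-4)

    def test_formula_path_needs_index(self):
        with pytest.raises(ValueError, match="price-index"):
            pv.air_purification_value(self.SPEC, SITE, idx=None)

    def test_formula_path_with_index(self):
        idx = PriceIndexRatio(2004, 2020, 8968.61 / 6066.36)
        v4 = pv.air_purification_value(self.SPEC, SITE, idx)
        # raw-sum path lands within 0.05% of the override path
        assert v4.amount / 1e6 == pytest.approx(119.94, rel=5e-4)

    def test_zero_fluxes_zero_value(self):
        spec = AirPollutantSpec(0, 0, 0, 0, 0.18, 1.44, 0.83, 0.76, source_year=2004)
        idx = PriceIndexRatio(2004, 2020, 1.5)
        assert pv.air_purification_value(spec, SITE, idx).amount == 0.0


class TestFlatRates:
    @pytest.mark.parametrize(
        "rate, expected_cny",
        [(375.0, 5_015_000), (911.98, 12_196_209), (0.0, 0.0)],
        ids=["pest", "biodiversity", "zero"],
    )
    def test_area_rate(self, rate, expected_cny):
        v = pv.area_rate_value(AreaRateService("svc", rate), SITE)
        assert v.amount == pytest.approx(expected_cny, rel=1e-3, abs=1e-9)


class TestWaterRegulation:
    def test_study_area_value(self):
        v7 = pv.water_regulation_value(WaterParameters(7.22, 0.2), SITE)
        assert v7.amount / 1e6 == pytest.approx(3.09, rel=1e-3)

    def test_zero_standing_water(self):
        dry = SiteProfile(13373.33, 180, 60, 0)
        assert pv.water_regulation_value(WaterParameters(7.22, 0.2), dry).amount == 0.0

    def test_mm_per_day_constructor_is_ten_times(self):
        # 7.22 mm/d over a hectare is 72.2 m3/(hm2 d): exactly 10x the value
        as_mm = pv.water_regulation_value(WaterParameters.from_mm_per_day(7.22, 0.2), SITE)
        as_m3 = pv.water_regulation_value(WaterParameters(7.22, 0.2), SITE)
        assert as_mm.amount == pytest.approx(10 * as_m3.amount, rel=1e-12)


class TestSoilConservation:
    SOIL = SoilProfile(0.2, 1.09, 44.61, 1.32, 0.43, 14.9, 2.75)

    def test_literal_formula_per_area(self):
        per_area, _ = pv.soil_conservation_value(self.SOIL, SITE)
        # hand evaluation: 2000 m3 x 1090 kg/m3 x 0.06126 x 2.75 CNY/kg
        assert per_area == pytest.approx(367_253.7, rel=1e-6)

    def test_zero_nutrients_zero_value(self):
        bare = SoilProfile(0.2, 1.09, 0, 0, 0, 0, 2.75)
        per_area, v8 = pv.soil_conservation_value(bare, SITE)
        assert per_area == 0.0 and v8.amount == 0.0

    def test_linear_in_depth(self):
        deep = SoilProfile(0.4, 1.09, 44.61, 1.32, 0.43, 14.9, 2.75)
        pa1, _ = pv.soil_conservation_value(self.SOIL, SITE)
        pa2, _ = pv.soil_conservation_value(deep, SITE)
        assert pa2 == pytest.approx(2 * pa1, rel=1e-12)

    def test_impossible_mass_fraction_rejected(self):
        with pytest.raises(ValueError, match="1000 g/kg"):
            SoilProfile(0.2, 1.09, 900, 90, 10, 10, 2.75)


CARBON = CarbonBudgetParams(
    root_biomass_kg_per_hm2=2100, root_carbon_fraction=0.346,
    straw_biomass_kg_per_hm2=12400, straw_carbon_fraction=0.414,
    annual_co2_kg_per_hm2=2123.63, annual_ch4_kg_per_hm2=29.64,
)


class TestSoilCarbon:
    def test_budget_components(self):
        isoc, osoc, bsoc = pv.soil_carbon_balance(CARBON)
        assert isoc == pytest.approx(4198, rel=1e-3)
        assert osoc == pytest.approx(595.61, rel=1e-4)
        assert bsoc == pytest.approx(3602.09, rel=1e-5)

    def test_balance_identity_exact(self):
        isoc, osoc, bsoc = pv.soil_carbon_balance(CARBON)
        assert bsoc + osoc == isoc

    def test_value_from_formula(self):
        _, _, bsoc = pv.soil_carbon_balance(CARBON)
        v9 = pv.soil_organic_value(bsoc, 1.53, SITE)
        # hand product of the printed per-area balance, price and area
        assert v9.amount == pytest.approx(3602.0859 * 1.53 * 13373.33, rel=1e-9)

    def test_value_linear_in_price(self):
        assert pv.soil_organic_value(3602.09, 3.06, SITE).amount == pytest.approx(
            2 * pv.soil_organic_value(3602.09, 1.53, SITE).amount
        )

    def test_zero_balance_zero_value(self):
        assert pv.soil_organic_value(0.0, 1.53, SITE).amount == 0.0


class TestOracleEquivalence:
    """Spreadsheet-style re-evaluation of every V-formula on random draws.

    The oracle recomputes each value with plain literal arithmetic on the
    drawn parameters, independently of the package's code paths.
    """

    def test_all_formulas_on_random_draws(self):
        rng = np.random.default_rng(20_220_713)
        for _ in range(100):
            A, D, Tn, Tw = rng.uniform(1, 2e4, 4)
            site = SiteProfile(A, D, Tn, Tw)
            Tr, a, b, c = rng.uniform(1, 1e5), rng.uniform(0.1, 1), rng.uniform(0.5, 3), rng.uniform(0.5, 3)
            Mc, d_gwp = rng.uniform(0.05, 0.95), rng.uniform(1, 50)
            Cc, Co = rng.uniform(10, 1000), rng.uniform(10, 5000)
            g1, g2, g3 = rng.uniform(0, 2), rng.uniform(0, 500), rng.uniform(0, 500)
            gas = GasParameters(Tr, a, b, c, Mc, d_gwp, Cc, Co, g1, g2, g3)

            assert pv.co2_fixation_value(gas).amount == pytest.approx(Tr * a * b * Mc * Cc, rel=1e-9)
            assert pv.o2_release_value(gas).amount == pytest.approx(Tr * a * c * Co, rel=1e-9)
            t = pv.ghg_totals_from_flux(gas, site)
            assert t.ch4_kg == pytest.approx(A * D * g1, rel=1e-9)
            assert t.co2_kg == pytest.approx(A * D * (g2 + g3), rel=1e-9)
            gt = pv.co2_equivalent_t(t, d_gwp)
            assert gt == pytest.approx((A * D * (g2 + g3) + d_gwp * A * D * g1) / 1000, rel=1e-9)
            assert pv.ghg_emission_value(gt, gas).amount == pytest.approx(gt * Mc * Cc, rel=1e-9)

            E, e, P = rng.uniform(0.5, 20), rng.uniform(1, 100), rng.uniform(100, 2000)
            _, _, v3 = pv.climate_regulation_value(ClimateParameters(E, e, P), site)
            assert v3.amount == pytest.approx(E * Tn * (e / 50) * P * A, rel=1e-9)

            q = rng.uniform(0, 1e5, 4)
            p = rng.uniform(0, 10, 4)
            ratio = rng.uniform(0.5, 3)
            spec = AirPollutantSpec(*q, *p, source_year=2004)
            v4 = pv.air_purification_value(spec, site, PriceIndexRatio(2004, 2020, ratio))
            assert v4.amount == pytest.approx(float(q @ p) * ratio * A, rel=1e-9)

            rate = rng.uniform(0, 5000)
            assert pv.area_rate_value(AreaRateService("x", rate), site).amount == pytest.approx(
                rate * A, rel=1e-9
            )

            f, Pw = rng.uniform(0.1, 100), rng.uniform(0.01, 5)
            assert pv.water_regulation_value(WaterParameters(f, Pw), site).amount == pytest.approx(
                f * A * Pw * Tw, rel=1e-9
            )

            ST, SBD, PF = rng.uniform(0.05, 1), rng.uniform(0.5, 2), rng.uniform(0.1, 10)
            som, tn, tp, tk = rng.uniform(0, 100, 4)
            per_area, v8 = pv.soil_conservation_value(
                SoilProfile(ST, SBD, som, tn, tp, tk, PF), site
            )
            want = 10_000 * ST * SBD * 1000 * (som + tn + tp + tk) / 1000 * PF
            assert per_area == pytest.approx(want, rel=1e-9)
            assert v8.amount == pytest.approx(want * A, rel=1e-9)

            Nt, Cr, Ns, Cs = rng.uniform(100, 5000), rng.uniform(0, 1), rng.uniform(100, 2e4), rng.uniform(0, 1)
            rco2, rch4, psoc = rng.uniform(0, 5000), rng.uniform(0, 100), rng.uniform(0.1, 10)
            cb = CarbonBudgetParams(Nt, Cr, Ns, Cs, 5.0, 0.11, rco2, rch4, 0.27, 0.75, psoc)
            isoc, osoc, bsoc = pv.soil_carbon_balance(cb)
            assert isoc == pytest.approx(Nt * 5 * Cr + Ns * 0.11 * Cs, rel=1e-9)
            assert osoc == pytest.approx(rco2 * 0.27 + rch4 * 0.75, rel=1e-9)
            assert pv.soil_organic_value(bsoc, psoc, site).amount == pytest.approx(
                bsoc * psoc * A, rel=1e-9
            )


class TestAreaLinearity:
    def test_every_value_scales_with_area(self):
        # every service value is computed per hm2 first, so doubling the
        # area exactly doubles each area-scaled value
        s1 = SiteProfile(5000, 180, 60, 160)
        s2 = SiteProfile(10000, 180, 60, 160)
        climate = ClimateParameters(3.83)
        water = WaterParameters(7.22, 0.2)
        soil = SoilProfile(0.2, 1.09, 44.61, 1.32, 0.43, 14.9, 2.75)
        pairs = [
            (pv.climate_regulation_value(climate, s1)[2], pv.climate_regulation_value(climate, s2)[2]),
            (pv.water_regulation_value(water, s1), pv.water_regulation_value(water, s2)),
            (pv.soil_conservation_value(soil, s1)[1], pv.soil_conservation_value(soil, s2)[1]),
            (pv.area_rate_value(AreaRateService("p", 375.0), s1),
             pv.area_rate_value(AreaRateService("p", 375.0), s2)),
            (pv.soil_organic_value(3602.09, 1.53, s1), pv.soil_organic_value(3602.09, 1.53, s2)),
        ]
        for small, big in pairs:
            assert big.amount == pytest.approx(2 * small.amount, rel=1e-12)
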