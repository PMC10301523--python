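"""Operating-cost model: medium pricing, factored facility cost, utilities,
labor, calibrations, rollup invariants."""

import numpy as np
import pytest

from algachlor.economics import (
    BBM_PRICES_USD_TON,
    MACRO_SALTS,
    CostFactors,
    EquipmentItem,
    PriceTable,
    annual_facility_cost,
    annual_labor_cost,
    annual_raw_material_cost,
    annual_utility_cost,
    calibrate_floc_dose,
    calibrate_medium_dose_scale,
    default_equipment,
    floc_solution_cost_usd_m3,
    medium_unit_cost,
)
from algachlor.flowsheet import BBM_COMPOSITION_MG_PER_L, FarmSpec, HarvestSpec, run_cultivation
from algachlor.growth import default_params
from algachlor.scenarios import CASES, ScenarioConfig, run_case


class TestMediumUnitCost:
    def test_macro_salts_plus_water(self):
        """The seven macro salts cost ~0.339 USD/m3; with water ~0.599."""
        composition = {k: BBM_COMPOSITION_MG_PER_L[k] for k in MACRO_SALTS}
        cost = medium_unit_cost(PriceTable(), composition=composition)
        salts = sum(v for k, v in cost.items_usd_m3.items() if k != "water")
        assert salts == pytest.approx(0.339251, abs=1e-5)
        assert cost.total_usd_m3 == pytest.approx(0.599251, abs=1e-5)

    def test_zero_dosing_leaves_water_only(self):
        cost = medium_unit_cost(PriceTable(), composition={})
        assert cost.total_usd_m3 == pytest.approx(0.26)

    def test_doubling_doses_doubles_non_water_part(self):
        base = medium_unit_cost(PriceTable(), glucose_dose_g_l=35.0)
        doubled = medium_unit_cost(PriceTable(), glucose_dose_g_l=35.0, dose_scale=2.0)
        base_nutrients = base.total_usd_m3 - 0.26
        assert doubled.total_usd_m3 - 0.26 == pytest.approx(2 * base_nutrients, rel=1e-12)

    def test_missing_price_named(self):
        with pytest.raises(ValueError, match="unobtainium"):
            medium_unit_cost(PriceTable(), composition={"unobtainium": 1.0})


class TestRawMaterials:
    def _cultivation(self, case_id, feed_scale=1.0):
        case = CASES[case_id]
        flow = FarmSpec(residence_time_h=case.residence_time_h).feed_flow * feed_scale
        farm = FarmSpec(residence_time_h=case.residence_time_h, feed_flow_l_h=flow)
        return run_cultivation(case, default_params(case.mode), farm), case

    def test_linear_in_feed_flow(self):
        res1, case = self._cultivation("M1")
        res4, _ = self._cultivation("M1", feed_scale=4.0)
        prices = PriceTable()
        c1 = annual_raw_material_cost(res1, prices, case.glucose_dose_g_l)
        c4 = annual_raw_material_cost(res4, prices, case.glucose_dose_g_l)
        assert c4.total_usd_yr == pytest.approx(4.0 * c1.total_usd_yr, rel=1e-12)

    def test_72h_case_costs_4x_288h_case(self):
        """Same mode and composition at 8160 vs 2040 L/h: exactly x4."""
        res_m1, case_m1 = self._cultivation("M1")
        res_m2, case_m2 = self._cultivation("M2")
        prices = PriceTable()
        c1 = annual_raw_material_cost(res_m1, prices, case_m1.glucose_dose_g_l)
        c2 = annual_raw_material_cost(res_m2, prices, case_m2.glucose_dose_g_l)
        assert c1.total_usd_yr == pytest.approx(4.0 * c2.total_usd_yr, rel=1e-12)

    def test_m1_calibrated_total(self):
        """With the dosing calibration the M1 cultivation raw-material total
        reproduces its 45,874 USD/yr reference within 5%."""
        res, case = self._cultivation("M1")
        prices = PriceTable()
        feed_m3_yr = res.inlet.vol_flow * 7920 / 1000.0
        scale = calibrate_medium_dose_scale(feed_m3_yr, case.glucose_dose_g_l,
                                            prices, 45_874.0)
        cost = annual_raw_material_cost(res, prices, case.glucose_dose_g_l, scale)
        assert cost.total_usd_yr == pytest.approx(45_874.0, rel=0.05)

    def test_flocculant_share_calibration(self):
        """The calibrated chitosan-solution dose makes flocculant cost 87.8%
        of total process raw materials."""
        cfg = ScenarioConfig(calibrate_flocculant=True)
        result = run_case("M1", cfg, scope="process")
        items = result.costs.raw_material_items
        floc = sum(v for (stage, _), v in items.items() if stage == "primary_harvest")
        assert floc / sum(items.values()) == pytest.approx(0.878, abs=1e-3)


class TestUtilities:
    def test_m1_specific_energy(self):
        """Default reactor power reproduces the 173.21 kWh/kg specific energy
        of case M1 within 2%."""
        res, _ = TestRawMaterials()._cultivation("M1")
        cost = annual_utility_cost(res.annual_dry_biomass_kg, res.farm.n_units,
                                   CostFactors(), PriceTable())
        assert cost.specific_energy_kwh_kg == pytest.approx(173.21, rel=0.02)

    def test_pbr_power_dominates(self):
        res, _ = TestRawMaterials()._cultivation("M1")
        cost = annual_utility_cost(res.annual_dry_biomass_kg, res.farm.n_units,
                                   CostFactors(), PriceTable(), include_extraction=True)
        assert cost.pbr_power_share >= 0.99

    def test_zero_power_zero_cost(self):
        cost = annual_utility_cost(1000.0, 2176, CostFactors(pbr_power_kw_per_unit=0.0),
                                   PriceTable())
        assert cost.items[("cultivation", "power")] == 0.0

    def test_zero_production_warns_infinite(self):
        with pytest.warns(UserWarning):
            cost = annual_utility_cost(0.0, 2176, CostFactors(), PriceTable())
        assert cost.specific_energy_kwh_kg == float("inf")


class TestLabor:
    def test_default_matches_reference_total(self):
        assert annual_labor_cost(CostFactors(), PriceTable()) == pytest.approx(8327, rel=0.02)

    def test_single_operator_arithmetic(self):
        cost = annual_labor_cost(CostFactors(operators=1.0), PriceTable())
        assert cost == pytest.approx(2930.40, abs=1e-9)

    def test_zero_operators(self):
        assert annual_labor_cost(CostFactors(operators=0.0), PriceTable()) == 0.0


class TestFacility:
    def test_cultivation_band(self):
        """Factored method with default factors puts the cultivation-stage
        facility cost inside the 4,768,000-4,770,000 USD/yr reference band."""
        equipment = [e for e in default_equipment() if e.stage == "cultivation"]
        by_stage = annual_facility_cost(equipment, CostFactors())
        assert 4_768_000 <= by_stage["cultivation"] <= 4_770_000

    def test_linearity_in_dfc_multiplier(self):
        eq = default_equipment()
        base = annual_facility_cost(eq, CostFactors())
        doubled = annual_facility_cost(eq, CostFactors(dfc_multiplier=12.0))
        for stage in base:
            assert doubled[stage] == pytest.approx(2 * base[stage], rel=1e-12)

    def test_pbr_share_of_equipment(self):
        eq = default_equipment()
        total = sum(e.cost_usd for e in eq)
        pbr = next(e for e in eq if e.name == "photobioreactor")
        assert total == 4_538_000
        assert int(100 * pbr.cost_usd / total) == 95

    def test_empty_equipment_rejected(self):
        with pytest.raises(ValueError):
            annual_facility_cost([], CostFactors())


class TestRollup:
    def test_shares_normalised_and_totals_conserved(self):
        result = run_case("M1", scope="process")
        report = result.costs
        assert report.category_shares.sum() == pytest.approx(1.0, abs=1e-9)
        assert report.stage_shares.sum() == pytest.approx(1.0, abs=1e-9)
        assert report.category_totals.sum() == pytest.approx(report.total_usd_yr, rel=1e-12)
        assert report.stage_totals.sum() == pytest.approx(report.total_usd_yr, rel=1e-12)
        assert (report.matrix.to_numpy() >= 0).all()

    def test_cultivation_stage_dominates(self):
        report = run_case("M1", scope="process").costs
        assert report.stage_shares["cultivation"] > 0.70

    def test_wet_basis_is_paste_mass(self):
        result = run_case("M1", scope="process")
        paste_kg = result.process.annual_paste_mass_kg
        assert result.costs.annual_wet_biomass_kg == pytest.approx(paste_kg)
        # paste at 200 g/L with density 1 kg/L => dry/wet = 0.2
        assert (result.process.annual_paste_biomass_kg / paste_kg
                == pytest.approx(0.2, rel=1e-9))

    def test_parameters_echoed(self):
        report = run_case("M1", scope="process").costs
        params = report.parameters
        assert params["dfc_multiplier"] == 6.0
        assert params["pbr_power_kw_per_unit"] == 1.02
        assert params["outlet_override_used"] is True
        assert params["data_notices"]


class TestCalibrators:
    def test_medium_scale_solves_target_exactly(self):
        prices = PriceTable()
        scale = calibrate_medium_dose_scale(64_627.2, 35.0, prices, 45_874.0)
        cost = medium_unit_cost(prices, 35.0, dose_scale=scale)
        assert cost.total_usd_m3 * 64_627.2 == pytest.approx(45_874.0, rel=1e-9)

    def test_medium_target_below_water_cost_rejected(self):
        with pytest.raises(ValueError, match="water"):
            calibrate_medium_dose_scale(64_627.2, 35.0, PriceTable(), 100.0)

    def test_floc_dose_solves_share(self):
        harvest = HarvestSpec()
        prices = PriceTable()
        dose = calibrate_floc_dose(64_627.2, 50_000.0, harvest, prices, 0.878)
        sol_m3 = dose * 64_627.2 / 1000.0
        floc_cost = sol_m3 * floc_solution_cost_usd_m3(harvest, prices)
        assert floc_cost / (floc_cost + 50_000.0) == pytest.approx(0.878, rel=1e-9)

    def test_acetic_acid_dominates_solution_cost(self):
        # 20% v/v acetic acid at 730 USD/ton is the expensive part
        cost = floc_solution_cost_usd_m3(HarvestSpec(), PriceTable())
        assert cost == pytest.approx(0.2 * 730 + 0.001 * 224 + 0.8 * 0.26, rel=1e-12)
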