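"""Flowsheet units: farm sizing, feed flows, separation train, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algachlor.flowsheet import (
    DENSITY_KG_PER_L,
    ExtractionSpec,
    FarmSpec,
    HarvestSpec,
    Stream,
    bbm_inlet_stream,
    evaporate,
    extract,
    feed_flow_for_residence,
    filter_press,
    flocculate,
    run_cultivation,
    run_process,
    size_farm,
)
from algachlor.growth import default_params
from algachlor.scenarios import CASES


def stream_close(a: Stream, b: Stream, rel=1e-9):
    comps = set(a.mass) | set(b.mass)
    for c in comps:
        assert a.get(c) == pytest.approx(b.get(c), rel=rel, abs=1e-12), c


def total_by_component(*streams):
    out = {}
    for s in streams:
        for c, v in s.mass.items():
            out[c] = out.get(c, 0.0) + v
    return out


def assert_conserved(inlets, outlets, rel=1e-9):
    tin = total_by_component(*inlets)
    tout = total_by_component(*outlets)
    for c in set(tin) | set(tout):
        assert tout.get(c, 0.0) == pytest.approx(tin.get(c, 0.0), rel=rel, abs=1e-9), c


class TestFarmSizing:
    def test_geometric_count_is_ceiling(self):
        spec = FarmSpec(n_units=None)
        size = size_farm(spec)
        assert size.n_units == size.n_units_computed == 2174

    def test_costed_override_wins_with_computed_logged(self):
        size = size_farm(FarmSpec())
        assert size.n_units == 2176
        assert size.n_units_computed == 2174
        assert size.total_volume_l == 2176 * 300

    def test_single_unit_farm(self):
        size = size_farm(FarmSpec(total_area_m2=4.6, n_units=None, feed_flow_l_h=10.0))
        assert size.n_units == 1

    def test_oversized_unit_rejected(self):
        with pytest.raises(ValueError):
            FarmSpec(total_area_m2=4.0, area_per_unit_m2=4.6)


class TestFeedFlow:
    def test_scaling_to_288h(self):
        assert feed_flow_for_residence(288.0) == pytest.approx(2040.0, abs=0)

    def test_identity_at_reference(self):
        assert feed_flow_for_residence(72.0) == 8160.0

    def test_volume_per_residence_period_invariant(self):
        assert 8160 * 72 == feed_flow_for_residence(288.0) * 288 == 587_520

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            feed_flow_for_residence(0.0)


class TestStream:
    def test_vol_mass_consistency(self):
        s = Stream("x", {"water": 990.0, "dry_biomass": 10.0})
        assert s.vol_flow == 1000.0 / DENSITY_KG_PER_L
        assert s.biomass_conc == pytest.approx(10.0)

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            Stream("x", {"gold": 1.0})

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            Stream("x", {"water": -1.0})


class TestCultivation:
    def test_m1_annual_production(self):
        case = CASES["M1"]
        res = run_cultivation(case, default_params(case.mode),
                              FarmSpec(residence_time_h=72.0))
        assert res.annual_dry_biomass_kg == pytest.approx(101_465, rel=1e-3)
        assert res.annual_chlorophyll_kg == pytest.approx(838, rel=2e-3)
        assert res.overridden

    def test_zero_feed_zero_production(self):
        case = CASES["M1"]
        res = run_cultivation(case, default_params(case.mode),
                              FarmSpec(residence_time_h=72.0, feed_flow_l_h=0.0))
        assert res.annual_dry_biomass_kg == 0.0

    def test_glucose_partially_consumed(self):
        case = CASES["H1"]
        res = run_cultivation(case, default_params(case.mode),
                              FarmSpec(residence_time_h=72.0))
        fed = res.inlet.get("glucose")
        assert res.outlet.get("glucose") == pytest.approx(0.075 * fed, rel=1e-9)

    def test_medium_feed_itemises_salts(self):
        s = bbm_inlet_stream(1000.0, glucose_dose_g_l=35.0)
        assert s.get("bbm:NaNO3") == pytest.approx(250e-6 * 1000.0)
        assert s.get("glucose") == pytest.approx(35.0)
        assert s.vol_flow == pytest.approx(1000.0)


@pytest.fixture
def culture() -> Stream:
    """A 100 kg/h biomass culture at ~1.57 g/L (M1-like, scaled)."""
    flow = 100.0 / 1.57 * 1000.0  # L/h
    return Stream("culture", {"dry_biomass": 100.0, "chlorophyll": 0.8,
                              "glucose": 5.0, "water": flow - 105.8})


class TestFlocculation:
    def test_recovery_split(self, culture):
        conc, sup = flocculate(culture, HarvestSpec())
        assert conc.get("dry_biomass") == pytest.approx(80.0)
        assert sup.get("dry_biomass") == pytest.approx(20.0)

    def test_concentrate_volume_from_outlet_conc(self, culture):
        conc, _ = flocculate(culture, HarvestSpec())
        assert conc.vol_flow == pytest.approx(80.0 / 0.050, rel=1e-9)
        assert conc.biomass_conc == pytest.approx(50.0)

    def test_full_recovery_empties_supernatant(self, culture):
        conc, sup = flocculate(culture, HarvestSpec(floc_recovery=1.0))
        assert sup.get("dry_biomass") == 0.0

    def test_mass_conserved_including_dose(self, culture):
        spec = HarvestSpec()
        from algachlor.flowsheet import floc_solution_stream
        dose = floc_solution_stream(culture.vol_flow, spec)
        conc, sup = flocculate(culture, spec)
        assert_conserved([culture, dose], [conc, sup])

    def test_precondition_violation(self):
        thick = Stream("thick", {"dry_biomass": 60.0, "water": 940.0})
        with pytest.raises(ValueError):
            flocculate(thick, HarvestSpec())


class TestFilterPress:
    def test_paste_recovery_and_concentration(self, culture):
        conc, _ = flocculate(culture, HarvestSpec())
        paste, filtrate = filter_press(conc, HarvestSpec())
        assert paste.get("dry_biomass") == pytest.approx(72.0)
        assert paste.biomass_conc == pytest.approx(200.0)

    def test_overall_recovery_is_product_of_stages(self, culture):
        conc, _ = flocculate(culture, HarvestSpec())
        paste, _ = filter_press(conc, HarvestSpec())
        assert paste.get("dry_biomass") / culture.get("dry_biomass") == pytest.approx(0.72)

    def test_mass_conserved_including_wash(self, culture):
        spec = HarvestSpec()
        conc, _ = flocculate(culture, spec)
        wash_water = spec.wash_water_l_per_kg * conc.get("dry_biomass")
        paste, filtrate = filter_press(conc, spec)
        assert_conserved(
            [conc, Stream("wash", {"water": wash_water})], [paste, filtrate])


class TestExtraction:
    def test_methanol_demand_is_half_paste_volume(self):
        paste = Stream("paste", {"dry_biomass": 200.0, "chlorophyll": 1.0,
                                 "water": 799.0})
        organic, spent = extract(paste, ExtractionSpec())
        assert organic.get("methanol") == pytest.approx(paste.vol_flow / 2.0)

    @pytest.mark.parametrize("eff, organic_chl", [(0.9, 0.9), (0.0, 0.0), (1.0, 1.0)])
    def test_efficiency_partition(self, eff, organic_chl):
        paste = Stream("paste", {"dry_biomass": 200.0, "chlorophyll": 1.0,
                                 "water": 799.0})
        organic, spent = extract(paste, ExtractionSpec(extraction_efficiency=eff))
        assert organic.get("chlorophyll") == pytest.approx(organic_chl)
        assert spent.get("chlorophyll") == pytest.approx(1.0 - organic_chl)

    def test_empty_paste_rejected(self):
        with pytest.raises(ValueError):
            extract(Stream("empty", {}), ExtractionSpec())


class TestEvaporation:
    def test_makeup_is_unrecovered_fraction(self):
        organic = Stream("org", {"methanol": 500.0, "chlorophyll": 1.0})
        res = evaporate(organic, ExtractionSpec(solvent_recovery=0.95))
        assert res.makeup_kg_h == pytest.approx(25.0)
        assert res.recycled_solvent.get("methanol") == pytest.approx(475.0)

    def test_full_recovery_zero_makeup(self):
        organic = Stream("org", {"methanol": 500.0, "chlorophyll": 1.0})
        res = evaporate(organic, ExtractionSpec(solvent_recovery=1.0))
        assert res.makeup_kg_h == pytest.approx(0.0)

    def test_chlorophyll_nonvolatile(self):
        organic = Stream("org", {"methanol": 500.0, "chlorophyll": 1.0})
        res = evaporate(organic, ExtractionSpec())
        assert res.product.get("chlorophyll") == pytest.approx(1.0)


class TestRunProcess:
    def test_m1_product_chlorophyll_chain(self):
        case = CASES["M1"]
        res = run_process(case, default_params(case.mode), FarmSpec(residence_time_h=72.0))
        # 838 kg/yr out of the reactor x 0.8 x 0.9 recovery x 0.9 extraction
        assert res.annual_product_chlorophyll_kg == pytest.approx(838.3 * 0.72 * 0.9, rel=2e-3)

    def test_global_balance_closes(self):
        for case_id in ("M1", "F2", "H1"):
            case = CASES[case_id]
            res = run_process(case, default_params(case.mode),
                              FarmSpec(residence_time_h=case.residence_time_h))
            assert res.max_balance_residual() < 1e-6

    def test_all_recoveries_one_moves_everything_to_product(self):
        case = CASES["M1"]
        harvest = HarvestSpec(floc_recovery=1.0, filter_recovery=1.0)
        extraction = ExtractionSpec(extraction_efficiency=1.0)
        res = run_process(case, default_params(case.mode),
                          FarmSpec(residence_time_h=72.0), harvest, extraction)
        assert res.annual_product_chlorophyll_kg == pytest.approx(
            res.annual_chlorophyll_kg, rel=1e-9)

    def test_concentration_ordering_along_train(self):
        case = CASES["M1"]
        res = run_process(case, default_params(case.mode), FarmSpec(residence_time_h=72.0))
        concs = [res.streams["culture_out"].biomass_conc,
                 res.streams["floc_concentrate"].biomass_conc,
                 res.streams["biomass_paste"].biomass_conc]
        assert concs == sorted(concs)
        assert concs[0] == pytest.approx(1.57, rel=1e-9)
        assert concs[1] == pytest.approx(50.0, rel=1e-9)
        assert concs[2] == pytest.approx(200.0, rel=1e-9)

    @pytest.mark.parametrize("param, spec_cls", [
        ("floc_recovery", "harvest"), ("filter_recovery", "harvest"),
        ("extraction_efficiency", "extraction"),
    ])
    def test_product_monotone_in_recoveries(self, param, spec_cls):
        """More recovery at any stage never reduces product chlorophyll."""
        case = CASES["M1"]
        growth_params = default_params(case.mode)
        farm = FarmSpec(residence_time_h=72.0)
        values = [0.5, 0.7, 0.9, 1.0]
        products = []
        for v in values:
            harvest = HarvestSpec(**({param: v} if spec_cls == "harvest" else {}))
            extraction = ExtractionSpec(**({param: v} if spec_cls == "extraction" else {}))
            res = run_process(case, growth_params, farm, harvest, extraction)
            products.append(res.annual_product_chlorophyll_kg)
        assert products == sorted(products)


@settings(max_examples=50, deadline=None)
@given(
    biomass=st.floats(1.0, 400.0),
    chl=st.floats(0.0, 5.0),
    conc_g_l=st.floats(0.5, 30.0),
    floc_recovery=st.floats(0.05, 1.0),
    dose=st.floats(0.0, 50.0),
)
def test_flocculation_conserves_mass_property(biomass, chl, conc_g_l, floc_recovery, dose):
    """Component-wise conservation of the flocculation unit over a wide
    parameter range (<=1e-9 relative)."""
    flow = biomass / conc_g_l * 1000.0
    culture = Stream("c", {"dry_biomass": biomass, "chlorophyll": chl,
                           "water": flow - biomass - chl})
    spec = HarvestSpec(floc_recovery=floc_recovery, floc_dose_l_per_m3=dose)
    from algachlor.flowsheet import floc_solution_stream
    dose_stream = floc_solution_stream(culture.vol_flow, spec)
    conc, sup = flocculate(culture, spec)
    assert_conserved([culture, dose_stream], [conc, sup])
    assert conc.get("dry_biomass") == pytest.approx(floc_recovery * biomass, rel=1e-9)
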