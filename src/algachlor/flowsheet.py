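"""Steady-state mass-balance flowsheet of the 1-ha cultivation and
chlorophyll-extraction process.

The process train: preparation of Bold's Basal Medium (BBM, plus glucose for
the hetero-/mixotrophic modes) → a farm of 300-L airlift photobioreactors
covering 1 ha (4.6 m² each) operated continuously at a 72-h or 288-h
residence time → primary harvest by chitosan flocculation (1 g/L chitosan in
20:80 v/v acetic acid:water; 80% biomass recovery, concentrate at 50 g/L) →
plate-and-frame filter press with a water wash (90% recovery, paste at
200 g/L) → methanol extraction at a 2:1 v/v biomass:solvent ratio (5 min mix,
24 h settling at 4 °C) → evaporation at 60 °C with solvent recycle.

All streams are carried as component mass flows (kg/h); every aqueous stream
and methanol are treated at 1 kg/L for volume↔mass conversion, so a stream's
volumetric flow is its total mass flow.  Each separation unit conserves every
component to ≤1e-9 relative; the photobioreactor is the one unit with
generation terms (biomass and chlorophyll produced, glucose consumed), which
the global balance report accounts for explicitly.

Chlorophyll is intracellular until extraction, so it partitions with the
biomass in the harvest units; dissolved species (glucose, salts, chitosan,
acetic acid) partition with the liquid phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, NamedTuple

import pandas as pd

from .growth import GrowthParams, concentration_at_residence

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import CaseSpec

__all__ = [
    "DENSITY_KG_PER_L",
    "BBM_COMPOSITION_MG_PER_L",
    "Stream",
    "FarmSpec",
    "FarmSize",
    "HarvestSpec",
    "ExtractionSpec",
    "size_farm",
    "feed_flow_for_residence",
    "bbm_inlet_stream",
    "run_cultivation",
    "CultivationResult",
    "flocculate",
    "filter_press",
    "extract",
    "evaporate",
    "run_process",
    "ProcessResult",
    "OPERATING_HOURS_PER_YEAR",
]

#: all liquids (water, medium, methanol) at 1 kg/L — documented simplification
DENSITY_KG_PER_L = 1.0

#: continuous operation, 330 days/yr
OPERATING_HOURS_PER_YEAR = 330 * 24

#: BBM dosing, mg per litre of prepared medium.  Macro salts are dosed
#: directly; the three stock solutions (microelements, EDTA/KOH, iron) are
#: dosed at 1 mL of stock per litre, so grams-per-litre-of-stock become
#: mg per litre of medium.  H2SO4: 1 mL concentrated acid per litre of stock
#: at 1.84 g/mL.
BBM_COMPOSITION_MG_PER_L: dict[str, float] = {
    "KH2PO4": 175.0,
    "CaCl2.2H2O": 25.0,
    "MgSO4.7H2O": 75.0,
    "NaNO3": 250.0,
    "K2HPO4": 75.0,
    "NaCl": 25.0,
    "H3BO3": 11.42,
    "ZnSO4.7H2O": 8.82,
    "MnCl2.4H2O": 1.44,
    "MoO3": 0.71,
    "CuSO4.5H2O": 1.57,
    "Co(NO3)2.6H2O": 0.49,
    "Na2EDTA": 50.0,
    "KOH": 3.1,
    "FeSO4": 4.98,
    "H2SO4": 1.84,
}

_CORE_COMPONENTS = (
    "water", "dry_biomass", "chlorophyll", "glucose",
    "chitosan", "acetic_acid", "methanol",
)
#: closed component set: core species + itemised BBM reagents
COMPONENTS: tuple[str, ...] = _CORE_COMPONENTS + tuple(
    f"bbm:{name}" for name in BBM_COMPOSITION_MG_PER_L
)
_BBM_KEYS = tuple(f"bbm:{name}" for name in BBM_COMPOSITION_MG_PER_L)
#: species that travel with the liquid phase in solid/liquid separations
_DISSOLVED = ("glucose", "chitosan", "acetic_acid", "methanol") + _BBM_KEYS


@dataclass
class Stream:
    """A process stream: component mass flows in kg/h.

    Volumetric flow is derived from total mass at 1 kg/L.  Component names
    outside :data:`COMPONENTS` are rejected; tiny negative flows from
    floating-point cancellation (> −1e-9) are snapped to zero.
    """

    name: str
    mass: dict[str, float] = field(default_factory=dict)
    temperature: float | None = None

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for comp, flow in self.mass.items():
            if comp not in COMPONENTS:
                raise ValueError(f"unknown stream component {comp!r}")
            if flow < -1e-9:
                raise ValueError(f"negative flow for {comp!r} in stream {self.name!r}: {flow}")
            clean[comp] = max(float(flow), 0.0)
        self.mass = clean

    def get(self, comp: str) -> float:
        if comp not in COMPONENTS:
            raise ValueError(f"unknown stream component {comp!r}")
        return self.mass.get(comp, 0.0)

    @property
    def total_mass(self) -> float:
        """Total mass flow, kg/h."""
        return sum(self.mass.values())

    @property
    def vol_flow(self) -> float:
        """Volumetric flow, L/h (total mass at 1 kg/L)."""
        return self.total_mass / DENSITY_KG_PER_L

    def conc(self, comp: str) -> float:
        """Component concentration, g/L."""
        v = self.vol_flow
        return 1000.0 * self.get(comp) / v if v > 0 else 0.0

    @property
    def biomass_conc(self) -> float:
        """Dry-biomass concentration, g/L."""
        return self.conc("dry_biomass")

    def with_name(self, name: str) -> "Stream":
        return Stream(name, dict(self.mass), self.temperature)

    def __add__(self, other: "Stream") -> "Stream":
        merged = dict(self.mass)
        for comp, flow in other.mass.items():
            merged[comp] = merged.get(comp, 0.0) + flow
        return Stream(f"{self.name}+{other.name}", merged)


@dataclass(frozen=True)
class FarmSpec:
    """Geometry and feed basis of the photobioreactor farm.

    ``n_units`` defaults to 2176, the unit count used for equipment costing;
    the geometric count ceil(total_area / area_per_unit) = 2174 is always
    computed and reported alongside (the two differ in the source material,
    and the costed count wins).  Feed flows are configuration values
    (8160 L/h at 72 h, 2040 L/h at 288 h) rather than derived from farm
    volume, whose basis is not stated.
    """

    total_area_m2: float = 10_000.0
    area_per_unit_m2: float = 4.6
    unit_volume_l: float = 300.0
    n_units: int | None = 2176
    residence_time_h: float = 72.0
    feed_flow_l_h: float | None = None

    def __post_init__(self) -> None:
        for val, name in ((self.total_area_m2, "total_area_m2"),
                          (self.area_per_unit_m2, "area_per_unit_m2"),
                          (self.unit_volume_l, "unit_volume_l"),
                          (self.residence_time_h, "residence_time_h")):
            if not val > 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if self.n_units is not None and self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.area_per_unit_m2 > self.total_area_m2:
            raise ValueError("area_per_unit_m2 exceeds total_area_m2")

    @property
    def feed_flow(self) -> float:
        """Feed flow, L/h; defaults to the 8160 L/h @ 72 h reference scaled
        to the residence time."""
        if self.feed_flow_l_h is not None:
            return self.feed_flow_l_h
        return feed_flow_for_residence(self.residence_time_h)


class FarmSize(NamedTuple):
    n_units: int
    n_units_computed: int
    total_volume_l: float
    per_unit_throughput_l_h: float


def size_farm(spec: FarmSpec) -> FarmSize:
    """Number of reactors, installed volume, per-unit throughput.

    The geometric count is ceil(total_area / area_per_unit); an explicit
    ``spec.n_units`` (the costed count) wins, with the computed value
    reported alongside.
    """
    computed = math.ceil(spec.total_area_m2 / spec.area_per_unit_m2)
    used = spec.n_units if spec.n_units is not None else computed
    total_volume = used * spec.unit_volume_l
    return FarmSize(used, computed, total_volume, spec.feed_flow / used)


def feed_flow_for_residence(tau: float, reference: tuple[float, float] = (72.0, 8160.0)) -> float:
    """Feed flow (L/h) at residence time ``tau`` from a reference pair,
    holding the volume fed per residence period constant:
    flow = flow_ref * tau_ref / tau (8160 L/h @ 72 h ⇒ 2040 L/h @ 288 h)."""
    if not tau > 0:
        raise ValueError(f"residence time must be positive, got {tau}")
    tau_ref, flow_ref = reference
    if not (tau_ref > 0 and flow_ref >= 0):
        raise ValueError("reference residence time must be positive and flow non-negative")
    return flow_ref * tau_ref / tau


@dataclass(frozen=True)
class HarvestSpec:
    """Primary harvest (chitosan flocculation) and filter-press parameters.

    The chitosan solution is 1 g/L chitosan in 20:80 v/v acetic acid:water,
    dosed at ``floc_dose_l_per_m3`` litres of solution per m³ of culture (the
    dose itself is a configuration value; the source process does not state
    it).  Wash-water use in the filter press is likewise configurable.
    """

    floc_recovery: float = 0.80
    floc_outlet_conc_g_l: float = 50.0
    chitosan_conc_g_l: float = 1.0
    acetic_fraction_v: float = 0.20
    floc_dose_l_per_m3: float = 10.0
    filter_recovery: float = 0.90
    filter_outlet_conc_g_l: float = 200.0
    wash_water_l_per_kg: float = 1.0

    def __post_init__(self) -> None:
        for frac, name in ((self.floc_recovery, "floc_recovery"),
                           (self.filter_recovery, "filter_recovery")):
            if not (0 < frac <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {frac}")
        if not (0 <= self.acetic_fraction_v < 1):
            raise ValueError("acetic_fraction_v must lie in [0, 1)")
        if not (0 < self.floc_outlet_conc_g_l < self.filter_outlet_conc_g_l):
            raise ValueError("outlet concentrations must increase along the train")
        if self.floc_dose_l_per_m3 < 0 or self.wash_water_l_per_kg < 0:
            raise ValueError("doses must be non-negative")
        if self.chitosan_conc_g_l < 0:
            raise ValueError("chitosan_conc_g_l must be non-negative")


@dataclass(frozen=True)
class ExtractionSpec:
    """Methanol extraction and evaporation parameters.

    ``biomass_to_solvent_v`` is the printed 2:1 v/v biomass:solvent ratio, so
    methanol demand = paste volume / 2.  Extraction efficiency and solvent
    recovery are not printed in the source process; the defaults 0.90 and
    0.95 are configuration values surfaced in every report.
    """

    biomass_to_solvent_v: float = 2.0
    mix_time_min: float = 5.0
    settle_time_h: float = 24.0
    settle_temp_c: float = 4.0
    extraction_efficiency: float = 0.90
    evap_temp_c: float = 60.0
    solvent_recovery: float = 0.95

    def __post_init__(self) -> None:
        if not self.biomass_to_solvent_v > 0:
            raise ValueError("biomass_to_solvent_v must be positive")
        for frac, name in ((self.extraction_efficiency, "extraction_efficiency"),
                           (self.solvent_recovery, "solvent_recovery")):
            if not (0 <= frac <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")


def bbm_inlet_stream(flow_l_h: float, glucose_dose_g_l: float = 0.0,
                     name: str = "medium_feed") -> Stream:
    """Prepared-medium feed: water plus itemised BBM salts (and glucose for
    hetero-/mixotrophic modes) at the given volumetric flow."""
    if flow_l_h < 0:
        raise ValueError("flow must be non-negative")
    mass: dict[str, float] = {}
    solutes = 0.0
    for reagent, dose_mg_l in BBM_COMPOSITION_MG_PER_L.items():
        kg_h = dose_mg_l * 1e-6 * flow_l_h
        mass[f"bbm:{reagent}"] = kg_h
        solutes += kg_h
    if glucose_dose_g_l:
        mass["glucose"] = glucose_dose_g_l * 1e-3 * flow_l_h
        solutes += mass["glucose"]
    total = flow_l_h * DENSITY_KG_PER_L
    if solutes > total:
        raise ValueError("solute mass exceeds stream mass; check dosing")
    mass["water"] = total - solutes
    return Stream(name, mass)


class CultivationResult(NamedTuple):
    inlet: Stream
    outlet: Stream
    farm: FarmSize
    annual_dry_biomass_kg: float
    annual_chlorophyll_kg: float
    overridden: bool


def run_cultivation(case: "CaseSpec", growth_params: GrowthParams,
                    farm: FarmSpec) -> CultivationResult:
    """Continuous cultivation: medium feed in, culture out, annualised.

    Outlet biomass/chlorophyll concentrations come from the growth model at
    the case's residence time, or from the case's measured outlet override
    when present.  Annual masses use 330 operating days.  Glucose is consumed
    at the growth parameters' consumption fraction; biomass and chlorophyll
    appear as generation terms (the reactor is not a conserving unit).
    """
    if case.residence_time_h != farm.residence_time_h:
        raise ValueError(
            f"case residence time {case.residence_time_h} h does not match "
            f"farm residence time {farm.residence_time_h} h")
    flow = farm.feed_flow
    inlet = bbm_inlet_stream(flow, case.glucose_dose_g_l)
    override = case.outlet_override_model_units()
    conc = concentration_at_residence(growth_params, case.residence_time_h, override)

    biomass_kg_h = conc.biomass_g_l * 1e-3 * flow
    chl_kg_h = conc.chlorophyll_ug_ml * 1e-6 * flow  # µg/mL ≡ mg/L
    glucose_out = inlet.get("glucose") * (1.0 - growth_params.glucose_consumption)

    mass = {comp: inlet.get(comp) for comp in _BBM_KEYS}
    mass["dry_biomass"] = biomass_kg_h
    mass["chlorophyll"] = chl_kg_h
    mass["glucose"] = glucose_out
    solutes = sum(mass.values())
    total = flow * DENSITY_KG_PER_L
    mass["water"] = max(total - solutes, 0.0)
    outlet = Stream("culture_out", mass)

    hours = OPERATING_HOURS_PER_YEAR
    return CultivationResult(
        inlet, outlet, size_farm(farm),
        annual_dry_biomass_kg=biomass_kg_h * hours,
        annual_chlorophyll_kg=chl_kg_h * hours,
        overridden=conc.overridden,
    )


def _split_solids(inlet: Stream, recovery: float, outlet_conc_g_l: float,
                  conc_name: str, rem_name: str) -> tuple[Stream, Stream]:
    """Split a suspension into a concentrate at a set biomass concentration
    and a remainder carrying the rest; dissolved species and water follow the
    liquid phase pro-rata."""
    if inlet.biomass_conc >= outlet_conc_g_l:
        raise ValueError(
            f"inlet biomass concentration {inlet.biomass_conc:.3g} g/L is not "
            f"below the outlet target {outlet_conc_g_l} g/L")
    b_in = inlet.get("dry_biomass")
    chl_in = inlet.get("chlorophyll")
    b_conc = recovery * b_in
    chl_conc = recovery * chl_in
    v_conc = 1000.0 * b_conc / outlet_conc_g_l if b_conc > 0 else 0.0
    # solid phase = biomass + intracellular chlorophyll; liquid volume =
    # total volume − solid volume (all at 1 kg/L)
    liq_in = inlet.vol_flow - (b_in + chl_in) / DENSITY_KG_PER_L
    liq_conc = v_conc - (b_conc + chl_conc) / DENSITY_KG_PER_L
    if liq_conc < 0 or liq_conc > liq_in:
        raise ValueError("infeasible concentrate liquid balance")
    f = liq_conc / liq_in if liq_in > 0 else 0.0

    conc_mass = {"dry_biomass": b_conc, "chlorophyll": chl_conc,
                 "water": f * inlet.get("water")}
    rem_mass = {"dry_biomass": b_in - b_conc, "chlorophyll": (1 - recovery) * chl_in,
                "water": (1 - f) * inlet.get("water")}
    for comp in _DISSOLVED:
        flow = inlet.get(comp)
        if flow:
            conc_mass[comp] = f * flow
            rem_mass[comp] = (1 - f) * flow
    return Stream(conc_name, conc_mass), Stream(rem_name, rem_mass)


def floc_solution_stream(culture_vol_l_h: float, spec: HarvestSpec,
                         name: str = "floc_solution") -> Stream:
    """Chitosan flocculant solution dosed to a culture flow: chitosan at
    ``chitosan_conc_g_l`` in acetic acid:water (``acetic_fraction_v`` v/v)."""
    dose_l_h = spec.floc_dose_l_per_m3 * culture_vol_l_h / 1000.0
    chitosan = spec.chitosan_conc_g_l * 1e-3 * dose_l_h
    acetic = spec.acetic_fraction_v * dose_l_h * DENSITY_KG_PER_L
    water = dose_l_h * DENSITY_KG_PER_L - chitosan - acetic
    return Stream(name, {"chitosan": chitosan, "acetic_acid": acetic, "water": water})


def flocculate(inlet: Stream, spec: HarvestSpec) -> tuple[Stream, Stream]:
    """Chitosan flocculation: 80% of biomass into a 50 g/L concentrate.

    The flocculant solution is dosed per m³ of incoming culture and tracked;
    the supernatant carries unrecovered biomass and displaced medium.
    """
    dosed = (inlet + floc_solution_stream(inlet.vol_flow, spec)).with_name("floc_mixed")
    return _split_solids(dosed, spec.floc_recovery, spec.floc_outlet_conc_g_l,
                         "floc_concentrate", "floc_supernatant")


def filter_press(inlet: Stream, spec: HarvestSpec,
                 ) -> tuple[Stream, Stream]:
    """Filter press with water wash: 90% of biomass into a 200 g/L paste."""
    wash_l_h = spec.wash_water_l_per_kg * inlet.get("dry_biomass")
    washed = (inlet + Stream("wash_water", {"water": wash_l_h * DENSITY_KG_PER_L})
              ).with_name("filter_feed")
    paste, filtrate = _split_solids(
        washed, spec.filter_recovery, spec.filter_outlet_conc_g_l,
        "biomass_paste", "filtrate")
    return paste, filtrate


def extract(paste: Stream, spec: ExtractionSpec,
            methanol_feed: Stream | None = None) -> tuple[Stream, Stream]:
    """Methanol extraction of chlorophyll from the biomass paste.

    Methanol demand is paste volume / biomass_to_solvent_v (the 2:1 v/v
    biomass:solvent ratio).  The stated fraction of the chlorophyll transfers
    to the organic phase; biomass, water and dissolved salts leave in the
    spent stream.
    """
    if paste.vol_flow <= 0:
        raise ValueError("extraction requires a non-empty paste stream")
    demand_kg_h = paste.vol_flow / spec.biomass_to_solvent_v * DENSITY_KG_PER_L
    if methanol_feed is None:
        methanol_feed = Stream("methanol_feed", {"methanol": demand_kg_h})
    elif abs(methanol_feed.get("methanol") - demand_kg_h) > 1e-6 * max(demand_kg_h, 1.0):
        raise ValueError(
            f"methanol feed {methanol_feed.get('methanol'):.6g} kg/h does not "
            f"match the 1:{spec.biomass_to_solvent_v:g} demand {demand_kg_h:.6g} kg/h")

    chl_in = paste.get("chlorophyll")
    chl_extracted = spec.extraction_efficiency * chl_in
    organic = Stream("organic_phase", {
        "methanol": methanol_feed.get("methanol"),
        "chlorophyll": chl_extracted,
    }, temperature=spec.settle_temp_c)
    spent_mass = dict(paste.mass)
    spent_mass["chlorophyll"] = chl_in - chl_extracted
    spent = Stream("spent_biomass", spent_mass)
    return organic, spent


class EvaporationResult(NamedTuple):
    product: Stream
    recycled_solvent: Stream
    makeup_kg_h: float


def evaporate(organic: Stream, spec: ExtractionSpec) -> EvaporationResult:
    """Evaporate methanol off the organic phase at 60 °C.

    ``solvent_recovery`` of the methanol is condensed and recycled; the
    remainder leaves with the chlorophyll product.  At steady state the
    makeup requirement equals demand − recycled.  Chlorophyll is
    non-volatile: all of it stays in the product.
    """
    meoh = organic.get("methanol")
    if meoh <= 0:
        raise ValueError("organic phase carries no methanol to evaporate")
    recycled = spec.solvent_recovery * meoh
    product = Stream("chlorophyll_product", {
        "chlorophyll": organic.get("chlorophyll"),
        "methanol": meoh - recycled,
    }, temperature=spec.evap_temp_c)
    recycle = Stream("solvent_recycle", {"methanol": recycled})
    return EvaporationResult(product, recycle, makeup_kg_h=meoh - recycled)


@dataclass(frozen=True)
class ProcessResult:
    """All streams of one steady-state case plus annualised production and a
    component balance report."""

    case_id: str
    streams: dict[str, Stream]
    farm: FarmSize
    annual_dry_biomass_kg: float
    annual_chlorophyll_kg: float
    annual_product_chlorophyll_kg: float
    annual_paste_biomass_kg: float
    annual_paste_mass_kg: float
    methanol_makeup_kg_h: float
    overridden: bool
    balance: dict[str, dict[str, float]]

    def stream_table(self) -> pd.DataFrame:
        """One row per stream, one column per component (kg/h) plus volume."""
        rows = {}
        for name, s in self.streams.items():
            row = {comp: s.get(comp) for comp in COMPONENTS}
            row["vol_flow_l_h"] = s.vol_flow
            rows[name] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def max_balance_residual(self) -> float:
        """Largest relative component-balance residual (should be ≲1e-6)."""
        return max(abs(rec["relative_residual"]) for rec in self.balance.values())


def _component_balance(inputs: list[Stream], outputs: list[Stream],
                       generation: dict[str, float]) -> dict[str, dict[str, float]]:
    report: dict[str, dict[str, float]] = {}
    for comp in COMPONENTS:
        total_in = sum(s.get(comp) for s in inputs)
        total_out = sum(s.get(comp) for s in outputs)
        gen = generation.get(comp, 0.0)
        residual = total_in + gen - total_out
        scale = max(total_in + max(gen, 0.0), total_out, 1e-12)
        report[comp] = {
            "in_kg_h": total_in, "generation_kg_h": gen, "out_kg_h": total_out,
            "residual_kg_h": residual, "relative_residual": residual / scale,
        }
    return report


def run_process(case: "CaseSpec", growth_params: GrowthParams, farm: FarmSpec,
                harvest: HarvestSpec | None = None,
                extraction: ExtractionSpec | None = None) -> ProcessResult:
    """Chain all units of the chlorophyll process for one case.

    Any unit failure is re-raised with the unit named.  The balance report
    checks every component globally (inputs + generation − outputs), with the
    solvent recycle treated as an internal stream.
    """
    harvest = harvest or HarvestSpec()
    extraction = extraction or ExtractionSpec()

    def _unit(name, fn, *args):
        try:
            return fn(*args)
        except ValueError as exc:
            raise ValueError(f"unit '{name}' failed: {exc}") from exc

    cult = _unit("cultivation", run_cultivation, case, growth_params, farm)
    floc_sol = floc_solution_stream(cult.outlet.vol_flow, harvest)
    concentrate, supernatant = _unit("flocculation", flocculate, cult.outlet, harvest)
    wash_l_h = harvest.wash_water_l_per_kg * concentrate.get("dry_biomass")
    wash = Stream("wash_water", {"water": wash_l_h * DENSITY_KG_PER_L})
    paste, filtrate = _unit("filter_press", filter_press, concentrate, harvest)
    organic, spent = _unit("extraction", extract, paste, extraction)
    evap = _unit("evaporation", evaporate, organic, extraction)
    makeup = Stream("methanol_makeup", {"methanol": evap.makeup_kg_h})

    streams = {
        "medium_feed": cult.inlet, "culture_out": cult.outlet,
        "floc_solution": floc_sol, "floc_concentrate": concentrate,
        "floc_supernatant": supernatant, "wash_water": wash,
        "biomass_paste": paste, "filtrate": filtrate,
        "organic_phase": organic, "spent_biomass": spent,
        "chlorophyll_product": evap.product, "solvent_recycle": evap.recycled_solvent,
        "methanol_makeup": makeup,
    }

    # reactor generation terms: biomass/chlorophyll formed, glucose consumed,
    # and the net water change that closes the reactor's overall balance
    # (metabolic water / CO2 exchange are not tracked as separate species)
    generation = {
        comp: cult.outlet.get(comp) - cult.inlet.get(comp)
        for comp in ("dry_biomass", "chlorophyll", "glucose", "water")
    }
    balance = _component_balance(
        inputs=[cult.inlet, floc_sol, wash, makeup],
        outputs=[supernatant, filtrate, spent, evap.product],
        generation=generation,
    )

    hours = OPERATING_HOURS_PER_YEAR
    return ProcessResult(
        case_id=case.case_id,
        streams=streams,
        farm=cult.farm,
        annual_dry_biomass_kg=cult.annual_dry_biomass_kg,
        annual_chlorophyll_kg=cult.annual_chlorophyll_kg,
        annual_product_chlorophyll_kg=evap.product.get("chlorophyll") * hours,
        annual_paste_biomass_kg=paste.get("dry_biomass") * hours,
        annual_paste_mass_kg=paste.total_mass * hours,
        methanol_makeup_kg_h=evap.makeup_kg_h,
        overridden=cult.overridden,
        balance=balance,
    )
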