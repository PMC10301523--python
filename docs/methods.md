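# Methods

This note documents the models behind `algachlor`, the parameter defaults
and where they come from, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design was
genuinely open.

## Assay calibrations

Biomass is assayed as optical density at 680 nm and converted with the
fitted line DCW = 0.2983·OD₆₈₀ − 0.05 (g/L, R² = 0.9792). The calibration is
treated as consortium-wide (species-resolved calibrations are not
available). Chlorophyll *a*/*b* come from the standard two-wavelength linear
system for methanol extracts (A₆₅₂, A₆₆₅; coefficients in
`calibration.CalibrationCoefficients`). The published ± tolerances of the
chlorophyll equations (0.04696 and 0.05776 µg/mL) are stored as metadata and
used only in reporting — the conversion itself is exact linear algebra, and
the 2×2 system (determinant ≈ −354.711) is inverted exactly for the
synthetic-data path.

Because the DCW line has a negative intercept and the chlorophyll system has
negative coefficients, raw conversions can be negative at low absorbance.
Concentrations are physical quantities and the downstream mass balances
require non-negativity, so negative raw values are clipped to zero and
flagged rather than propagated. Note the default chlorophyll matrix has an
elementwise-positive inverse, so every non-negative pigment pair maps to
feasible absorbances; the infeasibility guard in
`absorbance_from_chlorophyll` matters only for user-supplied coefficient
sets.

## Growth model

No kinetic law is attached to the source growth curves, which are saturating
over 288 h; the package uses the three-parameter logistic, the minimal
saturating model with interpretable parameters (carrying capacity K g/L,
specific rate r 1/h, inoculum x₀ g/L). Defaults per mode:

| mode          | K (g/L) | r (1/h) | x₀ (g/L) | chl ratio (µg/mg) |
|---------------|---------|---------|----------|-------------------|
| phototrophic  | 0.5740  | 0.018   | 0.2      | 35.793            |
| heterotrophic | 2.0687  | 0.10    | 0.2      | 1.6224            |
| mixotrophic   | 1.9888  | 0.049   | 0.2      | 6.8089            |

K is the measured 288-h biomass maximum of each mode and x₀ the 200 mg/L
inoculum. The rates are calibrated a priori to two qualitative anchors: each
curve sits within ~1% of its plateau at 288 h, and the 72-h level matches
the continuous study's relative outlet concentrations where the logistic can
(mixotrophic r = 0.049 puts x(72 h) ≈ 1.57 g/L; heterotrophic r = 0.10
reaches plateau by 72 h, as the near-equal 72-h/288-h outlet pair requires).
The phototrophic 72-h outlet (0.04 g/L) is *below* the 0.2 g/L inoculum and
therefore unreachable by any monotone growth law from that inoculum; the
phototrophic rate (0.018) only enforces the 288-h anchor, and the measured
outlet pairs are handled by per-case overrides (below).

Chlorophyll is modelled as proportional to biomass with a mode-specific
ratio (the measured chlorophyll maximum over the biomass maximum); pigment
kinetics beyond the endpoint pairs are not available. Glucose fed to the
hetero-/mixotrophic cultures (35 g/L) is consumed at a fixed 92.5% — the
midpoint of the observed 90–95% organic-carbon remobilisation — and the
remainder leaves in the reactor outlet.

`LogisticGrowthModel.fit()` uses bounded Levenberg–Marquardt/TRF least
squares (`scipy.optimize.curve_fit`) with deterministic data-driven starting
values (K from the series maximum, x₀ from the first point, r from the
half-saturation crossing time). Noiseless model data are recovered to
≤1e-6 relative; a fitted K within 5% of x₀ is flagged `degenerate`
(flat series carry no growth signal); non-convergence raises
`GrowthFitError` with the starting point in the message.

## Synthetic experiments

`synthdata.generate_experiment` emulates the 12-day triplicate bench
experiments: 13 time points over 288 h (daily sampling), 3 replicates per
point, noiseless instrument readings obtained by pushing the model
trajectories through the *inverse* calibrations, and additive Gaussian noise
(σ = 0.02 absorbance units on OD and on each absorbance, truncated at zero)
applied to the readings — measurement error arises at the spectrophotometer,
not in the culture. The error-bar magnitudes of the real experiments are not
published; σ = 0.02 is a typical instrument repeatability and is a
documented assumption. The chlorophyll a:b split required to invert the
two-wavelength system is fixed at 75% chlorophyll *a* (the usual ~3:1 ratio
in green algae); the observable total is split-invariant. Per-timepoint
measurements are analysed as replicate means, as an experimenter would plot
them.

The generator does **not** emulate species composition or succession within
the consortium, bacterial contamination, photoperiod/light-gradient effects,
or heteroscedastic/multiplicative instrument error. Passing recovery tests
therefore show that the analysis pipeline is consistent and well-conditioned
under the stated noise model, not that real consortium data will fit a
logistic this cleanly.

One consequence of the noise model worth knowing: total chlorophyll is a
linear combination of the two absorbances with weights (19.34, 4.35), so
absorbance noise is amplified ~20× (σ ≈ 0.40 µg/mL per reading, ≈ 0.23
after triplicate averaging). The *maximum* over the many near-plateau points
of a fast-saturating run is then upward-biased by ~1.5σ. This is negligible
against the phototrophic signal (~20.5 µg/mL) but is ~+8% of the small
heterotrophic signal (3.36 µg/mL): the per-experiment maximum statistic
overestimates that mode's chlorophyll plateau by construction, and the
package reports the statistic honestly rather than debiasing it.

## Flowsheet

Continuous steady state, 330 operating days (7920 h) per year. Farm: 1 ha at
4.6 m² per 300-L airlift unit gives a geometric count of ⌈10,000/4.6⌉ = 2174
units; the equipment-costed count is 2176 and is used by default, with the
geometric count always reported alongside. Feed flows are configuration
values — 8160 L/h at 72 h residence and 2040 L/h at 288 h, related by
flow·τ = constant (587,520 L per residence period) — rather than derived
from installed volume, whose basis is not stated in the source design.

Unit operations and their fixed points:

* **Flocculation** — chitosan solution (1 g/L in 20:80 v/v acetic
  acid:water) dosed at 10 L of solution per m³ of culture (default; the true
  dose is not published, and an optional calibration mode solves the dose
  instead — see Economics); 80% of biomass to a 50 g/L concentrate.
* **Filter press** — wash water at 1 L per kg of incoming biomass (default;
  not published); 90% of biomass to a 200 g/L paste.
* **Extraction** — methanol at paste volume / 2 (the printed 2:1 v/v
  biomass:solvent ratio, read with the parenthetical ordering); 5 min mix,
  24 h settling at 4 °C; extraction efficiency 0.90 (not published;
  configurable and echoed in reports).
* **Evaporation** — 60 °C; 95% of methanol recycled (not published;
  configurable), makeup = demand − recycle at steady state; chlorophyll is
  non-volatile.

Numerical conventions: all aqueous streams and methanol at 1 kg/L, so
volumetric flow ≡ total mass flow; intracellular chlorophyll travels with
the biomass (solid phase) in every separation, dissolved species with the
liquid, pro-rata by liquid volume. Every separation unit conserves each
component to ≤1e-9 relative. The photobioreactor is the one non-conserving
unit: its generation terms (biomass and chlorophyll formed, glucose
consumed, and the compensating net water change — CO₂ and metabolic water
are not tracked as species) are reported explicitly, and the global balance
then closes to ≤1e-6 relative (machine precision in practice). Supernatant
and filtrate are reported as recyclable water by-products but not re-fed.

The measured outlet concentrations of the six study cases (F/H/M × 72/288 h)
override the growth model's prediction by default, because the continuous
study's outlet pairs are not exactly reproducible by any single logistic
parameterisation (e.g. the heterotrophic 72-h outlet exceeds the 288-h one).
Every result flags whether the override was used; disable with
`use_table_overrides: false` to run in pure model mode.

## Economics

Stage × category matrix (cultivation, primary harvest, secondary harvest,
extraction × raw materials, labor, facility, utilities), with unit costs per
kg dry biomass, per kg wet biomass (paste mass at 200 g/L, i.e. dry/0.2) and
per kg chlorophyll product.

* **Raw materials** — itemised at market prices (USD/ton) per reagent of
  Bold's Basal Medium, dosed directly (macro salts, mg/L) or via stock
  solutions at 1 mL/L; water at 0.26 USD/m³; glucose and methanol prices are
  not published and default to market-range 450 and 400 USD/ton.
* **Labor** — 2.84 operator-equivalents × 0.37 USD/h × 7920 h ≈ 8323 USD/yr
  (the operator count is calibrated to the published annual labor total; the
  0.37 USD/h rate is the price-table value, preferred over a 0.39 figure
  appearing in prose). Labor is allocated to stages pro-rata by equipment
  cost, the same driver as the facility charge.
* **Facility-dependent** — a factored method replaces the proprietary
  simulator's internal correlations: DFC = `dfc_multiplier` × total
  equipment purchase cost and annual cost = `facility_annual_fraction` ×
  DFC, allocated pro-rata by stage equipment cost. Defaults 6.0 and 0.1826
  are calibrated so the cultivation stage (4,353,000 USD of equipment)
  yields ≈4.769 M USD/yr, inside the published 4,768–4,770 k band; a DFC of
  6× equipment and an 18.3%/yr charge (maintenance + depreciation +
  insurance/taxes) are ordinary magnitudes for this method.
* **Utilities** — photobioreactor power at 1.02 kW per unit continuously,
  calibrated so the M1 case's specific energy reproduces the published
  173.21 kWh per kg dry biomass; reactor power is >99.9% of process
  electricity. The extraction stage's small chilled-water/steam/glycol/power
  duties default to the published annual values of the reference process.

Two optional calibrations close gaps left by unpublished prices/doses, both
off by default and echoed in `CostReport.parameters` when active:
`calibrate_dosing` rescales nutrient + glucose dosing so the M1
cultivation raw-material total matches 45,874 USD/yr (at face-value market
prices the 35 g/L glucose feed alone would cost ~1 M USD/yr, which is
irreconcilable with that total), and `calibrate_flocculant` solves the
chitosan-solution dose so flocculant cost reaches 87.8% of process raw
materials.

Known irreconcilables, reported but not enforced: the published per-stage
percentage breakdowns are arithmetically inconsistent with the published
absolute costs, and the headline ≈47 USD/kg wet-biomass figure cannot be
recovered from them under any consistent wet basis — the package reports its
own unit costs under the stated paste basis instead.

## Problem sizes and determinism

All computations are closed-form or small least-squares problems; the full
test suite and the acceptance script each run in seconds. Simulation studies
use 13-point × 3-replicate experiments, 20 seeds for the pipeline maxima and
100 replicates for parameter recovery. All randomness flows through
`numpy.random.default_rng` seeds carried in `SynthSpec`; derived seeds come
from `SeedSequence`, so every table and report is reproducible bit-for-bit
for a fixed seed.

## Limitations

Single lumped consortium (no species dynamics); logistic growth with
constant chlorophyll:biomass ratio; no light, pH, temperature or CO₂
transfer modelling inside the reactors; densities fixed at 1 kg/L;
continuous steady state only (no scheduling, start-up or cleaning); factored
economics with two free factors rather than equipment-level design
correlations; no capital budgeting (NPV/IRR) and no cost-index inflation
adjustment.
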