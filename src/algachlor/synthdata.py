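"""Synthetic laboratory experiments: OD680 / A652 / A665 time series.

Emulates the 12-day (288 h) triplicate growth experiments: a logistic biomass
trajectory and a proportional chlorophyll trajectory are pushed through the
*inverse* assay calibrations to obtain noiseless instrument readings, and
additive Gaussian noise (truncated at zero) is applied on the readings — the
spectrophotometer is where measurement error arises, not the concentrations
themselves.  Default noise is 0.02 absorbance units, a typical instrument
repeatability; the real experiments' error-bar magnitudes are not available,
so this default is an assumption and is documented as such.

The chlorophyll a:b split (needed to invert the two-wavelength system) is
fixed at 75% chlorophyll a, the usual ~3:1 a:b ratio of green microalgae;
only totals are observable downstream, and the total is split-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCoefficients,
    DEFAULT_COEFFICIENTS,
    absorbance_from_chlorophyll,
    chlorophyll_from_absorbance,
    dcw_to_od,
    od_to_dcw,
)
from .growth import (
    GrowthParams,
    LogisticGrowthModel,
    GrowthFitError,
    TrophicMode,
    chlorophyll_trajectory,
    default_params,
    simulate_logistic,
)

__all__ = [
    "SynthSpec",
    "generate_experiment",
    "replicate_mean",
    "max_dcw",
    "max_total_chlorophyll",
    "recovery_study",
]

#: chlorophyll a as a fraction of total chlorophyll in the generator
CHL_A_FRACTION = 0.75


@dataclass(frozen=True)
class SynthSpec:
    """Specification of one synthetic growth experiment.

    ``n_timepoints`` points are spread evenly over ``[0, t_end]`` hours
    (default 13 points over 288 h, i.e. one sample per day); each point is
    measured in ``replicates`` replicate wells.
    """

    mode: TrophicMode
    ground_truth: GrowthParams | None = None
    n_timepoints: int = 13
    t_end: float = 288.0
    noise_sd_od: float = 0.02
    noise_sd_abs: float = 0.02
    seed: int = 0
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_timepoints < 5:
            raise ValueError("n_timepoints must be >= 5")
        if self.noise_sd_od < 0 or self.noise_sd_abs < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")

    @property
    def params(self) -> GrowthParams:
        return self.ground_truth if self.ground_truth is not None else default_params(self.mode)

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_timepoints)


def generate_experiment(
    spec: SynthSpec,
    coeffs: CalibrationCoefficients = DEFAULT_COEFFICIENTS,
) -> tuple[pd.DataFrame, dict]:
    """Generate one synthetic experiment.

    Returns
    -------
    df
        Long-format assay table with columns ``time_h,od680,a652,a665``;
        replicates appear as repeated time rows.  Reproducible: a fixed
        ``spec`` (including seed) yields an identical table.
    truth
        Ground-truth record: the generating parameters and the noiseless
        trajectories, for parameter-recovery studies.
    """
    params = spec.params
    t = spec.times
    biomass = simulate_logistic(params, t)
    chl_total = chlorophyll_trajectory(params, t)
    chl_a = CHL_A_FRACTION * chl_total
    chl_b = (1.0 - CHL_A_FRACTION) * chl_total

    od_clean = np.asarray(dcw_to_od(biomass, coeffs))
    a652_clean, a665_clean = absorbance_from_chlorophyll(chl_a, chl_b, coeffs)

    rng = np.random.default_rng(spec.seed)
    rows = []
    for _ in range(spec.replicates):
        od = np.maximum(od_clean + rng.normal(0.0, spec.noise_sd_od, t.size), 0.0)
        a652 = np.maximum(a652_clean + rng.normal(0.0, spec.noise_sd_abs, t.size), 0.0)
        a665 = np.maximum(a665_clean + rng.normal(0.0, spec.noise_sd_abs, t.size), 0.0)
        rows.append(pd.DataFrame({"time_h": t, "od680": od, "a652": a652, "a665": a665}))
    df = pd.concat(rows, ignore_index=True).sort_values(
        ["time_h"], kind="stable").reset_index(drop=True)

    truth = {
        "mode": params.mode.value,
        "k_cap": params.k_cap,
        "rate": params.rate,
        "x0": params.x0,
        "chl_ratio": params.chl_ratio,
        "chl_a_fraction": CHL_A_FRACTION,
        "seed": spec.seed,
        "times_h": t.tolist(),
        "biomass_g_l": biomass.tolist(),
        "chlorophyll_ug_ml": chl_total.tolist(),
    }
    return df, truth


def replicate_mean(df: pd.DataFrame) -> pd.DataFrame:
    """Average replicate readings per time point (what an experimenter
    reports when plotting mean ± error bars)."""
    return df.groupby("time_h", sort=True, as_index=False).mean()


def max_dcw(df: pd.DataFrame, coeffs: CalibrationCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Maximum DCW (g/L) of an experiment: replicate-mean OD series converted
    through the calibration line, then maximised over time."""
    mean = replicate_mean(df)
    dcw, _ = od_to_dcw(mean["od680"].to_numpy(), coeffs)
    return float(np.max(dcw))


def max_total_chlorophyll(
    df: pd.DataFrame, coeffs: CalibrationCoefficients = DEFAULT_COEFFICIENTS
) -> float:
    """Maximum total chlorophyll (µg/mL) of an experiment, from the
    replicate-mean absorbances via the two-wavelength equations."""
    mean = replicate_mean(df)
    res = chlorophyll_from_absorbance(
        mean["a652"].to_numpy(), mean["a665"].to_numpy(), coeffs)
    return float(np.max(np.asarray(res.chl_total)))


def _fit_generated(df: pd.DataFrame, coeffs: CalibrationCoefficients):
    mean = replicate_mean(df)
    dcw, _ = od_to_dcw(mean["od680"].to_numpy(), coeffs)
    model = LogisticGrowthModel(dcw, mean["time_h"].to_numpy())
    return model.fit()


def recovery_study(
    spec: SynthSpec,
    n_reps: int,
    coeffs: CalibrationCoefficients = DEFAULT_COEFFICIENTS,
) -> pd.DataFrame:
    """Generate→fit simulation study of logistic parameter recovery.

    Runs ``n_reps`` experiments with seeds derived deterministically from
    ``spec.seed``, fits each, and tabulates per-parameter bias and median
    absolute relative error.  Fit failures are counted, not fatal.

    Returns a dataframe indexed by parameter with columns
    ``true, median_estimate, bias, median_abs_rel_err, n_ok, n_failed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seed_rng = np.random.default_rng(spec.seed)
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=n_reps)

    truth = {"k_cap": spec.params.k_cap, "rate": spec.params.rate, "x0": spec.params.x0}
    estimates: dict[str, list[float]] = {k: [] for k in truth}
    n_failed = 0
    for s in child_seeds:
        rep_spec = SynthSpec(
            mode=spec.mode, ground_truth=spec.ground_truth,
            n_timepoints=spec.n_timepoints, t_end=spec.t_end,
            noise_sd_od=spec.noise_sd_od, noise_sd_abs=spec.noise_sd_abs,
            seed=int(s), replicates=spec.replicates,
        )
        df, _ = generate_experiment(rep_spec, coeffs)
        try:
            res = _fit_generated(df, coeffs)
        except GrowthFitError:
            n_failed += 1
            continue
        for name, val in zip(("k_cap", "rate", "x0"), res.params):
            estimates[name].append(float(val))

    records = []
    for name, true_val in truth.items():
        est = np.asarray(estimates[name])
        rel = (est - true_val) / true_val if est.size else np.array([np.nan])
        records.append({
            "parameter": name,
            "true": true_val,
            "median_estimate": float(np.median(est)) if est.size else np.nan,
            "bias": float(np.mean(est) - true_val) if est.size else np.nan,
            "median_abs_rel_err": float(np.median(np.abs(rel))),
            "n_ok": int(est.size),
            "n_failed": n_failed,
        })
    return pd.DataFrame.from_records(records).set_index("parameter")
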