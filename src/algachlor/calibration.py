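"""Spectrophotometric assay calibrations for biomass and chlorophyll.

Biomass concentration of the microalgal consortium is measured as optical
density at 680 nm (OD680) and converted to dry cell weight (DCW, g/L) with a
fitted linear calibration::

    DCW = 0.2983 * OD680 - 0.05        (R^2 = 0.9792)

Chlorophyll *a* and *b* are quantified from the absorbance of a methanol
extract at 652 and 665 nm with the standard two-wavelength linear system for
methanol extracts::

    Chl a = -8.0962 * A652 + 16.5169 * A665   (µg/mL)
    Chl b = 27.4405 * A652 - 12.1688 * A665   (µg/mL)

Both maps are affine/linear and therefore exactly invertible; the inverses are
what the synthetic-data generator uses to turn a known concentration
trajectory into instrument readings.  Because the DCW calibration has a
negative intercept and the chlorophyll system has negative coefficients, raw
conversions can be negative at very low absorbance: those values are clipped
to zero and flagged, since concentrations are physical quantities and the
downstream mass balances require non-negativity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCoefficients",
    "DEFAULT_COEFFICIENTS",
    "ChlorophyllResult",
    "DcwResult",
    "od_to_dcw",
    "dcw_to_od",
    "chlorophyll_from_absorbance",
    "absorbance_from_chlorophyll",
    "read_assay_csv",
    "write_assay_csv",
    "ASSAY_COLUMNS",
]

#: column order of the assay CSV dialect
ASSAY_COLUMNS = ("time_h", "od680", "a652", "a665")


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Coefficients of the OD→DCW line and the chlorophyll 2x2 system.

    Parameters
    ----------
    od_slope, od_intercept
        DCW (g/L) = od_slope * OD680 + od_intercept.
    chl_matrix
        2x2 coefficients, µg/mL per absorbance unit; rows (chl a, chl b),
        columns (A652, A665).
    chl_a_tol, chl_b_tol
        Reported ± uncertainty of the chlorophyll equations, µg/mL.  Stored
        as metadata for reporting only; the conversion itself is exact
        linear algebra.
    """

    od_slope: float = 0.2983
    od_intercept: float = -0.05
    chl_matrix: tuple[tuple[float, float], tuple[float, float]] = (
        (-8.0962, 16.5169),
        (27.4405, -12.1688),
    )
    chl_a_tol: float = 0.04696
    chl_b_tol: float = 0.05776

    def __post_init__(self) -> None:
        m = np.asarray(self.chl_matrix, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("chl_matrix must be 2x2")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("chl_matrix is singular; cannot invert the chlorophyll system")
        if self.od_slope == 0:
            raise ValueError("od_slope must be non-zero")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.chl_matrix, dtype=float)

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.matrix))


DEFAULT_COEFFICIENTS = CalibrationCoefficients()


class DcwResult(NamedTuple):
    """Dry-cell-weight conversion with its clipping flag."""

    dcw: float | np.ndarray
    clipped: bool | np.ndarray


class ChlorophyllResult(NamedTuple):
    """Chlorophyll a/b/total (µg/mL) with a clipping flag."""

    chl_a: float | np.ndarray
    chl_b: float | np.ndarray
    chl_total: float | np.ndarray
    clipped: bool | np.ndarray


def _as_finite(x, name: str, allow_negative: bool = False) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if not allow_negative and np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def _unwrap(scalar_input: bool, *arrays):
    out = tuple(a.item() if scalar_input else a for a in arrays)
    return out[0] if len(out) == 1 else out


def od_to_dcw(od680, coeffs: CalibrationCoefficients = DEFAULT_COEFFICIENTS) -> DcwResult:
    """Convert OD680 readings to dry cell weight (g/L).

    Raw values below zero (possible because the calibration intercept is
    negative) are clipped to 0 g/L and flagged.
    """
    od = _as_finite(od680, "od680")
    scalar = np.ndim(od680) == 0
    raw = coeffs.od_slope * od + coeffs.od_intercept
    clipped = raw < 0
    dcw = np.where(clipped, 0.0, raw)
    return DcwResult(*_unwrap(scalar, dcw, clipped))


def dcw_to_od(dcw, coeffs: CalibrationCoefficients = DEFAULT_COEFFICIENTS):
    """Exact affine inverse of :func:`od_to_dcw` (no clipping).

    Zero biomass maps to the root of the calibration line,
    OD680 = -intercept/slope ≈ 0.16762.
    """
    x = _as_finite(dcw, "dcw")
    scalar = np.ndim(dcw) == 0
    od = (x - coeffs.od_intercept) / coeffs.od_slope
    return _unwrap(scalar, od)


def chlorophyll_from_absorbance(
    a652, a665, coeffs: CalibrationCoefficients = DEFAULT_COEFFICIENTS
) -> ChlorophyllResult:
    """Chlorophyll a, b and total (µg/mL) from methanol-extract absorbances.

    Negative raw components are clipped to zero and flagged; the total is the
    sum of the clipped components.
    """
    x652 = _as_finite(a652, "a652")
    x665 = _as_finite(a665, "a665")
    scalar = np.ndim(a652) == 0 and np.ndim(a665) == 0
    m = coeffs.matrix
    raw_a = m[0, 0] * x652 + m[0, 1] * x665
    raw_b = m[1, 0] * x652 + m[1, 1] * x665
    clipped = (raw_a < 0) | (raw_b < 0)
    chl_a = np.where(raw_a < 0, 0.0, raw_a)
    chl_b = np.where(raw_b < 0, 0.0, raw_b)
    return ChlorophyllResult(*_unwrap(scalar, chl_a, chl_b, chl_a + chl_b, clipped))


def absorbance_from_chlorophyll(
    chl_a, chl_b, coeffs: CalibrationCoefficients = DEFAULT_COEFFICIENTS
):
    """Solve the 2x2 chlorophyll system for (A652, A665).

    Inverse of :func:`chlorophyll_from_absorbance` (before clipping); raises
    if the implied absorbances are negative, which marks a chlorophyll pair
    the instrument model cannot produce.
    """
    ca = _as_finite(chl_a, "chl_a")
    cb = _as_finite(chl_b, "chl_b")
    scalar = np.ndim(chl_a) == 0 and np.ndim(chl_b) == 0
    inv = np.linalg.inv(coeffs.matrix)
    a652 = inv[0, 0] * ca + inv[0, 1] * cb
    a665 = inv[1, 0] * ca + inv[1, 1] * cb
    if np.any(a652 < -1e-12) or np.any(a665 < -1e-12):
        bad = np.argmax((np.atleast_1d(a652) < -1e-12) | (np.atleast_1d(a665) < -1e-12))
        raise ValueError(
                "infeasible chlorophyll pair "
                f"(chl_a={np.atleast_1d(ca).ravel()[bad]:g}, "
                f"chl_b={np.atleast_1d(cb).ravel()[bad]:g}): implied absorbance is negative"
        )
    a652 = np.clip(a652, 0.0, None)
    a665 = np.clip(a665, 0.0, None)
    return _unwrap(scalar, a652, a665)


def read_assay_csv(path) -> pd.DataFrame:
    """Read an assay time series (``time_h,od680,a652,a665``).

    The absorbance columns may be absent when only DCW is of interest.
    """
    df = pd.read_csv(path)
    if "time_h" not in df.columns or "od680" not in df.columns:
        raise ValueError(f"assay CSV must contain at least 'time_h' and 'od680'; got {list(df.columns)}")
    extra = [c for c in df.columns if c not in ASSAY_COLUMNS]
    if extra:
        raise ValueError(f"unexpected assay CSV columns: {extra}")
    if (df["time_h"] < 0).any():
        raise ValueError("time_h must be non-negative")
    return df


def write_assay_csv(df: pd.DataFrame, path) -> None:
    """Write an assay time series in the canonical column order."""
    cols = [c for c in ASSAY_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)
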