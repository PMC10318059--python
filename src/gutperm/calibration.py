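"""Linear MFI ↔ FITC-dextran concentration calibration.

Image MFI is linear in tracer concentration over the assay's dynamic range
(1–100 µg/mL), so a standard curve fitted on known dilutions converts
endpoint MFI into µg/mL, and the agreement between image-derived ratios and
fluorometer-derived ratios is summarized as a squared Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

VALID_RANGE_UG_PER_ML = (1.0, 100.0)


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float  # MFI per (µg/mL)
    intercept: float  # MFI at zero concentration
    r_squared: float
    valid_range: tuple[float, float] = VALID_RANGE_UG_PER_ML

    def predict_mfi(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def fit_calibration(
    pairs: list[tuple[float, float]] | np.ndarray,
) -> CalibrationCurve:
    """OLS line MFI = a·concentration + b from (concentration, MFI) pairs.

    Needs at least 3 pairs over at least 3 distinct concentrations; warns if
    any concentration lies outside the 1–100 µg/mL dynamic range.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (concentration, MFI) pairs")
    conc, mfi = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    lo, hi = VALID_RANGE_UG_PER_ML
    if conc.min() < lo or conc.max() > hi:
        warnings.warn(
            f"concentrations outside the {lo}-{hi} ug/mL dynamic range", stacklevel=2
        )
    res = stats.linregress(conc, mfi)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def estimate_concentration(
    curve: CalibrationCurve, mfi: float
) -> tuple[float, bool]:
    """Invert the standard curve: (mfi − b)/a.

    Returns (concentration µg/mL, extrapolated) where ``extrapolated`` flags
    estimates outside the curve's valid range.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; curve is not invertible")
    conc = (mfi - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    return float(conc), bool(conc < lo or conc > hi)


def correlate_endpoints(
    image_mfi_ratios: np.ndarray, od_ratios: np.ndarray
) -> float:
    """Squared Pearson correlation between image and fluorometer ratio series."""
    x = np.asarray(image_mfi_ratios, dtype=float)
    y = np.asarray(od_ratios, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length series of >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a ratio series")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)
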