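"""IVIM parameter estimation on a detected lesion ROI.

Five quantities characterize a lesion's diffusion behavior:

* ADC — apparent diffusion coefficient, the mono-exponential decay rate
  fitted through the origin: ln(S_b/S_0) = -b * ADC.
* signal decay slope — ordinary least-squares slope of the normalized
  signal S_b/S_0 (linear domain) against b.
* D, D*, PF — pure diffusion coefficient, pseudo-diffusion coefficient
  and perfusion fraction of the bi-exponential model
  S_b/S_0 = (1-PF) exp(-b D) + PF exp(-b D*).

The bi-exponential fit is segmented: a log-linear fit on the high-b tail
(b >= b_split, default 200 s/mm^2, beyond the perfusion-dominated regime)
yields D and, through the intercept, PF; an optional bounded nonlinear
least-squares refinement over (D, D*, PF) then polishes all three on the
full curve.  All fits operate on the ROI-mean decay curve by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .cube import BValueCube
from .errors import EmptyDetectionError, InvalidSpecError

D_MAX = 5e-3
DSTAR_MAX = 0.5


@dataclass
class DecayCurve:
    """ROI-mean normalized signal per b-value; value at b=0 is 1."""

    bvalues: np.ndarray
    signal: np.ndarray  # S_b / S_0

    def __post_init__(self) -> None:
        self.bvalues = np.asarray(self.bvalues, float)
        self.signal = np.asarray(self.signal, float)
        if self.bvalues.shape != self.signal.shape:
            raise InvalidSpecError("bvalues and signal must have equal length")


@dataclass
class IVIMParams:
    """Per-ROI quantitative parameters (PF is a fraction in [0, 1])."""

    ADC: float
    decay_slope: float
    D: float
    Dstar: float
    PF: float
    converged: bool = True


def ivim_model(b: np.ndarray, D: float, Dstar: float, PF: float) -> np.ndarray:
    return (1 - PF) * np.exp(-b * D) + PF * np.exp(-b * Dstar)


def roi_decay_curve(cube: BValueCube, mask: np.ndarray) -> DecayCurve:
    """Mean intensity over the mask per band, normalized by the b=0 mean."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise EmptyDetectionError("cannot build a decay curve from an empty mask")
    means = cube.data[mask].mean(axis=0)
    if means[0] <= 0:
        raise InvalidSpecError("b=0 mean signal must be positive")
    return DecayCurve(cube.bvalues, means / means[0])


def adc_fit(curve: DecayCurve) -> float:
    """ADC from the through-origin log-linear fit ln(S_b/S_0) = -b * ADC."""
    b, y = curve.bvalues, curve.signal
    if b.size < 2:
        raise InvalidSpecError("ADC fit needs at least two b-values")
    if np.any(y <= 0):
        raise InvalidSpecError("ADC fit needs strictly positive signals")
    ly = np.log(y)
    denom = float(b @ b)
    if denom == 0:
        raise InvalidSpecError("ADC fit needs a non-zero b-value")
    return float(-(b @ ly) / denom)


def decay_slope(curve: DecayCurve) -> float:
    """OLS slope of the normalized signal (linear domain) against b."""
    b, y = curve.bvalues, curve.signal
    if b.size < 2:
        raise InvalidSpecError("slope fit needs at least two b-values")
    bm, ym = b.mean(), y.mean()
    return float(((b - bm) @ (y - ym)) / ((b - bm) @ (b - bm)))


def ivim_fit(curve: DecayCurve, b_split: float = 200.0, refine: bool = True) -> IVIMParams:
    """Segmented (+ optional NLLS-refined) bi-exponential fit.

    Stage 1: OLS of ln(S/S0) on b over b >= b_split gives D (slope) and
    the intercept alpha; PF = 1 - exp(alpha).  Stage 2 (default): bounded
    nonlinear least squares over (D, D*, PF) on the full curve, started
    from stage 1 with D* = 10 D.
    """
    b, y = curve.bvalues, curve.signal
    if b.size < 4:
        raise InvalidSpecError("IVIM fit needs at least four b-values")
    if np.any(y <= 0):
        raise InvalidSpecError("IVIM fit needs strictly positive signals")
    hi = b >= b_split
    if hi.sum() < 2:
        raise InvalidSpecError(
            f"need at least two b-values >= b_split={b_split:g}"
        )
    if hi.all():
        raise InvalidSpecError("b_split must leave low-b points for the perfusion term")
    slope, alpha = np.polyfit(b[hi], np.log(y[hi]), 1)
    D0 = float(np.clip(-slope, 0.0, D_MAX))
    PF0 = float(np.clip(1.0 - np.exp(alpha), 0.0, 1.0))
    adc = adc_fit(curve)
    slope_lin = decay_slope(curve)
    if not refine:
        return IVIMParams(adc, slope_lin, D0, 10.0 * D0, PF0)

    Dstar0 = float(np.clip(10.0 * max(D0, 1e-5), 0.0, DSTAR_MAX))

    def resid(theta: np.ndarray) -> np.ndarray:
        return ivim_model(b, *theta) - y

    sol = least_squares(
        resid,
        x0=[D0, Dstar0, PF0],
        bounds=([0.0, 0.0, 0.0], [D_MAX, DSTAR_MAX, 1.0]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        return IVIMParams(adc, slope_lin, D0, Dstar0, PF0, converged=False)
    D, Dstar, PF = (float(v) for v in sol.x)
    return IVIMParams(adc, slope_lin, D, Dstar, PF)


def quantify_detection(cube: BValueCube, mask: np.ndarray) -> tuple[IVIMParams, DecayCurve]:
    """ROI report for one detection mask: decay curve + all five parameters."""
    curve = roi_decay_curve(cube, mask)
    return ivim_fit(curve), curve


def params_table(rows: dict[str, IVIMParams]) -> "object":
    """Per-method parameter table (one row per detection method)."""
    import pandas as pd

    records = []
    for method, p in rows.items():
        records.append(
            {
                "Method": method,
                "ADC": p.ADC,
                "SignalDecaySlope": p.decay_slope,
                "Dstar": p.Dstar,
                "D": p.D,
                "PF": p.PF,
            }
        )
    return pd.DataFrame.from_records(records)
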