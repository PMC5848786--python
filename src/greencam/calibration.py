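"""Sensor-response fitting and colour-balance stability checks.

Three small utilities used when validating camera data quality:

* an exponential response fit ``DN = a * exp(b * ln(exposure))``
  characterizing how a camera maps exposure (integration time times
  irradiance) to digital numbers;
* reference-panel stability -- the SD of Gcc over a grey reflectance
  panel in the field of view, after screening for adequate solar
  elevation and panel brightness;
* relative-Gcc rescaling, a per-year linear transform setting the
  dormant-season mean to 0 and the peak-summer mean to 1 so that series
  from different cameras can be compared on a common scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ResponseFit",
    "PanelConfig",
    "fit_response",
    "panel_stability",
    "relative_gcc",
]

#: DN above which a point is treated as approaching sensor saturation.
SATURATION_DN = 220.0


@dataclass(frozen=True)
class ResponseFit:
    """Parameters of the exponential sensor response y = a*exp(b*x)."""

    a: float
    b: float
    residuals: np.ndarray
    rmse: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(x, float))


@dataclass(frozen=True)
class PanelConfig:
    """Screening for reference-panel records."""

    min_solar_elev: float = 5.0
    brightness_min: float = 200.0
    brightness_max: float = 565.0

    def __post_init__(self) -> None:
        if self.brightness_min >= self.brightness_max:
            raise ValueError("brightness window bounds out of order")


def fit_response(xs: np.ndarray, ys: np.ndarray) -> ResponseFit:
    """Least-squares fit of DN = a*exp(b*x), x = ln(exposure).

    Saturated points (DN > 220) are excluded before fitting.  The fit is
    initialized by ordinary least squares on ln(y) and refined by
    nonlinear least squares on the DN scale.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if np.any(ys <= 0) or np.any(ys >= 255):
        raise ValueError("DN values must lie strictly within (0, 255)")
    keep = ys <= SATURATION_DN
    if keep.sum() < 3:
        raise ValueError("need at least 3 unsaturated points")
    x, y = xs[keep], ys[keep]
    slope, intercept = np.polyfit(x, np.log(y), 1)
    a0, b0 = math.exp(intercept), slope
    try:
        (a, b), _ = curve_fit(
            lambda x_, a_, b_: a_ * np.exp(b_ * x_), x, y, p0=(a0, b0), maxfev=10000
        )
    except RuntimeError:
        a, b = a0, b0
    residuals = ys - a * np.exp(b * xs)
    rmse = float(np.sqrt(np.mean(residuals[keep] ** 2)))
    return ResponseFit(a=float(a), b=float(b), residuals=residuals, rmse=rmse)


def panel_stability(
    records: pd.DataFrame, cfg: PanelConfig = PanelConfig()
) -> tuple[float, int, float]:
    """(SD of panel Gcc, records used, 2.5*SD conservative 99% half-width).

    Records are screened to solar elevation above 5 degrees and
    channel-mean brightness sum within [200, 565] (inclusive bounds).
    """
    total = records["r_mean"] + records["g_mean"] + records["b_mean"]
    keep = (
        (records["solar_elev"] > cfg.min_solar_elev)
        & (total >= cfg.brightness_min)
        & (total <= cfg.brightness_max)
    )
    gcc = records.loc[keep, "gcc"].to_numpy(float)
    gcc = gcc[np.isfinite(gcc)]
    if len(gcc) < 10:
        raise ValueError(f"only {len(gcc)} usable panel records (need >= 10)")
    sd = float(gcc.std(ddof=1))
    return sd, len(gcc), 2.5 * sd


def relative_gcc(
    doy: np.ndarray,
    gcc: np.ndarray,
    dormant: tuple[int, int] = (290, 110),
    peak: tuple[int, int] = (150, 180),
) -> np.ndarray:
    """Rescale a one-year Gcc series to the relative 0-1 scale.

    The dormant-season mean (after day 290 or before day 110) maps to 0
    and the peak-summer mean (after day 150, before day 180) maps to 1.
    The transform is linear, so it is invariant to affine changes of the
    input.  Requires at least 3 points in each window.
    """
    doy = np.asarray(doy)
    gcc = np.asarray(gcc, float)
    dormant_mask = (doy > dormant[0]) | (doy < dormant[1])
    peak_mask = (doy > peak[0]) & (doy < peak[1])
    for mask, name in ((dormant_mask, "dormant"), (peak_mask, "peak")):
        if np.isfinite(gcc[mask]).sum() < 3:
            raise ValueError(f"fewer than 3 points in the {name} window")
    lo = float(np.nanmean(gcc[dormant_mask]))
    hi = float(np.nanmean(gcc[peak_mask]))
    if abs(hi - lo) < 1e-9:
        raise ValueError("zero seasonal amplitude; cannot rescale")
    return (gcc - lo) / (hi - lo)
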