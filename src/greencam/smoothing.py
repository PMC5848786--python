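"""AICc-selected smoothing splines and iterative outlier rejection.

A family of cubic smoothing splines (penalized least squares, fixed
30-point log-spaced grid of smoothing parameters) is fitted to each
greenness series; the optimal member is chosen by the
Hurvich-Simonoff-Tsai corrected AIC for nonparametric regression,

    AICc = ln(RSS/n) + (1 + edf/n) / (1 - (edf + 2)/n),

with edf the trace of the linear smoother matrix.  Residuals are
modelled as Laplace: the scale is the mean absolute residual b, and the
residual SD is sqrt(2)*b.  Points more than 4 SD above or 2 SD below the
spline are flagged as outliers -- the asymmetry filters the predominantly
negative artefacts (snow, rain droplets, fog) more aggressively -- and
fitting repeats on the unflagged points, up to 20 passes or until no new
flags appear.  A final refit provides the smoothed series, its RMSE, and
a constant-width 1.96-sigma confidence band.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline

__all__ = [
    "LAM_GRID",
    "OutlierConfig",
    "SmoothFit",
    "InsufficientDataError",
    "DataQualityError",
    "fit_spline",
    "aicc",
    "select_spline",
    "laplace_sd",
    "detect_outliers",
    "interpolation_flag",
    "smooth_summary",
]

#: Fixed smoothing-parameter grid, near-interpolation to near-linear.
LAM_GRID = np.logspace(-2.0, 8.0, 30)

#: Residual SDs below this are treated as a degenerate (noise-free) fit.
_SIGMA_FLOOR = 1e-9

_MIN_POINTS = 8


class InsufficientDataError(ValueError):
    """Too few observations to fit a smoothing spline."""


class DataQualityError(ValueError):
    """Outlier rejection would discard an implausible share of the data."""


@dataclass(frozen=True)
class OutlierConfig:
    """Asymmetric flagging thresholds, in residual SDs."""

    k_upper: float = 4.0
    k_lower: float = 2.0
    max_iter: int = 20

    def __post_init__(self) -> None:
        if self.k_upper <= 0 or self.k_lower <= 0 or self.max_iter < 1:
            raise ValueError("thresholds must be positive and max_iter >= 1")


@dataclass
class SmoothFit:
    """A fitted smoothing spline and its residual summaries."""

    lam: float
    t: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    edf: float
    spline: BSpline = field(repr=False)

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fitted

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    @property
    def rmse(self) -> float:
        return float(math.sqrt(self.rss / len(self.t)))

    @property
    def sigma(self) -> float:
        """Residual SD under the Laplace model."""
        return laplace_sd(self.residuals)

    @property
    def ci_halfwidth(self) -> float:
        """One-sided 95% band half-width (1.96 sigma, constant in time)."""
        return 1.96 * self.sigma

    def predict(self, t_new: np.ndarray) -> np.ndarray:
        """Evaluate the spline; extrapolation is clamped to the data range."""
        t_new = np.clip(np.asarray(t_new, float), self.t.min(), self.t.max())
        return np.asarray(self.spline(t_new), float)


def fit_spline(t: np.ndarray, y: np.ndarray, lam: float) -> SmoothFit:
    """Cubic smoothing spline at a fixed smoothing parameter.

    The smoother is linear in ``y``; its trace (edf) is obtained by
    pushing the identity matrix through the same fit.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < _MIN_POINTS:
        raise InsufficientDataError(f"need >= {_MIN_POINTS} points, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    n = len(t)
    target = np.column_stack([y, np.eye(n)])
    spl = make_smoothing_spline(t, target, lam=lam)
    values = spl(t)
    fitted = values[:, 0]
    edf = float(np.trace(values[:, 1:]))
    spline_y = make_smoothing_spline(t, y, lam=lam)
    return SmoothFit(lam=float(lam), t=t, y=y, fitted=fitted, edf=edf, spline=spline_y)


def aicc(rss: float, edf: float, n: int) -> float:
    """Corrected AIC for smoothing-parameter selection.

    Undefined (raises) when ``n <= edf + 2``; such over-parameterized
    candidates are excluded from the selection grid.
    """
    if n <= edf + 2:
        raise ValueError(f"AICc undefined for n={n}, edf={edf}")
    rss = max(float(rss), 1e-300)
    return math.log(rss / n) + (1.0 + edf / n) / (1.0 - (edf + 2.0) / n)


def select_spline(
    t: np.ndarray, y: np.ndarray, lam_grid: np.ndarray = LAM_GRID
) -> SmoothFit:
    """Fit the spline family over the grid and keep the AICc minimizer.

    Deterministic given the (fixed) grid; falls back to the stiffest
    candidate with a warning if every candidate is over-parameterized.
    """
    n = len(np.asarray(t))
    best: SmoothFit | None = None
    best_score = math.inf
    for lam in lam_grid:
        fit = fit_spline(t, y, lam)
        if n <= fit.edf + 2:
            continue
        score = aicc(fit.rss, fit.edf, n)
        if score < best_score:
            best, best_score = fit, score
    if best is None:
        warnings.warn(
            "all spline candidates over-parameterized; using maximum smoothing",
            stacklevel=2,
        )
        best = fit_spline(t, y, lam_grid[-1])
    return best


def laplace_sd(residuals: np.ndarray) -> float:
    """Residual SD assuming a Laplace distribution: sqrt(2) * mean |r|."""
    residuals = np.asarray(residuals, float)
    return float(math.sqrt(2.0) * np.mean(np.abs(residuals)))


def detect_outliers(
    t: np.ndarray, y: np.ndarray, cfg: OutlierConfig = OutlierConfig()
) -> tuple[np.ndarray, SmoothFit]:
    """Iterative asymmetric outlier flagging against the AICc spline.

    Flags accumulate across passes; each pass refits on the unflagged
    points only, while the residual SD is estimated from *all* points'
    residuals about the current spline (keeping the scale honest once
    gross outliers are excluded from the fit, so that ordinary noise is
    not progressively eaten).  Returns the 0/1 flags (aligned with
    ``t``) and the final refit.  A degenerate fit (sigma ~ 0) flags
    nothing.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    flags = np.zeros(n, dtype=bool)
    for _ in range(cfg.max_iter):
        keep = ~flags
        fit = select_spline(t[keep], y[keep])
        pred = fit.predict(t)
        sigma = laplace_sd(y - pred)
        if sigma <= _SIGMA_FLOOR:
            break
        new = keep & (
            (y > pred + cfg.k_upper * sigma) | (y < pred - cfg.k_lower * sigma)
        )
        if not new.any():
            break
        flags |= new
        if flags.sum() > 0.5 * n:
            raise DataQualityError(
                f"outlier rejection flagged {int(flags.sum())}/{n} points"
            )
    final = select_spline(t[~flags], y[~flags])
    return flags.astype(int), final


def interpolation_flag(
    dates: list[_dt.date], observed: list[_dt.date], min_gap_days: int = 14
) -> np.ndarray:
    """1 for rows lying strictly inside a data gap of >= 14 days.

    ``observed`` are the dates with usable (non-missing, unflagged)
    values; rows before the first or after the last observation are not
    inside a gap and stay 0.
    """
    observed = sorted(observed)
    out = np.zeros(len(dates), dtype=int)
    if len(observed) < 2:
        return out
    obs = np.array([d.toordinal() for d in observed])
    for i, d in enumerate(dates):
        o = d.toordinal()
        j = np.searchsorted(obs, o)
        if 0 < j < len(obs) and obs[j] != o:
            if obs[j] - obs[j - 1] >= min_gap_days:
                out[i] = 1
    return out


_ALL_STATS = ("gcc_mean", "gcc_50", "gcc_75", "gcc_90",
              "rcc_mean", "rcc_50", "rcc_75", "rcc_90")
_GCC_STATS = _ALL_STATS[:4]


def smooth_summary(
    df: pd.DataFrame,
    cfg: OutlierConfig = OutlierConfig(),
) -> tuple[pd.DataFrame, dict[str, SmoothFit]]:
    """Populate smooth_*, smooth_ci_*, outlierflag_* and int_flag columns.

    Each of the eight Gcc/Rcc statistics is smoothed independently with
    its own outlier flags; only the Gcc flags are reported as columns.
    The smoothed series is evaluated on every summary row (gap
    interpolation), with extrapolation beyond the observed range clamped.
    Series with fewer than 8 observations are left missing.

    Returns the augmented copy of the frame and the final fit per
    statistic (used downstream for transition dates and RMSE reporting).
    """
    df = df.copy()
    dates = list(df["date"])
    t_all = np.array([d.toordinal() for d in dates], float)
    t_all -= t_all[0]
    fits: dict[str, SmoothFit] = {}
    for stat in _ALL_STATS:
        y = df[stat].to_numpy(float)
        obs = np.isfinite(y)
        if obs.sum() < _MIN_POINTS:
            continue
        flags, fit = detect_outliers(t_all[obs], y[obs], cfg)
        fits[stat] = fit
        df[f"smooth_{stat}"] = fit.predict(t_all)
        df[f"smooth_ci_{stat}"] = fit.ci_halfwidth
        if stat in _GCC_STATS:
            col = np.full(len(df), math.nan)
            col[obs] = flags
            df[f"outlierflag_{stat}"] = col
    # gap flag keyed to the usable gcc_mean observations
    y = df["gcc_mean"].to_numpy(float)
    obs_mask = np.isfinite(y)
    if "gcc_mean" in fits:
        flagged = df["outlierflag_gcc_mean"].to_numpy(float) == 1
        usable = obs_mask & ~flagged
    else:
        usable = obs_mask
    observed_dates = [d for d, u in zip(dates, usable) if u]
    df["int_flag"] = interpolation_flag(dates, observed_dates)
    return df, fits
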