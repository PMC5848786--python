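"""Phenophase transition dates from smoothed greenness series.

The smoothed Gcc series is segmented with PELT (Pruned Exact Linear
Time) changepoint detection -- an exact minimizer of the penalized
sum of Gaussian change-in-mean segment costs -- using penalty beta = 0.5
on the SD-standardized series and a minimum segment length of 14 days.
Segments are classified as greenness-rising or greenness-falling by the
sign of their net smoothed change and merged into stages; for each stage
the baseline minimum and peak maximum define an amplitude, and the
dates at which the spline crosses 10%, 25% and 50% of that amplitude
are reported with 1.96-sigma confidence intervals floored at one
sampling step (+-1 d / +-3 d for the 1-/3-day products, wider across
data gaps).  Because stages come from changepoints rather than a fitted
sigmoid, sites with multiple green-up cycles per year, or cycles
spanning calendar years, are handled naturally.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _io
from .smoothing import SmoothFit

__all__ = [
    "TransitionConfig",
    "Stage",
    "TRANSITION_COLUMNS",
    "pelt",
    "extract_stages",
    "transition_dates",
    "extract_transitions",
    "write_transitions",
    "read_transitions",
]


@dataclass(frozen=True)
class TransitionConfig:
    """Segmentation and threshold settings."""

    beta: float = 0.5
    min_segment_days: int = 14
    thresholds: tuple[float, ...] = (0.10, 0.25, 0.50)
    z: float = 1.96
    #: stages with amplitude below max(2*RMSE, this) are discarded; the
    #: default is the 8-bit quantization resolution of Gcc at typical
    #: ROI brightness (one DN step on a channel sum of ~300).
    min_amplitude: float = 0.002

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not all(0 < f < 1 for f in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must increase")

    def minseg_samples(self, step: int) -> int:
        return max(2, math.ceil(self.min_segment_days / step))


@dataclass(frozen=True)
class Stage:
    """One greenness-rising or greenness-falling stage."""

    direction: str  # "rising" | "falling"
    start_idx: int
    end_idx: int  # inclusive
    start_date: _dt.date
    end_date: _dt.date
    min_gcc: float
    max_gcc: float

    @property
    def amplitude(self) -> float:
        return self.max_gcc - self.min_gcc


def _seg_cost(cs: np.ndarray, cs2: np.ndarray, i: int, j: int) -> float:
    """Gaussian change-in-mean cost of x[i:j] from cumulative sums."""
    n = j - i
    s = cs[j] - cs[i]
    return (cs2[j] - cs2[i]) - s * s / n


def pelt(signal: np.ndarray, beta: float, minseg: int) -> list[int]:
    """Exact penalized changepoint positions (segment start indices).

    Minimizes sum of segment costs + beta * (number of changepoints)
    with every segment at least ``minseg`` samples long; identical to
    the O(n^2) optimal-partitioning dynamic program, but with PELT
    pruning of the candidate set.
    """
    x = np.asarray(signal, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if minseg < 2:
        raise ValueError("minseg must be >= 2")
    n = len(x)
    if n < 2 * minseg:
        return []
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    last = np.zeros(n + 1, dtype=int)
    cands = [0]
    # a candidate dominated at time t is only safely removable once the
    # dominating changepoint itself becomes admissible, i.e. at t+minseg
    removal: dict[int, int] = {}
    for t in range(minseg, n + 1):
        cands = [tau for tau in cands if removal.get(tau, n + 2) > t]
        valid = [tau for tau in cands if t - tau >= minseg]
        if not valid:
            cands.append(t)
            continue
        totals = [F[tau] + _seg_cost(cs, cs2, tau, t) + beta for tau in valid]
        k = int(np.argmin(totals))
        F[t] = totals[k]
        last[t] = valid[k]
        for tau, tot in zip(valid, totals):
            if tot - beta > F[t] and tau not in removal:
                removal[tau] = t + minseg
        cands.append(t)
    cps = []
    t = n
    while last[t] != 0:
        cps.append(last[t])
        t = last[t]
    return sorted(cps)


def extract_stages(
    dates: list[_dt.date],
    smooth: np.ndarray,
    rmse: float,
    step: int,
    cfg: TransitionConfig = TransitionConfig(),
) -> list[Stage]:
    """Rising/falling stages from the PELT segmentation of a smoothed series.

    The series is standardized by its own SD before segmentation (the
    penalty is scale-dependent).  Consecutive segments with the same
    sign of net change are merged, and stages with amplitude below the
    noise floor max(2*RMSE, quantization floor) are discarded -- a flat
    evergreen series yields no stages.
    """
    smooth = np.asarray(smooth, float)
    n = len(smooth)
    sd = float(smooth.std())
    if sd == 0.0 or n < 2:
        return []
    z = (smooth - smooth.mean()) / sd
    cps = pelt(z, cfg.beta, cfg.minseg_samples(step))
    bounds = [0, *cps, n]
    segs = []  # (start, end_inclusive, direction)
    for a, b in zip(bounds[:-1], bounds[1:]):
        net = smooth[b - 1] - smooth[a]
        segs.append([a, b - 1, "rising" if net >= 0 else "falling"])
    merged = [segs[0]]
    for seg in segs[1:]:
        if seg[2] == merged[-1][2]:
            merged[-1][1] = seg[1]
        else:
            merged.append(seg)
    # changepoints need not coincide with the curve's extrema, but the
    # baseline/peak of a stage is the trough/peak *between* stages, so
    # relocate each inter-stage boundary to the extremum of the smoothed
    # curve over the two adjacent stages
    for left, right in zip(merged[:-1], merged[1:]):
        a, b = left[0], right[1]
        span = smooth[a : b + 1]
        j = a + int(np.argmax(span) if left[2] == "rising" else np.argmin(span))
        j = min(max(j, a + 1), b - 1)
        left[1] = j
        right[0] = j
    floor = max(2.0 * rmse, cfg.min_amplitude)
    stages = []
    for a, b, direction in merged:
        lo = float(smooth[a : b + 1].min())
        hi = float(smooth[a : b + 1].max())
        if hi - lo < floor:
            continue
        stages.append(
            Stage(
                direction=direction,
                start_idx=a,
                end_idx=b,
                start_date=dates[a],
                end_date=dates[b],
                min_gcc=lo,
                max_gcc=hi,
            )
        )
    return stages


def _neighbour_observation(
    when: _dt.date, observed: list[_dt.date], step: int, side: str
) -> _dt.date:
    """Nearest usable observation before/after a transition date.

    Falls back to one sampling step when there is no observation on that
    side; this is what floors the confidence interval at +-step days and
    widens it across missing-data runs.
    """
    if side == "before":
        prior = [d for d in observed if d < when]
        return max(prior) if prior else when - _dt.timedelta(days=step)
    after = [d for d in observed if d > when]
    return min(after) if after else when + _dt.timedelta(days=step)


def transition_dates(
    stage: Stage,
    dates: list[_dt.date],
    smooth: np.ndarray,
    ci_halfwidth: float,
    step: int,
    observed: list[_dt.date] | None = None,
    cfg: TransitionConfig = TransitionConfig(),
) -> dict:
    """Threshold-crossing dates and confidence intervals for one stage.

    Thresholds are min_gcc + f * amplitude.  Rising stages report the
    first crossing date; falling stages the last date still above the
    threshold.  CI endpoints are the corresponding crossings of the
    spline +- its confidence band, then widened to at least the adjacent
    observation on each side.  Dates are reported at the native sampling
    resolution of the series.
    """
    if stage.amplitude <= 0:
        raise ValueError("stage has non-positive amplitude")
    observed = observed if observed is not None else list(dates)
    idx = np.arange(stage.start_idx, stage.end_idx + 1)
    seg = np.asarray(smooth, float)[idx]
    rising = stage.direction == "rising"
    row: dict = {"direction": stage.direction,
                 "min_gcc": stage.min_gcc, "max_gcc": stage.max_gcc}

    def crossing(curve: np.ndarray, thr: float) -> int | None:
        above = np.nonzero(curve >= thr)[0]
        if not len(above):
            return None
        return int(idx[above[0] if rising else above[-1]])

    for f in cfg.thresholds:
        pct = round(100 * f)
        thr = stage.min_gcc + f * stage.amplitude
        row[f"threshold_{pct}"] = thr
        i_mid = crossing(seg, thr)
        # the threshold lies within [min, max] of the segment, so the
        # central crossing always exists
        t_date = dates[i_mid]
        if rising:
            i_lo = crossing(seg + ci_halfwidth, thr)
            i_hi = crossing(seg - ci_halfwidth, thr)
        else:
            i_lo = crossing(seg - ci_halfwidth, thr)
            i_hi = crossing(seg + ci_halfwidth, thr)
        if i_lo is None:
            warnings.warn("confidence band never crosses threshold; clamping",
                          stacklevel=2)
            i_lo = stage.start_idx
        if i_hi is None:
            warnings.warn("confidence band never crosses threshold; clamping",
                          stacklevel=2)
            i_hi = stage.end_idx
        lo_date = min(dates[i_lo], _neighbour_observation(t_date, observed, step, "before"))
        hi_date = max(dates[i_hi], _neighbour_observation(t_date, observed, step, "after"))
        row[f"transition_{pct}"] = t_date
        row[f"transition_{pct}_lower_ci"] = lo_date
        row[f"transition_{pct}_upper_ci"] = hi_date
    return row


_GCC_STATS = ("gcc_mean", "gcc_50", "gcc_75", "gcc_90")

TRANSITION_COLUMNS = [
    "sitename", "veg_type", "roi_id", "direction", "gcc_value",
    "transition_10", "transition_25", "transition_50",
    "transition_10_lower_ci", "transition_25_lower_ci", "transition_50_lower_ci",
    "transition_10_upper_ci", "transition_25_upper_ci", "transition_50_upper_ci",
    "threshold_10", "threshold_25", "threshold_50",
    "min_gcc", "max_gcc",
]


def extract_transitions(
    smoothed: pd.DataFrame,
    fits: dict[str, SmoothFit],
    sitename: str,
    veg_type: str,
    roi_id: str,
    step: int,
    cfg: TransitionConfig = TransitionConfig(),
) -> pd.DataFrame:
    """Transition-date table from a smoothed summary frame.

    One row per stage per Gcc statistic (gcc_mean, gcc_50, gcc_75,
    gcc_90), each segmented on its own smoothed series.
    """
    dates = list(smoothed["date"])
    rows = []
    for stat in _GCC_STATS:
        if stat not in fits:
            continue
        fit = fits[stat]
        smooth = smoothed[f"smooth_{stat}"].to_numpy(float)
        obs_mask = np.isfinite(smoothed[stat].to_numpy(float))
        flag = smoothed[f"outlierflag_{stat}"].to_numpy(float)
        usable = obs_mask & (flag != 1)
        observed = [d for d, u in zip(dates, usable) if u]
        for stage in extract_stages(dates, smooth, fit.rmse, step, cfg):
            row = transition_dates(
                stage, dates, smooth, fit.ci_halfwidth, step, observed, cfg
            )
            row.update(sitename=sitename, veg_type=veg_type, roi_id=roi_id,
                       gcc_value=stat)
            rows.append(row)
    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


def _transitions_header(meta: dict[str, str], step: int,
                        rmse: dict[str, float]) -> list[str]:
    g = meta.get
    return [
        "#",
        f"# Transition date estimates for {g('Site', '')}",
        "#",
        f"# Site: {g('Site', '')}",
        f"# Veg Type: {g('Veg Type', '')}",
        f"# ROI ID Number: {g('ROI ID Number', '')}",
        f"# Aggregation Period: {step}",
        f"# Year Min: {g('Year Min', '')}",
        f"# Year Max: {g('Year Max', '')}",
        f"# Creation Date: {g('Creation Date', '')}",
        f"# Creation Time: {g('Creation Time', '')}",
        f"# RMSE gcc_mean: {_io.fmt_float(rmse.get('gcc_mean'))}",
        f"# RMSE gcc_50: {_io.fmt_float(rmse.get('gcc_50'))}",
        f"# RMSE gcc_75: {_io.fmt_float(rmse.get('gcc_75'))}",
        f"# RMSE gcc_90: {_io.fmt_float(rmse.get('gcc_90'))}",
        "#",
    ]


def write_transitions(
    df: pd.DataFrame,
    path,
    meta: dict[str, str],
    step: int,
    rmse: dict[str, float] | None = None,
) -> None:
    """Write the transition-date CSV (16 ``#`` metadata lines + header + rows)."""
    from pathlib import Path

    rmse = rmse or {
        k: _io.parse_float(meta.get(f"RMSE {k}", "NA")) for k in _GCC_STATS
    }
    lines = _transitions_header(meta, step, rmse)
    lines.append(",".join(TRANSITION_COLUMNS))
    date_cols = [c for c in TRANSITION_COLUMNS if c.startswith("transition")]
    for _, row in df.iterrows():
        toks = []
        for col in TRANSITION_COLUMNS:
            v = row[col]
            if col in date_cols:
                toks.append(v.isoformat() if isinstance(v, _dt.date) else _io.NA)
            elif col in ("threshold_10", "threshold_25", "threshold_50",
                         "min_gcc", "max_gcc"):
                toks.append(_io.fmt_float(v))
            else:
                toks.append(_io.fmt_str(v))
        lines.append(",".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


def read_transitions(path) -> tuple[pd.DataFrame, dict[str, str], int]:
    """Read a transition-date CSV back into (frame, metadata, step)."""
    meta, data = _io.read_header_block(path)
    if not data:
        raise ValueError(f"{path}: no column header line")
    if data[0].split(",") != TRANSITION_COLUMNS:
        raise ValueError(f"{path}: column mismatch")
    step = int(meta.get("Aggregation Period", "0"))
    date_cols = {c for c in TRANSITION_COLUMNS if c.startswith("transition")}
    records = []
    for ln in data[1:]:
        toks = ln.split(",")
        rec = {}
        for col, tok in zip(TRANSITION_COLUMNS, toks):
            if col in date_cols:
                if tok == _io.NA:
                    rec[col] = None
                else:
                    try:
                        rec[col] = _dt.date.fromisoformat(tok)
                    except ValueError:
                        raise ValueError(
                            f"{path}: malformed date {tok!r} in {col}"
                        ) from None
            elif col in ("threshold_10", "threshold_25", "threshold_50",
                         "min_gcc", "max_gcc"):
                rec[col] = _io.parse_float(tok)
            else:
                rec[col] = _io.parse_str(tok)
        records.append(rec)
    return pd.DataFrame(records, columns=TRANSITION_COLUMNS), meta, step
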