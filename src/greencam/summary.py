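"""Quality filtering and 1-/3-day summary products.

Images are screened with three filters before aggregation: solar
elevation at least 10 degrees above the horizon, and ROI-mean total
brightness (r_mean + g_mean + b_mean) within [100, 665] DN.  All
inequalities are strict, so boundary values pass.

Aggregation windows sit on a fixed day-of-year grid: one window per
calendar day for the 1-day product; for the 3-day product, windows are
centred on doy 2, 5, 8, ..., 365 and cover {doy-1, doy, doy+1}.  The
final 3-day window (label 365) holds two days in non-leap years and
three (doy 364-366) in leap years.  Each window also carries statistics
of the single "midday image" -- the image recorded closest to 12:00
local standard time on the window's middle day, chosen without quality
filtering.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _io

__all__ = [
    "QcConfig",
    "Window",
    "SUMMARY_COLUMNS",
    "qc_pass",
    "bin_windows",
    "select_midday",
    "summarize_window",
    "make_summary",
    "write_summary",
    "read_summary",
]


@dataclass(frozen=True)
class QcConfig:
    """Image selection thresholds (degrees / DN)."""

    min_solar_elev: float = 10.0
    dark_sum: float = 100.0
    bright_sum: float = 665.0

    def __post_init__(self) -> None:
        if not self.dark_sum < self.bright_sum:
            raise ValueError("dark_sum must be below bright_sum")


@dataclass(frozen=True)
class Window:
    """One aggregation window; ``date`` is the reported (middle) day."""

    date: _dt.date
    doy: int
    days: tuple[_dt.date, ...]

    @property
    def middle_day(self) -> _dt.date:
        return self.date


_GCC_STATS = ("gcc_mean", "gcc_50", "gcc_75", "gcc_90")

SUMMARY_COLUMNS = (
    ["date", "year", "doy", "image_count", "midday_filename",
     "midday_r", "midday_g", "midday_b", "midday_gcc", "midday_rcc",
     "r_mean", "r_std", "g_mean", "g_std", "b_mean", "b_std",
     "gcc_mean", "gcc_std", "gcc_50", "gcc_75", "gcc_90",
     "rcc_mean", "rcc_std", "rcc_50", "rcc_75", "rcc_90",
     "max_solar_elev", "snowflag"]
    + [f"outlierflag_{s}" for s in _GCC_STATS]
    + [f"smooth_{s}" for s in _GCC_STATS]
    + [f"smooth_{s}" for s in ("rcc_mean", "rcc_50", "rcc_75", "rcc_90")]
    + [f"smooth_ci_{s}" for s in _GCC_STATS]
    + [f"smooth_ci_{s}" for s in ("rcc_mean", "rcc_50", "rcc_75", "rcc_90")]
    + ["int_flag"]
)


def qc_pass(rec, cfg: QcConfig = QcConfig()) -> tuple[bool, str]:
    """Whether one all-image record passes the selection filters.

    Returns ``(ok, reason)``; the reason is "" for passing records.
    """
    elev = rec["solar_elev"]
    total = rec["r_mean"] + rec["g_mean"] + rec["b_mean"]
    if elev < cfg.min_solar_elev:
        return False, "low sun"
    if total > cfg.bright_sum:
        return False, "too bright"
    if total < cfg.dark_sum:
        return False, "too dark"
    return True, ""


def _days_in_year(year: int) -> int:
    return _dt.date(year, 12, 31).timetuple().tm_yday


def bin_windows(year: int, step: int) -> list[Window]:
    """The fixed aggregation grid for one calendar year."""
    if step not in (1, 3):
        raise ValueError("step must be 1 or 3")
    ndays = _days_in_year(year)
    jan1 = _dt.date(year, 1, 1)
    windows: list[Window] = []
    if step == 1:
        for doy in range(1, ndays + 1):
            d = jan1 + _dt.timedelta(days=doy - 1)
            windows.append(Window(date=d, doy=doy, days=(d,)))
    else:
        for doy in range(2, 366, 3):
            last = min(doy + 1, ndays) if doy == 365 else doy + 1
            days = tuple(
                jan1 + _dt.timedelta(days=d - 1) for d in range(doy - 1, last + 1)
            )
            windows.append(
                Window(date=jan1 + _dt.timedelta(days=doy - 1), doy=doy, days=days)
            )
    return windows


def select_midday(records: pd.DataFrame, window: Window):
    """The record closest to 12:00 noon on the window's middle day.

    Ties break to the earlier image; ``None`` when the middle day has no
    records at all.  No quality filtering is applied here.
    """
    noon = _dt.timedelta(hours=12)
    day = records[records["date"] == window.middle_day]
    if not len(day):
        return None
    offsets = day["local_std_time"].map(
        lambda t: abs(
            _dt.timedelta(hours=t.hour, minutes=t.minute, seconds=t.second) - noon
        )
    )
    # stable sort on (offset, time): earlier image wins ties
    order = sorted(
        day.index, key=lambda i: (offsets[i], day.loc[i, "local_std_time"])
    )
    return day.loc[order[0]]


def _percentile(vals: np.ndarray, q: float) -> float:
    return float(np.percentile(vals, q))


def summarize_window(
    valid: pd.DataFrame,
    midday,
    window: Window,
    snowflags: dict[str, int] | None = None,
) -> dict:
    """One summary row from the window's valid records and midday record.

    ``valid`` holds the records passing :func:`qc_pass`; aggregate
    statistics are computed across the per-image ROI-mean values.
    Standard deviations are sample SDs and reported missing for fewer
    than two images.  The snow flag is looked up by midday filename.
    """
    row: dict = {
        "date": window.date,
        "year": window.date.year,
        "doy": window.doy,
        "image_count": len(valid),
    }
    nan = math.nan
    if midday is not None:
        row.update(
            midday_filename=midday["filename"],
            midday_r=midday["r_mean"],
            midday_g=midday["g_mean"],
            midday_b=midday["b_mean"],
            midday_gcc=midday["gcc"],
            midday_rcc=midday["rcc"],
        )
        if snowflags is not None:
            row["snowflag"] = snowflags.get(midday["filename"], nan)
        else:
            row["snowflag"] = nan
    else:
        row.update(
            midday_filename=None, midday_r=nan, midday_g=nan, midday_b=nan,
            midday_gcc=nan, midday_rcc=nan, snowflag=nan,
        )
    if len(valid):
        for c in ("r", "g", "b"):
            vals = valid[f"{c}_mean"].to_numpy(float)
            row[f"{c}_mean"] = float(vals.mean())
            row[f"{c}_std"] = float(vals.std(ddof=1)) if len(vals) >= 2 else nan
        for idx in ("gcc", "rcc"):
            vals = valid[idx].to_numpy(float)
            row[f"{idx}_mean"] = float(vals.mean())
            row[f"{idx}_std"] = float(vals.std(ddof=1)) if len(vals) >= 2 else nan
            for q in (50, 75, 90):
                row[f"{idx}_{q}"] = _percentile(vals, q)
        row["max_solar_elev"] = float(valid["solar_elev"].max())
    else:
        for col in ("r_mean", "r_std", "g_mean", "g_std", "b_mean", "b_std",
                    "gcc_mean", "gcc_std", "gcc_50", "gcc_75", "gcc_90",
                    "rcc_mean", "rcc_std", "rcc_50", "rcc_75", "rcc_90",
                    "max_solar_elev"):
            row[col] = nan
    for s in _GCC_STATS:
        row[f"outlierflag_{s}"] = nan
    for s in ("gcc_mean", "gcc_50", "gcc_75", "gcc_90",
              "rcc_mean", "rcc_50", "rcc_75", "rcc_90"):
        row[f"smooth_{s}"] = nan
        row[f"smooth_ci_{s}"] = nan
    row["int_flag"] = nan
    return row


def make_summary(
    allimage: pd.DataFrame,
    step: int,
    snowflags: dict[str, int] | None = None,
    cfg: QcConfig = QcConfig(),
) -> pd.DataFrame:
    """Aggregate an all-image frame to the 1- or 3-day summary grid.

    Covers every window of every calendar year present in the input;
    smoothed columns are left missing (see
    :func:`greencam.smoothing.smooth_summary`).
    """
    if not len(allimage):
        raise ValueError("empty all-image frame")
    ok = allimage.apply(lambda r: qc_pass(r, cfg)[0], axis=1)
    valid_all = allimage[ok]
    years = range(allimage["date"].min().year, allimage["date"].max().year + 1)
    rows = []
    for year in years:
        for window in bin_windows(year, step):
            in_win = allimage[allimage["date"].isin(window.days)]
            valid = valid_all[valid_all["date"].isin(window.days)]
            midday = select_midday(in_win, window)
            rows.append(summarize_window(valid, midday, window, snowflags))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _summary_header(meta: dict[str, str], step: int, cfg: QcConfig) -> list[str]:
    g = meta.get
    return [
        "#",
        f"# {step}-day summary product timeseries for {g('Site', '')}",
        "#",
        f"# Site: {g('Site', '')}",
        f"# Veg Type: {g('Veg Type', '')}",
        f"# ROI ID Number: {g('ROI ID Number', '')}",
        f"# Lat: {g('Lat', '')}",
        f"# Lon: {g('Lon', '')}",
        f"# Elev: {g('Elev', '')}",
        f"# UTC Offset: {g('UTC Offset', '')}",
        f"# Image Count Threshold: {g('Image Count Threshold', 'None')}",
        f"# Aggregation Period: {step}",
        f"# Solar Elevation Min: {cfg.min_solar_elev:g}",
        f"# Time of Day Min: {g('Time of Day Min', 'None')}",
        f"# Time of Day Max: {g('Time of Day Max', 'None')}",
        f"# ROI Brightness Min: {cfg.dark_sum:g}",
        f"# ROI Brightness Max: {cfg.bright_sum:g}",
        f"# Creation Date: {g('Creation Date', '')}",
        f"# Creation Time: {g('Creation Time', '')}",
        f"# Update Date: {g('Update Date', '')}",
        f"# Update Time: {g('Update Time', '')}",
        f"# Smoothing Method: {g('Smoothing Method', 'AICc cubic smoothing spline')}",
        f"# Outlier Thresholds: {g('Outlier Thresholds', '4.0 SD above, 2.0 SD below (Laplace)')}",
        "#",
    ]


def write_summary(
    df: pd.DataFrame,
    path,
    meta: dict[str, str],
    step: int,
    cfg: QcConfig = QcConfig(),
) -> None:
    """Write a 1-/3-day summary CSV (24 ``#`` metadata lines + header + rows)."""
    from pathlib import Path

    lines = _summary_header(meta, step, cfg)
    lines.append(",".join(SUMMARY_COLUMNS))
    int_cols = {"year", "doy", "image_count", "snowflag", "int_flag",
                *(f"outlierflag_{s}" for s in _GCC_STATS)}
    for _, row in df.iterrows():
        toks = [row["date"].isoformat()]
        for col in SUMMARY_COLUMNS[1:]:
            v = row[col]
            if col == "midday_filename":
                toks.append(_io.fmt_str(v))
            elif col in int_cols:
                toks.append(_io.fmt_int(v))
            else:
                toks.append(_io.fmt_float(v))
        lines.append(",".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


def read_summary(path) -> tuple[pd.DataFrame, dict[str, str], int]:
    """Read a summary CSV back into (frame, metadata, aggregation step)."""
    meta, data = _io.read_header_block(path)
    if not data:
        raise ValueError(f"{path}: no column header line")
    cols = data[0].split(",")
    if cols != SUMMARY_COLUMNS:
        raise ValueError(f"{path}: column mismatch")
    try:
        step = int(meta["Aggregation Period"])
    except (KeyError, ValueError):
        raise ValueError(f"{path}: missing or bad 'Aggregation Period' header") from None
    if step not in (1, 3):
        raise ValueError(f"{path}: unsupported aggregation period {step}")
    int_cols = {"year", "doy", "image_count", "snowflag", "int_flag",
                *(f"outlierflag_{s}" for s in _GCC_STATS)}
    records = []
    for ln in data[1:]:
        toks = ln.split(",")
        rec = {"date": _dt.date.fromisoformat(toks[0])}
        for col, tok in zip(SUMMARY_COLUMNS[1:], toks[1:]):
            if col == "midday_filename":
                rec[col] = _io.parse_str(tok)
            elif col in int_cols:
                rec[col] = _io.parse_int(tok)
            else:
                rec[col] = _io.parse_float(tok)
        records.append(rec)
    return pd.DataFrame(records, columns=SUMMARY_COLUMNS), meta, step
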