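"""Per-image ROI colour statistics and the all-image product.

For each image, the red/green/blue digital numbers inside the ROI are
summarized (mean, population SD, seven percentiles, pairwise Pearson
correlations) and converted to chromatic coordinates

    Gcc = G_DN / (R_DN + G_DN + B_DN),    Rcc = R_DN / (R_DN + G_DN + B_DN),

where X_DN is the ROI-mean digital number of channel X.  Chromatic
coordinates are invariant under multiplicative exposure changes, which
is what makes them useful as a greenness index.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import _io
from .roi import BinaryMask, RoiList, conform_image, load_mask, select_mask
from .solar import FilenameError, SiteLocation, parse_image_filename, solar_elevation

__all__ = [
    "PERCENTILES",
    "ALLIMAGE_COLUMNS",
    "chromatic_coords",
    "roi_channel_stats",
    "process_image",
    "process_directory",
    "write_roistats",
    "read_roistats",
]

logger = logging.getLogger(__name__)

#: Percentile levels reported per colour channel.
PERCENTILES = (5, 10, 25, 50, 75, 90, 95)

_CHANNELS = ("r", "g", "b")


def _channel_cols(c: str) -> list[str]:
    return [f"{c}_mean", f"{c}_std"] + [f"{c}_{q}_qtl" for q in PERCENTILES]


#: Column order of the all-image product.
ALLIMAGE_COLUMNS = (
    ["date", "local_std_time", "doy", "filename", "solar_elev", "exposure",
     "mask_index", "gcc", "rcc"]
    + _channel_cols("r")
    + _channel_cols("g")
    + _channel_cols("b")
    + ["r_g_cor", "g_b_cor", "b_r_cor"]
)


def chromatic_coords(r_mean: float, g_mean: float, b_mean: float) -> tuple[float, float]:
    """(Gcc, Rcc) from ROI-mean digital numbers; NaNs when the sum is zero."""
    total = r_mean + g_mean + b_mean
    if total <= 0:
        return (math.nan, math.nan)
    return (g_mean / total, r_mean / total)


def roi_channel_stats(image: np.ndarray, mask: BinaryMask) -> dict[str, float]:
    """Channel summaries and pairwise correlations over the ROI pixels.

    Standard deviations use the population divisor N (a descriptive
    statistic of the full ROI), percentiles use linear interpolation
    between closest ranks, and a zero-variance channel yields missing
    correlations.
    """
    if image.shape[:2] != (mask.height, mask.width):
        raise ValueError(
            f"image shape {image.shape[:2]} does not match mask "
            f"({mask.height}, {mask.width}); conform the image first"
        )
    pixels = image[mask.include].astype(np.float64)  # (n, 3)
    out: dict[str, float] = {}
    for k, c in enumerate(_CHANNELS):
        vals = pixels[:, k]
        out[f"{c}_mean"] = float(vals.mean())
        out[f"{c}_std"] = float(vals.std(ddof=0))
        qs = np.percentile(vals, PERCENTILES)
        for q, v in zip(PERCENTILES, qs):
            out[f"{c}_{q}_qtl"] = float(v)
    for name, (i, j) in (("r_g_cor", (0, 1)), ("g_b_cor", (1, 2)), ("b_r_cor", (2, 0))):
        xi, xj = pixels[:, i], pixels[:, j]
        if xi.std() == 0.0 or xj.std() == 0.0 or len(xi) < 2:
            out[name] = math.nan
        else:
            out[name] = float(np.corrcoef(xi, xj)[0, 1])
    return out


def process_image(
    path: str | Path,
    roi: RoiList,
    loc: SiteLocation,
    mask_dir: str | Path | None = None,
    _mask_cache: dict | None = None,
) -> dict | None:
    """One all-image record from a JPEG, or ``None`` when skipped.

    Images whose timestamp falls outside every mask window are skipped
    (they produce no row), as are unreadable files; the reason is logged.
    """
    path = Path(path)
    try:
        ts = parse_image_filename(path.name)
    except FilenameError as exc:
        logger.warning("skipping %s: %s", path.name, exc)
        return None
    entry = select_mask(roi, ts)
    if entry is None:
        logger.info("skipping %s: outside all mask windows", path.name)
        return None
    mask_dir = Path(mask_dir) if mask_dir is not None else path.parent
    cache = _mask_cache if _mask_cache is not None else {}
    if entry.mask_file not in cache:
        cache[entry.mask_file] = load_mask(mask_dir / entry.mask_file)
    mask = cache[entry.mask_file]
    try:
        with Image.open(path) as im:
            if im.mode != "RGB":
                raise ValueError(f"expected RGB JPEG, got mode {im.mode}")
            arr = np.asarray(im)
    except Exception as exc:  # unreadable or non-RGB image
        logger.warning("skipping %s: %s", path.name, exc)
        return None
    arr = conform_image(arr, mask)
    stats = roi_channel_stats(arr, mask)
    gcc, rcc = chromatic_coords(stats["r_mean"], stats["g_mean"], stats["b_mean"])
    rec = {
        "date": ts.date,
        "local_std_time": ts.local_std_time,
        "doy": ts.doy,
        "filename": path.name,
        "solar_elev": solar_elevation(loc, ts),
        "exposure": math.nan,  # camera metadata pass-through, when available
        "mask_index": entry.mask_index,
        "gcc": gcc,
        "rcc": rcc,
    }
    rec.update(stats)
    return rec


def process_directory(
    image_dir: str | Path,
    roi: RoiList,
    loc: SiteLocation,
    mask_dir: str | Path | None = None,
) -> pd.DataFrame:
    """All-image product for every parseable JPEG under ``image_dir``.

    Rows are sorted chronologically; the frame has the all-image
    product's column order.
    """
    image_dir = Path(image_dir)
    mask_dir = Path(mask_dir) if mask_dir is not None else image_dir
    cache: dict = {}
    records = []
    for path in sorted(image_dir.glob("*.jpg")):
        rec = process_image(path, roi, loc, mask_dir=mask_dir, _mask_cache=cache)
        if rec is not None:
            records.append(rec)
    df = pd.DataFrame(records, columns=ALLIMAGE_COLUMNS)
    if len(df):
        df = df.sort_values(["date", "local_std_time"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def _roistats_header(meta: dict[str, str]) -> list[str]:
    g = meta.get
    return [
        "#",
        f"# All-image colour statistics timeseries for {g('Site', '')}",
        "#",
        f"# Site: {g('Site', '')}",
        f"# Veg Type: {g('Veg Type', '')}",
        f"# ROI ID Number: {g('ROI ID Number', '')}",
        f"# Lat: {g('Lat', '')}",
        f"# Lon: {g('Lon', '')}",
        f"# Elev: {g('Elev', '')}",
        f"# UTC Offset: {g('UTC Offset', '')}",
        f"# Resized Images: {g('Resized Images', 'false')}",
        f"# Creation Date: {g('Creation Date', '')}",
        f"# Creation Time: {g('Creation Time', '')}",
        f"# Update Date: {g('Update Date', '')}",
        f"# Update Time: {g('Update Time', '')}",
        "#",
    ]


def write_roistats(df: pd.DataFrame, path: str | Path, meta: dict[str, str]) -> None:
    """Write the all-image product CSV (16 ``#`` metadata lines + header + rows)."""
    lines = _roistats_header(meta)
    lines.append(",".join(ALLIMAGE_COLUMNS))
    for _, row in df.iterrows():
        toks = [
            row["date"].isoformat(),
            row["local_std_time"].isoformat(),
            str(int(row["doy"])),
            row["filename"],
            _io.fmt_float(row["solar_elev"]),
            _io.fmt_int(row["exposure"]),
            str(int(row["mask_index"])),
            _io.fmt_float(row["gcc"]),
            _io.fmt_float(row["rcc"]),
        ]
        for c in _CHANNELS:
            toks += [_io.fmt_float(row[col]) for col in _channel_cols(c)]
        toks += [_io.fmt_float(row[k]) for k in ("r_g_cor", "g_b_cor", "b_r_cor")]
        lines.append(",".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


def read_roistats(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an all-image product CSV back into (frame, metadata)."""
    import datetime as _dt

    meta, data = _io.read_header_block(path)
    if not data:
        raise ValueError(f"{path}: no column header line")
    cols = data[0].split(",")
    if cols != ALLIMAGE_COLUMNS:
        raise ValueError(f"{path}: column mismatch: {cols[:5]}...")
    records = []
    for ln in data[1:]:
        toks = ln.split(",")
        rec = {
            "date": _dt.date.fromisoformat(toks[0]),
            "local_std_time": _dt.time.fromisoformat(toks[1]),
            "doy": int(toks[2]),
            "filename": toks[3],
            "solar_elev": _io.parse_float(toks[4]),
            "exposure": _io.parse_int(toks[5]),
            "mask_index": int(toks[6]),
            "gcc": _io.parse_float(toks[7]),
            "rcc": _io.parse_float(toks[8]),
        }
        for name, tok in zip(ALLIMAGE_COLUMNS[9:], toks[9:]):
            rec[name] = _io.parse_float(tok)
        records.append(rec)
    return pd.DataFrame(records, columns=ALLIMAGE_COLUMNS), meta
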