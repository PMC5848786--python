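"""Synthetic camera sites with known phenological ground truth.

The generator emulates the seasonal canopy-colour trajectory of a
temperate site as a double-logistic pulse (or a sum of pulses for
bimodal sites) in Gcc:

    gcc(t) = baseline + sum_p A_p * [ 1/(1+exp(-rs_p (t-ts_p)))
                                    - 1/(1+exp(-ra_p (t-ta_p))) ]

with additive Laplace noise on the index, optional snow days (colour
pulled toward the achromatic 1/3), gross negative outliers, per-image
multiplicative illumination changes (which Gcc is invariant to), and an
optional field-of-view shift.  True transition dates are solved from
the noiseless trajectory by root finding, independently of the image
pipeline, so every processing stage can be checked against the truth.

``make_series`` produces a summary-like Gcc series directly;
``make_site_images`` renders an actual image archive (JPEGs, TIFF
masks, ROI list, site metadata) whose ROI-mean chromatic coordinates
track the trajectory to within 8-bit quantization.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.optimize import brentq

from .metadata import write_metadata
from .roi import MaskEntry, RoiList, write_roi_list
from .summary import bin_windows

__all__ = [
    "LogisticPulse",
    "SyntheticSiteSpec",
    "SyntheticTruth",
    "TruthStage",
    "make_series",
    "make_site_images",
    "solve_rgb",
]


@dataclass(frozen=True)
class LogisticPulse:
    """One green-up/green-down cycle of the trajectory."""

    amplitude: float = 0.10
    spring_midpoint: float = 140.0  # day of year of the rising inflection
    spring_rate: float = 0.10  # 1/day
    autumn_midpoint: float = 270.0
    autumn_rate: float = 0.08

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.spring_midpoint >= self.autumn_midpoint:
            raise ValueError("spring midpoint must precede autumn midpoint")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        rise = 1.0 / (1.0 + np.exp(-self.spring_rate * (t - self.spring_midpoint)))
        fall = 1.0 / (1.0 + np.exp(-self.autumn_rate * (t - self.autumn_midpoint)))
        return self.amplitude * (rise - fall)


@dataclass(frozen=True)
class SyntheticSiteSpec:
    """Everything needed to reproduce one simulated site."""

    seed: int = 0
    sitename: str = "greenwood"
    veg_type: str = "DB"
    roi_id_number: str = "0001"
    year: int = 2015
    step: int = 3  # days between images / summary windows
    baseline: float = 0.35
    pulses: tuple[LogisticPulse, ...] = (LogisticPulse(),)
    noise_sigma: float = 0.004  # SD of the Laplace noise on gcc
    outlier_frac: float = 0.0  # fraction of points turned into gross negatives
    outlier_scale: float = 10.0  # outlier depth in units of noise_sigma
    snow_doys: tuple[int, ...] = ()
    illumination_range: tuple[float, float] = (0.8, 1.2)
    fov_shift: tuple[int, int] | None = None  # (doy, pixel offset)
    dims: tuple[int, int] = (120, 160)  # (height, width)
    roi_box: tuple[int, int, int, int] = (30, 40, 100, 140)  # top,left,bottom,right
    brightness_sum: float = 300.0  # target r+g+b channel-mean sum (DN)
    lat: float = 42.5
    lon: float = -72.2
    elevation: float = 340.0
    utc_offset: float = -5.0

    def trajectory(self, t: np.ndarray) -> np.ndarray:
        """Noiseless Gcc trajectory at (fractional) day of year ``t``."""
        t = np.asarray(t, float)
        out = np.full(t.shape, self.baseline)
        for pulse in self.pulses:
            out = out + pulse(t)
        return out


@dataclass
class TruthStage:
    """One true rising/falling limb of the noiseless trajectory."""

    direction: str
    start_doy: float
    end_doy: float
    min_gcc: float
    max_gcc: float
    transitions: dict[int, float]  # percent threshold -> fractional doy


@dataclass
class SyntheticTruth:
    """Generating parameters plus derived analytic ground truth."""

    spec: SyntheticSiteSpec
    doys: np.ndarray
    trajectory: np.ndarray
    stages: list[TruthStage]
    outlier_indices: list[int]
    snow_doys: list[int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": dataclasses.asdict(self.spec),
            "doys": self.doys.tolist(),
            "trajectory": self.trajectory.tolist(),
            "stages": [dataclasses.asdict(s) for s in self.stages],
            "outlier_indices": self.outlier_indices,
            "snow_doys": self.snow_doys,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def analytic_stages(
    spec: SyntheticSiteSpec,
    thresholds: tuple[float, ...] = (0.10, 0.25, 0.50),
    min_amplitude: float = 0.005,
) -> list[TruthStage]:
    """Rising/falling limbs of the noiseless trajectory with exact crossings.

    Extrema are located on a fine grid and threshold crossings refined
    by Brent root finding -- an oracle independent of the processing
    pipeline.
    """
    ndays = 366 if _dt.date(spec.year, 12, 31).timetuple().tm_yday == 366 else 365
    t = np.arange(1.0, ndays + 1e-9, 0.05)
    g = spec.trajectory(t)
    dg = np.diff(g)
    sign = np.sign(dg)
    turn = np.nonzero(np.diff(sign) != 0)[0] + 1
    knots = [0, *turn.tolist(), len(t) - 1]
    stages: list[TruthStage] = []
    for a, b in zip(knots[:-1], knots[1:]):
        lo, hi = float(min(g[a], g[b])), float(max(g[a], g[b]))
        if hi - lo < min_amplitude:
            continue
        rising = g[b] > g[a]
        crossings = {}
        for f in thresholds:
            thr = lo + f * (hi - lo)
            crossings[round(100 * f)] = float(
                brentq(lambda x: float(spec.trajectory(x)) - thr, t[a], t[b])
            )
        stages.append(
            TruthStage(
                direction="rising" if rising else "falling",
                start_doy=float(t[a]),
                end_doy=float(t[b]),
                min_gcc=lo,
                max_gcc=hi,
                transitions=crossings,
            )
        )
    return stages


def make_series(spec: SyntheticSiteSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Summary-like Gcc series on the fixed doy grid, with ground truth.

    Laplace noise uses scale b = sigma/sqrt(2); snow days are replaced
    by values around the achromatic 1/3; injected outliers drop the
    value by ``outlier_scale * noise_sigma``.  Deterministic given the
    spec (the seed lives in the spec).
    """
    rng = np.random.default_rng(spec.seed)
    windows = bin_windows(spec.year, spec.step)
    dates = [w.date for w in windows]
    doys = np.array([w.doy for w in windows], float)
    clean = spec.trajectory(doys)
    b = spec.noise_sigma / math.sqrt(2.0)
    gcc = clean + rng.laplace(0.0, b, size=len(doys)) if b > 0 else clean.copy()
    snow = [int(d) for d in spec.snow_doys]
    for i, d in enumerate(doys):
        if int(d) in snow:
            gcc[i] = 1.0 / 3.0 + (rng.laplace(0.0, b) if b > 0 else 0.0)
    candidates = [i for i, d in enumerate(doys) if int(d) not in snow]
    n_out = int(round(spec.outlier_frac * len(candidates)))
    outliers = sorted(
        rng.choice(candidates, size=n_out, replace=False).tolist()
    ) if n_out else []
    for i in outliers:
        gcc[i] -= spec.outlier_scale * spec.noise_sigma
    df = pd.DataFrame({"date": dates, "doy": doys.astype(int), "gcc": gcc})
    truth = SyntheticTruth(
        spec=spec,
        doys=doys,
        trajectory=clean,
        stages=analytic_stages(spec),
        outlier_indices=list(outliers),
        snow_doys=snow,
    )
    return df, truth


def solve_rgb(gcc: float, rcc: float, total: float) -> tuple[float, float, float]:
    """Channel means (DN) realizing the target chromatic coordinates.

    Given a brightness budget ``total`` = r+g+b, the solution is exact:
    r = rcc*total, g = gcc*total, b = the remainder.  Raises when any
    channel leaves the 8-bit gamut.
    """
    r, g = rcc * total, gcc * total
    bb = total - r - g
    for name, v in (("r", r), ("g", g), ("b", bb)):
        if not 0.0 <= v <= 255.0:
            raise ValueError(
                f"target gcc={gcc:.3f}, rcc={rcc:.3f} at sum {total:g} puts "
                f"channel {name} at {v:.1f} DN, outside the 8-bit gamut"
            )
    return r, g, bb


def _dither(shape: tuple[int, int], value: float, rng: np.random.Generator) -> np.ndarray:
    """Integer field whose mean equals ``value`` (stochastic rounding)."""
    base = math.floor(value)
    frac = value - base
    return base + (rng.random(shape) < frac)


def _render_scene(
    spec: SyntheticSiteSpec,
    gcc: float,
    factor: float,
    shift: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synthetic frame: striped landscape, sky band, canopy ROI patch."""
    h, w = spec.dims
    top, left, bottom, right = spec.roi_box
    x = np.arange(w) + shift
    stripes = 128 + 60 * np.sin(2 * np.pi * x / 40.0)
    img = np.empty((h, w, 3), float)
    img[:] = stripes[None, :, None]
    img[: h // 6] = 220.0  # sky band along the top
    rcc = (1.0 - gcc) / 2.0  # split the non-green budget evenly
    r, g, bb = solve_rgb(gcc, rcc, spec.brightness_sum)
    box = (slice(top, bottom), slice(left + shift, right + shift))
    shape = (bottom - top, right - left)
    for k, v in enumerate((r, g, bb)):
        img[box[0], box[1], k] = _dither(shape, min(v * factor, 255.0), rng)
    img[: h // 6] *= factor
    return np.clip(img, 0, 255).astype(np.uint8)


def make_site_images(
    spec: SyntheticSiteSpec, outdir: str | Path
) -> tuple[Path, SyntheticTruth]:
    """Render a full synthetic site archive under ``outdir``.

    Writes one midday JPEG per ``step`` days, the binary TIFF mask(s)
    and ROI list, site metadata (JSON and text), and the ground-truth
    JSON.  A field-of-view shift translates the scene content after the
    shift date and adds a second mask entry covering the shifted canopy
    patch.  Returns the site directory and the truth object.
    """
    import tifffile

    outdir = Path(outdir)
    site_dir = outdir / spec.sitename
    img_dir = site_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)

    series, truth = make_series(
        dataclasses.replace(spec, noise_sigma=0.0, outlier_frac=0.0)
    )
    shift_doy, shift_px = spec.fov_shift if spec.fov_shift else (None, 0)

    for _, row in series.iterrows():
        date, doy, gcc = row["date"], int(row["doy"]), float(row["gcc"])
        if doy in truth.snow_doys:
            gcc = 1.0 / 3.0
        factor = rng.uniform(*spec.illumination_range)
        shift = shift_px if (shift_doy is not None and doy >= shift_doy) else 0
        frame = _render_scene(spec, gcc, factor, shift, rng)
        name = (
            f"{spec.sitename}_{date.year:04d}_{date.month:02d}_{date.day:02d}"
            f"_120000.jpg"
        )
        Image.fromarray(frame).save(
            img_dir / name, "JPEG", quality=95, subsampling=0
        )

    h, w = spec.dims
    top, left, bottom, right = spec.roi_box
    roi_name = f"{spec.sitename}_{spec.veg_type}_{spec.roi_id_number}"
    entries = []

    def _write_mask(index: int, offset: int) -> str:
        mask = np.full((h, w), 255, np.uint8)
        mask[top:bottom, left + offset : right + offset] = 0
        fname = f"{roi_name}_{index:02d}.tif"
        tifffile.imwrite(str(site_dir / fname), mask)
        return fname

    year_start = _dt.date(spec.year, 1, 1)
    midnight, day_end = _dt.time(0, 0, 0), _dt.time(23, 59, 59)
    if shift_doy is None:
        entries.append(
            MaskEntry(year_start, midnight, _dt.date(9999, 12, 31), day_end,
                      _write_mask(1, 0), "", 1)
        )
    else:
        shift_date = year_start + _dt.timedelta(days=shift_doy - 1)
        entries.append(
            MaskEntry(year_start, midnight,
                      shift_date - _dt.timedelta(days=1), day_end,
                      _write_mask(1, 0), "", 1)
        )
        entries.append(
            MaskEntry(shift_date, midnight, _dt.date(9999, 12, 31), day_end,
                      _write_mask(2, shift_px), "", 2)
        )
    roi = RoiList(
        sitename=spec.sitename,
        veg_type=spec.veg_type,
        roi_id_number=spec.roi_id_number,
        entries=entries,
        description="synthetic canopy patch with known greenness trajectory",
    )
    write_roi_list(roi, site_dir / f"{roi_name}_roi.csv")

    meta = {
        "sitename": spec.sitename,
        "long_name": f"synthetic site {spec.sitename}",
        "lat": spec.lat,
        "lon": spec.lon,
        "elevation": spec.elevation,
        "utc_offset": spec.utc_offset,
        "site_type": "I",
        "primary_veg_type": spec.veg_type,
        "date_start": series["date"].iloc[0].isoformat(),
        "date_end": series["date"].iloc[-1].isoformat(),
        "active": "False",
        "nimage": int(len(series)),
    }
    write_metadata(meta, site_dir / f"{spec.sitename}_meta.json")
    write_metadata(meta, site_dir / f"{spec.sitename}_meta.txt")
    truth.to_json(site_dir / f"{spec.sitename}_truth.json")
    return site_dir, truth
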