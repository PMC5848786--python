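"""Region-of-interest mask sequences.

An ROI is delineated by a sequence of binary 8-bit TIFF masks, each valid
over a date/time window listed in an ROI list CSV.  Mask pixels below DN
128 (black) are *inside* the ROI; white pixels are excluded.  The end
date ``9999-12-31`` marks an open-ended window.

Also provides image conformance (resizing an image to the mask
dimensions) and the yearly field-of-view inspection composite built from
the centre column of each midday image.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .solar import ImageTimestamp

__all__ = [
    "VEG_TYPES",
    "MaskEntry",
    "RoiList",
    "BinaryMask",
    "RoiFormatError",
    "read_roi_list",
    "write_roi_list",
    "load_mask",
    "select_mask",
    "conform_image",
    "build_composite",
]

#: Two-letter vegetation type codes admissible in ROI identifiers.
VEG_TYPES = frozenset(
    ["AG", "DB", "DN", "EB", "EN", "GR", "MX", "SH", "TN", "WT", "NV", "RF", "XX"]
)

#: Sentinel end date marking an open-ended mask window.
OPEN_END_DATE = _dt.date(9999, 12, 31)

_ROI_COLUMNS = "start_date,start_time,end_date,end_time,mask_file,sample_image"


class RoiFormatError(ValueError):
    """Raised on malformed ROI list files or masks."""


@dataclass(frozen=True)
class MaskEntry:
    """One window of the mask sequence.  Boundaries are inclusive."""

    start_date: _dt.date
    start_time: _dt.time
    end_date: _dt.date
    end_time: _dt.time
    mask_file: str
    sample_image: str
    mask_index: int  # 1-based position in the sequence

    @property
    def start(self) -> _dt.datetime:
        return _dt.datetime.combine(self.start_date, self.start_time)

    @property
    def end(self) -> _dt.datetime:
        return _dt.datetime.combine(self.end_date, self.end_time)

    def contains(self, when: _dt.datetime) -> bool:
        return self.start <= when <= self.end


@dataclass
class RoiList:
    """ROI list: identifies one site/veg-type/ROI-id mask sequence."""

    sitename: str
    veg_type: str
    roi_id_number: str  # 4-digit code, "0001" for the first list
    entries: list[MaskEntry] = field(default_factory=list)
    owner: str = ""
    created: str = ""
    updated: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.veg_type not in VEG_TYPES:
            raise RoiFormatError(f"unknown veg_type {self.veg_type!r}")

    @property
    def roi_name(self) -> str:
        return f"{self.sitename}_{self.veg_type}_{self.roi_id_number}"


@dataclass(frozen=True)
class BinaryMask:
    """Pixel inclusion grid; ``include[i, j]`` True for ROI pixels."""

    include: np.ndarray  # bool, shape (height, width)

    @property
    def height(self) -> int:
        return int(self.include.shape[0])

    @property
    def width(self) -> int:
        return int(self.include.shape[1])

    @property
    def n_include(self) -> int:
        return int(self.include.sum())


def _parse_date(tok: str, what: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(tok)
    except ValueError:
        raise RoiFormatError(f"bad {what} {tok!r}") from None


def _parse_time(tok: str, what: str) -> _dt.time:
    try:
        return _dt.time.fromisoformat(tok)
    except ValueError:
        raise RoiFormatError(f"bad {what} {tok!r}") from None


def read_roi_list(path: str | Path) -> RoiList:
    """Read an ROI list CSV (13 ``#`` header lines, column header, rows)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header = [ln for ln in lines if ln.startswith("#")]
    meta: dict[str, str] = {}
    for ln in header:
        body = ln.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    data_lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not data_lines:
        raise RoiFormatError(f"{path}: no column header line")
    if data_lines[0].replace(" ", "") != _ROI_COLUMNS:
        raise RoiFormatError(
            f"{path}: expected columns {_ROI_COLUMNS!r}, got {data_lines[0]!r}"
        )
    entries: list[MaskEntry] = []
    for i, ln in enumerate(data_lines[1:], start=1):
        toks = [t.strip() for t in ln.split(",")]
        if len(toks) != 6:
            raise RoiFormatError(f"{path}: row {i} has {len(toks)} fields, expected 6")
        entry = MaskEntry(
            start_date=_parse_date(toks[0], "start_date"),
            start_time=_parse_time(toks[1], "start_time"),
            end_date=_parse_date(toks[2], "end_date"),
            end_time=_parse_time(toks[3], "end_time"),
            mask_file=toks[4],
            sample_image=toks[5],
            mask_index=i,
        )
        if entry.end < entry.start:
            raise RoiFormatError(
                f"{path}: row {i} window ends before it starts ({toks[2]} < {toks[0]})"
            )
        entries.append(entry)
    sitename = meta.get("Site", path.stem.split("_")[0])
    veg_type = meta.get("Veg Type", "XX")
    roi_id = meta.get("ROI ID Number", "0001")
    return RoiList(
        sitename=sitename,
        veg_type=veg_type,
        roi_id_number=roi_id,
        entries=entries,
        owner=meta.get("Owner", ""),
        created=meta.get("Creation Date", ""),
        updated=meta.get("Update Date", ""),
        description=meta.get("Description", ""),
    )


def write_roi_list(roi: RoiList, path: str | Path) -> None:
    """Write an ROI list CSV; ``read_roi_list(write(...))`` round-trips."""
    lines = [
        "#",
        f"# ROI List for {roi.sitename}",
        "#",
        f"# Site: {roi.sitename}",
        f"# Veg Type: {roi.veg_type}",
        f"# ROI ID Number: {roi.roi_id_number}",
        f"# Owner: {roi.owner}",
        f"# Creation Date: {roi.created}",
        "# Creation Time: ",
        f"# Update Date: {roi.updated}",
        "# Update Time: ",
        f"# Description: {roi.description}",
        "#",
        _ROI_COLUMNS,
    ]
    for e in roi.entries:
        lines.append(
            f"{e.start_date.isoformat()},{e.start_time.isoformat()},"
            f"{e.end_date.isoformat()},{e.end_time.isoformat()},"
            f"{e.mask_file},{e.sample_image}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_mask(tiff_path: str | Path) -> BinaryMask:
    """Load a single-band 8-bit TIFF mask; DN < 128 means "include"."""
    arr = tifffile.imread(str(tiff_path))
    if arr.ndim != 2:
        raise RoiFormatError(
            f"{tiff_path}: expected a single-band mask, got shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        raise RoiFormatError(f"{tiff_path}: expected 8-bit mask, got dtype {arr.dtype}")
    include = arr < 128
    if not include.any():
        raise RoiFormatError(f"{tiff_path}: empty ROI (no pixels below DN 128)")
    return BinaryMask(include=include)


def select_mask(roi: RoiList, ts: ImageTimestamp) -> MaskEntry | None:
    """Return the first mask entry whose window contains the timestamp.

    Windows are inclusive at both ends; overlapping windows trigger a
    configuration warning and the first match wins.  ``None`` when no
    window contains the instant (the image is then skipped entirely).
    """
    when = ts.datetime
    matches = [e for e in roi.entries if e.contains(when)]
    if not matches:
        return None
    if len(matches) > 1:
        warnings.warn(
            f"timestamp {when} falls in {len(matches)} overlapping mask windows "
            f"of {roi.roi_name}; using mask_index {matches[0].mask_index}",
            stacklevel=2,
        )
    return matches[0]


def conform_image(image: np.ndarray, mask: BinaryMask) -> np.ndarray:
    """Resize an RGB image to the mask dimensions (bilinear) if they differ."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    h, w = image.shape[:2]
    if (h, w) == (mask.height, mask.width):
        return image
    if abs((w / h) - (mask.width / mask.height)) / (mask.width / mask.height) > 0.01:
        warnings.warn(
            f"aspect ratio mismatch between image ({w}x{h}) and mask "
            f"({mask.width}x{mask.height}); resizing anyway",
            stacklevel=2,
        )
    pil = Image.fromarray(np.ascontiguousarray(image.astype(np.uint8)))
    resized = pil.resize((mask.width, mask.height), Image.BILINEAR)
    return np.asarray(resized)


def build_composite(
    midday_images: dict[_dt.date, np.ndarray],
    year: int,
    fill: tuple[int, int, int] = (128, 128, 128),
) -> np.ndarray:
    """Field-of-view inspection composite for one calendar year.

    Column ``i`` (0-based, day-of-year ``i+1``) is the centre column
    (index ``width // 2``) of that day's midday image; days without an
    image get the fill colour.  Horizon-line discontinuities between
    adjacent columns reveal camera field-of-view shifts.
    """
    if not midday_images:
        raise ValueError("no images supplied for composite")
    days = 366 if _dt.date(year, 12, 31).timetuple().tm_yday == 366 else 365
    first = next(iter(midday_images.values()))
    height = first.shape[0]
    comp = np.empty((height, days, 3), dtype=np.uint8)
    comp[:] = np.asarray(fill, dtype=np.uint8)
    for date, img in midday_images.items():
        if date.year != year:
            continue
        if img.shape[0] != height:
            raise ValueError(
                f"image for {date} has height {img.shape[0]}, expected {height}"
            )
        comp[:, date.timetuple().tm_yday - 1, :] = img[:, img.shape[1] // 2, :]
    return comp
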