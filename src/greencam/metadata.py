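"""Site metadata: JSON and key-value text dialects.

Metadata travel both as JSON and as plain text files with ``key: value``
lines; the two dialects round-trip each other and unknown keys are
preserved verbatim.  Four keys are required for processing: sitename,
lat, lon, and utc_offset (hours from UTC to local standard time).
"""

from __future__ import annotations

import json
from pathlib import Path

from .solar import SiteLocation

__all__ = [
    "REQUIRED_KEYS",
    "MetadataError",
    "read_metadata",
    "write_metadata",
    "site_location",
]

REQUIRED_KEYS = ("sitename", "lat", "lon", "utc_offset")

_SITE_TYPES = {"I", "II", "III"}


class MetadataError(ValueError):
    """Missing or invalid site metadata."""


def _validate(meta: dict) -> dict:
    for key in REQUIRED_KEYS:
        if key not in meta or meta[key] in (None, ""):
            raise MetadataError(f"missing required metadata key {key!r}")
    lat, lon = _num(meta["lat"]), _num(meta["lon"])
    if not -90 <= lat <= 90:
        raise MetadataError(f"lat out of range: {lat}")
    if not -180 <= lon <= 180:
        raise MetadataError(f"lon out of range: {lon}")
    off = _num(meta["utc_offset"])
    if not -14 <= off <= 14:
        raise MetadataError(f"utc_offset out of range: {off}")
    st = meta.get("site_type")
    if st is not None and str(st) not in _SITE_TYPES:
        raise MetadataError(f"site_type must be one of I/II/III, got {st!r}")
    return meta


def _num(value) -> float:
    """Parse a number, accepting the unicode minus sign."""
    if isinstance(value, (int, float)):
        return float(value)
    return float(str(value).replace("−", "-").strip())


def read_metadata(path: str | Path) -> dict:
    """Read site metadata from either dialect (chosen by file suffix)."""
    path = Path(path)
    if path.suffix == ".json":
        meta = json.loads(path.read_text())
    else:
        meta = {}
        for ln in path.read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#") or ":" not in ln:
                continue
            key, _, val = ln.partition(":")
            meta[key.strip()] = val.strip()
    return _validate(meta)


def write_metadata(meta: dict, path: str | Path) -> None:
    """Write site metadata as JSON (``.json``) or key-value text."""
    path = Path(path)
    _validate(meta)
    if path.suffix == ".json":
        path.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    else:
        lines = [f"{k}: {v}" for k, v in meta.items()]
        path.write_text("\n".join(lines) + "\n")


def site_location(meta: dict) -> SiteLocation:
    """Build the solar-geometry location from validated metadata."""
    return SiteLocation(
        lat=_num(meta["lat"]),
        lon=_num(meta["lon"]),
        elevation=_num(meta.get("elevation", 0) or 0),
        utc_offset=_num(meta["utc_offset"]),
    )
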