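"""Shared CSV dialect helpers.

All product files use comma-separated values, ``#``-prefixed metadata
lines, ISO dates, and the literal ``NA`` for missing values.  Numeric
formatting is canonical (five decimals for real-valued columns) so that
write -> read -> write is byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path

NA = "NA"


def fmt_float(x, nd: int = 5) -> str:
    if x is None:
        return NA
    try:
        xf = float(x)
    except (TypeError, ValueError):
        return NA
    if math.isnan(xf):
        return NA
    return f"{xf:.{nd}f}"


def fmt_int(x) -> str:
    if x is None:
        return NA
    try:
        xf = float(x)
    except (TypeError, ValueError):
        return NA
    if math.isnan(xf):
        return NA
    return str(int(xf))


def fmt_str(x) -> str:
    if x is None:
        return NA
    s = str(x)
    return s if s and s != "nan" else NA


def parse_float(tok: str) -> float:
    return math.nan if tok == NA or tok == "" else float(tok)


def parse_int(tok: str):
    return math.nan if tok == NA or tok == "" else int(tok)


def parse_str(tok: str):
    return None if tok == NA or tok == "" else tok


def read_header_block(path: str | Path) -> tuple[dict[str, str], list[str]]:
    """Split a product file into parsed ``#`` metadata and data lines."""
    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    data: list[str] = []
    for ln in lines:
        if ln.startswith("#"):
            body = ln.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
        elif ln.strip():
            data.append(ln)
    return meta, data
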