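"""Image-filename timestamps and solar elevation.

Camera images are named ``<sitename>_<YYYY_MM_DD>_<hhmmss>.jpg`` with the
timestamp in local *standard* time (daylight saving is never applied).
Solar elevation is computed with the NOAA solar-calculator ephemeris
(declination + equation of time + hour angle, from Meeus' series);
atmospheric refraction is ignored.  Accuracy is a few hundredths of a
degree -- ample for the 10-degree quality-control threshold used
downstream.
"""

from __future__ import annotations

import datetime as _dt
import math
import re
from dataclasses import dataclass

__all__ = [
    "ImageTimestamp",
    "SiteLocation",
    "FilenameError",
    "parse_image_filename",
    "format_image_filename",
    "solar_elevation",
]


class FilenameError(ValueError):
    """Raised when an image filename does not follow the naming convention."""


_FILENAME_RE = re.compile(
    r"^(?P<site>.+)_(?P<year>\d{4})_(?P<month>\d{2})_(?P<day>\d{2})"
    r"_(?P<hms>\d{6})\.jpg$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class ImageTimestamp:
    """Sitename plus local-standard-time instant parsed from a filename."""

    sitename: str
    date: _dt.date
    local_std_time: _dt.time

    @property
    def doy(self) -> int:
        """1-based day of year (1..366)."""
        return self.date.timetuple().tm_yday

    @property
    def datetime(self) -> _dt.datetime:
        return _dt.datetime.combine(self.date, self.local_std_time)


@dataclass(frozen=True)
class SiteLocation:
    """Camera location; ``utc_offset`` is hours from UTC to local standard time.

    Longitude is in decimal degrees, negative west of the prime meridian
    (e.g. a New England site is near lon=-72, utc_offset=-5).
    """

    lat: float
    lon: float
    elevation: float = 0.0
    utc_offset: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")


def parse_image_filename(name: str) -> ImageTimestamp:
    """Parse ``<sitename>_<YYYY_MM_DD>_<hhmmss>.jpg`` into a timestamp.

    The sitename is everything before the final ``_YYYY_MM_DD_hhmmss``
    suffix, so sitenames containing digits (e.g. ``howland1``) are fine.

    Raises
    ------
    FilenameError
        If the name does not match the convention or encodes an invalid
        calendar date or time; the message names the offending token.
    """
    m = _FILENAME_RE.match(name)
    if m is None:
        raise FilenameError(
            f"filename {name!r} does not match <sitename>_<YYYY_MM_DD>_<hhmmss>.jpg"
        )
    try:
        date = _dt.date(int(m["year"]), int(m["month"]), int(m["day"]))
    except ValueError as exc:
        raise FilenameError(
            f"invalid date token {m['year']}_{m['month']}_{m['day']} in {name!r}: {exc}"
        ) from None
    hms = m["hms"]
    try:
        time = _dt.time(int(hms[0:2]), int(hms[2:4]), int(hms[4:6]))
    except ValueError as exc:
        raise FilenameError(f"invalid time token {hms!r} in {name!r}: {exc}") from None
    return ImageTimestamp(sitename=m["site"], date=date, local_std_time=time)


def format_image_filename(ts: ImageTimestamp) -> str:
    """Inverse of :func:`parse_image_filename` (exact round-trip)."""
    return (
        f"{ts.sitename}_{ts.date.year:04d}_{ts.date.month:02d}_{ts.date.day:02d}"
        f"_{ts.local_std_time.hour:02d}{ts.local_std_time.minute:02d}"
        f"{ts.local_std_time.second:02d}.jpg"
    )


def _declination_eqtime(ts: ImageTimestamp, utc_offset: float) -> tuple[float, float]:
    """Solar declination (radians) and equation of time (minutes).

    NOAA solar-calculator series (Meeus): geometric mean longitude and
    anomaly -> equation of centre -> apparent longitude and obliquity
    -> declination; the equation of time from the same elements.
    """
    t = ts.local_std_time
    day_frac = (t.hour + t.minute / 60.0 + t.second / 3600.0 - utc_offset) / 24.0
    jd = ts.date.toordinal() + 1721424.5 + day_frac
    T = (jd - 2451545.0) / 36525.0

    L0 = math.radians((280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0)
    M = math.radians(357.52911 + T * (35999.05029 - 0.0001537 * T))
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    C = (
        (1.914602 - T * (0.004817 + 0.000014 * T)) * math.sin(M)
        + (0.019993 - 0.000101 * T) * math.sin(2 * M)
        + 0.000289 * math.sin(3 * M)
    )
    true_long = math.degrees(L0) + C
    omega = math.radians(125.04 - 1934.136 * T)
    app_long = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - 0.001813 * T))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))

    decl = math.asin(math.sin(eps) * math.sin(app_long))
    y = math.tan(eps / 2.0) ** 2
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * L0)
        - 2.0 * e * math.sin(M)
        + 4.0 * e * y * math.sin(M) * math.cos(2 * L0)
        - 0.5 * y * y * math.sin(4 * L0)
        - 1.25 * e * e * math.sin(2 * M)
    )
    return decl, eqtime


def solar_elevation(loc: SiteLocation, ts: ImageTimestamp) -> float:
    """Solar elevation angle in degrees at the given site and local instant.

    Declination and equation of time feed the hour angle in true solar
    time; elevation follows from the spherical triangle.  No refraction
    correction is applied (the quality filter threshold downstream is
    far coarser than refraction's ~0.5 degrees at the horizon).
    """
    decl, eqtime = _declination_eqtime(ts, loc.utc_offset)
    t = ts.local_std_time
    minutes = t.hour * 60.0 + t.minute + t.second / 60.0
    # loc.lon positive east, utc_offset hours ahead of UTC
    true_solar_minutes = minutes + eqtime + 4.0 * loc.lon - 60.0 * loc.utc_offset
    hour_angle = math.radians(true_solar_minutes / 4.0 - 180.0)

    lat = math.radians(loc.lat)
    cos_zenith = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(
        decl
    ) * math.cos(hour_angle)
    cos_zenith = min(1.0, max(-1.0, cos_zenith))
    return 90.0 - math.degrees(math.acos(cos_zenith))
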