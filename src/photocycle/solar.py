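"""Solar geometry: declination, day length, and equinox strata.

Day length is operationalized as the time elapsed between sunrise and
sunset at a geographic point, computed from the sunrise hour-angle
equation ``cos w0 = (sin(-0.833 deg) - sin(phi) sin(delta)) / (cos(phi)
cos(delta))`` where ``phi`` is latitude and ``delta`` the solar
declination.  The -0.833 deg zenith offset is the conventional
correction for atmospheric refraction plus the apparent solar radius.
Poleward of the polar circles the equation has no solution and day
length clamps to 0 or 1440 minutes.  Day length is timezone-free, so
longitude does not enter the computation; it is carried on
:class:`GeoPoint` for schema completeness.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeoPoint",
    "solar_declination",
    "day_length_minutes",
    "equinox_stratum",
    "SPRING_EQUINOX_DOY",
    "AUTUMN_EQUINOX_DOY",
]

#: Zenith offset (degrees below horizontal) for refraction + solar disk.
REFRACTION_OFFSET_DEG = -0.833

#: Approximate day-of-year of the March and September equinoxes.
SPRING_EQUINOX_DOY = 79
AUTUMN_EQUINOX_DOY = 266


@dataclass(frozen=True)
class GeoPoint:
    """A geographic location; latitude positive north, longitude positive east."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not abs(self.latitude) <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not (-180.0 < self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} outside (-180, 180]")


def solar_declination(day_of_year):
    """Solar declination (degrees) for a day of year, 1..366.

    Uses the Spencer Fourier-series approximation in the fractional
    year, accurate to roughly 0.01 rad; the result satisfies
    ``|delta| <= 23.45`` degrees.  Accepts scalars or arrays.
    """
    doy = np.asarray(day_of_year)
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("day_of_year must lie in [1, 366]")
    g = 2.0 * np.pi * (doy - 1) / 365.0
    delta_rad = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.001480 * np.sin(3 * g)
    )
    out = np.degrees(delta_rad)
    return float(out) if np.isscalar(day_of_year) else out


def _doy(date) -> int:
    if isinstance(date, (_dt.datetime, _dt.date)):
        return date.timetuple().tm_yday
    raise TypeError(f"expected a date, got {type(date).__name__}")


def day_length_minutes_from_doy(
    latitude, day_of_year, zenith_offset_deg: float = REFRACTION_OFFSET_DEG
):
    """Vectorized day length (minutes) from latitude (deg) and day of year.

    ``zenith_offset_deg`` is the documented horizon correction: the
    default -0.833 deg accounts for refraction plus the solar disk and
    lengthens the day (by ~7 min at mid latitude, more toward the
    poles); 0 gives the geometric (center-of-sun, no-atmosphere) day
    length, exactly 12 h when the declination is zero.
    """
    lat = np.radians(np.asarray(latitude, dtype=float))
    delta = np.radians(solar_declination(np.asarray(day_of_year)))
    z = np.radians(zenith_offset_deg)
    cos_w0 = (np.sin(z) - np.sin(lat) * np.sin(delta)) / (
        np.cos(lat) * np.cos(delta)
    )
    # |cos w0| > 1: polar day (argument < -1) or polar night (> 1); clamp.
    cos_w0 = np.clip(cos_w0, -1.0, 1.0)
    w0 = np.degrees(np.arccos(cos_w0))
    minutes = 2.0 * w0 * 4.0  # 1 degree of hour angle = 4 minutes
    return minutes


def day_length_minutes(
    geo: GeoPoint, date, zenith_offset_deg: float = REFRACTION_OFFSET_DEG
) -> float:
    """Sunrise-to-sunset duration in minutes at ``geo`` on ``date``.

    Result lies in [0, 1440]; polar day/night clamp rather than fail.
    """
    return float(
        day_length_minutes_from_doy(geo.latitude, _doy(date), zenith_offset_deg)
    )


def equinox_stratum(day_length: float, twelve_hour_tol: float = 5.0) -> str:
    """Assign a day length (minutes) to an equinox stratum.

    ``twelve_hour`` when within ``twelve_hour_tol`` minutes of exactly
    12 h; ``near_equinox`` for the 11-13 h band outside that tolerance;
    ``other`` otherwise.
    """
    if day_length < 0:
        raise ValueError(f"day length must be non-negative, got {day_length}")
    if abs(day_length - 720.0) <= twelve_hour_tol:
        return "twelve_hour"
    if 660.0 <= day_length <= 780.0:
        return "near_equinox"
    return "other"
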