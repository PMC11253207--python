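"""Solar position and biological-night computation.

Sunset and sunrise are computed with the NOAA solar calculator algorithm
(the Meeus-based formulation used in the NOAA spreadsheet), at the standard
refraction-corrected zenith of 90.833 degrees, i.e. solar elevation
-0.833 deg at the moment the upper limb of the disk touches the horizon.

All timestamps are UTC.  Polar latitudes (|lat| >= 66 deg), where the sun
may not cross the horizon at all, are rejected explicitly: the study region
(the Levant) never needs them.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

__all__ = ["NightWindow", "solar_night", "sunset_sunrise", "solar_noon_utc"]

#: Zenith angle (degrees) of the refraction-corrected solar disk edge.
SUNRISE_SUNSET_ZENITH = 90.833

#: Latitude beyond which polar day/night can occur; unsupported.
POLAR_LATITUDE = 66.0


@dataclass(frozen=True)
class NightWindow:
    """One biological night at a site: sunset of the evening date to the
    following sunrise."""

    site_id: str
    night_id: dt.date  # calendar date of the evening, site-local
    sunset: dt.datetime  # UTC
    sunrise: dt.datetime  # UTC

    @property
    def duration_h(self) -> float:
        return (self.sunrise - self.sunset).total_seconds() / 3600.0

    def contains(self, when: dt.datetime) -> bool:
        """Closed interval [sunset, sunrise]."""
        return self.sunset <= when <= self.sunrise


def _julian_day(date: dt.date) -> float:
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_geometry(jc: float) -> tuple[float, float]:
    """Return (equation of time in minutes, solar declination in degrees)
    for a Julian-century epoch ``jc`` since J2000."""
    gml = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    gma_r = math.radians(gma)
    ceq = (
        math.sin(gma_r) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * gma_r) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * gma_r) * 0.000289
    )
    true_long = gml + ceq
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(omega))
    obliq_r = math.radians(obliq)
    decl = math.degrees(math.asin(math.sin(obliq_r) * math.sin(math.radians(app_long))))

    var_y = math.tan(obliq_r / 2.0) ** 2
    gml_r = math.radians(gml)
    eqtime = 4.0 * math.degrees(
        var_y * math.sin(2 * gml_r)
        - 2 * ecc * math.sin(gma_r)
        + 4 * ecc * var_y * math.sin(gma_r) * math.cos(2 * gml_r)
        - 0.5 * var_y * var_y * math.sin(4 * gml_r)
        - 1.25 * ecc * ecc * math.sin(2 * gma_r)
    )
    return eqtime, decl


def _hour_angle_deg(lat: float, decl: float, zenith: float) -> float:
    lat_r, decl_r = math.radians(lat), math.radians(decl)
    cos_ha = (
        math.cos(math.radians(zenith)) - math.sin(lat_r) * math.sin(decl_r)
    ) / (math.cos(lat_r) * math.cos(decl_r))
    if not -1.0 <= cos_ha <= 1.0:  # sun never rises/sets on this date
        raise ValueError(
            f"sun does not cross zenith {zenith} deg at latitude {lat}: polar day or night"
        )
    return math.degrees(math.acos(cos_ha))


def _event_minutes_utc(date: dt.date, lat: float, lon: float, rising: bool) -> float:
    """Minutes past UTC midnight of sunrise/sunset, iterated once for the
    sub-minute drift of declination over the day."""
    jd = _julian_day(date)
    minutes = 720.0 - 4.0 * lon  # first guess: solar noon
    for _ in range(2):
        jc = (jd + minutes / 1440.0 - 2451545.0) / 36525.0
        eqtime, decl = _solar_geometry(jc)
        ha = _hour_angle_deg(lat, decl, SUNRISE_SUNSET_ZENITH)
        if rising:
            minutes = 720.0 - 4.0 * (lon + ha) - eqtime
        else:
            minutes = 720.0 - 4.0 * (lon - ha) - eqtime
    return minutes


def _minutes_to_dt(date: dt.date, minutes: float) -> dt.datetime:
    base = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    return base + dt.timedelta(minutes=minutes)


def solar_noon_utc(date: dt.date, lon: float) -> dt.datetime:
    jc = (_julian_day(date) + 0.5 - 2451545.0) / 36525.0
    eqtime, _ = _solar_geometry(jc)
    return _minutes_to_dt(date, 720.0 - 4.0 * lon - eqtime)


def sunset_sunrise(lat: float, lon: float, date: dt.date) -> tuple[dt.datetime, dt.datetime]:
    """Sunset on the local calendar ``date`` and sunrise of the following
    morning, both UTC."""
    if abs(lat) >= POLAR_LATITUDE:
        raise ValueError(
            f"latitude {lat} is inside the polar-circle band (|lat| >= {POLAR_LATITUDE}); "
            "polar day/night handling is unsupported"
        )
    sunset = _minutes_to_dt(date, _event_minutes_utc(date, lat, lon, rising=False))
    next_day = date + dt.timedelta(days=1)
    sunrise = _minutes_to_dt(next_day, _event_minutes_utc(next_day, lat, lon, rising=True))
    # At eastern longitudes the UTC clock time of local events shifts earlier;
    # the pair above is always ordered for |lat| < 66.
    assert sunrise > sunset
    return sunset, sunrise


def solar_night(lat: float, lon: float, date: dt.date, site_id: str = "") -> NightWindow:
    """The biological night that starts on the evening of local ``date``.

    ``date`` is interpreted as the site-local calendar date (local time taken
    as the longitude-based mean solar offset, lon/15 hours), so a night is
    keyed to the evening on which it begins even though it spans two UTC
    dates.
    """
    sunset, sunrise = sunset_sunrise(lat, lon, date)
    return NightWindow(site_id=site_id, night_id=date, sunset=sunset, sunrise=sunrise)
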