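"""Sunrise/sunset and solar-phase classification.

Implements the NOAA low-precision solar position algorithm (fractional-year
Fourier series for declination and the equation of time). Sunrise/sunset are
defined at solar elevation -0.833 deg (refraction + solar radius), accurate
to a minute or two — ample for hour-scale phase classification.

Phases: ``day`` between sunrise and sunset, ``night`` otherwise, and
``dawn_dusk`` within one hour of either event. Polar day/night collapse to
``day``/``night`` with 24 h / 0 h of daylight.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

ZENITH_OFFICIAL = 90.833  # degrees

DAY = "day"
NIGHT = "night"
DAWN_DUSK = "dawn_dusk"


def _fractional_year(ts: dt.datetime) -> float:
    doy = ts.timetuple().tm_yday
    return 2.0 * np.pi / 365.0 * (doy - 1 + (ts.hour - 12) / 24.0)


def _eqtime_decl(gamma: float):
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(gamma) - 0.032077 * np.sin(gamma)
                       - 0.014615 * np.cos(2 * gamma) - 0.040849 * np.sin(2 * gamma))
    decl = (0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
            - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
            - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma))
    return eqtime, decl


def sun_elevation_deg(lon: float, lat: float, ts: dt.datetime) -> float:
    """Solar elevation angle (degrees) at a UTC instant."""
    gamma = _fractional_year(ts)
    eqtime, decl = _eqtime_decl(gamma)
    minutes = ts.hour * 60 + ts.minute + ts.second / 60.0
    tst = minutes + eqtime + 4.0 * lon  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)  # hour angle
    phi = np.radians(lat)
    cos_zen = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    return 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))


def sunrise_sunset_utc(lon: float, lat: float, date: dt.date):
    """(sunrise, sunset) as UTC datetimes for a calendar date, or None for polar day/night.

    Returns ``(None, None, is_polar_day)`` style tuple:
    ``(sunrise, sunset)`` where both are ``None`` under polar conditions;
    use :func:`daylight_hours` for the 24/0 convention.
    """
    noonish = dt.datetime(date.year, date.month, date.day, 12, tzinfo=dt.timezone.utc)
    gamma = _fractional_year(noonish)
    eqtime, decl = _eqtime_decl(gamma)
    phi = np.radians(lat)
    cos_ha = (np.cos(np.radians(ZENITH_OFFICIAL)) / (np.cos(phi) * np.cos(decl))
              - np.tan(phi) * np.tan(decl))
    if cos_ha > 1.0 or cos_ha < -1.0:  # polar night / polar day
        return None, None
    ha_deg = np.degrees(np.arccos(cos_ha))
    sunrise_min = 720.0 - 4.0 * (lon + ha_deg) - eqtime
    sunset_min = 720.0 - 4.0 * (lon - ha_deg) - eqtime
    base = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    return (base + dt.timedelta(minutes=float(sunrise_min)),
            base + dt.timedelta(minutes=float(sunset_min)))


def daylight_hours(lon: float, lat: float, date: dt.date):
    """(daylight_h, dark_h) for a date; (24, 0) under polar day, (0, 24) polar night."""
    sr, ss = sunrise_sunset_utc(lon, lat, date)
    if sr is None:
        noonish = dt.datetime(date.year, date.month, date.day, 12, tzinfo=dt.timezone.utc)
        elev = sun_elevation_deg(lon, lat, noonish)
        return (24.0, 0.0) if elev > 0 else (0.0, 24.0)
    h = (ss - sr).total_seconds() / 3600.0
    return h, 24.0 - h


def solar_phase(lon: float, lat: float, ts: dt.datetime) -> str:
    """Classify a UTC instant as day / night / dawn_dusk at a location.

    dawn_dusk = within one hour of the local sunrise or sunset.
    """
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=dt.timezone.utc)
    sr, ss = sunrise_sunset_utc(lon, lat, ts.date())
    if sr is None:  # polar: no events, forced phase
        return DAY if sun_elevation_deg(lon, lat, ts) > 0 else NIGHT
    one_h = dt.timedelta(hours=1)
    if abs(ts - sr) <= one_h or abs(ts - ss) <= one_h:
        return DAWN_DUSK
    # events on adjacent dates can also be within the hour (near-midnight fixes)
    for shift in (-1, 1):
        d2 = ts.date() + dt.timedelta(days=shift)
        sr2, ss2 = sunrise_sunset_utc(lon, lat, d2)
        if sr2 is not None and (abs(ts - sr2) <= one_h or abs(ts - ss2) <= one_h):
            return DAWN_DUSK
    return DAY if sr <= ts <= ss else NIGHT


def is_daylight(lon: float, lat: float, ts: dt.datetime) -> bool:
    """True if the sun is above the horizon (used to apportion dawn_dusk flight)."""
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=dt.timezone.utc)
    return sun_elevation_deg(lon, lat, ts) > -0.833
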