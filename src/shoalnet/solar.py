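"""Solar geometry for day/night classification.

Implements the standard NOAA solar-position equations (low-precision
ephemeris, good to well under 0.1 degree over the relevant decades),
vectorised over numpy datetime64 arrays.  The day/night boundary is solar
elevation 0 degrees at the site, with no twilight band and no refraction
correction, so the sunrise/sunset times returned here are exactly the
zero-crossings of the elevation used to classify bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_J2000 = np.datetime64("2000-01-01T12:00:00")


def _julian_century(times: np.ndarray) -> np.ndarray:
    days = (times - _J2000) / np.timedelta64(1, "s") / 86400.0
    return days / 36525.0


def _sun_geometry(T: np.ndarray):
    """Declination (rad) and equation of time (minutes) at Julian century T."""
    L0 = np.mod(280.46646 + T * (36000.76983 + 0.0003032 * T), 360.0)
    M = np.deg2rad(357.52911 + T * (35999.05029 - 0.0001537 * T))
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    C = (
        np.sin(M) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * M) * (0.019993 - 0.000101 * T)
        + np.sin(3 * M) * 0.000289
    )
    true_long = L0 + C
    omega = np.deg2rad(125.04 - 1934.136 * T)
    lam = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - 0.001813 * T))) / 60.0) / 60.0
    eps = np.deg2rad(eps0 + 0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(eps) * np.sin(lam))
    y = np.tan(eps / 2.0) ** 2
    L0r = np.deg2rad(L0)
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * L0r)
        - 2.0 * e * np.sin(M)
        + 4.0 * e * y * np.sin(M) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * e * e * np.sin(2 * M)
    )
    return decl, eot


def solar_elevation(times_utc, lat: float, lon: float) -> np.ndarray:
    """Solar elevation angle in degrees at UTC instants ``times_utc``.

    ``times_utc`` may be a DatetimeIndex or datetime64 array (naive values
    are taken as UTC).  East longitude positive.
    """
    times = np.asarray(pd.DatetimeIndex(times_utc).tz_localize(None).values, "datetime64[s]")
    T = _julian_century(times)
    decl, eot = _sun_geometry(T)
    minutes_utc = (
        (times - times.astype("datetime64[D]").astype("datetime64[s]"))
        / np.timedelta64(1, "s")
        / 60.0
    )
    tst = np.mod(minutes_utc + eot + 4.0 * lon, 1440.0)
    hour_angle = np.deg2rad(tst / 4.0 - 180.0)
    phi = np.deg2rad(lat)
    sin_elev = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(hour_angle)
    return np.rad2deg(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))


def sun_events(dates, lat: float, lon: float) -> pd.DataFrame:
    """Sunrise and sunset (UTC) for each civil date.

    Uses the elevation-0 hour angle cos H = -tan(phi) tan(delta), evaluated
    with the sun geometry at local solar noon.  Raises for latitudes where
    the sun does not cross the horizon.
    """
    if abs(lat) > 66.6:
        raise ValueError("polar day/night unsupported beyond |lat| = 66.6 deg")
    dates = pd.DatetimeIndex(dates).normalize().tz_localize(None)
    noon_guess = dates.values.astype("datetime64[s]") + np.timedelta64(12 * 3600, "s")
    T = _julian_century(noon_guess)
    decl, eot = _sun_geometry(T)
    solar_noon_min = 720.0 - 4.0 * lon - eot
    phi = np.deg2rad(lat)
    cos_ha = -np.tan(phi) * np.tan(decl)
    if np.any(np.abs(cos_ha) > 1.0):
        raise ValueError("sun does not cross the horizon on some requested dates")
    ha_min = 4.0 * np.rad2deg(np.arccos(cos_ha))
    day0 = dates.values.astype("datetime64[s]")
    sunrise = day0 + ((solar_noon_min - ha_min) * 60).astype("timedelta64[s]")
    sunset = day0 + ((solar_noon_min + ha_min) * 60).astype("timedelta64[s]")
    return pd.DataFrame({"date": dates, "sunrise": sunrise, "sunset": sunset})
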