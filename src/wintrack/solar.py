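"""Sunrise/sunset and day/night classification.

Implements the NOAA solar-position equations (the algorithm behind the
NOAA solar calculator): Julian-century polynomial series for the sun's
geometric mean longitude/anomaly, equation of center, apparent
longitude, corrected obliquity, declination and equation of time, with
sunrise/sunset at a zenith of 90.833 degrees (accounts for refraction
and the solar disc).  Accuracy is well within the package's +-5 minute
contract for mid-latitudes.

Longitudes are degrees east (west Colorado is about -106); timestamps
are UTC throughout.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

_ZENITH = 90.833  # degrees; official sunrise/sunset


def _julian_day(date: _dt.date) -> float:
    ts = pd.Timestamp(date)
    return ts.to_julian_date() + 0.5  # midnight UTC of `date`


def _sun_geometry(jc: float):
    """Declination (deg) and equation of time (min) at Julian century jc."""
    l0 = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = np.radians(m)
    c = (
        np.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * mr) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = np.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(omega)
    decl = np.degrees(
        np.arcsin(np.sin(np.radians(obliq)) * np.sin(np.radians(app_long)))
    )
    y = np.tan(np.radians(obliq) / 2.0) ** 2
    l0r = np.radians(l0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2.0 * e * np.sin(mr)
        + 4.0 * e * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * e * e * np.sin(2 * mr)
    )
    return decl, eot


def _events_minutes(date: _dt.date, lat: float, lon: float) -> tuple[float, float]:
    """Sunrise and sunset as minutes after UTC midnight of `date`."""
    jd = _julian_day(date)
    noon_guess = 720.0 - 4.0 * lon
    rise, sett = noon_guess, noon_guess
    for target in (0, 1):  # 0 = sunrise, 1 = sunset
        minutes = noon_guess
        for _ in range(2):  # one refinement pass on the event time
            jc = (jd + minutes / 1440.0 - 2451545.0) / 36525.0
            decl, eot = _sun_geometry(jc)
            cos_ha = (
                np.cos(np.radians(_ZENITH))
                / (np.cos(np.radians(lat)) * np.cos(np.radians(decl)))
                - np.tan(np.radians(lat)) * np.tan(np.radians(decl))
            )
            if cos_ha < -1.0 or cos_ha > 1.0:
                raise ValueError(
                    f"polar day/night at lat={lat} on {date}: no sunrise/sunset"
                )
            ha = np.degrees(np.arccos(cos_ha))
            noon = 720.0 - 4.0 * lon - eot
            minutes = noon + 4.0 * ha if target else noon - 4.0 * ha
        if target:
            sett = minutes
        else:
            rise = minutes
    return rise, sett


def sunrise_sunset(
    date: _dt.date, lat: float, lon: float
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """UTC sunrise and sunset timestamps for a calendar date at (lat, lon)."""
    rise, sett = _events_minutes(date, lat, lon)
    base = pd.Timestamp(date, tz="UTC")
    return base + pd.Timedelta(minutes=rise), base + pd.Timedelta(minutes=sett)


def solar_period(timestamps, lat: float, lon: float) -> np.ndarray:
    """'day' or 'night' for each timestamp.

    Day is the half-open interval [sunrise, sunset) of the timestamp's
    own UTC date.  Note the UTC date's sunrise/sunset pair brackets
    local daylight correctly for longitudes where local solar noon falls
    within the same UTC day (true for the Americas and Europe).
    """
    ts = pd.DatetimeIndex(timestamps)
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    out = np.empty(len(ts), dtype=object)
    dates = ts.normalize()
    for d in pd.unique(dates):
        mask = dates == d
        rise, sett = sunrise_sunset(pd.Timestamp(d).date(), lat, lon)
        sub = ts[mask]
        out[np.flatnonzero(mask)] = np.where(
            (sub >= rise) & (sub < sett), "day", "night"
        )
    return out.astype(str)


def period_key(timestamps, lat: float, lon: float) -> pd.DataFrame:
    """Assign each timestamp a (date, period) key.

    A day period is keyed to its own date; a night period spans sunset
    to the next sunrise and is keyed to the date it starts on (times
    before sunrise belong to the previous date's night).
    """
    ts = pd.DatetimeIndex(timestamps)
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    period = solar_period(ts, lat, lon)
    key_date = ts.normalize()
    # pre-dawn fixes belong to the night that started the previous day
    rises = {}
    for d in pd.unique(key_date):
        rises[d] = sunrise_sunset(pd.Timestamp(d).date(), lat, lon)[0]
    before_dawn = np.array([t < rises[d] for t, d in zip(ts, key_date)])
    adj = key_date.where(~((period == "night") & before_dawn), key_date - pd.Timedelta(days=1))
    return pd.DataFrame({"date": adj.date, "period": period}, index=range(len(ts)))
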