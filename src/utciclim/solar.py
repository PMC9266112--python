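"""Astronomical solar geometry: extraterrestrial radiation and day length.

Both quantities follow the FAO-56 daily formulation (Allen et al., 1998):
solar declination and inverse relative Earth-Sun distance from the day of
year, sunset hour angle from latitude and declination, and the analytic
integral of the solar flux over the daylight period.  Extraterrestrial
radiation is returned as a daily-mean flux density in W/m^2 (the FAO value
in MJ m^-2 day^-1 divided by 0.0864), the unit used for all radiation
quantities in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: FAO-56 solar constant, MJ m^-2 min^-1.
SOLAR_CONSTANT = 0.0820

#: MJ m^-2 day^-1 per W m^-2 (86400 s/day * 1e-6).
MJ_PER_DAY_TO_W = 0.0864


@dataclass(frozen=True)
class SolarGeometry:
    """Daily solar geometry for one station-day.

    Attributes
    ----------
    Re : float
        Daily-mean extraterrestrial radiation, W/m^2 (>= 0).
    S0 : float
        Potential sunshine hours (astronomical day length), in [0, 24].
    """

    Re: float
    S0: float


def _check_inputs(latitude, day_of_year):
    lat = np.asarray(latitude, dtype=float)
    doy = np.asarray(day_of_year)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError(f"latitude out of range [-90, 90]: {latitude!r}")
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError(f"day_of_year out of range [1, 366]: {day_of_year!r}")
    return lat, np.asarray(doy, dtype=float)


def solar_declination(day_of_year):
    """Solar declination (radians), FAO-56 Eq. 24."""
    doy = np.asarray(day_of_year, dtype=float)
    return 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)


def sunset_hour_angle(latitude, day_of_year):
    """Sunset hour angle (radians), clipped for polar day/night."""
    lat, doy = _check_inputs(latitude, day_of_year)
    phi = np.radians(lat)
    delta = solar_declination(doy)
    # |arg| > 1 means the sun never rises (polar night) or never sets
    # (polar day); clipping yields ws = pi or 0 accordingly.
    arg = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    return np.arccos(arg)


def extraterrestrial_radiation(latitude, day_of_year):
    """Daily-mean extraterrestrial radiation (W/m^2), FAO-56 Eq. 21.

    Parameters
    ----------
    latitude : float or array
        Geographic latitude in degrees, in [-90, 90].
    day_of_year : int or array
        Day of year, 1..366.
    """
    lat, doy = _check_inputs(latitude, day_of_year)
    phi = np.radians(lat)
    delta = solar_declination(doy)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    ws = sunset_hour_angle(lat, doy)
    ra_mj = (
        24.0 * 60.0 / np.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    ra = np.maximum(ra_mj, 0.0) / MJ_PER_DAY_TO_W
    return float(ra) if ra.ndim == 0 else ra


def day_length(latitude, day_of_year):
    """Astronomical day length in hours (FAO-56 Eq. 34), in [0, 24]."""
    ws = sunset_hour_angle(latitude, day_of_year)
    s0 = 24.0 / np.pi * ws
    s0 = np.asarray(s0)
    return float(s0) if s0.ndim == 0 else s0


def noon_solar_elevation(latitude, day_of_year):
    """Solar elevation angle at local solar noon (degrees, clipped at 0).

    Used as the representative elevation when converting a daily-mean
    global flux into the short-wave load on a person.
    """
    lat, doy = _check_inputs(latitude, day_of_year)
    phi = np.radians(lat)
    delta = solar_declination(doy)
    sin_elev = np.clip(np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta),
                       -1.0, 1.0)
    elev = np.degrees(np.arcsin(sin_elev))
    elev = np.maximum(elev, 0.0)
    return float(elev) if elev.ndim == 0 else elev


def geometry(latitude, day_of_year) -> SolarGeometry:
    """Bundle Re and S0 for one station-day."""
    return SolarGeometry(
        Re=float(extraterrestrial_radiation(latitude, day_of_year)),
        S0=float(day_length(latitude, day_of_year)),
    )


def geometry_table(latitude, dates):
    """Vectorised Re and S0 for a DatetimeIndex-like sequence of dates.

    Returns ``(Re, S0)`` arrays aligned with ``dates``.
    """
    import pandas as pd

    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy()
    return extraterrestrial_radiation(latitude, doy), day_length(latitude, doy)
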