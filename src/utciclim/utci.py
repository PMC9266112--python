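"""Daily UTCI engine: radiant fluxes, mean radiant temperature, the
operational polynomial, and thermal-stress classification.

The Universal Thermal Climate Index is the air temperature of a reference
environment (calm wind, Tmrt = Ta, 50% relative humidity) that would evoke
the same dynamic physiological strain as the actual environment.  The full
multi-node thermoregulation model is far too expensive for climatological
scans, so the operational procedure approximates the offset ``UTCI - Ta``
with a sixth-order polynomial in air temperature, wind speed, vapour
pressure and the radiant excess ``Tmrt - Ta``; that polynomial (210
published constants) is what this module evaluates.

Mean radiant temperature is obtained from a daily radiant budget: the
short-wave flux absorbed by an unclothed reference person (``Rp``), the
long-wave flux emitted by the ground (``Lg``) and the long-wave flux from
the atmosphere (``La``), inverted through the Stefan-Boltzmann law with an
emissivity of 0.95 for the human body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utci_coefficients import COEFFICIENTS, exponents
from ._utci_coefficients import checksum as coefficients_checksum  # noqa: F401

__all__ = [
    "CategoryScheme",
    "RadiantState",
    "UtciDay",
    "DEFAULT_SCHEME",
    "wind_speed",
    "vapor_pressure_from_dewpoint",
    "longwave_fluxes",
    "mean_radiant_temperature",
    "projected_area_factor",
    "rp_from_global",
    "utci",
    "utci_polynomial",
    "classify",
    "aggregate_category_days",
]

# Human-body emissivity and Stefan-Boltzmann constant of the Tmrt inversion.
_BODY_EMISSIVITY = 0.95
_SIGMA = 5.667e-8

# Validity box of the operational polynomial.
WIND_MIN, WIND_MAX = 0.5, 17.0
TA_MIN, TA_MAX = -50.0, 50.0
DMRT_MIN, DMRT_MAX = -30.0, 70.0

#: hPa per kPa: the engine's vapour-pressure unit is hPa, the polynomial's kPa.
_HPA_PER_KPA = 10.0


@dataclass(frozen=True)
class RadiantState:
    """Radiant budget of one station-day (all fluxes in W/m^2)."""

    Rp: float
    Lg: float
    La: float
    Tmrt: float


@dataclass(frozen=True)
class UtciDay:
    """Daily UTCI value with its stress category and quality flags."""

    date: object
    utci: float
    category: int
    flags: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered thermal-stress intervals covering the whole real line.

    ``bounds`` are the inner breakpoints in increasing order; interval ``m``
    is ``[bounds[m-1], bounds[m])`` (half-open, closed below).  ``labels``
    run from the coldest to the hottest interval.  Category numbers follow
    the convention that category 1 is the hottest, so with 10 intervals the
    coldest is category 10.
    """

    bounds: tuple = (-40.0, -27.0, -13.0, 0.0, 9.0, 26.0, 32.0, 38.0, 46.0)
    labels: tuple = (
        "extreme cold stress",
        "very strong cold stress",
        "strong cold stress",
        "moderate cold stress",
        "slight cold stress",
        "no thermal stress",
        "moderate heat stress",
        "strong heat stress",
        "very strong heat stress",
        "extreme heat stress",
    )

    def __post_init__(self):
        if len(self.labels) != len(self.bounds) + 1:
            raise ValueError("labels must have one more entry than bounds")
        if any(b2 <= b1 for b1, b2 in zip(self.bounds, self.bounds[1:])):
            raise ValueError("bounds must be strictly increasing")

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    def label(self, category: int) -> str:
        return self.labels[self.n_categories - category]


DEFAULT_SCHEME = CategoryScheme()


def wind_speed(Vu, Vv):
    """Scalar wind speed (m/s) from meridional/zonal components."""
    return np.hypot(np.asarray(Vu, dtype=float), np.asarray(Vv, dtype=float))


def vapor_pressure_from_dewpoint(Td):
    """Water-vapour pressure e (hPa) from dew-point temperature (degC).

    Magnus-type integration of Clausius-Clapeyron anchored at the triple
    point: ``e = 6.11 exp[5417.753 (1/273.16 - 1/(273.16 + Td))]``, which
    returns exactly 6.11 hPa at Td = 0 degC.
    """
    td = np.asarray(Td, dtype=float)
    if not np.all(np.isfinite(td)):
        raise ValueError("dew-point temperature must be finite")
    e = 6.11 * np.exp(5417.753 * (1.0 / 273.16 - 1.0 / (273.16 + td)))
    return float(e) if e.ndim == 0 else e


def longwave_fluxes(Tg, Ta, e):
    """Ground and atmospheric long-wave fluxes (W/m^2).

    ``Lg`` is grey-body emission of the ground surface at temperature Tg;
    ``La`` is atmospheric emission at air temperature with an empirical
    clear-sky emissivity that grows with vapour pressure e (hPa) and
    saturates at 0.82.
    """
    tg = np.asarray(Tg, dtype=float)
    ta = np.asarray(Ta, dtype=float)
    ehpa = np.asarray(e, dtype=float)
    lg = 5.5e-8 * (273.0 + tg) ** 4
    la = 5.5e-8 * (273.0 + ta) ** 4 * (0.82 - 0.25 * 10.0 ** (-0.094 * ehpa))
    if lg.ndim == 0:
        return float(lg), float(la)
    return lg, la


def mean_radiant_temperature(Rp, Lg, La):
    """Mean radiant temperature (degC) from the daily radiant budget.

    Inverts Stefan-Boltzmann for a person absorbing the full short-wave
    flux Rp plus half of each long-wave stream (upper/lower hemisphere):
    ``Tmrt = [(Rp + 0.5 Lg + 0.5 La) / (0.95 sigma)]^(1/4) - 273``.
    """
    rp = np.asarray(Rp, dtype=float)
    if np.any(rp < 0):
        raise ValueError("absorbed short-wave flux Rp must be >= 0")
    radicand = (rp + 0.5 * np.asarray(Lg, float) + 0.5 * np.asarray(La, float)) / (
        _BODY_EMISSIVITY * _SIGMA
    )
    tmrt = radicand**0.25 - 273.0
    return float(tmrt) if tmrt.ndim == 0 else tmrt


def projected_area_factor(solar_elevation):
    """Fraction of body surface projected toward the sun (standing person).

    Empirical fit used in operational radiant-load models; peaks near 0.31
    at grazing sun and falls toward ~0.21 overhead.  Elevation in degrees.
    """
    gamma = np.asarray(solar_elevation, dtype=float)
    return 0.308 * np.cos(np.radians(gamma * (0.998 - gamma**2 / 50000.0)))


def rp_from_global(Rg, solar_elevation, absorption_coeff=0.7, area_factor=None):
    """Short-wave flux absorbed by the reference person (W/m^2).

    Default model: ``Rp = alpha * fp(elevation) * Rg`` with short-wave
    absorption coefficient ``alpha`` (default 0.7) and the standing-person
    projected-area factor ``fp``.  Any callable ``area_factor(elevation)``
    may be plugged in instead of the default.
    """
    rg = np.asarray(Rg, dtype=float)
    if np.any(rg < 0):
        raise ValueError("global radiation must be >= 0")
    fp = (area_factor or projected_area_factor)(solar_elevation)
    rp = absorption_coeff * fp * rg
    return float(rp) if np.ndim(rp) == 0 else rp


_EXPONENTS = np.array(exponents(), dtype=np.int64)
_COEFFS = np.asarray(COEFFICIENTS, dtype=float)


def utci_polynomial(Ta, va, Tmrt, pa_kpa):
    """Raw operational polynomial: UTCI (degC) without clamping or flags.

    Inputs: air temperature (degC), 10-m wind speed (m/s), mean radiant
    temperature (degC) and water-vapour pressure in kPa.
    """
    ta = np.asarray(Ta, dtype=float)
    va_ = np.asarray(va, dtype=float)
    d = np.asarray(Tmrt, dtype=float) - ta
    pa = np.asarray(pa_kpa, dtype=float)
    # powers[v][p] = v**p for p = 0..6, broadcast over input shape
    shape = np.broadcast(ta, va_, d, pa).shape
    vars_ = [np.broadcast_to(x, shape) for x in (ta, va_, d, pa)]
    powers = [np.stack([v**p for p in range(7)]) for v in vars_]
    i, j, k, l = _EXPONENTS.T
    terms = _COEFFS[:, None] * (
        powers[0][i].reshape(len(_COEFFS), -1)
        * powers[1][j].reshape(len(_COEFFS), -1)
        * powers[2][k].reshape(len(_COEFFS), -1)
        * powers[3][l].reshape(len(_COEFFS), -1)
    )
    offset = terms.sum(axis=0).reshape(shape)
    out = np.asarray(ta + offset)
    return float(out) if out.ndim == 0 else out


def utci(Ta, V, e, Tmrt, dates=None, scheme: CategoryScheme = DEFAULT_SCHEME):
    """Daily UTCI with classification and quality flags.

    Parameters
    ----------
    Ta, V, e, Tmrt:
        Air temperature (degC), scalar wind speed (m/s), vapour pressure
        (hPa) and mean radiant temperature (degC); scalars or aligned
        arrays.
    dates:
        Optional date labels; with array input a DataFrame indexed by them
        is returned.

    Wind outside [0.5, 17] m/s is clamped to the polynomial's validity
    range (flag ``wind_clamped``); air temperature outside [-50, 50] degC
    or a radiant excess outside [-30, 70] K is never clamped but flagged
    ``input_out_of_range``.

    Returns a :class:`UtciDay` for scalar input, else a DataFrame with
    columns ``utci``, ``category``, ``wind_clamped``, ``input_out_of_range``.
    """
    ta = np.asarray(Ta, dtype=float)
    v = np.asarray(V, dtype=float)
    ehpa = np.asarray(e, dtype=float)
    tmrt = np.asarray(Tmrt, dtype=float)
    for name, arr in (("Ta", ta), ("V", v), ("e", ehpa), ("Tmrt", tmrt)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite {name} passed to utci()")

    v_used = np.clip(v, WIND_MIN, WIND_MAX)
    wind_clamped = v_used != v
    d = tmrt - ta
    out_of_range = (ta < TA_MIN) | (ta > TA_MAX) | (d < DMRT_MIN) | (d > DMRT_MAX)

    value = utci_polynomial(ta, v_used, tmrt, ehpa / _HPA_PER_KPA)
    category = classify(value, scheme)

    scalar = np.ndim(value) == 0
    if scalar:
        flags = set()
        if bool(wind_clamped):
            flags.add("wind_clamped")
        if bool(out_of_range):
            flags.add("input_out_of_range")
        return UtciDay(date=dates, utci=float(value), category=int(category),
                       flags=frozenset(flags))
    df = pd.DataFrame(
        {
            "utci": np.atleast_1d(value),
            "category": np.atleast_1d(category),
            "wind_clamped": np.atleast_1d(np.broadcast_to(wind_clamped, np.shape(value))),
            "input_out_of_range": np.atleast_1d(np.broadcast_to(out_of_range, np.shape(value))),
        }
    )
    if dates is not None:
        df.index = pd.DatetimeIndex(dates)
        df.index.name = "date"
    return df


def classify(utci_value, scheme: CategoryScheme = DEFAULT_SCHEME):
    """Thermal-stress category (1 = hottest) for a UTCI value (degC).

    Intervals are half-open ``[lower, upper)``; the top interval is closed
    above, so e.g. with the default scheme 26.0 degC already counts as
    moderate heat stress.
    """
    value = np.asarray(utci_value, dtype=float)
    idx = np.searchsorted(np.asarray(scheme.bounds), value, side="right")
    category = scheme.n_categories - idx
    return int(category) if category.ndim == 0 else category


def aggregate_category_days(days: pd.DataFrame, window: str = "calendar_year",
                            scheme: CategoryScheme = DEFAULT_SCHEME,
                            season_months=(6, 7, 8)) -> pd.DataFrame:
    """Count days per stress category per window.

    ``days`` must be a DataFrame indexed by unique dates with a
    ``category`` column (as produced by :func:`utci`).  ``window`` is
    ``"calendar_year"`` (every day of each year) or ``"season"`` (only the
    months in ``season_months``, labelled by year).  Columns are ``C1`` ...
    ``C10``; rows always sum to the number of days in the window.
    """
    if days.index.has_duplicates:
        dup = days.index[days.index.duplicated()][0]
        raise ValueError(f"duplicate date in daily series: {dup}")
    if window not in ("calendar_year", "season"):
        raise ValueError(f"unknown window {window!r}")
    idx = pd.DatetimeIndex(days.index)
    sub = days
    if window == "season":
        keep = idx.month.isin(season_months)
        sub = days.loc[keep]
        idx = idx[keep]
    cats = range(1, scheme.n_categories + 1)
    counts = (
        pd.crosstab(idx.year, sub["category"])
        .reindex(columns=cats, fill_value=0)
        .rename(columns=lambda c: f"C{c}")
    )
    counts.index.name = "year"
    return counts


def summarize_category_days(counts: pd.DataFrame) -> pd.DataFrame:
    """Across-year summary of a day-count table: mean, sd, min, max.

    Mirrors the conventional climatology presentation
    ``mean +/- sd [min, max]`` per category.
    """
    return pd.DataFrame(
        {
            "mean": counts.mean(),
            "sd": counts.std(ddof=1),
            "min": counts.min(),
            "max": counts.max(),
        }
    )
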