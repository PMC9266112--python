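"""Seeded synthetic daily station weather with a known radiation law.

The generator emulates the statistical structure of multi-decadal daily
records from mid-latitude surface stations: a sinusoidal annual temperature
cycle with AR(1) day-to-day anomalies, a bounded sunshine fraction, a
diurnal temperature range positively correlated with sunshine (so that
temperature-based radiation models have signal to work with), humidity
kept within physical bounds, and daily global radiation produced by an
Angstrom-type law ``Ra = Re (a + b S/S0)`` with multiplicative noise.
Because the radiation law and its coefficients are known exactly, every
downstream stage (calibration, UTCI propagation, trends) can be tested
against ground truth without any observational download.

All randomness flows from the single integer seed in
:class:`GeneratorConfig`; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .utci import vapor_pressure_from_dewpoint

__all__ = [
    "StationMeta",
    "GeneratorConfig",
    "DailyMeteoRecord",
    "generate_station_series",
    "degrade_and_impute",
    "impute_missing",
    "dewpoint_from_vapor_pressure",
    "IMPUTABLE_COLUMNS",
]

#: Columns that the degradation/imputation step may mask and restore.
IMPUTABLE_COLUMNS = ("S", "Ta", "Tmax", "Tmin", "Td", "e", "Vu", "Vv",
                     "cloudiness", "Tg", "precip", "Ra_obs")


@dataclass(frozen=True)
class StationMeta:
    """Identity and location of one station."""

    station_id: str
    latitude: float
    longitude: float
    altitude: float = 0.0
    climate_zone: str = ""

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if self.altitude < -500.0:
            raise ValueError(f"altitude below -500 m: {self.altitude}")


@dataclass(frozen=True)
class DailyMeteoRecord:
    """One station-day of meteorology (scalar view of a series row)."""

    date: pd.Timestamp
    S: float
    Ta: float
    Tmax: float
    Tmin: float
    Td: float
    e: float
    Vu: float
    Vv: float
    cloudiness: float
    Tg: float
    precip: float
    Ra_obs: float | None = None
    flags: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic station-weather generator.

    The defaults describe a temperate mid-latitude station: annual-mean
    temperature 12 degC with a 14 degC seasonal amplitude peaking in July,
    day-to-day anomalies with AR(1) persistence 0.7, a mean sunshine
    fraction around 0.55, and an Angstrom radiation law with the average
    coefficients of calibrated Chinese stations (a = 0.161, b = 0.528) plus
    10% multiplicative noise.
    """

    years: int = 10
    seed: int = 0
    start_year: int = 1991
    angstrom_a: float = 0.161
    angstrom_b: float = 0.528
    noise_cv: float = 0.10
    temp_mean: float = 12.0
    temp_amplitude: float = 14.0
    temp_ar1: float = 0.7
    temp_innovation_sd: float = 2.0
    #: diurnal range = dtr_base + dtr_gain * sunshine_fraction + noise (degC)
    dtr_base: float = 5.0
    dtr_gain: float = 8.0
    dtr_noise_sd: float = 1.0
    sunshine_mean: float = 0.55
    sunshine_sd: float = 0.25
    wind_sd: float = 1.8
    #: ground temperature offset per unit clearness index (degC)
    tg_gain: float = 3.0
    tg_noise_sd: float = 0.8
    missing_rate: float = 0.0
    #: optional linear warming applied to all temperatures (degC per year)
    warming_per_year: float = 0.0

    def __post_init__(self):
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if not self.angstrom_a > 0:
            raise ValueError(f"angstrom_a must be > 0, got {self.angstrom_a}")
        if self.angstrom_a + self.angstrom_b > 1.0:
            raise ValueError(
                "angstrom_a + angstrom_b must be <= 1 (clearness index bound), "
                f"got {self.angstrom_a + self.angstrom_b:.3f}"
            )
        if not 0.0 <= self.missing_rate < 0.05:
            raise ValueError(f"missing_rate must be in [0, 0.05): {self.missing_rate}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def dewpoint_from_vapor_pressure(e):
    """Invert the Magnus-type vapour-pressure formula: e (hPa) -> Td (degC)."""
    e = np.asarray(e, dtype=float)
    td = 1.0 / (1.0 / 273.16 - np.log(e / 6.11) / 5417.753) - 273.16
    return float(td) if td.ndim == 0 else td


def generate_station_series(meta: StationMeta, cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate a daily weather series for one station.

    Returns a DataFrame indexed by date with columns ``S`` (sunshine
    hours), ``Ta``/``Tmax``/``Tmin`` (degC), ``Td`` (degC), ``e`` (hPa),
    ``Vu``/``Vv`` (m/s), ``cloudiness`` (tenths), ``Tg`` (degC), ``precip``
    (mm), ``Ra_obs`` (W/m^2) and a boolean ``imputed`` flag column.
    Deterministic for a fixed ``(meta, cfg)``.
    """
    rng = np.random.default_rng(cfg.seed)
    dates = pd.date_range(
        f"{cfg.start_year}-01-01", f"{cfg.start_year + cfg.years - 1}-12-31", freq="D"
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    years_elapsed = (dates - dates[0]).days.to_numpy() / 365.25

    re_flux = solar.extraterrestrial_radiation(meta.latitude, doy)
    s0 = solar.day_length(meta.latitude, doy)

    # sunshine fraction: truncated Gaussian in [0, 1]
    s_frac = np.clip(rng.normal(cfg.sunshine_mean, cfg.sunshine_sd, n), 0.0, 1.0)
    sunshine = s_frac * s0

    # seasonal cycle peaking mid-July (northern convention), AR(1) anomaly
    seasonal = cfg.temp_mean - cfg.temp_amplitude * np.cos(
        2.0 * np.pi * (doy - 15.0) / 365.25
    ) * np.sign(meta.latitude or 1.0)
    anom = np.empty(n)
    innov = rng.normal(0.0, cfg.temp_innovation_sd, n)
    anom[0] = innov[0] / np.sqrt(1.0 - cfg.temp_ar1**2)
    for t in range(1, n):
        anom[t] = cfg.temp_ar1 * anom[t - 1] + innov[t]
    ta = seasonal + anom + cfg.warming_per_year * years_elapsed

    # diurnal range tied to sunshine: clear days swing harder
    dtr = np.maximum(
        cfg.dtr_base + cfg.dtr_gain * s_frac + rng.normal(0.0, cfg.dtr_noise_sd, n),
        0.5,
    )
    tmax = ta + 0.5 * dtr
    tmin = ta - 0.5 * dtr

    # humidity: RH in [20, 100]%, drier on sunny days
    rh = np.clip(90.0 - 40.0 * s_frac + rng.normal(0.0, 8.0, n), 20.0, 100.0)
    e_sat = vapor_pressure_from_dewpoint(ta)  # saturation when Td = Ta
    e = rh / 100.0 * e_sat
    td = dewpoint_from_vapor_pressure(e)

    vu = rng.normal(0.0, cfg.wind_sd, n)
    vv = rng.normal(0.0, cfg.wind_sd, n)

    cloudiness = np.clip(
        np.round(10.0 * (1.0 - s_frac) + rng.normal(0.0, 0.8, n)), 0, 10
    )

    # Angstrom-type radiation law with multiplicative noise, clipped to
    # the physical range [0, Re]
    clearness = cfg.angstrom_a + cfg.angstrom_b * s_frac
    noise = 1.0 + cfg.noise_cv * rng.standard_normal(n)
    ra_obs = np.clip(re_flux * clearness * noise, 0.0, re_flux)

    tg = ta + cfg.tg_gain * np.divide(
        ra_obs, re_flux, out=np.zeros(n), where=re_flux > 0
    ) + rng.normal(0.0, cfg.tg_noise_sd, n)

    wet = rng.random(n) < 0.5 * (1.0 - s_frac)
    precip = np.where(wet, rng.exponential(5.0, n), 0.0)

    df = pd.DataFrame(
        {
            "S": sunshine,
            "Ta": ta,
            "Tmax": tmax,
            "Tmin": tmin,
            "Td": td,
            "e": e,
            "Vu": vu,
            "Vv": vv,
            "cloudiness": cloudiness,
            "Tg": tg,
            "precip": precip,
            "Ra_obs": ra_obs,
            "imputed": np.zeros(n, dtype=bool),
        },
        index=dates,
    )
    df.index.name = "date"

    if cfg.missing_rate > 0:
        df = degrade_and_impute(df, cfg.missing_rate, seed=rng.integers(2**31))
    return df


def impute_missing(series: pd.DataFrame, columns=IMPUTABLE_COLUMNS) -> pd.DataFrame:
    """Fill missing (NaN) values from neighbouring days.

    A single missing day is replaced by the mean of the nearest preceding
    and following observations; runs of consecutive missing days are
    filled by linear interpolation between the bracketing observations
    (the natural generalisation of the single-gap rule).  Missing values
    at the series edge take the nearest observation.  Rows touched by
    imputation get ``imputed = True``.

    Raises ``ValueError`` if every value of some variable is missing
    (nothing to interpolate from).
    """
    out = series.copy()
    touched = np.zeros(len(out), dtype=bool)
    for col in (c for c in columns if c in out.columns):
        vals = out[col].astype(float)
        mask = vals.isna().to_numpy()
        if mask.all():
            raise ValueError(f"all values of {col!r} missing; cannot impute")
        if not mask.any():
            continue
        out[col] = vals.interpolate(method="linear", limit_direction="both")
        touched |= mask
    if "imputed" in out.columns:
        out["imputed"] = out["imputed"].to_numpy() | touched
    else:
        out["imputed"] = touched
    return out


def degrade_and_impute(series: pd.DataFrame, missing_rate: float, seed: int,
                       columns=IMPUTABLE_COLUMNS) -> pd.DataFrame:
    """Randomly mask values at ``missing_rate``, then restore them with
    :func:`impute_missing`.  Output length always equals input length."""
    if not 0.0 <= missing_rate < 0.05:
        raise ValueError(f"missing_rate must be in [0, 0.05): {missing_rate}")
    out = series.copy()
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    for col in (c for c in columns if c in out.columns):
        mask = rng.random(len(out)) < missing_rate
        vals = out[col].astype(float).copy()
        vals[mask] = np.nan
        out[col] = vals
    return impute_missing(out, columns=columns)


def to_records(df: pd.DataFrame) -> list[DailyMeteoRecord]:
    """Scalar-record view of a generated series (one dataclass per day)."""
    records = []
    for date, row in df.iterrows():
        flags = frozenset({"imputed"}) if row.get("imputed", False) else frozenset()
        records.append(
            DailyMeteoRecord(
                date=date, S=row["S"], Ta=row["Ta"], Tmax=row["Tmax"],
                Tmin=row["Tmin"], Td=row["Td"], e=row["e"], Vu=row["Vu"],
                Vv=row["Vv"], cloudiness=row["cloudiness"], Tg=row["Tg"],
                precip=row["precip"], Ra_obs=row.get("Ra_obs"), flags=flags,
            )
        )
    return records


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a station series as CSV with ISO-8601 dates."""
    df.to_csv(path, date_format="%Y-%m-%d")


def read_csv(path) -> pd.DataFrame:
    """Read a station series CSV written by :func:`write_csv`."""
    df = pd.read_csv(path, parse_dates=["date"], index_col="date")
    if "imputed" in df.columns:
        df["imputed"] = df["imputed"].astype(bool)
    return df
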