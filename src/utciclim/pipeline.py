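"""End-to-end orchestration: weather -> radiation models -> UTCI ->
climatology -> trends, as reproducible stages driven by one config.

Every stage is a plain function taking a :class:`RunConfig` (and
optionally pre-generated station series) and returning DataFrames; when
``cfg.output_dir`` is set the tables are also written as CSV together
with a JSON manifest recording the config hash, the master seed and the
checksum of the UTCI polynomial constants.  A fixed config and seed yield
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import radiation, solar, trends, utci as utci_mod
from .metrics import fit_metrics
from .synthetic import GeneratorConfig, StationMeta, generate_station_series
from .utci import (aggregate_category_days, longwave_fluxes,
                   mean_radiant_temperature, rp_from_global,
                   summarize_category_days, vapor_pressure_from_dewpoint,
                   wind_speed)

__all__ = [
    "RunConfig",
    "daily_utci",
    "prepare_station_frame",
    "run_calibration_validation",
    "run_climatology_trends",
    "run_all",
]

_EMPIRICAL = radiation.MODEL_IDS
_ML = ("bp", "svm")


@dataclass
class RunConfig:
    """One reproducible run of the full analysis."""

    stations: list = field(default_factory=lambda: [
        StationMeta("S40N", latitude=40.0, longitude=116.0, altitude=50.0,
                    climate_zone="temperate")
    ])
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    models: tuple = _EMPIRICAL
    #: leading fraction of calendar years used for calibration
    calibration_fraction: float = 2.0 / 3.0
    #: radiation model driving the climatology/trend stages
    best_model: str = "angstrom"
    season_months: tuple = (6, 7, 8)
    #: year ranges for the period-distribution comparison; None = first
    #: half vs second half of the record
    periods: tuple | None = None
    include_flagged_days: bool = True
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.stations:
            raise ValueError("at least one station required")
        if not self.models:
            raise ValueError("at least one model must be selected")
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration_fraction must be in (0, 1)")

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        stations = [StationMeta(**s) for s in raw.pop("stations", [])]
        gen = GeneratorConfig(**raw.pop("generator", {}))
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in ("stations", "generator"):
                continue
            if f.name in raw:
                v = raw.pop(f.name)
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        if stations:
            kwargs["stations"] = stations
        return cls(generator=gen, **kwargs)


def generate_all(cfg: RunConfig) -> dict:
    """Generate (deterministically) one series per configured station."""
    out = {}
    for i, meta in enumerate(cfg.stations):
        gen = dataclasses.replace(cfg.generator, seed=(cfg.seed + 7919 * i) % 2**31)
        out[meta.station_id] = generate_station_series(meta, gen)
    return out


def prepare_station_frame(meta: StationMeta, df: pd.DataFrame) -> pd.DataFrame:
    """Attach derived per-day columns used by models and the UTCI engine.

    Adds ``Re``, ``S0`` (solar geometry), ``V`` (scalar wind), ``dT``
    (diurnal range), ``humidity`` (%), ``precip_event`` and the noon solar
    elevation ``elev``.
    """
    out = df.copy()
    doy = pd.DatetimeIndex(out.index).dayofyear.to_numpy()
    out["Re"] = solar.extraterrestrial_radiation(meta.latitude, doy)
    out["S0"] = solar.day_length(meta.latitude, doy)
    out["V"] = wind_speed(out["Vu"], out["Vv"])
    out["dT"] = out["Tmax"] - out["Tmin"]
    out["humidity"] = 100.0 * out["e"] / vapor_pressure_from_dewpoint(out["Ta"].to_numpy())
    out["precip_event"] = (out["precip"] > 0).astype(float)
    out["elev"] = solar.noon_solar_elevation(meta.latitude, doy)
    return out


def daily_utci(frame: pd.DataFrame, radiation_wm2=None) -> pd.DataFrame:
    """Daily UTCI series from a prepared station frame.

    ``radiation_wm2`` defaults to the observed column ``Ra_obs``; pass an
    estimated series to propagate a radiation model instead.  Ground
    temperature falls back to air temperature where unavailable.
    """
    rg = np.asarray(frame["Ra_obs"] if radiation_wm2 is None else radiation_wm2,
                    dtype=float)
    tg = frame["Tg"].to_numpy() if "Tg" in frame.columns else frame["Ta"].to_numpy()
    tg = np.where(np.isfinite(tg), tg, frame["Ta"].to_numpy())
    rp = rp_from_global(rg, frame["elev"].to_numpy())
    lg, la = longwave_fluxes(tg, frame["Ta"].to_numpy(), frame["e"].to_numpy())
    tmrt = mean_radiant_temperature(rp, lg, la)
    return utci_mod.utci(frame["Ta"].to_numpy(), frame["V"].to_numpy(),
                         frame["e"].to_numpy(), tmrt, dates=frame.index)


def _split_years(frame: pd.DataFrame, fraction: float):
    years = sorted(set(pd.DatetimeIndex(frame.index).year))
    n_cal = max(1, int(round(fraction * len(years))))
    if n_cal >= len(years):
        n_cal = len(years) - 1
    cal_years, val_years = years[:n_cal], years[n_cal:]
    year = pd.DatetimeIndex(frame.index).year
    cal = frame.loc[np.isin(year, cal_years)]
    val = frame.loc[np.isin(year, val_years)]
    if cal.empty:
        raise ValueError(f"empty calibration period {cal_years}")
    if val.empty:
        raise ValueError(f"empty validation period {val_years}")
    return cal, val


def _fit_model(model_id: str, frame: pd.DataFrame, seed: int = 0):
    """Calibrate one model (empirical or ML) on a prepared frame."""
    if model_id in _EMPIRICAL:
        return radiation.calibrate_model(
            model_id, frame["Ra_obs"], frame["Re"], S=frame["S"], S0=frame["S0"],
            Tmax=frame["Tmax"], Tmin=frame["Tmin"],
        )
    if model_id in _ML:
        table = frame.loc[:, [c for c in radiation.ML_FEATURES if c in frame.columns]]
        fs = radiation.prune_features(table)
        return radiation.fit_ml_regressor(model_id, table, frame["Ra_obs"],
                                          features=fs.names, seed=seed)
    raise ValueError(f"unknown model {model_id!r}")


def _predict(fit, frame: pd.DataFrame):
    if isinstance(fit, radiation.MLRegressor):
        return fit.predict(frame)
    return radiation.predict_radiation(
        fit, frame["Re"], S=frame["S"], S0=frame["S0"],
        Tmax=frame["Tmax"], Tmin=frame["Tmin"],
    )


def run_calibration_validation(cfg: RunConfig, series: dict | None = None) -> dict:
    """Calibrate every configured model per station, then validate.

    Returns ``{"calibration": ..., "validation": ..., "utci_validation": ...}``
    DataFrames shaped like the conventional model-comparison tables
    (model x station rows; coefficients and NSE/MAPE/RMSE/Slope/Inter/n
    columns).  The UTCI validation compares daily UTCI computed from
    estimated radiation against UTCI from observed radiation on the
    validation split.
    """
    series = series if series is not None else generate_all(cfg)
    cal_rows, val_rows, utci_rows = [], [], []
    fits = {}
    for meta in cfg.stations:
        frame = prepare_station_frame(meta, series[meta.station_id])
        cal, val = _split_years(frame, cfg.calibration_fraction)
        for model_id in cfg.models:
            fit = _fit_model(model_id, cal, seed=cfg.seed)
            fits[(meta.station_id, model_id)] = fit
            coeffs = {"a": np.nan, "b": np.nan, "c": np.nan}
            if isinstance(fit, radiation.RadiationModelFit):
                coeffs.update(dict(zip("abc", fit.coefficients())))
            cal_rows.append({"model": model_id, "station": meta.station_id,
                             **coeffs, **fit.metrics.as_dict()})
            val_pred = _predict(fit, val)
            vm = fit_metrics(val["Ra_obs"], val_pred)
            val_rows.append({"model": model_id, "station": meta.station_id,
                             **vm.as_dict()})
            u_obs = daily_utci(val)
            u_est = daily_utci(val, radiation_wm2=val_pred)
            um = fit_metrics(u_obs["utci"], u_est["utci"])
            utci_rows.append({"model": model_id, "station": meta.station_id,
                              **um.as_dict()})
    result = {
        "calibration": pd.DataFrame(cal_rows),
        "validation": pd.DataFrame(val_rows),
        "utci_validation": pd.DataFrame(utci_rows),
        "fits": fits,
    }
    _maybe_write(cfg, {k: v for k, v in result.items() if k != "fits"},
                 stage="calibration_validation")
    return result


def run_climatology_trends(cfg: RunConfig, series: dict | None = None) -> dict:
    """Day-count climatology, trend tables and period-distribution shifts.

    The configured ``best_model`` is calibrated per station on the
    calibration split and then drives UTCI for the whole record.
    """
    series = series if series is not None else generate_all(cfg)
    summary_rows, trend_rows, summer_rows, shift_rows = [], [], [], []
    counts_by_station = {}
    for meta in cfg.stations:
        frame = prepare_station_frame(meta, series[meta.station_id])
        cal, _ = _split_years(frame, cfg.calibration_fraction)
        fit = _fit_model(cfg.best_model, cal, seed=cfg.seed)
        est = _predict(fit, frame)
        days = daily_utci(frame, radiation_wm2=est)
        if not cfg.include_flagged_days:
            days = days.loc[~days["input_out_of_range"]]
        counts = aggregate_category_days(days, "calendar_year")
        counts_by_station[meta.station_id] = counts

        yearly_utci = days["utci"].groupby(pd.DatetimeIndex(days.index).year).mean()
        summ = summarize_category_days(counts)
        row = {"station": meta.station_id,
               "UTCI_mean": yearly_utci.mean(), "UTCI_sd": yearly_utci.std(ddof=1)}
        for cat in counts.columns:
            row[f"{cat}_mean"] = summ.loc[cat, "mean"]
            row[f"{cat}_sd"] = summ.loc[cat, "sd"]
            row[f"{cat}_min"] = summ.loc[cat, "min"]
            row[f"{cat}_max"] = summ.loc[cat, "max"]
        summary_rows.append(row)

        tr = trends.trend(yearly_utci.to_numpy())
        trend_rows.append({"station": meta.station_id, "series": "UTCI",
                           "beta": tr.beta, "z": tr.z, "tier": tr.significance_tier})
        for cat in counts.columns:
            tr = trends.trend(counts[cat].to_numpy())
            trend_rows.append({"station": meta.station_id, "series": cat,
                               "beta": tr.beta, "z": tr.z,
                               "tier": tr.significance_tier})

        seasonal = aggregate_category_days(days, "season",
                                           season_months=cfg.season_months)
        for cat in seasonal.columns:
            tr = trends.trend(seasonal[cat].to_numpy())
            summer_rows.append({"station": meta.station_id, "series": cat,
                                "beta": tr.beta, "z": tr.z,
                                "tier": tr.significance_tier})

        years = counts.index.to_numpy()
        if cfg.periods is not None:
            period_a, period_b = (tuple(p) for p in cfg.periods)
        else:
            mid = years[len(years) // 2]
            period_a, period_b = (int(years[0]), int(mid - 1)), (int(mid), int(years[-1]))
        report = trends.period_distribution(counts, period_a, period_b, smooth=False)
        for cat, info in report.items():
            shift_rows.append({"station": meta.station_id, "series": cat,
                               "period_a": f"{period_a[0]}-{period_a[1]}",
                               "period_b": f"{period_b[0]}-{period_b[1]}",
                               "mean_a": info["mean_a"], "mean_b": info["mean_b"],
                               "mean_shift": info["mean_shift"]})

    result = {
        "summary": pd.DataFrame(summary_rows),
        "trends": pd.DataFrame(trend_rows),
        "summer_trends": pd.DataFrame(summer_rows),
        "period_shift": pd.DataFrame(shift_rows),
        "counts": counts_by_station,
    }
    _maybe_write(cfg, {k: v for k, v in result.items() if k != "counts"},
                 stage="climatology_trends")
    return result


def run_all(cfg: RunConfig) -> dict:
    """Generate data once, then run both analysis stages on it."""
    series = generate_all(cfg)
    out = run_calibration_validation(cfg, series)
    out.update(run_climatology_trends(cfg, series))
    return out


def _maybe_write(cfg: RunConfig, tables: dict, stage: str) -> None:
    if cfg.output_dir is None:
        return
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6f")
        written[name] = path.name
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "utci_constants_sha256": utci_mod.coefficients_checksum(),
        "outputs": written,
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))
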