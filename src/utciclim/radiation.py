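"""Empirical daily solar-radiation models and their calibration.

Four classic empirical models estimate daily-mean global radiation ``Ra``
(W/m^2) from extraterrestrial radiation ``Re``, relative sunshine duration
``S/S0`` or the diurnal temperature range ``dT = Tmax - Tmin``:

- ``angstrom``:    Ra = Re (a + b S/S0)
- ``ogelman``:     Ra = Re (a + b S/S0 + c (S/S0)^2)
- ``bristow``:     Ra = a Re (1 - exp(-b dT^c))
- ``hargreaves``:  Ra = Re (a dT^0.5 + b)

Calibration minimises the sum of squared flux residuals.  The sunshine
models and Hargreaves are linear in their coefficients, so they are solved
exactly by linear least squares; Bristow is fitted by bounded
trust-region nonlinear least squares.  A pluggable machine-learning
harness (feed-forward network / support-vector regression) trains on a
pruned feature table and predicts through the same evaluation path as the
empirical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .metrics import EvalMetrics, fit_metrics

__all__ = [
    "MODEL_IDS",
    "RadiationModelFit",
    "FeatureSet",
    "IdentifiabilityError",
    "predict_radiation",
    "calibrate_model",
    "prune_features",
    "fit_ml_regressor",
    "MLRegressor",
    "ML_FEATURES",
]

MODEL_IDS = ("angstrom", "ogelman", "bristow", "hargreaves")

#: default feature columns offered to the ML harness (before pruning)
ML_FEATURES = ("Re", "S", "S0", "cloudiness", "Ta", "Tmax", "Tmin", "dT",
               "e", "humidity", "wind", "precip", "precip_event")


class IdentifiabilityError(ValueError):
    """Raised when the predictor carries no information (constant input)."""


@dataclass(frozen=True)
class RadiationModelFit:
    """Calibrated empirical radiation model: id, coefficients, skill."""

    model_id: str
    a: float
    b: float
    c: float = 0.0
    n: int = 0
    metrics: EvalMetrics | None = None

    def coefficients(self) -> tuple:
        if self.model_id in ("angstrom", "hargreaves"):
            return (self.a, self.b)
        return (self.a, self.b, self.c)


@dataclass(frozen=True)
class FeatureSet:
    """Retained predictor names after correlation pruning."""

    names: tuple
    dropped: tuple = ()
    forced: tuple = ()


def _sunshine_fraction(S, S0):
    s = np.asarray(S, dtype=float)
    s0 = np.asarray(S0, dtype=float)
    frac = np.divide(s, s0, out=np.zeros_like(s * s0, dtype=float),
                     where=np.asarray(s0) > 0)
    return frac


def _model_inputs(model_id, Re, S=None, S0=None, Tmax=None, Tmin=None):
    if model_id in ("angstrom", "ogelman"):
        if S is None or S0 is None:
            raise ValueError(f"{model_id} needs sunshine hours S and day length S0")
        return np.asarray(Re, float), _sunshine_fraction(S, S0)
    if model_id in ("bristow", "hargreaves"):
        if Tmax is None or Tmin is None:
            raise ValueError(f"{model_id} needs Tmax and Tmin")
        dt = np.asarray(Tmax, float) - np.asarray(Tmin, float)
        if np.any(dt < 0):
            raise ValueError("Tmax < Tmin encountered")
        return np.asarray(Re, float), dt
    raise ValueError(f"unknown model {model_id!r}; choose from {MODEL_IDS}")


def _evaluate(model_id, coeffs, re_flux, x):
    """Raw model output (before the physical clamp at 0)."""
    if model_id == "angstrom":
        a, b = coeffs
        return re_flux * (a + b * x)
    if model_id == "ogelman":
        a, b, c = coeffs
        return re_flux * (a + b * x + c * x**2)
    if model_id == "bristow":
        a, b, c = coeffs
        return a * re_flux * (1.0 - np.exp(-b * np.power(x, c)))
    if model_id == "hargreaves":
        a, b = coeffs
        return re_flux * (a * np.sqrt(x) + b)
    raise ValueError(f"unknown model {model_id!r}")


def predict_radiation(fit: RadiationModelFit, Re, S=None, S0=None,
                      Tmax=None, Tmin=None, return_flags: bool = False):
    """Predict daily global radiation (W/m^2) with a calibrated model.

    Polar night (``S0 = 0`` for sunshine models, or ``Re = 0`` generally)
    yields 0; negative raw predictions (possible for Hargreaves with
    b < 0) are clamped to 0.  With ``return_flags=True`` also returns a
    boolean array marking days where clamping or polar night applied.
    """
    re_flux, x = _model_inputs(fit.model_id, Re, S, S0, Tmax, Tmin)
    raw = _evaluate(fit.model_id, fit.coefficients(), re_flux, x)
    polar = np.asarray(re_flux) == 0
    if fit.model_id in ("angstrom", "ogelman") and S0 is not None:
        polar = polar | (np.asarray(S0, float) == 0)
    clamped = (np.asarray(raw) < 0) | polar
    pred = np.where(polar, 0.0, np.maximum(raw, 0.0))
    if np.ndim(pred) == 0:
        pred = float(pred)
        clamped = bool(clamped)
    if return_flags:
        return pred, clamped
    return pred


def calibrate_model(model_id: str, Ra_obs, Re, S=None, S0=None,
                    Tmax=None, Tmin=None, min_records: int = 100
                    ) -> RadiationModelFit:
    """Fit a model's coefficients by least squares on the flux residuals.

    Only days with ``Re > 0`` (and finite observed radiation) enter the
    fit.  Deterministic for fixed input.  Raises
    :class:`IdentifiabilityError` when the predictor is constant.
    """
    ra = np.asarray(Ra_obs, dtype=float)
    re_flux, x = _model_inputs(model_id, Re, S, S0, Tmax, Tmin)
    ok = np.isfinite(ra) & (re_flux > 0) & np.isfinite(x)
    ra, re_flux, x = ra[ok], re_flux[ok], x[ok]
    if ra.size < min_records:
        raise ValueError(f"need >= {min_records} usable records, got {ra.size}")
    if np.std(x) < 1e-12:
        raise IdentifiabilityError(
            f"predictor for {model_id!r} is constant; coefficients not identifiable"
        )

    if model_id == "bristow":
        def residuals(p):
            return _evaluate(model_id, p, re_flux, x) - ra

        sol = least_squares(
            residuals, x0=(0.2, 0.5, 1.5),
            bounds=((1e-6, 1e-8, 1e-2), (1.5, np.inf, np.inf)),
            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        coeffs = tuple(sol.x)
    else:
        # linear in the coefficients: exact weighted design solve
        if model_id == "angstrom":
            design = np.column_stack([re_flux, re_flux * x])
        elif model_id == "ogelman":
            design = np.column_stack([re_flux, re_flux * x, re_flux * x**2])
        else:  # hargreaves: Ra = Re (a sqrt(dT) + b)
            design = np.column_stack([re_flux * np.sqrt(x), re_flux])
        coeffs, *_ = np.linalg.lstsq(design, ra, rcond=None)
        coeffs = tuple(float(v) for v in coeffs)

    fit = RadiationModelFit(
        model_id=model_id,
        a=coeffs[0], b=coeffs[1], c=coeffs[2] if len(coeffs) > 2 else 0.0,
        n=int(ra.size),
    )
    pred = _evaluate(model_id, fit.coefficients(), re_flux, x)
    return replace(fit, metrics=fit_metrics(ra, np.maximum(pred, 0.0)))


#: documented priority when breaking a correlated cluster: daily-mean
#: temperature represents the temperature block, then sky/moisture
#: proxies, then the redundant extremes
DEFAULT_PRIORITY = ("Ta", "dT", "cloudiness", "humidity", "wind", "precip",
                    "precip_event", "Tmax", "Tmin", "e")

#: the sunshine trio is always retained: the radiation signal lives there
FORCED_FEATURES = ("Re", "S", "S0")


def prune_features(table: pd.DataFrame, threshold: float = 0.8,
                   priority=DEFAULT_PRIORITY, forced=FORCED_FEATURES
                   ) -> FeatureSet:
    """Drop all but one feature from each highly correlated cluster.

    Features are visited in ``priority`` order (unlisted columns last, in
    table order); a feature is dropped when its absolute Pearson
    correlation with an already-retained non-forced feature exceeds
    ``threshold``.  The ``forced`` features are always retained and never
    cause a drop.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1): {threshold}")
    cols = list(table.columns)
    if len(cols) == 0:
        raise ValueError("empty predictor table")
    corr = table.corr().abs()
    order = [c for c in priority if c in cols] + [c for c in cols if c not in priority]
    kept, dropped = [], []
    for col in order:
        if col in forced:
            continue
        if any(corr.loc[col, k] > threshold for k in kept):
            dropped.append(col)
        else:
            kept.append(col)
    retained = [c for c in cols if c in kept or c in forced]
    return FeatureSet(names=tuple(retained), dropped=tuple(dropped),
                      forced=tuple(c for c in forced if c in cols))


@dataclass(frozen=True)
class MLRegressor:
    """Trained ML radiation model, usable like an empirical fit."""

    kind: str
    features: tuple
    pipeline: object = field(repr=False, compare=False, default=None)
    n: int = 0
    metrics: EvalMetrics | None = None

    model_id = property(lambda self: self.kind)

    def predict(self, table: pd.DataFrame):
        """Predict Ra (W/m^2, clamped at 0) from a feature table."""
        x = table.loc[:, list(self.features)].to_numpy(dtype=float)
        return np.maximum(self.pipeline.predict(x), 0.0)


def fit_ml_regressor(kind: str, table: pd.DataFrame, target, features=None,
                     hyperparams=None, seed: int = 0) -> MLRegressor:
    """Train a machine-learning radiation model.

    ``kind="bp"`` is a single-hidden-layer feed-forward network (10 hidden
    units, L2 weight decay 0.01, L-BFGS training); ``kind="svm"`` is
    epsilon-SVR with a radial kernel, cost 1 and gamma 0.125.  Features
    and the target are standardised inside the pipeline.  The training
    table must have no missing cells.
    """
    from sklearn.compose import TransformedTargetRegressor
    from sklearn.neural_network import MLPRegressor
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR

    feats = tuple(features) if features is not None else tuple(table.columns)
    x = table.loc[:, list(feats)]
    y = np.asarray(target, dtype=float)
    if x.isna().any().any() or not np.all(np.isfinite(y)):
        raise ValueError("training table must be complete (no missing cells)")
    hp = dict(hyperparams or {})
    if kind == "bp":
        est = MLPRegressor(
            hidden_layer_sizes=(hp.pop("hidden_units", 10),),
            alpha=hp.pop("weight_decay", 0.01),
            solver="lbfgs", max_iter=hp.pop("max_iter", 500),
            random_state=seed, **hp,
        )
    elif kind == "svm":
        est = SVR(kernel=hp.pop("kernel", "rbf"), C=hp.pop("cost", 1.0),
                  gamma=hp.pop("gamma", 0.125), **hp)
    else:
        raise ValueError(f"unknown ML regressor kind {kind!r}; use 'bp' or 'svm'")

    pipe = make_pipeline(
        StandardScaler(),
        TransformedTargetRegressor(regressor=est, transformer=StandardScaler()),
    )
    pipe.fit(x.to_numpy(dtype=float), y)
    model = MLRegressor(kind=kind, features=feats, pipeline=pipe, n=int(y.size))
    pred = model.predict(table)
    return MLRegressor(kind=kind, features=feats, pipeline=pipe, n=int(y.size),
                       metrics=fit_metrics(y, pred))
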