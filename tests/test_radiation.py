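"""Empirical radiation models: algebraic identities, calibration recovery
of known coefficients, feature pruning, and the ML harness."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from utciclim import (GeneratorConfig, calibrate_model, fit_ml_regressor,
                      generate_station_series, predict_radiation,
                      prune_features)
from utciclim.metrics import fit_metrics
from utciclim.radiation import IdentifiabilityError, RadiationModelFit


def fit_(model_id, **kw):
    return RadiationModelFit(model_id=model_id, **kw)


class TestPredict:
    def test_angstrom_overcast_limit(self):
        f = fit_("angstrom", a=0.2, b=0.5)
        assert predict_radiation(f, Re=300.0, S=0.0, S0=12.0) == pytest.approx(60.0)

    def test_ogelman_with_zero_c_reduces_to_angstrom(self):
        fa = fit_("angstrom", a=0.17, b=0.48)
        fo = fit_("ogelman", a=0.17, b=0.48, c=0.0)
        s = np.linspace(0, 11, 30)
        np.testing.assert_allclose(
            predict_radiation(fa, 280.0, S=s, S0=11.0),
            predict_radiation(fo, 280.0, S=s, S0=11.0))

    def test_bristow_zero_range_gives_zero(self):
        f = fit_("bristow", a=0.7, b=0.02, c=2.0)
        assert predict_radiation(f, 250.0, Tmax=15.0, Tmin=15.0) == 0.0

    def test_angstrom_full_sun_average_coefficients(self):
        # a + b at S/S0 = 1 with the average calibrated coefficients
        f = fit_("angstrom", a=0.161, b=0.528)
        assert predict_radiation(f, 300.0, S=12.0, S0=12.0) == pytest.approx(206.7)

    def test_polar_night_returns_zero_with_flag(self):
        f = fit_("angstrom", a=0.2, b=0.5)
        val, flag = predict_radiation(f, 0.0, S=0.0, S0=0.0, return_flags=True)
        assert val == 0.0 and flag

    def test_negative_hargreaves_clamped(self):
        f = fit_("hargreaves", a=0.1, b=-0.5)
        val, flag = predict_radiation(f, 300.0, Tmax=10.0, Tmin=9.0,
                                      return_flags=True)
        assert val == 0.0 and flag

    def test_missing_required_input_raises(self):
        with pytest.raises(ValueError, match="sunshine"):
            predict_radiation(fit_("angstrom", a=0.2, b=0.5), 300.0,
                              Tmax=20.0, Tmin=10.0)


class TestCalibration:
    def _noise_free(self, frame, a=0.2, b=0.5):
        frac = np.divide(frame["S"], frame["S0"],
                         out=np.zeros(len(frame)), where=frame["S0"] > 0)
        return frame["Re"].to_numpy() * (a + b * frac)

    def test_noise_free_recovery_exact(self, frame):
        ra = self._noise_free(frame)
        fit = calibrate_model("angstrom", ra, frame["Re"], S=frame["S"],
                              S0=frame["S0"])
        assert fit.a == pytest.approx(0.2, abs=1e-6)
        assert fit.b == pytest.approx(0.5, abs=1e-6)
        assert fit.metrics.rmse == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_agrees_with_iterative_solver(self, frame):
        """The exact linear-algebra solve and generic nonlinear least
        squares minimise the same flux residuals, so they must agree."""
        fit = calibrate_model("angstrom", frame["Ra_obs"], frame["Re"],
                              S=frame["S"], S0=frame["S0"])
        frac = (frame["S"] / frame["S0"]).to_numpy()
        re = frame["Re"].to_numpy()
        ra = frame["Ra_obs"].to_numpy()
        ok = re > 0
        popt, _ = curve_fit(lambda x, a, b: x[0] * (a + b * x[1]),
                            (re[ok], frac[ok]), ra[ok], p0=(0.2, 0.5))
        assert fit.a == pytest.approx(popt[0], abs=1e-6)
        assert fit.b == pytest.approx(popt[1], abs=1e-6)

    @pytest.mark.parametrize("model_id,truth", [
        ("angstrom", {"a": 0.161, "b": 0.528}),
        ("ogelman", {"a": 0.150, "b": 0.724, "c": -0.252}),
        ("hargreaves", {"a": 0.212, "b": -0.211}),
        ("bristow", {"a": 0.554, "b": 0.024, "c": 2.141}),
    ])
    def test_noisy_recovery_within_tolerance(self, meta, model_id, truth):
        """10% multiplicative noise, 10 years, mean over seeds: a and b
        recovered within +/- 0.02 of the generating coefficients."""
        rec_a, rec_b = [], []
        for seed in range(5):
            df = generate_station_series(meta, GeneratorConfig(years=10, seed=seed))
            from utciclim.pipeline import prepare_station_frame
            fr = prepare_station_frame(meta, df)
            gen = RadiationModelFit(model_id=model_id, **{"c": 0.0, **truth})
            clean = predict_radiation(gen, fr["Re"], S=fr["S"], S0=fr["S0"],
                                      Tmax=fr["Tmax"], Tmin=fr["Tmin"])
            rng = np.random.default_rng(1000 + seed)
            ra = np.clip(clean * (1 + 0.10 * rng.standard_normal(len(fr))),
                         0, fr["Re"])
            fit = calibrate_model(model_id, ra, fr["Re"], S=fr["S"], S0=fr["S0"],
                                  Tmax=fr["Tmax"], Tmin=fr["Tmin"])
            rec_a.append(fit.a)
            rec_b.append(fit.b)
        assert np.mean(rec_a) == pytest.approx(truth["a"], abs=0.02)
        assert np.mean(rec_b) == pytest.approx(truth["b"], abs=0.02)

    def test_constant_predictor_not_identifiable(self, frame):
        n = len(frame)
        with pytest.raises(IdentifiabilityError):
            calibrate_model("angstrom", frame["Ra_obs"], frame["Re"],
                            S=np.full(n, 6.0), S0=np.full(n, 12.0))

    def test_calibration_beats_perturbed_coefficients(self, frame):
        for model_id in ("angstrom", "ogelman", "bristow", "hargreaves"):
            fit = calibrate_model(model_id, frame["Ra_obs"], frame["Re"],
                                  S=frame["S"], S0=frame["S0"],
                                  Tmax=frame["Tmax"], Tmin=frame["Tmin"])
            worse = RadiationModelFit(model_id=model_id, a=fit.a * 1.1,
                                      b=fit.b * 1.1, c=fit.c * 1.1)
            pred = predict_radiation(worse, frame["Re"], S=frame["S"],
                                     S0=frame["S0"], Tmax=frame["Tmax"],
                                     Tmin=frame["Tmin"])
            m = fit_metrics(frame["Ra_obs"], pred)
            assert fit.metrics.rmse <= m.rmse + 1e-9

    def test_nested_ogelman_never_worse_than_angstrom(self, frame):
        fa = calibrate_model("angstrom", frame["Ra_obs"], frame["Re"],
                             S=frame["S"], S0=frame["S0"])
        fo = calibrate_model("ogelman", frame["Ra_obs"], frame["Re"],
                             S=frame["S"], S0=frame["S0"])
        assert fo.metrics.rmse <= fa.metrics.rmse + 1e-9

    def test_sunshine_models_beat_temperature_models(self, frame):
        rmse = {}
        for model_id in ("angstrom", "bristow", "hargreaves"):
            fit = calibrate_model(model_id, frame["Ra_obs"], frame["Re"],
                                  S=frame["S"], S0=frame["S0"],
                                  Tmax=frame["Tmax"], Tmin=frame["Tmin"])
            rmse[model_id] = fit.metrics.rmse
        assert rmse["angstrom"] < rmse["bristow"]
        assert rmse["angstrom"] < rmse["hargreaves"]


class TestPruning:
    def _table(self, rng, corr_spec):
        n = 2000
        base = rng.standard_normal(n)
        cols = {}
        for name, r in corr_spec.items():
            noise = rng.standard_normal(n)
            cols[name] = r * base + np.sqrt(max(1 - r**2, 0)) * noise
        return pd.DataFrame(cols)

    def test_pair_above_threshold_keeps_one(self):
        rng = np.random.default_rng(0)
        t = self._table(rng, {"x1": 0.97, "x2": 0.97})
        fs = prune_features(t, priority=("x1", "x2"), forced=())
        assert fs.names == ("x1",) and fs.dropped == ("x2",)

    def test_all_below_threshold_keeps_all(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.standard_normal((500, 4)),
                         columns=["p", "q", "r", "s"])
        fs = prune_features(t, forced=())
        assert set(fs.names) == {"p", "q", "r", "s"}

    def test_temperature_cluster_resolved_to_ta(self):
        """Ta highly correlated with Tmax, Tmin and e: the cluster keeps
        only Ta (brute-force greedy pruning on the correlation matrix)."""
        rng = np.random.default_rng(2)
        t = self._table(rng, {"Ta": 1.0, "Tmax": 0.95, "Tmin": 0.92,
                              "e": 0.9, "cloudiness": 0.1})
        fs = prune_features(t)
        assert "Ta" in fs.names and "cloudiness" in fs.names
        assert set(fs.dropped) == {"Tmax", "Tmin", "e"}

    def test_sunshine_trio_always_retained(self):
        rng = np.random.default_rng(3)
        n = 1000
        s = rng.standard_normal(n)
        t = pd.DataFrame({"Re": s + 0.01 * rng.standard_normal(n),
                          "S": s, "S0": s + 0.01 * rng.standard_normal(n),
                          "Ta": rng.standard_normal(n)})
        fs = prune_features(t)
        assert {"Re", "S", "S0"} <= set(fs.names)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            prune_features(pd.DataFrame())


class TestMLHarness:
    def test_noise_free_linear_target_learned(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.uniform(0, 1, (400, 3)), columns=["u", "v", "w"])
        # nonnegative target: predictions are clamped at 0 by contract
        y = 3.0 * x["u"] + 2.0 * x["v"] + 0.5
        for kind in ("bp", "svm"):
            model = fit_ml_regressor(kind, x, y, seed=0)
            assert model.metrics.nse > 0.99

    def test_seeded_reproducibility(self, frame):
        table = frame[["Re", "S", "S0", "Ta"]]
        a = fit_ml_regressor("bp", table, frame["Ra_obs"], seed=1)
        b = fit_ml_regressor("bp", table, frame["Ra_obs"], seed=1)
        np.testing.assert_array_equal(a.predict(table), b.predict(table))

    def test_svm_close_to_angstrom_on_angstrom_data(self, meta, frame):
        """On data generated by a sunshine law, SVR has no real edge over
        the correctly specified empirical model."""
        from utciclim.pipeline import _split_years
        cal, val = _split_years(frame, 2 / 3)
        fit = calibrate_model("angstrom", cal["Ra_obs"], cal["Re"],
                              S=cal["S"], S0=cal["S0"])
        pred_a = predict_radiation(fit, val["Re"], S=val["S"], S0=val["S0"])
        nse_a = fit_metrics(val["Ra_obs"], pred_a).nse
        table = cal[["Re", "S", "S0", "Ta"]]
        svm = fit_ml_regressor("svm", table, cal["Ra_obs"], seed=0)
        nse_s = fit_metrics(val["Ra_obs"], svm.predict(val)).nse
        assert nse_s == pytest.approx(nse_a, abs=0.05)

    def test_unknown_kind_and_incomplete_table_raise(self, frame):
        with pytest.raises(ValueError, match="unknown"):
            fit_ml_regressor("forest", frame[["Re"]], frame["Ra_obs"])
        bad = frame[["Re", "S"]].copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_ml_regressor("svm", bad, frame["Ra_obs"])
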