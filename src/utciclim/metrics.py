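"""Model-skill metrics: Nash-Sutcliffe efficiency, MAPE, RMSE and the
observed-vs-estimated regression line.

NSE compares the squared residuals against the variance of the
observations around their mean: 1 is a perfect model, 0 means the model is
no better than always predicting the observed mean, negative values mean
worse than that.  MAPE is reported in percent; terms with a zero
observation are excluded (and counted) rather than producing infinities.
The regression slope/intercept are ordinary least squares of the
*estimated* values on the *observed* ones, so an unbiased model gives
slope 1 and intercept 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EvalMetrics", "fit_metrics"]


@dataclass(frozen=True)
class EvalMetrics:
    nse: float
    mape: float
    rmse: float
    slope: float
    intercept: float
    n: int
    #: number of MAPE terms dropped because the observation was zero
    n_mape_excluded: int = 0

    def as_dict(self) -> dict:
        return {
            "NSE": self.nse, "MAPE": self.mape, "RMSE": self.rmse,
            "Slope": self.slope, "Inter": self.intercept, "n": self.n,
        }


def fit_metrics(observed, estimated) -> EvalMetrics:
    """Score ``estimated`` against ``observed`` (aligned 1-d sequences)."""
    o = np.asarray(observed, dtype=float)
    s = np.asarray(estimated, dtype=float)
    if o.shape != s.shape:
        raise ValueError(f"length mismatch: observed {o.shape} vs estimated {s.shape}")
    if o.size < 2:
        raise ValueError("need at least 2 paired values")
    denom = np.sum((o - o.mean()) ** 2)
    if denom == 0.0:
        raise ValueError("constant observations: NSE undefined")
    sq = (o - s) ** 2
    nse = 1.0 - np.sum(sq) / denom
    rmse = float(np.sqrt(sq.mean()))
    nonzero = o != 0.0
    n_excl = int((~nonzero).sum())
    if nonzero.any():
        mape = float(np.mean(np.abs((o[nonzero] - s[nonzero]) / o[nonzero])) * 100.0)
    else:
        mape = float("nan")
    reg = stats.linregress(o, s)
    return EvalMetrics(
        nse=float(nse), mape=mape, rmse=rmse,
        slope=float(reg.slope), intercept=float(reg.intercept),
        n=int(o.size), n_mape_excluded=n_excl,
    )
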