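"""Per-team score-series extrapolation baselines.

Five methods predict a team's score on task t from its own series alone:

* ``mean_oracle`` — non-causal reference: the mean over the *entire* series,
  observed and future alike;
* ``observed_mean`` — mean of the scores observed so far;
* ``naive`` — the immediately preceding score;
* ``least_squares`` — a least-squares line through the observed series,
  evaluated at t;
* ``arma`` — one-step-ahead mean forecast of an ARMA(1,1) model fitted by
  maximum likelihood.

Methods that need history fall back when it is too short: least squares needs
2 observations, ARMA needs 4 for a stable ML fit (or any fit failure), both
falling back to the observed mean; an empty history falls back to the
uninformative prior 0.5.  Forecasts are clipped to [0, 1] since scores are
bounded (clipping is logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ScoreTable
from .model import evaluate_rmse

logger = logging.getLogger(__name__)

__all__ = ["ForecastMethod", "METHODS", "forecast", "rmse_by_task"]


@dataclass(frozen=True)
class ForecastMethod:
    name: str
    min_history: int
    fallback: str | None  # method name used when history is too short

    def __post_init__(self) -> None:
        if self.min_history > 1 and self.fallback is None:
            raise ValueError(f"{self.name}: fallback required when min_history > 1")


METHODS: dict[str, ForecastMethod] = {
    m.name: m
    for m in (
        ForecastMethod("mean_oracle", 0, None),
        ForecastMethod("observed_mean", 0, None),
        ForecastMethod("naive", 1, "observed_mean"),
        ForecastMethod("least_squares", 2, "observed_mean"),
        ForecastMethod("arma", 4, "observed_mean"),
    )
}


def _clip(value: float, method: str) -> float:
    if value < 0.0 or value > 1.0:
        logger.debug("%s forecast %.4f clipped to [0, 1]", method, value)
    return float(np.clip(value, 0.0, 1.0))


def _arma_forecast(history: np.ndarray) -> float:
    from statsmodels.tsa.arima.model import ARIMA

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ARIMA(history, order=(1, 0, 1), trend="c").fit()
        value = float(fit.forecast(1)[0])
    if not np.isfinite(value):
        raise ValueError("non-finite ARMA forecast")
    return value


def forecast(
    method: str,
    history: Sequence[float],
    t: int | None = None,
    full_series: Sequence[float] | None = None,
) -> float:
    """Predict the score on task ``t`` from the observed ``history`` s(1..t-1).

    ``t`` defaults to len(history) + 1 (the next task).  ``mean_oracle``
    ignores the prefix and requires ``full_series``.  Forecasts are clipped
    to [0, 1].
    """
    if method not in METHODS:
        raise ValueError(f"unknown forecast method {method!r}")
    h = np.asarray(history, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("history contains non-finite values")
    if t is None:
        t = len(h) + 1

    if method == "mean_oracle":
        if full_series is None:
            raise ValueError("mean_oracle needs the full score series")
        full = np.asarray(full_series, dtype=float)
        if not np.all(np.isfinite(full)):
            raise ValueError("full series contains non-finite values")
        return _clip(full.mean(), method)

    spec = METHODS[method]
    if len(h) < spec.min_history:
        if spec.fallback is not None:
            return forecast(spec.fallback, h, t)
        return 0.5  # uninformative prior on an empty history
    if method == "observed_mean":
        return _clip(h.mean(), method) if len(h) else 0.5
    if method == "naive":
        return _clip(h[-1], method)
    if method == "least_squares":
        x = np.arange(1, len(h) + 1, dtype=float)
        slope, intercept = np.polyfit(x, h, 1)
        return _clip(intercept + slope * t, method)
    # arma
    try:
        return _clip(_arma_forecast(h), method)
    except Exception:
        logger.debug("ARMA fit failed on history of length %d; falling back", len(h))
        return forecast("observed_mean", h, t)


def rmse_by_task(
    method: str,
    table: ScoreTable,
    start_task: int = 4,
) -> pd.Series:
    """Per-task RMSE of a forecast method across teams.

    Tasks are 1-based; tasks before ``start_task`` have no prediction (NaN),
    matching protocols where the first three tasks only seed the history.
    Teams with missing scores in the prefix or the target are skipped for
    that task.
    """
    if method not in METHODS:
        raise ValueError(f"unknown forecast method {method!r}")
    out = pd.Series(np.nan, index=table.task_ids, dtype=float)
    for t in range(start_task, table.n_tasks + 1):
        preds, truths = [], []
        for i in range(table.n_teams):
            series = table.scores[i]
            prefix = series[: t - 1]
            if not (np.all(np.isfinite(prefix)) and np.isfinite(series[t - 1])):
                continue
            if method == "mean_oracle" and not np.all(np.isfinite(series)):
                continue
            preds.append(forecast(method, prefix, t, full_series=series))
            truths.append(series[t - 1])
        if preds:
            out.iloc[t - 1] = evaluate_rmse(np.array(preds), np.array(truths))
    return out
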