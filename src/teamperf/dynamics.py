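"""Features of the historical dynamics of a team's score series.

When predicting a team's score on task t, only the scores on tasks 1..t-1
have been observed.  This module condenses such a prefix into a fixed set of
descriptive statistics: raw endpoints and moments, the least-squares trend
line through the series, and counts of score movements.  Together they
capture the level, consistency and direction of a team's performance so far —
e.g. high-performing teams tend to start high and stay flat, while
low-performing teams start low with a positive trend.

Conventions (fixed and documented, since names alone don't pin them down):
standard deviation and variance use the sample (n-1) divisor; skewness is the
adjusted Fisher-Pearson estimator; kurtosis is excess kurtosis (also
bias-adjusted).  A constant series has zero spread and undefined (NaN)
skewness and kurtosis.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ScoreTable

__all__ = ["DYNAMICS_FEATURE_NAMES", "dynamics_features", "dynamics_feature_table"]

_TIE_TOL = 1e-9

DYNAMICS_FEATURE_NAMES = (
    "first",
    "last",
    "mean",
    "median",
    "std",
    "var",
    "skewness",
    "kurtosis",
    "fit_first",
    "fit_mid",
    "fit_last",
    "fit_slope_rad",
    "fit_last_minus_first",
    "n_increases",
    "n_decreases",
    "n_changes_above_median",
    "n_changes_below_median",
)


def dynamics_features(prefix: Sequence[float]) -> dict[str, float]:
    """Extract the dynamics feature set from an observed score prefix.

    The prefix must hold at least 3 scores (prediction starts from the fourth
    task).  The trend line is a least-squares fit against the task index
    1..len(prefix); ``fit_mid`` is the line's value at the middle abscissa
    (1 + len)/2, which may be fractional for even-length prefixes, and
    ``fit_slope_rad`` is atan(slope) so steepness is bounded.  Score changes
    exactly equal to the median change count as neither above nor below.
    """
    s = np.asarray(prefix, dtype=float)
    if s.ndim != 1 or len(s) < 3:
        raise ValueError("score prefix must be 1-D with at least 3 observed scores")
    if not np.all(np.isfinite(s)):
        raise ValueError("score prefix contains non-finite values")

    n = len(s)
    x = np.arange(1, n + 1, dtype=float)
    slope, intercept = np.polyfit(x, s, 1)

    if s.std() > 0:
        with warnings.catch_warnings():
            # near-constant prefixes trigger a precision warning; the values
            # are still the documented estimators
            warnings.simplefilter("ignore", RuntimeWarning)
            skew = float(stats.skew(s, bias=False))
            kurt = float(stats.kurtosis(s, fisher=True, bias=False))
    else:
        skew = kurt = float("nan")

    d = np.diff(s)
    med_change = float(np.median(d))
    fit_first = float(intercept + slope * 1.0)
    fit_last = float(intercept + slope * n)

    return {
        "first": float(s[0]),
        "last": float(s[-1]),
        "mean": float(s.mean()),
        "median": float(np.median(s)),
        "std": float(s.std(ddof=1)),
        "var": float(s.var(ddof=1)),
        "skewness": skew,
        "kurtosis": kurt,
        "fit_first": fit_first,
        "fit_mid": float(intercept + slope * (1.0 + n) / 2.0),
        "fit_last": fit_last,
        "fit_slope_rad": float(math.atan(slope)),
        "fit_last_minus_first": fit_last - fit_first,
        "n_increases": float(np.sum(d > 0)),
        "n_decreases": float(np.sum(d < 0)),
        # ties with the median change count as neither; the tolerance absorbs
        # floating-point noise in the differencing
        "n_changes_above_median": float(np.sum(d > med_change + _TIE_TOL)),
        "n_changes_below_median": float(np.sum(d < med_change - _TIE_TOL)),
    }


def dynamics_feature_table(table: ScoreTable, target_task: int) -> pd.DataFrame:
    """Dynamics features for every team, using only tasks before ``target_task``.

    ``target_task`` is 1-based; the prefix is columns 1..target_task-1, so the
    earliest valid target is task 4.  Teams with any missing prefix score get
    a NaN row.
    """
    if target_task < 4 or target_task > table.n_tasks + 1:
        raise ValueError(
            f"target_task must be in [4, {table.n_tasks + 1}], got {target_task}"
        )
    rows = {}
    for i, team in enumerate(table.team_ids):
        prefix = table.scores[i, : target_task - 1]
        if np.all(np.isfinite(prefix)):
            rows[team] = dynamics_features(prefix)
        else:
            rows[team] = {name: float("nan") for name in DYNAMICS_FEATURE_NAMES}
    return pd.DataFrame.from_dict(rows, orient="index")[list(DYNAMICS_FEATURE_NAMES)]
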