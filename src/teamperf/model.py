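"""Correlation screening and elastic-net regression of team performance.

The modeling recipe has two stages.  First, Pearson correlations between
features and task scores are screened, with p-values corrected by the
Benjamini-Hochberg step-up at a 10% false discovery rate and an additional
p < 0.05 display threshold.  Second, per task, an elastic net

    beta_hat = argmin ||y - X beta||^2 + lam1 ||beta||_1 + lam2 ||beta||^2

is fitted over a grid of (lam1, lam2) on column-standardized features, and a
bespoke model-selection rule picks the winner: only models *sparse enough* —
the 6 largest |beta_j| carrying at least 80% of the total sum of |beta_j| —
are eligible, and among those the one with the lowest 10-fold
cross-validation RMSE (pooled out-of-fold predictions) wins.  If nothing
eligible and non-degenerate remains, a degenerate model predicting the mean
score is returned.

Note the penalty is on the raw residual sum of squares (no 1/(2n) scaling);
the scikit-learn solver is re-parameterized accordingly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Ridge
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ElasticNetModel",
    "ScreeningReport",
    "pearson_screen",
    "fit_elastic_net",
    "elastic_net_objective",
    "select_model",
    "evaluate_rmse",
    "default_lambda_grid",
    "small_lambda_grid",
    "DEGENERATE_TOL",
]

DEGENERATE_TOL = 1e-6
#: Sparsity rule: the top TOP_K |coefficients| must carry at least MIN_SHARE
#: of the model's total coefficient weight.
TOP_K = 6
MIN_SHARE = 0.8


@dataclass
class ElasticNetModel:
    """A fitted elastic-net model on standardized features.

    ``coefficients`` are per standardized feature; ``intercept`` equals the
    training-response mean (features are centered).  When ``feature_means``
    / ``feature_stds`` are set, ``predict`` standardizes raw inputs with
    them, making the model self-contained.
    """

    coefficients: pd.Series
    intercept: float
    lam1: float
    lam2: float
    cv_rmse: float = float("nan")
    feature_means: pd.Series | None = None
    feature_stds: pd.Series | None = None

    @property
    def degenerate(self) -> bool:
        return bool((self.coefficients.abs() < DEGENERATE_TOL).all())

    def top_weight_share(self, k: int = TOP_K) -> float:
        """Share of total |beta| carried by the k largest coefficients (1.0
        for an all-zero model)."""
        magnitudes = np.sort(self.coefficients.abs().to_numpy())[::-1]
        total = magnitudes.sum()
        if total == 0:
            return 1.0
        return float(magnitudes[:k].sum() / total)

    def is_sparse_enough(self, k: int = TOP_K, min_share: float = MIN_SHARE) -> bool:
        return self.top_weight_share(k) >= min_share

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.coefficients.index]
        Z = np.asarray(X, dtype=float)
        if self.feature_means is not None:
            Z = (Z - self.feature_means.to_numpy()) / self.feature_stds.to_numpy()
        return Z @ self.coefficients.to_numpy() + self.intercept

    def to_json(self, path) -> None:
        payload = {
            "coefficients": self.coefficients.to_dict(),
            "intercept": self.intercept,
            "lam1": self.lam1,
            "lam2": self.lam2,
            "cv_rmse": self.cv_rmse,
            "degenerate": self.degenerate,
            "feature_means": None if self.feature_means is None else self.feature_means.to_dict(),
            "feature_stds": None if self.feature_stds is None else self.feature_stds.to_dict(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ElasticNetModel":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            coefficients=pd.Series(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            lam1=float(payload["lam1"]),
            lam2=float(payload["lam2"]),
            cv_rmse=float(payload["cv_rmse"]),
            feature_means=None if payload["feature_means"] is None
            else pd.Series(payload["feature_means"], dtype=float),
            feature_stds=None if payload["feature_stds"] is None
            else pd.Series(payload["feature_stds"], dtype=float),
        )


@dataclass
class ScreeningReport:
    """Pearson screening of features against targets with BH correction.

    All frames are features × targets.  ``bh_significant`` applies the
    Benjamini-Hochberg step-up at FDR ``q`` over every tested pair jointly;
    ``reported`` additionally requires the raw p-value below ``p_display``
    (the display threshold used alongside the FDR correction).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    bh_significant: pd.DataFrame
    reported: pd.DataFrame
    q: float
    p_display: float


def benjamini_hochberg(p_values: np.ndarray, q: float) -> np.ndarray:
    """BH step-up: boolean rejection mask at FDR level q (NaNs never rejected)."""
    p = np.asarray(p_values, dtype=float)
    mask = np.isfinite(p)
    out = np.zeros(p.shape, dtype=bool)
    if mask.sum():
        rejected, *_ = multipletests(p[mask], alpha=q, method="fdr_bh")
        out[mask] = rejected
    return out


def pearson_screen(
    X: pd.DataFrame,
    y: pd.DataFrame | pd.Series,
    q: float = 0.10,
    p_display: float = 0.05,
) -> ScreeningReport:
    """Correlate every feature with every target and correct for multiplicity.

    Pairs with fewer than 3 complete observations or a zero-variance side
    get a missing correlation (never tested).  The BH correction is applied
    jointly across all tested (feature, target) pairs.
    """
    targets = y.to_frame() if isinstance(y, pd.Series) else y
    r = pd.DataFrame(index=X.columns, columns=targets.columns, dtype=float)
    p = pd.DataFrame(index=X.columns, columns=targets.columns, dtype=float)
    for feat in X.columns:
        for target in targets.columns:
            xv = X[feat].to_numpy(dtype=float)
            yv = targets[target].reindex(X.index).to_numpy(dtype=float)
            ok = np.isfinite(xv) & np.isfinite(yv)
            if ok.sum() < 3 or np.std(xv[ok]) == 0 or np.std(yv[ok]) == 0:
                continue
            rr, pp = stats.pearsonr(xv[ok], yv[ok])
            r.loc[feat, target] = rr
            p.loc[feat, target] = pp
    flat = p.to_numpy().ravel()
    rejected = benjamini_hochberg(flat, q).reshape(p.shape)
    bh = pd.DataFrame(rejected, index=p.index, columns=p.columns)
    reported = bh & (p < p_display)
    return ScreeningReport(r=r, p=p, bh_significant=bh, reported=reported, q=q, p_display=p_display)


def elastic_net_objective(X: np.ndarray, y_centered: np.ndarray, beta: np.ndarray,
                          lam1: float, lam2: float) -> float:
    """||y - X beta||^2 + lam1 ||beta||_1 + lam2 ||beta||^2 (no 1/2n scaling)."""
    resid = y_centered - X @ beta
    return float(resid @ resid + lam1 * np.abs(beta).sum() + lam2 * beta @ beta)


def fit_elastic_net(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    lam1: float,
    lam2: float,
) -> ElasticNetModel:
    """Fit the elastic net at fixed penalties on pre-standardized features.

    The response is centered and the intercept set to mean(y).  The
    unpenalized limit reduces to ordinary least squares; the pure-ridge limit
    uses the closed-form normal equations via scikit-learn's Ridge.
    """
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be non-negative")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    Z = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(yv))):
        raise ValueError("non-finite entries in design matrix or response")
    n = Z.shape[0]
    intercept = float(yv.mean())
    yc = yv - intercept

    if lam1 == 0 and lam2 == 0:
        beta, *_ = np.linalg.lstsq(Z, yc, rcond=None)
    elif lam1 == 0:
        # sklearn Ridge minimizes ||y - Xb||^2 + alpha ||b||^2 exactly
        beta = Ridge(alpha=lam2, fit_intercept=False).fit(Z, yc).coef_
    else:
        # sklearn ElasticNet minimizes
        #   1/(2n) ||y - Xb||^2 + a * l1 * ||b||_1 + a/2 * (1 - l1) * ||b||^2
        # so lam1 = 2 n a l1 and lam2 = n a (1 - l1).
        alpha = lam1 / (2 * n) + lam2 / n
        l1_ratio = (lam1 / (2 * n)) / alpha
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = ElasticNet(
                alpha=alpha, l1_ratio=l1_ratio, fit_intercept=False,
                max_iter=20_000, tol=1e-8,
            ).fit(Z, yc)
        beta = est.coef_
    return ElasticNetModel(
        coefficients=pd.Series(np.asarray(beta, dtype=float), index=names),
        intercept=intercept, lam1=lam1, lam2=lam2,
    )


def default_lambda_grid(n_magnitudes: int = 20) -> list[tuple[float, float]]:
    """Mixing ratios lam1:lam2 in {100:0, 75:25, 50:50, 25:75, 0:100} crossed
    with total penalty magnitudes on a log grid 1e-3..1e1."""
    mixes = [(1.0, 0.0), (0.75, 0.25), (0.5, 0.5), (0.25, 0.75), (0.0, 1.0)]
    totals = np.logspace(-3, 1, n_magnitudes)
    return [(m1 * t, m2 * t) for t in totals for (m1, m2) in mixes]


def small_lambda_grid(n_magnitudes: int = 8) -> list[tuple[float, float]]:
    """Reduced grid (LASSO-dominant 75:25 mix only) for inner loops such as
    repeated policy simulation, where a full sweep per task is wasteful."""
    totals = np.logspace(-3, 1, n_magnitudes)
    return [(0.75 * t, 0.25 * t) for t in totals]


def _standardize(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)  # constant columns become all-zero
    return (Z - mu) / sd_safe, mu, sd_safe


def select_model(
    X: pd.DataFrame,
    y: np.ndarray,
    lambda_grid: list[tuple[float, float]] | None = None,
    k: int = 10,
    seed: int = 0,
    top_k: int = TOP_K,
    min_share: float = MIN_SHARE,
) -> ElasticNetModel:
    """Grid-search the penalties under the sparsity filter and CV-RMSE rule.

    For each (lam1, lam2): the sparsity filter is judged on the full-data fit
    (top ``top_k`` |beta| must carry >= ``min_share`` of total |beta|), while
    the score is the RMSE of pooled out-of-fold predictions from k-fold CV
    with a seed-fixed fold assignment; standardization statistics are
    recomputed on each training fold.  The eligible model with the lowest CV
    RMSE wins; if none is eligible, or the winner has all-zero coefficients,
    a degenerate model predicting mean(y) is returned.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    if not lambda_grid:
        raise ValueError("empty lambda grid")
    yv = np.asarray(y, dtype=float)
    if len(X) < k:
        raise ValueError(f"need at least k={k} samples, got {len(X)}")
    Zraw = X.to_numpy(dtype=float)
    if not (np.all(np.isfinite(Zraw)) and np.all(np.isfinite(yv))):
        raise ValueError("non-finite entries in design matrix or response")

    Zfull, mu, sd = _standardize(Zraw)
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(Zraw))

    def oof_rmse(lam1: float, lam2: float) -> float:
        preds = np.empty_like(yv)
        for train, test in folds:
            Ztr, mtr, str_ = _standardize(Zraw[train])
            sub = fit_elastic_net(
                pd.DataFrame(Ztr, columns=X.columns), yv[train], lam1, lam2)
            Zte = (Zraw[test] - mtr) / str_
            preds[test] = Zte @ sub.coefficients.to_numpy() + sub.intercept
        return evaluate_rmse(preds, yv)

    best: ElasticNetModel | None = None
    for lam1, lam2 in lambda_grid:
        full = fit_elastic_net(pd.DataFrame(Zfull, columns=X.columns), yv, lam1, lam2)
        if not full.is_sparse_enough(top_k, min_share):
            continue
        full.cv_rmse = oof_rmse(lam1, lam2)
        if best is None or full.cv_rmse < best.cv_rmse:
            best = full

    if best is None or best.degenerate:
        best = _degenerate_model(X, yv, folds)
    best.feature_means = pd.Series(mu, index=X.columns)
    best.feature_stds = pd.Series(sd, index=X.columns)
    return best


def _degenerate_model(X: pd.DataFrame, yv: np.ndarray, folds) -> ElasticNetModel:
    """All-zero model predicting the mean score, with an honest OOF RMSE."""
    preds = np.empty_like(yv)
    for train, test in folds:
        preds[test] = yv[train].mean()
    return ElasticNetModel(
        coefficients=pd.Series(np.zeros(X.shape[1]), index=X.columns),
        intercept=float(yv.mean()), lam1=0.0, lam2=0.0,
        cv_rmse=evaluate_rmse(preds, yv),
    )


def evaluate_rmse(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Root mean square error; raises on length mismatch."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("empty prediction vector")
    return float(np.sqrt(np.mean((p - t) ** 2)))
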