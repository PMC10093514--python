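"""PLSR modeling, leave-one-out latent-variable selection, and metrics.

PLS1 is implemented as NIPALS on mean-centered X and y with no variance
scaling (reflectance bands share units): per component, the weight
vector is X'y normalized, scores t = Xw, X and y are deflated by the
loading/score regression, and the regression coefficient vector is
recovered as B = W (P'W)^{-1} q.  The latent-variable count is selected
by leave-one-out cross-validation on the calibration set only, at the
minimum RMSE_cv (ties toward fewer components).

Model quality is reported as R^2 = 1 - SS_res/SS_tot (about each set's
own mean), RMSE, and RPD = SD(validation y) / RMSE_v with the population
SD convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSRModel",
    "CVCurve",
    "ModelReport",
    "fit_plsr",
    "predict",
    "loocv_curve",
    "choose_lv",
    "evaluate",
    "rmse",
    "r2_score",
    "rpd",
    "coefficient_of_variation",
]

_RESIDUAL_TOL = 1e-12  # relative residual norm at which deflation stops


# ---------------------------------------------------------------- metrics

def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r2_score(y_true: np.ndarray, y_pred: np.ndarray, kind: str = "explained_variance") -> float:
    """R^2 of predictions.

    ``explained_variance`` (default): 1 - SS_res/SS_tot about the set's
    own mean.  ``squared_correlation``: squared Pearson r between
    observed and predicted (sensitivity-check variant).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if kind == "explained_variance":
        ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
        if ss_tot == 0.0:
            raise ValueError("y has zero variance; R^2 undefined")
        return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    if kind == "squared_correlation":
        return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    raise ValueError(f"unknown R^2 kind {kind!r}")


def rpd(sd: float, rmse_value: float) -> float:
    """Relative analysis error: SD of reference values over RMSE."""
    return sd / rmse_value


def coefficient_of_variation(sd: float, mean: float) -> float:
    return sd / mean


# ------------------------------------------------------------------ PLSR

@dataclass
class PLSRModel:
    """Centered NIPALS PLS1 solution at a fixed number of latent variables."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, k) column-normalized weight vectors
    loadings: np.ndarray  # (p, k) X loadings
    q: np.ndarray  # (k,) y loadings
    coef: np.ndarray  # (p,) regression vector over bands
    n_lv: int
    fitted: np.ndarray  # fitted calibration values


@dataclass
class CVCurve:
    """RMSE_cv per latent-variable count 1..max_lv and the chosen count."""

    rmse_cv: np.ndarray
    chosen_lv: int = field(default=0)

    def __post_init__(self) -> None:
        self.rmse_cv = np.asarray(self.rmse_cv, dtype=float)
        if self.chosen_lv == 0:
            self.chosen_lv = choose_lv(self.rmse_cv)


@dataclass
class ModelReport:
    """Calibration/validation accuracy of one transform's model."""

    transform_tag: str
    analyte: str
    r2_c: float
    rmse_c: float
    r2_v: float
    rmse_v: float
    rpd: float  # NaN when undefined (zero validation variance or RMSE)
    n_lv: int
    cv_curve: CVCurve | None = None
    n_cal: int = 0
    n_val: int = 0


def choose_lv(rmse_cv: np.ndarray) -> int:
    """argmin of the CV curve, 1-based; ties toward the smaller count."""
    return int(np.argmin(rmse_cv)) + 1


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_lv: int, strict: bool = True):
    """Core NIPALS PLS1 on centered copies; returns (W, P, q, k_reached)."""
    n, p = X.shape
    Xd = X.copy()
    yd = y.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    y0_norm = float(np.linalg.norm(y)) or 1.0
    k_reached = 0
    for k in range(n_lv):
        w = Xd.T @ yd
        nw = float(np.linalg.norm(w))
        if nw <= _RESIDUAL_TOL * y0_norm or float(np.linalg.norm(yd)) <= _RESIDUAL_TOL * y0_norm:
            if strict:
                raise ValueError(
                    f"residual vanished after {k} components; {n_lv} unreachable"
                )
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _RESIDUAL_TOL:
            if strict:
                raise ValueError(
                    f"degenerate score at component {k + 1}; {n_lv} unreachable"
                )
            break
        pk = Xd.T @ t / tt
        qk = float(yd @ t) / tt
        Xd -= np.outer(t, pk)
        yd = yd - qk * t
        W[:, k] = w
        P[:, k] = pk
        q[k] = qk
        k_reached = k + 1
    return W[:, :k_reached], P[:, :k_reached], q[:k_reached], k_reached


def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSRModel:
    """NIPALS PLS1 on mean-centered X and y (no variance scaling)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y must align with X rows")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must lie in [1, {min(n - 1, p)}]")
    if float(np.std(y)) == 0.0:
        raise ValueError("y has zero variance; PLSR undefined")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, k = _nipals_pls1(X - x_mean, y - y_mean, n_lv, strict=True)
    coef = W @ np.linalg.solve(P.T @ W, q)
    fitted = y_mean + (X - x_mean) @ coef
    return PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        q=q,
        coef=coef,
        n_lv=k,
        fitted=fitted,
    )


def predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return model.y_mean + (X - model.x_mean) @ model.coef


def _predictions_by_lv(
    x_mean: np.ndarray, y_mean: float, W: np.ndarray, P: np.ndarray, q: np.ndarray,
    X: np.ndarray,
) -> np.ndarray:
    """Predictions at every component count 1..k, shape (n, k)."""
    Xd = X - x_mean
    n, k = X.shape[0], W.shape[1]
    preds = np.empty((n, k))
    acc = np.full(n, y_mean)
    for j in range(k):
        t = Xd @ W[:, j]
        acc = acc + q[j] * t
        Xd = Xd - np.outer(t, P[:, j])
        preds[:, j] = acc
    return preds


def loocv_curve(X: np.ndarray, y: np.ndarray, max_lv: int = 20) -> CVCurve:
    """Leave-one-out RMSE_cv for component counts 1..max_lv.

    Each left-out sample is predicted by a model refit on the remaining
    samples; one NIPALS pass per fold yields the nested predictions at
    every component count.  An infeasible max_lv is lowered with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    feasible = min(n - 2, p)  # n-1 training samples support n-2 components
    if max_lv > feasible:
        warnings.warn(
            f"max_lv={max_lv} infeasible for n={n}; lowered to {feasible}",
            stacklevel=2,
        )
        max_lv = feasible
    if max_lv < 1:
        raise ValueError("too few samples for leave-one-out cross-validation")
    preds = np.empty((n, max_lv))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xt, yt = X[keep], y[keep]
        x_mean = Xt.mean(axis=0)
        y_mean = float(yt.mean())
        W, P, q, k = _nipals_pls1(Xt - x_mean, yt - y_mean, max_lv, strict=False)
        row = _predictions_by_lv(x_mean, y_mean, W, P, q, X[i : i + 1])[0]
        if k < max_lv:  # residual vanished early: prediction frozen beyond k
            row = np.concatenate([row, np.full(max_lv - k, row[-1] if k else y_mean)])
        preds[i] = row
    curve = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return CVCurve(rmse_cv=curve)


def evaluate(
    model: PLSRModel,
    X_c: np.ndarray,
    y_c: np.ndarray,
    X_v: np.ndarray,
    y_v: np.ndarray,
    transform_tag: str = "",
    analyte: str = "",
    cv_curve: CVCurve | None = None,
    r2_kind: str = "explained_variance",
) -> ModelReport:
    """Calibration and validation metrics for a fitted model."""
    y_v = np.asarray(y_v, dtype=float)
    if y_v.size < 3:
        raise ValueError("validation set needs at least 3 samples")
    pred_c = predict(model, X_c)
    pred_v = predict(model, X_v)
    rmse_c = rmse(y_c, pred_c)
    rmse_v = rmse(y_v, pred_v)
    sd_v = float(y_v.std(ddof=0))
    # rmse at float-roundoff level counts as zero: RPD would be meaningless
    if sd_v == 0.0 or rmse_v < 1e-10 * max(sd_v, abs(float(y_v.mean())), 1e-300):
        warnings.warn("RPD undefined (zero validation SD or RMSE); reported missing",
                      stacklevel=2)
        rpd_v = float("nan")
    else:
        rpd_v = rpd(sd_v, rmse_v)
    return ModelReport(
        transform_tag=transform_tag,
        analyte=analyte,
        r2_c=r2_score(y_c, pred_c, kind=r2_kind),
        rmse_c=rmse_c,
        r2_v=r2_score(y_v, pred_v, kind=r2_kind),
        rmse_v=rmse_v,
        rpd=rpd_v,
        n_lv=model.n_lv,
        cv_curve=cv_curve,
        n_cal=int(np.asarray(y_c).size),
        n_val=int(y_v.size),
    )
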