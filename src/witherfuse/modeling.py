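"""Dataset splitting, SVR calibration and regression metrics.

The moisture model is an epsilon-SVR with RBF kernel, tuned on a
log2-spaced (c, g) grid by cross-validated RMSE on the calibration
set.  Performance is reported the way NIR calibration studies report
it: Pearson correlations of measured vs predicted MC on the
calibration (Rc) and prediction (Rp) sets, the corresponding RMSEC /
RMSEP, and RPD = sd(prediction-set reference MC) / RMSEP, where an RPD
above ~3 marks a reliable calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = [
    "SplitIndices",
    "SVRParams",
    "RegressionMetrics",
    "split_dataset",
    "default_svr_grid",
    "grid_search_svr",
    "train_predict_svr",
    "evaluate_metrics",
]


@dataclass
class SplitIndices:
    calibration: np.ndarray
    prediction: np.ndarray
    ratio: float
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.calibration = np.asarray(self.calibration, dtype=int)
        self.prediction = np.asarray(self.prediction, dtype=int)
        if np.intersect1d(self.calibration, self.prediction).size:
            raise ValueError("calibration and prediction sets overlap")


@dataclass(frozen=True)
class SVRParams:
    """libsvm-style epsilon-SVR hyperparameters: cost c, RBF width g."""

    c: float
    g: float
    epsilon: float = 0.01
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.c <= 0 or self.g <= 0 or self.epsilon < 0:
            raise ValueError("need c > 0, g > 0, epsilon >= 0")


@dataclass
class RegressionMetrics:
    rc: float
    rmsec: float
    rp: float
    rmsep: float
    rpd: float
    params: SVRParams | None = None
    n_variables: int | None = None

    def as_row(self) -> dict:
        return {
            "n_variables": self.n_variables,
            "c": None if self.params is None else self.params.c,
            "g": None if self.params is None else self.params.g,
            "Rc": self.rc,
            "RMSEC": self.rmsec,
            "Rp": self.rp,
            "RMSEP": self.rmsep,
            "RPD": self.rpd,
        }


def split_dataset(
    n_samples: int,
    strata: np.ndarray | None = None,
    ratio: float = 0.75,
    method: str = "stratified",
    seed: int = 0,
) -> SplitIndices:
    """3:1 calibration/prediction split.

    ``stratified`` (default): a seeded random draw allocating
    round(ratio * n) samples to calibration, proportionally per stratum
    (withering hour) with largest-remainder rounding so every stratum
    appears in both sets where possible.  A singleton stratum goes to
    calibration with a warning.  ``interleaved``: a rank-order
    alternative that sends every fourth sample (by stratum order) to
    prediction, for split-sensitivity checks.
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples to split")
    n_cal = int(round(ratio * n_samples))
    if strata is None:
        strata = np.zeros(n_samples, dtype=int)
    strata = np.asarray(strata)
    order_keys = np.unique(strata)

    if method == "interleaved":
        idx = np.lexsort((np.arange(n_samples), strata))
        pred = idx[3::4][: n_samples - n_cal]
        cal = np.setdiff1d(idx, pred)
        return SplitIndices(cal, pred, ratio, method, seed)
    if method != "stratified":
        raise ValueError(f"unknown split method {method!r}")

    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(strata == k) for k in order_keys]
    quota = np.array([ratio * g.size for g in groups])
    base = np.floor(quota).astype(int)
    # largest-remainder allocation to hit n_cal exactly
    short = n_cal - base.sum()
    remainders = quota - base
    for k in np.lexsort((np.arange(len(groups)), -remainders))[: max(0, short)]:
        base[k] += 1
    cal_parts, pred_parts = [], []
    for g, b in zip(groups, base):
        if g.size == 1:
            warnings.warn("singleton stratum assigned to calibration", stacklevel=2)
            cal_parts.append(g)
            continue
        b = min(max(b, 1), g.size - 1) if g.size > 1 else b
        perm = rng.permutation(g)
        cal_parts.append(perm[:b])
        pred_parts.append(perm[b:])
    cal = np.sort(np.concatenate(cal_parts))
    pred = np.sort(np.concatenate(pred_parts)) if pred_parts else np.array([], dtype=int)
    return SplitIndices(cal, pred, ratio, method, seed)


def default_svr_grid(log2_min: int = -8, log2_max: int = 8, step: int = 2) -> list[SVRParams]:
    """log2-spaced (c, g) grid, 2^-8 ... 2^8 by default."""
    vals = [2.0**e for e in range(log2_min, log2_max + 1, step)]
    return [SVRParams(c=c, g=g) for c in vals for g in vals]


def grid_search_svr(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    grid: list[SVRParams] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> SVRParams:
    """(c, g) pair minimizing cross-validated RMSE on the calibration set.

    Ties break toward smaller c, then smaller g.
    """
    if grid is None:
        grid = default_svr_grid()
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    kf = KFold(n_splits=min(cv_folds, y_cal.size), shuffle=True, random_state=seed)
    splits = list(kf.split(X_cal))
    best: tuple[float, float, float] | None = None
    best_params = grid[0]
    for params in grid:
        sq = 0.0
        for train, test in splits:
            model = SVR(kernel=params.kernel, C=params.c, gamma=params.g,
                        epsilon=params.epsilon)
            model.fit(X_cal[train], y_cal[train])
            sq += float(((model.predict(X_cal[test]) - y_cal[test]) ** 2).sum())
        rmse = np.sqrt(sq / y_cal.size)
        key = (rmse, params.c, params.g)
        if best is None or key < best:
            best = key
            best_params = params
    return best_params


def train_predict_svr(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_any: np.ndarray,
    params: SVRParams,
) -> np.ndarray:
    """Fit epsilon-SVR on the calibration set and predict anywhere."""
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    if np.ptp(y_cal) == 0:
        raise ValueError("constant calibration response: SVR degenerate")
    model = SVR(kernel=params.kernel, C=params.c, gamma=params.g, epsilon=params.epsilon)
    model.fit(np.asarray(X_cal, dtype=float), y_cal)
    pred = model.predict(np.asarray(X_any, dtype=float))
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("SVR produced non-finite predictions")
    return pred


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0:
        return np.nan
    return float(np.clip(ac @ bc / denom, -1.0, 1.0))


def evaluate_metrics(
    y_cal: np.ndarray,
    yhat_cal: np.ndarray,
    y_pred: np.ndarray,
    yhat_pred: np.ndarray,
    params: SVRParams | None = None,
    n_variables: int | None = None,
) -> RegressionMetrics:
    """Rc/RMSEC on the calibration set, Rp/RMSEP/RPD on the prediction set.

    RPD = sd(y_pred, ddof=1) / RMSEP; a perfect prediction set gets
    RPD = +inf with a warning.
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_cal.size < 3 or y_pred.size < 3:
        raise ValueError("need at least 3 samples per set")
    rmsec = float(np.sqrt(np.mean((np.asarray(yhat_cal).ravel() - y_cal) ** 2)))
    rmsep = float(np.sqrt(np.mean((np.asarray(yhat_pred).ravel() - y_pred) ** 2)))
    if rmsep == 0:
        warnings.warn("zero RMSEP: RPD reported as +inf", stacklevel=2)
        rpd = float("inf")
    else:
        rpd = float(np.std(y_pred, ddof=1) / rmsep)
    return RegressionMetrics(
        rc=_pearson(y_cal, yhat_cal),
        rmsec=rmsec,
        rp=_pearson(y_pred, yhat_pred),
        rmsep=rmsep,
        rpd=rpd,
        params=params,
        n_variables=n_variables,
    )
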