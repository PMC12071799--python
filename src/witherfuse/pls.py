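"""PLS1 regression engine with cross-validated RMSECV.

All three wavelength-selection algorithms score candidate variable
subsets by the cross-validated root-mean-square error of a PLS1 model,
so this engine is deliberately small and fast: a NIPALS fit that
returns regression coefficients for every latent-variable count in one
pass, and a k-fold RMSECV built on it.

With as many latent variables as the rank of the centred predictor
matrix, PLS1 coefficients coincide with the least-squares solution,
which gives the engine an exact external oracle on small full-rank
systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PLSSettings", "pls1_fit", "pls1_predict", "pls_cv_rmsecv", "rmsecv_per_lv"]


@dataclass(frozen=True)
class PLSSettings:
    """Shared PLS hyperparameters: max latent variables and CV fold count."""

    max_latent_variables: int = 10
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.max_latent_variables < 1:
            raise ValueError("max_latent_variables must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def pls1_fit(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1 fit.

    Returns ``(B, x_mean, y_mean, a_eff)`` where ``B`` is a
    (n_features, a_eff) matrix whose column a-1 holds the regression
    coefficients of the a-component model (on centred data), and
    ``a_eff <= n_components`` is the number of components actually
    extracted before the residual collapsed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xr = X - x_mean
    yc = y - y_mean
    A = max(1, min(n_components, p, n - 1))

    W = np.empty((p, A))
    P = np.empty((p, A))
    q = np.empty(A)
    a_eff = 0
    for a in range(A):
        w = Xr.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xr @ w
        tt = t @ t
        if tt < 1e-12:
            break
        p_a = Xr.T @ t / tt
        W[:, a] = w
        P[:, a] = p_a
        q[a] = (yc @ t) / tt
        Xr = Xr - np.outer(t, p_a)
        a_eff += 1
    if a_eff == 0:
        # X orthogonal to y (or constant): the best PLS model is the mean
        return np.zeros((p, 1)), x_mean, y_mean, 1

    B = np.empty((p, a_eff))
    PtW = P[:, :a_eff].T @ W[:, :a_eff]
    for a in range(1, a_eff + 1):
        r = np.linalg.solve(PtW[:a, :a], q[:a])
        B[:, a - 1] = W[:, :a] @ r
    return B, x_mean, y_mean, a_eff


def pls1_predict(X: np.ndarray, B: np.ndarray, x_mean: np.ndarray, y_mean: float) -> np.ndarray:
    """Predictions for every component count at once: (n, a_eff)."""
    return (np.asarray(X, dtype=float) - x_mean) @ B + y_mean


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    fold_id = np.empty(n, dtype=np.intp)
    fold_id[rng.permutation(n)] = np.arange(n) % folds
    return fold_id


def rmsecv_per_lv(
    X: np.ndarray,
    y: np.ndarray,
    settings: PLSSettings = PLSSettings(),
    seed: int = 0,
    fold_id: np.ndarray | None = None,
) -> np.ndarray:
    """k-fold RMSECV for latent-variable counts 1..max.

    ``fold_id`` lets callers reuse one deterministic fold assignment
    across many subset evaluations (common random numbers).  If a fold
    yields fewer components than requested, the last available model is
    carried forward for the missing counts.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if np.ptp(y) == 0:
        raise ValueError("constant response: RMSECV undefined")
    folds = min(settings.cv_folds, n)
    if fold_id is None:
        fold_id = _fold_assignment(n, folds, seed)
    A = settings.max_latent_variables
    sq = np.zeros(A)
    truncated = False
    for f in range(folds):
        test = fold_id == f
        train = ~test
        B, xm, ym, a_eff = pls1_fit(X[train], y[train], A)
        pred = pls1_predict(X[test], B, xm, ym)
        if a_eff < A:
            truncated = True
            pred = np.hstack([pred, np.repeat(pred[:, -1:], A - a_eff, axis=1)])
        sq += ((pred - y[test, None]) ** 2).sum(axis=0)
    if truncated:
        warnings.warn("rank-deficient fold: component count truncated", stacklevel=2)
    return np.sqrt(sq / n)


def pls_cv_rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    settings: PLSSettings = PLSSettings(),
    seed: int = 0,
    fold_id: np.ndarray | None = None,
) -> tuple[int, float]:
    """Best latent-variable count and its RMSECV (minimum over 1..max)."""
    curve = rmsecv_per_lv(X, y, settings, seed=seed, fold_id=fold_id)
    best = int(np.argmin(curve))
    return best + 1, float(curve[best])
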