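"""Wavelength selection: CARS, VISSA and VCPA-IRIV.

All three algorithms hunt for the spectral channels that carry the
moisture signal, scoring candidate subsets by the k-fold RMSECV of a
PLS1 model (the :mod:`witherfuse.pls` engine):

* CARS (competitive adaptive reweighted sampling): Monte-Carlo runs in
  which the live variable set is shrunk along an exponentially
  decreasing function (EDF) of the run index and resampled with
  probability proportional to |PLS coefficient|; the run with minimal
  RMSECV wins.
* VISSA (variable iterative space shrinkage approach): weighted
  binary-matrix sampling where each variable's inclusion weight is
  updated to its frequency among the best fraction of random
  sub-models, iterated while the elite-mean RMSECV improves.
* VCPA-IRIV: an EDF-driven space shrinkage in which random
  half-inclusion sub-models vote for variables (VCPA stage), followed
  by iterative retention analysis (IRIV): each surviving variable is
  kept or dropped by comparing the RMSECV distributions of sub-models
  that include vs exclude it (Mann-Whitney + sign of the mean
  difference), finished by backward elimination.

Every algorithm is deterministic under (X, y, settings, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import mannwhitneyu

from .pls import PLSSettings, _fold_assignment, pls1_fit, pls_cv_rmsecv

__all__ = [
    "SelectionResult",
    "PLSSettings",
    "edf_ratios",
    "cars_select",
    "vissa_select",
    "vcpa_iriv_select",
    "compression_rate",
]


def compression_rate(n_original: int, n_selected: int) -> float:
    """Percent of channels discarded: 100 (1 - n_selected/n_original),
    rounded half-up to one decimal."""
    if not 0 < n_selected <= n_original:
        raise ValueError("need 0 < n_selected <= n_original")
    pct = 100.0 * (1.0 - n_selected / n_original)
    return float(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SelectionResult:
    method: str
    selected_indices: np.ndarray
    n_original: int
    rmsecv_trace: list[float] = field(default_factory=list)
    seed: int | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected_indices = np.unique(np.asarray(self.selected_indices, dtype=int))
        if self.selected_indices.size and (
            self.selected_indices.min() < 0 or self.selected_indices.max() >= self.n_original
        ):
            raise ValueError("selected indices outside the original channel range")

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)

    @property
    def compression_rate(self) -> float:
        return compression_rate(self.n_original, self.n_selected)


def edf_ratios(p: int, n_runs: int, n_final: int = 2) -> np.ndarray:
    """Exponentially decreasing retention schedule r_i = a e^{-k i}.

    The boundary conditions fix the constants: r_1 = 1 (all p variables
    live on the first run) and r_N = n_final/p, giving
    k = ln(p/n_final)/(N-1) and a = e^k.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs for an EDF schedule")
    if not 2 <= n_final <= p:
        raise ValueError("need 2 <= n_final <= p")
    k = math.log(p / n_final) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    return math.exp(k) * np.exp(-k * i)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    return X, y


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    cv_folds: int = 5,
    settings: PLSSettings | None = None,
    seed: int = 0,
    mc_ratio: float = 0.8,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Per run: fit PLS on a random 80% calibration subset restricted to
    the live variables; rank by |regression coefficient|; enforce the
    EDF shrink to ceil(p * r_i) variables; then adaptive reweighted
    sampling (weighted draw with replacement, duplicates collapsed)
    fixes the live set, whose k-fold RMSECV is recorded.  The live set
    with minimal RMSECV over all runs is returned (earliest run wins
    ties).
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if settings is None:
        settings = PLSSettings(max_latent_variables=10, cv_folds=cv_folds)
    rng = np.random.default_rng(seed)
    fold_id = _fold_assignment(n, min(cv_folds, n), int(rng.integers(2**31 - 1)))
    ratios = edf_ratios(p, n_runs, n_final=2)
    live = np.arange(p)
    best_rmsecv = np.inf
    best_live = live.copy()
    trace: list[float] = []
    n_cal = max(2, round(mc_ratio * n))
    for r_i in ratios:
        sub = rng.choice(n, size=n_cal, replace=False)
        B, *_ = pls1_fit(X[np.ix_(sub, live)], y[sub], settings.max_latent_variables)
        # standardized coefficient: |b_j| sd(x_j), so importance measures a
        # channel's contribution rather than rewarding small-scale channels
        absb = np.abs(B[:, -1]) * X[np.ix_(sub, live)].std(axis=0)
        keep_n = max(2, int(np.ceil(p * r_i)))
        if keep_n < live.size:
            order = np.argsort(-absb, kind="stable")[:keep_n]
            live = live[order]
            absb = absb[order]
        if absb.sum() == 0:
            w = np.full(live.size, 1.0 / live.size)
        else:
            w = absb / absb.sum()
        draws = rng.choice(live.size, size=max(2, keep_n), replace=True, p=w)
        new_live = np.unique(live[draws])
        if new_live.size < 2:  # clamp: keep the top-2 coefficients
            new_live = live[np.argsort(-absb, kind="stable")[:2]]
        live = np.sort(new_live)
        _, rm = pls_cv_rmsecv(X[:, live], y, settings, fold_id=fold_id)
        trace.append(rm)
        if rm < best_rmsecv:
            best_rmsecv = rm
            best_live = live.copy()
    return SelectionResult(
        method="cars",
        selected_indices=best_live,
        n_original=p,
        rmsecv_trace=trace,
        seed=seed,
        settings={
            "n_runs": n_runs,
            "cv_folds": cv_folds,
            "mc_ratio": mc_ratio,
            "max_latent_variables": settings.max_latent_variables,
        },
    )


def _score_submodels(
    X: np.ndarray,
    y: np.ndarray,
    inclusion: np.ndarray,
    settings: PLSSettings,
    fold_id: np.ndarray,
) -> np.ndarray:
    scores = np.empty(inclusion.shape[0])
    for i, row in enumerate(inclusion):
        cols = np.flatnonzero(row)
        _, scores[i] = pls_cv_rmsecv(X[:, cols], y, settings, fold_id=fold_id)
    return scores


def vissa_select(
    X: np.ndarray,
    y: np.ndarray,
    settings: PLSSettings | None = None,
    seed: int = 0,
    n_submodels: int = 1000,
    best_fraction: float = 0.05,
    max_iterations: int = 100,
) -> SelectionResult:
    """Variable iterative space shrinkage approach.

    Inclusion weights start at 0.5 for every variable.  Each iteration
    draws ``n_submodels`` binary inclusion vectors (variable j included
    with probability w_j, empty draws redrawn), scores each by RMSECV,
    and resets w to the inclusion frequency among the best
    ``best_fraction`` of sub-models — accepted only while the
    elite-mean RMSECV improves.  Selected: final w_j >= 0.5.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if settings is None:
        settings = PLSSettings(max_latent_variables=15, cv_folds=5)
    rng = np.random.default_rng(seed)
    fold_id = _fold_assignment(n, min(settings.cv_folds, n), int(rng.integers(2**31 - 1)))
    w = np.full(p, 0.5)
    n_elite = max(1, int(round(best_fraction * n_submodels)))
    best_elite_mean = np.inf
    trace: list[float] = []
    for _ in range(max_iterations):
        M = rng.random((n_submodels, p)) < w
        empty = ~M.any(axis=1)
        while empty.any():
            M[empty] = rng.random((int(empty.sum()), p)) < np.maximum(w, 1.0 / p)
            empty = ~M.any(axis=1)
        scores = _score_submodels(X, y, M, settings, fold_id)
        elite = np.argsort(scores, kind="stable")[:n_elite]
        elite_mean = float(scores[elite].mean())
        if elite_mean >= best_elite_mean:
            break
        best_elite_mean = elite_mean
        trace.append(elite_mean)
        w = M[elite].mean(axis=0)
        if np.all((w == 0.0) | (w == 1.0)):
            break
    selected = np.flatnonzero(w >= 0.5)
    if selected.size == 0:
        raise RuntimeError("all inclusion weights collapsed to 0: no informative variables")
    return SelectionResult(
        method="vissa",
        selected_indices=selected,
        n_original=p,
        rmsecv_trace=trace,
        seed=seed,
        settings={
            "n_submodels": n_submodels,
            "best_fraction": best_fraction,
            "max_latent_variables": settings.max_latent_variables,
            "cv_folds": settings.cv_folds,
        },
    )


def _half_inclusion(rng: np.random.Generator, n_models: int, p: int) -> np.ndarray:
    """Binary matrix sampling: each sub-model includes floor(p/2) variables."""
    k = max(1, p // 2)
    M = np.zeros((n_models, p), dtype=bool)
    for i in range(n_models):
        M[i, rng.choice(p, size=k, replace=False)] = True
    return M


def vcpa_iriv_select(
    X: np.ndarray,
    y: np.ndarray,
    settings: PLSSettings | None = None,
    seed: int = 0,
    edf_runs: int = 50,
    bms_submodels: int = 1000,
    stage1_floor: int | None = None,
    alpha: float = 0.05,
    top_fraction: float = 0.10,
) -> SelectionResult:
    """Two-stage VCPA (EDF space shrinkage by sub-model voting) + IRIV.

    Stage 1 shrinks the live space along an EDF schedule: at each run,
    ``bms_submodels`` random half-inclusion sub-models are scored by
    RMSECV, the best ``top_fraction`` vote, and the space is truncated
    to ceil(p * r_i) highest-vote variables (never below
    ``stage1_floor``, default 10% of p and at least 5, clamped to
    >= 2).  Stage 2 (IRIV) repeatedly classifies each surviving
    variable by comparing the RMSECV of sub-models including vs
    excluding it (Mann-Whitney at ``alpha`` plus the sign of the mean
    difference); variables whose inclusion does not lower RMSECV are
    dropped until a round drops nothing.  A final backward elimination
    removes any variable whose exclusion lowers RMSECV.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if settings is None:
        settings = PLSSettings(max_latent_variables=5, cv_folds=10)
    if stage1_floor is None:
        stage1_floor = max(5, round(0.1 * p))
    stage1_floor = max(2, min(stage1_floor, p))
    rng = np.random.default_rng(seed)
    fold_id = _fold_assignment(n, min(settings.cv_folds, n), int(rng.integers(2**31 - 1)))
    trace: list[float] = []

    # --- stage 1: VCPA space shrinkage -------------------------------
    live = np.arange(p)
    if stage1_floor < p:
        ratios = edf_ratios(p, edf_runs, n_final=stage1_floor)
        for r_i in ratios:
            target = max(stage1_floor, int(np.ceil(p * r_i)))
            if target >= live.size:
                continue
            M = _half_inclusion(rng, bms_submodels, live.size)
            scores = _score_submodels(X[:, live], y, M, settings, fold_id)
            n_top = max(1, int(round(top_fraction * bms_submodels)))
            top = np.argsort(scores, kind="stable")[:n_top]
            votes = M[top].mean(axis=0)
            order = np.lexsort((np.arange(live.size), -votes))[:target]
            live = np.sort(live[order])
            trace.append(float(scores[top].mean()))

    # --- stage 2: IRIV ------------------------------------------------
    # independent Bernoulli(0.5) inclusion (expected size p/2): unlike the
    # exact-half design of stage 1, this keeps the include-vs-exclude
    # comparison a marginal-value measure even when few variables remain
    for _ in range(p):
        if live.size <= 2:
            break
        M = rng.random((bms_submodels, live.size)) < 0.5
        empty = ~M.any(axis=1)
        while empty.any():
            M[empty] = rng.random((int(empty.sum()), live.size)) < 0.5
            empty = ~M.any(axis=1)
        # every variable needs both included and excluded sub-models
        col_in = M.sum(axis=0)
        degenerate = (col_in == 0) | (col_in == bms_submodels)
        if degenerate.any():
            continue
        scores = _score_submodels(X[:, live], y, M, settings, fold_id)
        dmean = np.empty(live.size)
        pvals = np.empty(live.size)
        for j in range(live.size):
            s_in = scores[M[:, j]]
            s_out = scores[~M[:, j]]
            dmean[j] = s_out.mean() - s_in.mean()  # > 0: inclusion helps
            pvals[j] = mannwhitneyu(s_in, s_out, alternative="two-sided").pvalue
        keep = dmean > 0  # strongly (p < alpha) or weakly informative
        if keep.sum() < 2:  # clamp at 2 variables
            keep = np.zeros(live.size, dtype=bool)
            keep[np.argsort(-dmean, kind="stable")[:2]] = True
        if keep.all():
            break
        live = live[keep]

    # --- backward elimination ----------------------------------------
    _, base = pls_cv_rmsecv(X[:, live], y, settings, fold_id=fold_id)
    trace.append(base)
    while live.size > 2:
        drop_scores = np.empty(live.size)
        for j in range(live.size):
            cols = np.delete(live, j)
            _, drop_scores[j] = pls_cv_rmsecv(X[:, cols], y, settings, fold_id=fold_id)
        j_best = int(np.argmin(drop_scores))
        if drop_scores[j_best] < base:
            live = np.delete(live, j_best)
            base = drop_scores[j_best]
            trace.append(base)
        else:
            break

    return SelectionResult(
        method="vcpa-iriv",
        selected_indices=live,
        n_original=p,
        rmsecv_trace=trace,
        seed=seed,
        settings={
            "edf_runs": edf_runs,
            "bms_submodels": bms_submodels,
            "stage1_floor": stage1_floor,
            "alpha": alpha,
            "top_fraction": top_fraction,
            "max_latent_variables": settings.max_latent_variables,
            "cv_groups": settings.cv_folds,
        },
    )
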