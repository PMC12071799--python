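"""Low-, middle- and high-level fusion of spectral and image information.

Low level concatenates the raw (preprocessed) blocks; the middle level
concatenates per-sensor reduced representations — either leading
principal components with per-sensor score counts chosen by scanning
model RPD, or the variable-selection / correlation-screening outputs;
the high level stacks the per-sensor model predictions with a multiple
linear regression

    y = b + k1 x1 + ... + kn xn,

whose coefficients are fitted by ordinary least squares on the
calibration-set predictions of the already-trained single-sensor
models and then applied unchanged to prediction-set predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .modeling import SVRParams, evaluate_metrics, train_predict_svr

__all__ = [
    "FusedBlock",
    "StackedModel",
    "low_level_fuse",
    "pca_reduce_block",
    "select_optimal_pcs",
    "mid_level_fuse",
    "high_level_fit",
    "high_level_predict",
]


@dataclass
class FusedBlock:
    """Fused sample x variable matrix with per-column provenance.

    ``provenance`` holds one ``(sensor, kind, index)`` triple per fused
    column, e.g. ("nir", "channel", 412) or ("mv", "pc", 3).
    """

    matrix: np.ndarray
    provenance: list[tuple[str, str, int]]
    level: str

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.provenance):
            raise ValueError("provenance must cover every fused column exactly once")

    @property
    def n_fused(self) -> int:
        return self.matrix.shape[1]


@dataclass
class StackedModel:
    """MLR stacking coefficients k_1..k_n and intercept b."""

    coefficients: np.ndarray
    intercept: float
    sensor_order: tuple[str, ...]
    calibration_predictions: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        if len(self.sensor_order) != self.coefficients.size:
            raise ValueError("one coefficient required per sensor")


def low_level_fuse(
    blocks: list[np.ndarray],
    sample_ids: list[list[str]] | None = None,
    sensors: list[str] | None = None,
) -> FusedBlock:
    """Column-wise concatenation of aligned sensor blocks."""
    mats = [np.atleast_2d(np.asarray(b, dtype=float)) for b in blocks]
    if len(mats) == 0:
        raise ValueError("no blocks to fuse")
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("blocks have different sample counts")
    if sample_ids is not None:
        ref = list(sample_ids[0])
        for ids in sample_ids[1:]:
            if list(ids) != ref:
                raise ValueError("sample_ids misaligned across sensor blocks")
    if sensors is None:
        sensors = [f"sensor{i}" for i in range(len(mats))]
    provenance = [
        (sensor, "channel", j) for sensor, m in zip(sensors, mats) for j in range(m.shape[1])
    ]
    return FusedBlock(np.hstack(mats), provenance, level="low")


def pca_reduce_block(
    X_cal: np.ndarray,
    n_components: int,
    X_other: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Leading principal-component scores with calibration-only centering.

    Returns ``(scores_cal, explained_percent, cumulative_percent,
    scores_other)``.  Centering statistics and loadings come from the
    calibration rows only and are applied unchanged to ``X_other``.
    """
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    n, p = X_cal.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must lie in [1, {min(n - 1, p)}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X_cal)
    explained = pca.explained_variance_ratio_ * 100.0
    cumulative = np.cumsum(explained)
    other = None if X_other is None else pca.transform(np.asarray(X_other, dtype=float))
    return scores, explained, cumulative, other


def select_optimal_pcs(
    scores_cal: np.ndarray,
    y_cal: np.ndarray,
    scores_pred: np.ndarray,
    y_pred: np.ndarray,
    n_max: int = 18,
    params: SVRParams | None = None,
) -> tuple[int, np.ndarray]:
    """Scan k = 1..n_max leading PCs, model each with SVR, return the k
    maximizing prediction-set RPD (ties -> smallest k).

    Also returns the RPD curve for diagnostics.
    """
    if params is None:
        params = SVRParams(c=1.0, g=1.0)
    scores_cal = np.atleast_2d(np.asarray(scores_cal, dtype=float))
    n_max = min(n_max, scores_cal.shape[1])
    if np.ptp(np.asarray(y_cal)) == 0:
        raise ValueError("degenerate (constant) response")
    rpd_curve = np.empty(n_max)
    for k in range(1, n_max + 1):
        yhat_cal = train_predict_svr(scores_cal[:, :k], y_cal, scores_cal[:, :k], params)
        yhat_pred = train_predict_svr(scores_cal[:, :k], y_cal, scores_pred[:, :k], params)
        rpd_curve[k - 1] = evaluate_metrics(y_cal, yhat_cal, y_pred, yhat_pred).rpd
    best_k = int(np.argmax(rpd_curve)) + 1  # argmax takes the first (smallest k) tie
    return best_k, rpd_curve


def mid_level_fuse(
    spec_features: np.ndarray,
    img_features: np.ndarray,
    mode: str,
    spec_provenance: list[tuple[str, str, int]] | None = None,
    img_provenance: list[tuple[str, str, int]] | None = None,
) -> FusedBlock:
    """Concatenate per-sensor reduced/selected matrices (spectra first).

    ``mode`` tags the reduction that produced the spectral side:
    one of {"pca", "cars", "vcpa-iriv", "vissa"}.
    """
    if mode not in {"pca", "cars", "vcpa-iriv", "vissa"}:
        raise ValueError(f"unknown middle-level mode {mode!r}")
    spec = np.atleast_2d(np.asarray(spec_features, dtype=float))
    img = np.atleast_2d(np.asarray(img_features, dtype=float))
    if spec.shape[1] == 0 or img.shape[1] == 0:
        raise ValueError("empty selection on one sensor: nothing to fuse")
    if spec.shape[0] != img.shape[0]:
        raise ValueError("sensor blocks have different sample counts")
    kind = "pc" if mode == "pca" else "channel"
    if spec_provenance is None:
        spec_provenance = [("nir", kind, j) for j in range(spec.shape[1])]
    if img_provenance is None:
        img_provenance = [("mv", "pc" if mode == "pca" else "feature", j)
                          for j in range(img.shape[1])]
    return FusedBlock(
        np.hstack([spec, img]),
        list(spec_provenance) + list(img_provenance),
        level=f"mid-{mode}",
    )


def high_level_fit(
    pred_cal_per_sensor: np.ndarray,
    y_cal: np.ndarray,
    sensor_order: tuple[str, ...] = ("nir", "mv"),
) -> StackedModel:
    """OLS stacking of single-sensor calibration predictions.

    Regresses the actual calibration MC on the per-sensor predicted MC
    columns; a rank-deficient (collinear) design falls back to the
    minimum-norm solution with a warning.
    """
    Xp = np.atleast_2d(np.asarray(pred_cal_per_sensor, dtype=float))
    y = np.asarray(y_cal, dtype=float).ravel()
    n, k = Xp.shape
    if n <= k + 1:
        raise ValueError("need more calibration samples than sensors + 1")
    design = np.column_stack([Xp, np.ones(n)])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < k + 1:
        warnings.warn("collinear sensor predictions: minimum-norm stacking solution",
                      stacklevel=2)
    return StackedModel(
        coefficients=coef[:k],
        intercept=float(coef[k]),
        sensor_order=tuple(sensor_order),
        calibration_predictions=Xp,
    )


def high_level_predict(model: StackedModel, pred_per_sensor: np.ndarray) -> np.ndarray:
    """Affine combination b + sum_i k_i x_i of per-sensor predictions."""
    Xp = np.atleast_2d(np.asarray(pred_per_sensor, dtype=float))
    if Xp.shape[1] != model.coefficients.size:
        raise ValueError(
            f"model expects {model.coefficients.size} sensors, got {Xp.shape[1]}"
        )
    return Xp @ model.coefficients + model.intercept
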