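"""Color and texture descriptors of leaf images, normalization, and
Pearson screening against moisture content.

Twelve color features (R, G, B, H, S, V, L*, a*, b*, excess green
2G-R-B, R/G, CIELAB hue angle hab*) and six histogram-statistical
texture features (mean gray m, sd delta, smoothness r, normalized third
moment mu3, uniformity U, entropy e) summarise each masked leaf.  Color
conversions are computed from the in-mask mean RGB (one documented
convention; per-pixel averaging of converted values is a different
estimator and is deliberately not used).
"""

from __future__ import annotations

import colorsys
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.color import rgb2lab

__all__ = [
    "FEATURE_NAMES",
    "ScreeningReport",
    "extract_color_features",
    "extract_texture_features",
    "extract_features",
    "minmax_normalize",
    "pearson_screen",
    "retained_mask",
]

logger = logging.getLogger(__name__)

#: Fixed 18-slot feature order used by every table this package writes.
FEATURE_NAMES = (
    "R", "G", "B", "H", "S", "V", "L", "a", "b", "exg", "rg_ratio", "hab",
    "m", "delta", "r_smooth", "mu3", "U", "e",
)

_GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])
_HAB_TOL = 0.01  # |a*|,|b*| below this -> achromatic, hue angle defined as 0


def _masked_pixels(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3 RGB")
    pix = image[mask > 0].astype(float)
    if pix.shape[0] == 0:
        raise ValueError("empty mask: no leaf pixels to describe")
    return pix


def extract_color_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """The 12 color descriptors from the in-mask mean RGB.

    R, G, B are 0-255 channel means; H (degrees), S, V come from the
    hexcone model; L*, a*, b* from sRGB -> XYZ (D65) -> CIELAB;
    exg = 2G-R-B; rg_ratio = R/G (NaN-flagged when G = 0); hab* =
    atan2(b*, a*) in degrees on [0, 360), 0 for achromatic colors.
    """
    pix = _masked_pixels(image, mask)
    R, G, B = pix.mean(axis=0)
    h, s, v = colorsys.rgb_to_hsv(R / 255.0, G / 255.0, B / 255.0)
    H = h * 360.0
    lab = rgb2lab(np.array([[[R, G, B]]], dtype=float) / 255.0)[0, 0]
    L, a, b = (float(x) for x in lab)
    exg = 2.0 * G - R - B
    if G == 0:
        warnings.warn("G = 0: R/G ratio undefined for this sample", stacklevel=2)
        rg = np.nan
    else:
        rg = R / G
    if abs(a) < _HAB_TOL and abs(b) < _HAB_TOL:
        logger.info("achromatic color (a*=%.4f, b*=%.4f): hab* set to 0", a, b)
        hab = 0.0
    else:
        hab = float(np.degrees(np.arctan2(b, a)) % 360.0)
    return np.array([R, G, B, H, s, v, L, a, b, exg, rg, hab])


def extract_texture_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """The 6 histogram-statistical texture descriptors.

    Gray levels are the 0.299/0.587/0.114 luminance of RGB quantized to
    L = 256 levels.  With normalized in-mask histogram p(z):

    m = sum z p(z); delta = sqrt(sum (z-m)^2 p(z));
    r = 1 - 1/(1 + var/(L-1)^2); mu3 = sum (z-m)^3 p(z) / (L-1)^2;
    U = sum p(z)^2; e = -sum p(z) log2 p(z).
    """
    pix = _masked_pixels(image, mask)
    gray = np.clip(np.round(pix @ _GRAY_WEIGHTS), 0, 255).astype(int)
    counts = np.bincount(gray, minlength=256)
    p = counts / counts.sum()
    z = np.arange(256, dtype=float)
    m = float(z @ p)
    var = float(((z - m) ** 2) @ p)
    delta = float(np.sqrt(var))
    r_smooth = 1.0 - 1.0 / (1.0 + var / 255.0**2)
    mu3 = float(((z - m) ** 3) @ p) / 255.0**2
    U = float(p @ p)
    nz = p[p > 0]
    e = float(-(nz @ np.log2(nz)))
    return np.array([m, delta, r_smooth, mu3, U, e])


def extract_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """All 18 descriptors in the fixed :data:`FEATURE_NAMES` order."""
    return np.concatenate(
        [extract_color_features(image, mask), extract_texture_features(image, mask)]
    )


def minmax_normalize(
    block: np.ndarray, fit_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature (x-min)/(max-min) scaling fitted on calibration rows only.

    Rows outside ``fit_rows`` may map outside [0, 1].  A feature that is
    constant on the calibration rows is mapped to 0 everywhere (with a
    warning) rather than dividing by zero.

    Returns ``(normalized, mins, maxs)``.
    """
    block = np.atleast_2d(np.asarray(block, dtype=float))
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be nonempty")
    fit = block[fit_rows]
    mins = fit.min(axis=0)
    maxs = fit.max(axis=0)
    span = maxs - mins
    degenerate = span == 0
    if degenerate.any():
        warnings.warn(
            f"constant feature column(s) {np.flatnonzero(degenerate).tolist()} "
            "mapped to 0",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, span)
    out = (block - mins) / safe
    out[:, degenerate] = 0.0
    return out, mins, maxs


def retained_mask(r_values: np.ndarray, cutoff: float) -> np.ndarray:
    """Retention rule of the screening step: keep |r| >= cutoff.

    The comparison is inclusive so that a feature sitting exactly on the
    cutoff is kept.
    """
    return np.abs(np.asarray(r_values, dtype=float)) >= cutoff


@dataclass
class ScreeningReport:
    """Per-feature Pearson screening outcome against MC."""

    r: np.ndarray
    p_value: np.ndarray
    retained: np.ndarray
    cutoff: float
    feature_names: tuple[str, ...] | None = None

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


def pearson_screen(
    features: np.ndarray,
    mc: np.ndarray,
    cutoff: float = 0.6,
    feature_names: tuple[str, ...] | None = None,
) -> ScreeningReport:
    """Screen features by the absolute Pearson correlation with MC.

    Two-tailed p-values come from the t transform with n-2 degrees of
    freedom.  Zero-variance features have undefined r and are excluded
    with a warning.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(mc, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples for screening")
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    if np.ptp(y) == 0:
        raise ValueError("constant MC vector: correlation undefined")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    zero_var = sx == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance feature(s) {np.flatnonzero(zero_var).tolist()} "
            "excluded from screening",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    retained = retained_mask(np.where(zero_var, 0.0, r), cutoff)
    retained[zero_var] = False
    r[zero_var] = np.nan
    p[zero_var] = np.nan
    return ScreeningReport(r=r, p_value=p, retained=retained, cutoff=cutoff,
                           feature_names=feature_names)
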