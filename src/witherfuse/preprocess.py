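"""Replicate averaging and standard normal variate (SNV) preprocessing.

NIR spectra of stacked leaves carry additive baseline offsets and
multiplicative path-length effects from light scattering.  SNV removes
both by centring and scaling each spectrum individually, which is the
only preprocessing the withering pipeline applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralBlock",
    "average_replicates",
    "snv",
    "snv_transform",
    "read_spectra_csv",
    "write_spectra_csv",
]


@dataclass
class SpectralBlock:
    """Aligned sample x wavelength absorbance matrix.

    Attributes
    ----------
    wavelengths : (n_channels,) float array, strictly ascending, in nm.
    absorbance : (n_samples, n_channels) float array, finite.
    sample_ids : list of str, one per row.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = list(self.sample_ids)
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths given"
            )
        if self.absorbance.shape[0] != len(self.sample_ids):
            raise ValueError("one sample_id required per spectrum row")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]


def average_replicates(spectra: Sequence[np.ndarray]) -> np.ndarray:
    """Channel-wise arithmetic mean of replicate scans of one sample.

    Each withering sample is scanned at several local regions; the mean
    spectrum represents the sample downstream.
    """
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum to average")
    arrs = [np.asarray(s, dtype=float) for s in spectra]
    length = arrs[0].shape
    if any(a.shape != length for a in arrs):
        raise ValueError("replicate spectra have unequal lengths")
    return np.mean(arrs, axis=0)


def snv(X: np.ndarray) -> np.ndarray:
    """Row-wise SNV: subtract each row's mean, divide by its sample sd (ddof=1).

    Raises on any zero-spread row (the transform is undefined there).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"constant spectrum row(s) {bad.tolist()}: SNV undefined")
    return (X - mu) / sd


def snv_transform(block: SpectralBlock) -> SpectralBlock:
    """Apply SNV to every spectrum of a block; wavelengths are unchanged."""
    sd = block.absorbance.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [block.sample_ids[i] for i in bad]
        raise ValueError(f"constant spectrum for sample(s) {names}: SNV undefined")
    return SpectralBlock(
        wavelengths=block.wavelengths,
        absorbance=snv(block.absorbance),
        sample_ids=block.sample_ids,
    )


def write_spectra_csv(block: SpectralBlock, path: str | Path) -> None:
    """Write `sample_id,wl_<nm>,...` one row per sample."""
    cols = [f"wl_{round(w, 4)}" for w in block.wavelengths]
    df = pd.DataFrame(block.absorbance, columns=cols)
    df.insert(0, "sample_id", block.sample_ids)
    df.to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> SpectralBlock:
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c.startswith("wl_")]
    if not wl_cols:
        raise ValueError(f"{path}: no wl_<nm> columns found")
    wavelengths = np.array([float(c[3:]) for c in wl_cols])
    return SpectralBlock(
        wavelengths=wavelengths,
        absorbance=df[wl_cols].to_numpy(dtype=float),
        sample_ids=df["sample_id"].astype(str).tolist(),
    )
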