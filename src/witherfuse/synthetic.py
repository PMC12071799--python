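"""Seeded synthetic withering datasets with known ground truth.

The generator emulates a 12 h black-tea withering experiment: moisture
content (MC) falls from ~75% along a thin-layer exponential drying
curve through the three practical withering classes (insufficient
> 62%, moderate 58-62%, excessive < 58%).  Each hourly time point
yields several replicate samples; every sample gets

* a 900-1700 nm absorbance spectrum built from a smooth baseline plus
  Gaussian O-H / C-H overtone bands whose depths are affine in MC
  (water bands near 970/1190/1450 nm deepen with MC, dry-matter C-H
  bands near 1200/1700 nm deepen as MC falls), corrupted by additive
  offset + multiplicative slope scatter (removable by SNV) and iid
  channel noise;
* an elliptical leaf image whose green base colour darkens and whose
  speckle texture roughens as MC falls.

Each sensor reads MC through its own small response deviation, so
neither spectra nor images are a perfect MC encoder — the situation in
which multi-sensor fusion can actually help.

One global seed drives independent substreams (trajectory, scatter,
noise, images, sensor responses) so modules can be exercised in
isolation and datasets are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .preprocess import SpectralBlock, write_spectra_csv

__all__ = [
    "SyntheticConfig",
    "WitheringSample",
    "GroundTruth",
    "generate_mc_trajectory",
    "classify_withering_degree",
    "generate_spectra_block",
    "generate_leaf_image",
    "generate_dataset",
    "save_dataset",
    "spectra_block_from_samples",
]

# withering-degree boundaries on the moisture fraction; both boundary
# values belong to the moderate class
INSUFFICIENT_ABOVE = 0.62
EXCESSIVE_BELOW = 0.58

_SUBSTREAMS = ("trajectory", "scatter", "noise", "images", "nir_response", "mv_response")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults: 13 hourly time points x 15 replicates = 195
    samples, 760 channels over 900-1700 nm."""

    n_times: int = 13
    replicates_per_time: int = 15
    n_channels: int = 760
    wavelength_min: float = 900.0
    wavelength_max: float = 1700.0
    # O-H water bands (positive MC coefficient) and C-H dry-matter bands
    # (negative coefficient); widths chosen so neighbours overlap as in
    # real NIR of leaf tissue
    band_centers: tuple[float, ...] = (970.0, 1190.0, 1450.0, 1200.0, 1700.0)
    band_widths: tuple[float, ...] = (22.0, 30.0, 38.0, 16.0, 32.0)
    band_base_depth: tuple[float, ...] = (0.25, 0.35, 0.55, 0.30, 0.28)
    band_mc_coeff: tuple[float, ...] = (0.9, 0.7, 1.4, -0.5, -0.6)
    band_is_informative: tuple[bool, ...] = (True, True, True, True, True)
    # each band tracks MC through its own chemistry (water vs catechins),
    # so band depths carry small independent per-sample deviations
    band_response_sd: float = 0.005
    # drying curve mc(t) = mc_inf + (mc_0 - mc_inf) exp(-k t)
    mc_initial: float = 0.75
    mc_asymptote: float = 0.50
    drying_rate: float = 0.15
    replicate_jitter_sd: float = 0.004
    # sensor imperfections
    scatter_sd: float = 0.05
    noise_sd: float = 0.001
    nir_response_sd: float = 0.008
    mv_response_sd: float = 0.012
    image_size: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.wavelength_min >= self.wavelength_max:
            raise ValueError("wavelength_min must be < wavelength_max")
        if self.replicates_per_time < 1:
            raise ValueError("replicates_per_time must be >= 1")
        if self.n_times < 2:
            raise ValueError("n_times must be >= 2")
        nb = len(self.band_centers)
        for name in ("band_widths", "band_base_depth", "band_mc_coeff", "band_is_informative"):
            if len(getattr(self, name)) != nb:
                raise ValueError(f"{name} must have one entry per band")
        for c in self.band_centers:
            if not self.wavelength_min <= c <= self.wavelength_max:
                raise ValueError(f"band center {c} nm outside wavelength range")
        if self.scatter_sd < 0 or self.noise_sd < 0:
            raise ValueError("scatter_sd and noise_sd must be non-negative")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_min, self.wavelength_max, self.n_channels)

    def substream(self, name: str) -> np.random.Generator:
        """Independent per-purpose RNG derived from the global seed."""
        idx = _SUBSTREAMS.index(name)
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))[idx])


@dataclass
class WitheringSample:
    sample_id: str
    time_h: float
    mc: float
    degree: str
    spectrum: np.ndarray
    image: np.ndarray | None = None
    mask: np.ndarray | None = None
    image_features: np.ndarray | None = None


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    informative_channel_indices: tuple[int, ...]
    mc_curve_params: dict = field(default_factory=dict)
    color_map_params: dict = field(default_factory=dict)


def classify_withering_degree(mc: float) -> str:
    """Map a moisture fraction to its withering-degree class.

    > 0.62 insufficient; 0.58-0.62 (boundaries inclusive) moderate;
    < 0.58 excessive.
    """
    if not 0.0 <= mc <= 1.0:
        raise ValueError(f"moisture fraction {mc} outside [0, 1]")
    if mc > INSUFFICIENT_ABOVE:
        return "insufficient"
    if mc >= EXCESSIVE_BELOW:
        return "moderate"
    return "excessive"


def mc_curve(t: np.ndarray | float, config: SyntheticConfig) -> np.ndarray | float:
    """Thin-layer exponential drying law mc(t) = mc_inf + (mc_0-mc_inf) e^{-kt}."""
    return config.mc_asymptote + (config.mc_initial - config.mc_asymptote) * np.exp(
        -config.drying_rate * np.asarray(t, dtype=float)
    )


def generate_mc_trajectory(config: SyntheticConfig) -> list[tuple[float, float]]:
    """Hourly MC trajectory with seeded replicate jitter.

    Returns ``n_times * replicates_per_time`` pairs ``(time_h, mc)``.
    The noiseless curve must start above the insufficient threshold and
    end below the excessive one so all three classes are covered.
    """
    times = np.arange(config.n_times, dtype=float)
    clean = np.asarray(mc_curve(times, config))
    if clean[0] <= INSUFFICIENT_ABOVE or clean[-1] >= EXCESSIVE_BELOW:
        raise ValueError(
            "drying-curve endpoints cannot span the three withering classes: "
            f"mc(0)={clean[0]:.4f} must exceed {INSUFFICIENT_ABOVE} and "
            f"mc({times[-1]:.0f})={clean[-1]:.4f} must fall below {EXCESSIVE_BELOW}"
        )
    rng = config.substream("trajectory")
    out: list[tuple[float, float]] = []
    for t, m in zip(times, clean):
        jitter = rng.normal(0.0, config.replicate_jitter_sd, config.replicates_per_time)
        for j in jitter:
            out.append((float(t), float(np.clip(m + j, 0.0, 1.0))))
    return out


def _band_profiles(config: SyntheticConfig) -> np.ndarray:
    wl = config.wavelengths
    centers = np.asarray(config.band_centers)
    widths = np.asarray(config.band_widths)
    return np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / widths[:, None]) ** 2)


def _baseline(config: SyntheticConfig) -> np.ndarray:
    u = (config.wavelengths - config.wavelength_min) / (
        config.wavelength_max - config.wavelength_min
    )
    return 0.40 + 0.15 * u + 0.10 * u**2


def generate_spectra_block(
    mc_values: np.ndarray,
    config: SyntheticConfig,
    sample_ids: list[str] | None = None,
    scatter_rng: np.random.Generator | None = None,
    noise_rng: np.random.Generator | None = None,
) -> tuple[SpectralBlock, GroundTruth]:
    """Absorbance block whose informative band depths are affine in MC.

    Each spectrum is baseline + sum of Gaussian bands, then per-sample
    affine scatter ``(1+slope)*x + offset`` (slope, offset ~ N(0,
    scatter_sd)) and iid channel noise.  The ground truth records the
    channel nearest each informative band centre.
    """
    mc_values = np.asarray(mc_values, dtype=float).ravel()
    if scatter_rng is None:
        scatter_rng = config.substream("scatter")
    if noise_rng is None:
        noise_rng = config.substream("noise")
    profiles = _band_profiles(config)  # (n_bands, n_channels)
    base_depth = np.asarray(config.band_base_depth)
    coeff = np.where(config.band_is_informative, np.asarray(config.band_mc_coeff), 0.0)
    # depth affine in mc, anchored at the mid-trajectory moisture 0.6;
    # each band reads mc through its own small per-sample deviation
    mc_eff = mc_values[:, None] - 0.6
    if config.band_response_sd > 0:
        mc_eff = mc_eff + noise_rng.normal(
            0.0, config.band_response_sd, (mc_values.size, len(config.band_centers))
        )
    depths = base_depth[None, :] + mc_eff * coeff[None, :]  # (n, n_bands)
    clean = _baseline(config)[None, :] + depths @ profiles
    n = mc_values.size
    offset = scatter_rng.normal(0.0, config.scatter_sd, (n, 1))
    slope = scatter_rng.normal(0.0, config.scatter_sd, (n, 1))
    noisy = (1.0 + slope) * clean + offset
    if config.noise_sd > 0:
        noisy = noisy + noise_rng.normal(0.0, config.noise_sd, noisy.shape)
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n)]
    wl = config.wavelengths
    informative = tuple(
        int(np.argmin(np.abs(wl - c)))
        for c, inf, k in zip(config.band_centers, config.band_is_informative, config.band_mc_coeff)
        if inf and k != 0
    )
    block = SpectralBlock(wavelengths=wl, absorbance=noisy, sample_ids=sample_ids)
    truth = GroundTruth(
        informative_channel_indices=informative,
        mc_curve_params={
            "mc_initial": config.mc_initial,
            "mc_asymptote": config.mc_asymptote,
            "drying_rate": config.drying_rate,
        },
        color_map_params=dict(_COLOR_MAP),
    )
    return block, truth


# leaf base colour ramp: bright green at high MC -> dark green at low MC
_COLOR_MAP = {
    "mc_high": 0.80,
    "mc_low": 0.45,
    "bright_rgb": (72.0, 186.0, 78.0),
    "dark_rgb": (30.0, 92.0, 44.0),
    "speckle_amp_min": 4.0,
    "speckle_amp_max": 30.0,
    "background_gray": 176.0,
}


def generate_leaf_image(
    mc: float, config: SyntheticConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic leaf photograph: elliptical leaf on a neutral background.

    The in-leaf base colour interpolates bright->dark green as MC falls
    and a band-limited speckle field (surface wrinkling) grows in
    amplitude as the leaf dries.  Returns (uint8 RGB image, uint8 mask
    with 255 inside the leaf).
    """
    s = config.image_size
    if s < 16:
        raise ValueError("image_size must be >= 16 px")
    cm = _COLOR_MAP
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    cx = cy = (s - 1) / 2.0
    mask = ((xx - cx) / (0.42 * s)) ** 2 + ((yy - cy) / (0.30 * s)) ** 2 <= 1.0
    u = float(np.clip((mc - cm["mc_low"]) / (cm["mc_high"] - cm["mc_low"]), 0.0, 1.0))
    base = np.array(cm["dark_rgb"]) + u * (np.array(cm["bright_rgb"]) - np.array(cm["dark_rgb"]))
    amp = cm["speckle_amp_min"] + (1.0 - u) * (cm["speckle_amp_max"] - cm["speckle_amp_min"])
    field = gaussian_filter(rng.standard_normal((s, s)), sigma=1.5)
    field = field / field.std() * amp
    img = np.full((s, s, 3), cm["background_gray"])
    img[mask] = base[None, :] + field[mask, None]
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, (mask.astype(np.uint8) * 255)


def generate_dataset(
    config: SyntheticConfig, with_images: bool = True
) -> tuple[list[WitheringSample], GroundTruth]:
    """Full seeded dataset: trajectory -> spectra -> images.

    ``n_times * replicates_per_time`` samples (195 under defaults).
    Spectra and images each read MC through their own small seeded
    response deviation.
    """
    traj = generate_mc_trajectory(config)
    mc = np.array([m for _, m in traj])
    n = mc.size
    ids = [
        f"t{int(t):02d}_r{r:02d}"
        for t, _ in [traj[i * config.replicates_per_time] for i in range(config.n_times)]
        for r in range(config.replicates_per_time)
    ]
    mc_nir = mc + config.substream("nir_response").normal(0.0, config.nir_response_sd, n)
    mc_mv = mc + config.substream("mv_response").normal(0.0, config.mv_response_sd, n)
    block, truth = generate_spectra_block(mc_nir, config, sample_ids=ids)
    image_seeds = config.substream("images").integers(0, 2**31 - 1, n)
    samples = []
    for i, (t, m) in enumerate(traj):
        img = msk = None
        if with_images:
            img, msk = generate_leaf_image(float(mc_mv[i]), config, int(image_seeds[i]))
        samples.append(
            WitheringSample(
                sample_id=ids[i],
                time_h=t,
                mc=m,
                degree=classify_withering_degree(m),
                spectrum=block.absorbance[i],
                image=img,
                mask=msk,
            )
        )
    return samples, truth


def spectra_block_from_samples(
    samples: list[WitheringSample], config: SyntheticConfig
) -> SpectralBlock:
    return SpectralBlock(
        wavelengths=config.wavelengths,
        absorbance=np.vstack([s.spectrum for s in samples]),
        sample_ids=[s.sample_id for s in samples],
    )


def save_dataset(
    samples: list[WitheringSample],
    truth: GroundTruth,
    config: SyntheticConfig,
    outdir: str | Path,
) -> None:
    """Serialize to the on-disk layout: spectra.csv, reference.csv,
    images/<id>.png, masks/<id>.png, ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block = spectra_block_from_samples(samples, config)
    write_spectra_csv(block, outdir / "spectra.csv")
    import pandas as pd

    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "time_h": [s.time_h for s in samples],
            "mc": [s.mc for s in samples],
            "degree": [s.degree for s in samples],
        }
    ).to_csv(outdir / "reference.csv", index=False)
    if any(s.image is not None for s in samples):
        (outdir / "images").mkdir(exist_ok=True)
        (outdir / "masks").mkdir(exist_ok=True)
        for s in samples:
            if s.image is not None:
                Image.fromarray(s.image).save(outdir / "images" / f"{s.sample_id}.png")
                Image.fromarray(s.mask).save(outdir / "masks" / f"{s.sample_id}.png")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "informative_channel_indices": list(truth.informative_channel_indices),
                "mc_curve_params": truth.mc_curve_params,
                "color_map_params": {
                    k: list(v) if isinstance(v, tuple) else v
                    for k, v in truth.color_map_params.items()
                },
            },
            fh,
            indent=2,
        )
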