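import numpy as np
import pytest

from witherfuse.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Full study-scale synthetic dataset (195 samples, 760 channels), seed 1."""
    cfg = SyntheticConfig(seed=1)
    samples, truth = generate_dataset(cfg)
    return cfg, samples, truth


def planted_signal(seed: int, n_channels: int = 50):
    """Recovery fixture: 3 narrow bands planted on grid channels.

    Bands are one channel wide (6 nm vs ~16 nm spacing) and carry
    band-specific response deviations, so each planted channel is
    individually necessary for the best model rather than collinear
    with its neighbours.
    """
    wl = np.linspace(900, 1700, n_channels)
    idx = (round(0.12 * n_channels), round(0.48 * n_channels), round(0.86 * n_channels))
    cfg = SyntheticConfig(
        seed=seed,
        n_channels=n_channels,
        n_times=10,
        replicates_per_time=10,
        band_centers=tuple(float(wl[i]) for i in idx),
        band_widths=(6.0, 6.0, 6.0),
        band_base_depth=(0.3, 0.4, 0.3),
        band_mc_coeff=(1.0, -0.8, 0.9),
        band_is_informative=(True, True, True),
        band_response_sd=0.02,
        noise_sd=0.003,
        scatter_sd=0.0,
    )
    samples, truth = generate_dataset(cfg, with_images=False)
    y = np.array([s.mc for s in samples])
    X = np.vstack([s.spectrum for s in samples])
    return X, y, set(truth.informative_channel_indices)
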