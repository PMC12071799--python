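"""Generator contracts: trajectory, degree labels, spectra, images, datasets."""

import math

import numpy as np
import pytest

from witherfuse.preprocess import snv
from witherfuse.synthetic import (
    SyntheticConfig,
    classify_withering_degree,
    generate_dataset,
    generate_leaf_image,
    generate_mc_trajectory,
    generate_spectra_block,
)


class TestTrajectory:
    def test_default_trajectory_spans_all_three_degree_classes(self):
        traj = generate_mc_trajectory(SyntheticConfig(seed=0))
        mcs = [m for _, m in traj]
        assert mcs[0] > 0.62
        assert mcs[-1] < 0.58

    def test_exponential_drying_law_matches_closed_form(self):
        # mc(t) = 0.50 + 0.25 exp(-0.15 t): 0.75 at t=0, 0.5413 at t=12
        cfg = SyntheticConfig(seed=0, replicate_jitter_sd=0.0)
        traj = generate_mc_trajectory(cfg)
        by_time = {t: m for t, m in traj}
        assert by_time[0.0] == pytest.approx(0.75, abs=1e-12)
        expected_12h = 0.50 + 0.25 * math.exp(-0.15 * 12)
        assert expected_12h == pytest.approx(0.5413, abs=5e-5)
        assert by_time[12.0] == pytest.approx(expected_12h, abs=1e-12)

    def test_curve_that_cannot_span_classes_is_rejected(self):
        with pytest.raises(ValueError, match="withering classes"):
            generate_mc_trajectory(SyntheticConfig(seed=0, mc_initial=0.60))
        with pytest.raises(ValueError, match="withering classes"):
            generate_mc_trajectory(SyntheticConfig(seed=0, mc_asymptote=0.70, mc_initial=0.80))


class TestDegreeClassification:
    @pytest.mark.parametrize(
        "mc,degree",
        [
            (0.65, "insufficient"),
            (0.60, "moderate"),
            (0.55, "excessive"),
            (0.62, "moderate"),  # boundaries belong to moderate
            (0.58, "moderate"),
            (0.6201, "insufficient"),
            (0.5799, "excessive"),
        ],
    )
    def test_thresholds(self, mc, degree):
        assert classify_withering_degree(mc) == degree

    @pytest.mark.parametrize("mc", [-0.1, 1.1])
    def test_out_of_range_rejected(self, mc):
        with pytest.raises(ValueError):
            classify_withering_degree(mc)


class TestSpectraBlock:
    def test_water_band_absorbance_increases_with_moisture(self):
        cfg = SyntheticConfig(seed=0, noise_sd=0.0, scatter_sd=0.0, band_response_sd=0.0)
        block, truth = generate_spectra_block(np.array([0.75, 0.55]), cfg)
        ch_1450 = int(np.argmin(np.abs(block.wavelengths - 1450)))
        assert ch_1450 in truth.informative_channel_indices
        assert block.absorbance[0, ch_1450] > block.absorbance[1, ch_1450]

    def test_default_block_shape_is_760_channels(self):
        cfg = SyntheticConfig(seed=0)
        block, _ = generate_spectra_block(np.linspace(0.5, 0.75, 7), cfg)
        assert block.absorbance.shape == (7, 760)

    def test_planted_channels_track_moisture(self):
        # low-noise signal property: every informative channel has
        # |r| > 0.9 with MC after scatter correction, > 0.95 at 1450 nm
        cfg = SyntheticConfig(seed=3, noise_sd=0.001)
        rng = np.random.default_rng(11)
        mc = rng.uniform(0.5, 0.78, 120)
        block, truth = generate_spectra_block(mc, cfg)
        Xs = snv(block.absorbance)
        rs = {
            ch: np.corrcoef(mc, Xs[:, ch])[0, 1] for ch in truth.informative_channel_indices
        }
        assert all(abs(r) > 0.9 for r in rs.values())
        ch_1450 = int(np.argmin(np.abs(block.wavelengths - 1450)))
        assert abs(rs[ch_1450]) > 0.95

    def test_negative_noise_levels_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=0, noise_sd=-0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(seed=0, scatter_sd=-0.1)

    def test_band_center_outside_range_rejected(self):
        with pytest.raises(ValueError, match="band center"):
            SyntheticConfig(seed=0, band_centers=(800.0,), band_widths=(10.0,),
                            band_base_depth=(0.3,), band_mc_coeff=(1.0,),
                            band_is_informative=(True,))

    def test_snv_removes_injected_scatter(self):
        # the additive/multiplicative scatter terms are exactly the class
        # of effects SNV is built to remove: >= 95% of the injected
        # variance must vanish after the transform
        mc = np.linspace(0.5, 0.78, 30)
        clean_cfg = SyntheticConfig(seed=7, noise_sd=0.0, scatter_sd=0.0)
        scat_cfg = SyntheticConfig(seed=7, noise_sd=0.0, scatter_sd=0.08)
        clean, _ = generate_spectra_block(mc, clean_cfg)
        scattered, _ = generate_spectra_block(mc, scat_cfg)
        injected = np.var(scattered.absorbance - clean.absorbance)
        assert injected > 0
        residual = np.var(snv(scattered.absorbance) - snv(clean.absorbance))
        assert residual <= 0.05 * injected


class TestLeafImage:
    def test_leaf_darkens_as_moisture_falls(self):
        cfg = SyntheticConfig(seed=0)
        wet, mask = generate_leaf_image(0.75, cfg, seed=42)
        dry, _ = generate_leaf_image(0.55, cfg, seed=42)
        inside = mask > 0
        assert wet[..., 1][inside].mean() > dry[..., 1][inside].mean()

    def test_texture_roughens_as_moisture_falls(self):
        cfg = SyntheticConfig(seed=0)
        wet, mask = generate_leaf_image(0.75, cfg, seed=42)
        dry, _ = generate_leaf_image(0.55, cfg, seed=42)
        inside = mask > 0
        gray = lambda im: im[inside].astype(float) @ [0.299, 0.587, 0.114]  # noqa: E731
        assert gray(wet).std() < gray(dry).std()

    def test_images_deterministic_under_seed(self):
        cfg = SyntheticConfig(seed=0)
        a, ma = generate_leaf_image(0.66, cfg, seed=9)
        b, mb = generate_leaf_image(0.66, cfg, seed=9)
        assert np.array_equal(a, b) and np.array_equal(ma, mb)

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError, match="image_size"):
            generate_leaf_image(0.6, SyntheticConfig(seed=0, image_size=8), seed=0)


class TestDataset:
    def test_default_dataset_has_195_samples(self, default_dataset):
        _, samples, _ = default_dataset
        assert len(samples) == 195

    def test_sample_count_is_times_by_replicates(self):
        samples, _ = generate_dataset(
            # drying must be fast enough to cross both class boundaries in 2 h
            SyntheticConfig(seed=0, n_times=3, replicates_per_time=1, drying_rate=0.8),
            with_images=False,
        )
        assert len(samples) == 3

    def test_every_degree_class_represented(self, default_dataset):
        _, samples, _ = default_dataset
        degrees = {s.degree for s in samples}
        assert degrees == {"insufficient", "moderate", "excessive"}

    def test_degree_labels_consistent_with_mc(self, default_dataset):
        _, samples, _ = default_dataset
        assert all(s.degree == classify_withering_degree(s.mc) for s in samples)

    def test_identical_seed_gives_identical_dataset(self):
        cfg = SyntheticConfig(seed=5, n_times=4, replicates_per_time=2, image_size=32,
                              drying_rate=0.8)
        a, _ = generate_dataset(cfg)
        b, _ = generate_dataset(cfg)
        for sa, sb in zip(a, b):
            assert sa.sample_id == sb.sample_id
            assert sa.mc == sb.mc
            assert np.array_equal(sa.spectrum, sb.spectrum)
            assert np.array_equal(sa.image, sb.image)

    def test_serialized_dataset_round_trips(self, tmp_path):
        from witherfuse.preprocess import read_spectra_csv
        from witherfuse.synthetic import save_dataset

        cfg = SyntheticConfig(seed=5, n_times=4, replicates_per_time=2, image_size=32,
                              drying_rate=0.8)
        samples, truth = generate_dataset(cfg)
        save_dataset(samples, truth, cfg, tmp_path)
        block = read_spectra_csv(tmp_path / "spectra.csv")
        assert block.n_samples == 8
        assert np.allclose(block.absorbance, np.vstack([s.spectrum for s in samples]))
        assert (tmp_path / "images" / f"{samples[0].sample_id}.png").exists()
        assert (tmp_path / "ground_truth.json").exists()
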