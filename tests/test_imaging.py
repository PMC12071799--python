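"""Color/texture descriptor oracles, normalization, Pearson screening."""

import numpy as np
import pytest

from witherfuse.imaging import (
    FEATURE_NAMES,
    extract_color_features,
    extract_features,
    extract_texture_features,
    minmax_normalize,
    pearson_screen,
)


def solid(rgb, size=8):
    img = np.zeros((size, size, 3), dtype=np.uint8)
    img[:] = rgb
    mask = np.full((size, size), 255, dtype=np.uint8)
    return img, mask


def srgb_to_lab(rgb255):
    """Independent CIELAB oracle: sRGB -> linear -> XYZ (D65) -> Lab."""
    c = np.asarray(rgb255, dtype=float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    M = np.array([[0.4124, 0.3576, 0.1805],
                  [0.2126, 0.7152, 0.0722],
                  [0.0193, 0.1192, 0.9505]])
    xyz = M @ lin
    white = np.array([0.95047, 1.0, 1.08883])
    t = xyz / white
    f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
    L = 116 * f[1] - 16
    a = 500 * (f[0] - f[1])
    b = 200 * (f[1] - f[2])
    return L, a, b


class TestColorFeatures:
    def test_pure_green_definitional_values(self):
        img, mask = solid((0, 255, 0))
        R, G, B, H, S, V, L, a, b, exg, rg, hab = extract_color_features(img, mask)
        assert (R, G, B) == (0.0, 255.0, 0.0)
        assert H == pytest.approx(120.0)
        assert S == pytest.approx(1.0)
        assert V == pytest.approx(1.0)
        assert exg == pytest.approx(510.0)
        assert rg == pytest.approx(0.0)

    def test_white_maps_to_lab_white_point(self):
        img, mask = solid((255, 255, 255))
        f = dict(zip(FEATURE_NAMES, extract_color_features(img, mask)))
        assert f["L"] == pytest.approx(100.0, abs=0.01)
        assert abs(f["a"]) < 0.01 and abs(f["b"]) < 0.01
        assert f["hab"] == 0.0  # achromatic rule

    def test_half_green_half_black_matches_pixel_sum_oracle(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, :, 1] = 255  # two green, two black pixels
        mask = np.full((2, 2), 255, dtype=np.uint8)
        R, G, B, H, S, V, L, a, b, exg, rg, hab = extract_color_features(img, mask)
        assert (R, G, B) == (0.0, 127.5, 0.0)
        # HSV of the mean RGB by the hexcone definitions
        assert H == pytest.approx(120.0)
        assert S == pytest.approx(1.0)
        assert V == pytest.approx(127.5 / 255.0)
        Lo, ao, bo = srgb_to_lab([0, 127.5, 0])
        assert L == pytest.approx(Lo, abs=0.05)
        assert a == pytest.approx(ao, abs=0.05)
        assert b == pytest.approx(bo, abs=0.05)
        assert hab == pytest.approx(np.degrees(np.arctan2(bo, ao)) % 360, abs=0.05)
        assert exg == pytest.approx(255.0)

    def test_zero_green_flags_rg_ratio(self):
        img, mask = solid((10, 0, 0))
        with pytest.warns(UserWarning, match="R/G"):
            f = extract_color_features(img, mask)
        assert np.isnan(f[FEATURE_NAMES.index("rg_ratio")])

    def test_empty_mask_rejected(self):
        img, _ = solid((0, 255, 0))
        with pytest.raises(ValueError, match="mask"):
            extract_color_features(img, np.zeros((8, 8), dtype=np.uint8))


class TestTextureFeatures:
    def test_constant_region_is_smooth_uniform_zero_entropy(self):
        img, mask = solid((100, 100, 100))
        m, delta, r, mu3, U, e = extract_texture_features(img, mask)
        assert delta == 0 and r == 0 and mu3 == 0
        assert U == 1.0 and e == 0.0

    def test_even_black_white_mix(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0] = 255
        mask = np.full((2, 2), 255, dtype=np.uint8)
        m, delta, r, mu3, U, e = extract_texture_features(img, mask)
        assert m == pytest.approx(127.5)
        assert U == pytest.approx(0.5)
        assert e == pytest.approx(1.0)
        assert mu3 == pytest.approx(0.0)
        assert delta == pytest.approx(127.5)

    def test_random_texture_matches_histogram_oracle(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        mask = (rng.random((16, 16)) < 0.7).astype(np.uint8) * 255
        got = extract_texture_features(img, mask)
        # brute-force recomputation from the quantized gray histogram
        gray = np.round(img[mask > 0].astype(float) @ [0.299, 0.587, 0.114]).astype(int)
        p = np.bincount(gray, minlength=256) / gray.size
        z = np.arange(256.0)
        m = (z * p).sum()
        var = ((z - m) ** 2 * p).sum()
        expected = np.array([
            m,
            np.sqrt(var),
            1 - 1 / (1 + var / 255**2),
            ((z - m) ** 3 * p).sum() / 255**2,
            (p**2).sum(),
            -(p[p > 0] * np.log2(p[p > 0])).sum(),
        ])
        assert np.max(np.abs(got - expected)) < 1e-9

    def test_uniformity_and_entropy_move_oppositely_on_two_bin_histograms(self):
        # as a two-level histogram concentrates (mix 0.5 -> 0.95), U rises
        # while e falls: the negative U-e association at histogram level
        Us, es = [], []
        n = 400
        for frac in (0.5, 0.65, 0.8, 0.95):
            k = int(frac * n)
            img = np.zeros((n, 1, 3), dtype=np.uint8)
            img[:k] = 255
            mask = np.full((n, 1), 255, dtype=np.uint8)
            _, _, _, _, U, e = extract_texture_features(img, mask)
            Us.append(U)
            es.append(e)
        assert np.all(np.diff(Us) > 0)
        assert np.all(np.diff(es) < 0)


class TestMaskInvariance:
    def test_background_pixels_do_not_affect_any_feature(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[4:16, 6:14] = 255
        base = extract_features(img, mask)
        tampered = img.copy()
        tampered[mask == 0] = rng.integers(0, 256, ((mask == 0).sum(), 3))
        assert np.array_equal(base, extract_features(tampered, mask))


class TestMinMaxNormalize:
    def test_fit_column_maps_to_unit_interval(self):
        out, mins, maxs = minmax_normalize(np.array([[2.0], [4.0], [6.0]]), np.arange(3))
        assert np.allclose(out.ravel(), [0, 0.5, 1])
        assert mins[0] == 2 and maxs[0] == 6

    def test_constant_column_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out, _, _ = minmax_normalize(np.full((4, 1), 7.0), np.arange(4))
        assert np.all(out == 0)

    def test_rows_outside_fit_range_may_exceed_unit_interval(self):
        X = np.array([[0.0], [10.0], [20.0]])
        out, _, _ = minmax_normalize(X, np.array([0, 1]))  # fit on first two rows
        assert out[2, 0] == pytest.approx(2.0)  # beyond [0, 1] is allowed


class TestPearsonScreen:
    def test_feature_equal_to_mc_is_retained_with_r_one(self):
        rng = np.random.default_rng(6)
        mc = rng.uniform(0.5, 0.8, 50)
        rep = pearson_screen(mc[:, None], mc, cutoff=0.6)
        assert rep.r[0] == pytest.approx(1.0)
        assert rep.retained[0]

    def test_permuted_mc_is_not_retained(self):
        rng = np.random.default_rng(7)
        mc = rng.uniform(0.5, 0.8, 200)
        feat = mc[rng.permutation(200)][:, None]
        rep = pearson_screen(feat, mc, cutoff=0.6)
        assert abs(rep.r[0]) < 0.2
        assert not rep.retained[0]

    def test_matches_covariance_sum_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        rep = pearson_screen(X, y, cutoff=0.3)
        for j in range(6):
            xc = X[:, j] - X[:, j].mean()
            yc = y - y.mean()
            r_oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            assert rep.r[j] == pytest.approx(r_oracle, abs=1e-12)
            assert rep.retained[j] == (abs(r_oracle) >= 0.3)

    def test_zero_variance_feature_excluded(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=30)
        X = np.column_stack([y, np.full(30, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            rep = pearson_screen(X, y, cutoff=0.6)
        assert rep.retained[0] and not rep.retained[1]
        assert np.isnan(rep.r[1])

    def test_pvalues_small_for_strong_correlations(self):
        rng = np.random.default_rng(10)
        mc = rng.uniform(0.5, 0.8, 60)
        X = np.column_stack([mc + rng.normal(0, 0.02, 60)])
        rep = pearson_screen(X, mc, cutoff=0.6)
        assert rep.p_value[0] < 0.01
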