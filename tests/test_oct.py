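import itertools

import numpy as np
import pytest

from momix.containers import OCTVolume
from momix.core import ParameterError
from momix.oct import (
    HARALICK_NAMES,
    annular_frequency_features,
    attenuation_coefficient,
    extract_oct_features,
    haralick_features,
    quantize_levels,
)
from momix.synthetic import generate_oct_phantom


def brute_force_haralick(image, levels):
    """Independent GLCM + 13-statistic implementation with explicit loops.

    Expects an already-quantized integer image with values in [0, levels).
    """
    import warnings

    img = np.asarray(image)
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]  # 0, 45, 90, 135 degrees
    per_angle = []
    for dr, dc in offsets:
        counts = np.zeros((levels, levels))
        nr, nc = img.shape
        for r in range(nr):
            for c in range(nc):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc:
                    counts[img[r, c], img[r2, c2]] += 1
                    counts[img[r2, c2], img[r, c]] += 1  # symmetric
        P = counts / counts.sum()
        per_angle.append(_stats13(P))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.array(per_angle), axis=0)


def _stats13(P):
    L = P.shape[0]
    px = [sum(P[i][j] for j in range(L)) for i in range(L)]
    py = [sum(P[i][j] for i in range(L)) for j in range(L)]
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sd_x = sum((i - mu_x) ** 2 * px[i] for i in range(L)) ** 0.5
    sd_y = sum((j - mu_y) ** 2 * py[j] for j in range(L)) ** 0.5
    psum = [0.0] * (2 * L - 1)
    pdiff = [0.0] * L
    for i in range(L):
        for j in range(L):
            psum[i + j] += P[i][j]
            pdiff[abs(i - j)] += P[i][j]

    def h(vals):
        return -sum(v * np.log2(v) for v in vals if v > 0)

    asm = sum(P[i][j] ** 2 for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * P[i][j] for i in range(L) for j in range(L))
    if sd_x * sd_y > 0:
        corr = sum((i - mu_x) * (j - mu_y) * P[i][j] for i in range(L) for j in range(L)) / (
            sd_x * sd_y
        )
    else:
        corr = np.nan
    var = sum((i - mu_x) ** 2 * P[i][j] for i in range(L) for j in range(L))
    idm = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    savg = sum(k * psum[k] for k in range(2 * L - 1))
    sent = h(psum)
    svar = sum((k - savg) ** 2 * psum[k] for k in range(2 * L - 1))
    ent = h([P[i][j] for i in range(L) for j in range(L)])
    davg = sum(k * pdiff[k] for k in range(L))
    dvar = sum((k - davg) ** 2 * pdiff[k] for k in range(L))
    dent = h(pdiff)
    hx, hy = h(px), h(py)
    hxy1 = -sum(
        P[i][j] * np.log2(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log2(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if px[i] * py[j] > 0
    )
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else np.nan
    arg = 1 - np.exp(-2 * (hxy2 - ent))
    imc2 = np.sqrt(arg) if arg >= 0 else 0.0
    return [asm, contrast, corr, var, idm, savg, svar, sent, ent, dvar, dent, imc1, imc2]


class TestHaralick:
    def test_constant_image_limits(self):
        feats = dict(zip(HARALICK_NAMES, haralick_features(np.full((8, 8), 3.0), levels=8)))
        assert feats["asm"] == pytest.approx(1.0)
        assert feats["contrast"] == pytest.approx(0.0)
        assert np.isnan(feats["correlation"])

    def test_toy_image_matches_brute_force(self):
        img = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]])
        ours = haralick_features(img.astype(float), levels=4)
        ref = brute_force_haralick(img, levels=4)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_exhaustive_all_3x3_binary_images(self):
        # every 3x3 binary image against the brute-force oracle
        for bits in itertools.product([0, 1], repeat=9):
            img = np.array(bits).reshape(3, 3)
            ours = haralick_features(img.astype(float) * 10.0, levels=2)
            ref = brute_force_haralick(quantize_levels(img * 10.0, 2), levels=2)
            np.testing.assert_allclose(ours, ref, atol=1e-10, equal_nan=True)

    def test_checkerboard_maximizes_horizontal_contrast(self):
        # among all 3x3 binary images, the checkerboard attains the maximal
        # 0-degree GLCM contrast
        def contrast_0deg(img):
            counts = np.zeros((2, 2))
            for r in range(3):
                for c in range(2):
                    counts[img[r, c], img[r, c + 1]] += 1
                    counts[img[r, c + 1], img[r, c]] += 1
            P = counts / counts.sum()
            return sum((i - j) ** 2 * P[i, j] for i in range(2) for j in range(2))

        checker = np.indices((3, 3)).sum(axis=0) % 2
        best = max(
            contrast_0deg(np.array(bits).reshape(3, 3))
            for bits in itertools.product([0, 1], repeat=9)
        )
        assert contrast_0deg(checker) == pytest.approx(best)

    def test_quantization_range(self, rng):
        q = quantize_levels(rng.standard_normal((20, 20)), 64)
        assert q.min() == 0 and q.max() == 63

    def test_tiny_slice_rejected(self):
        with pytest.raises(ParameterError):
            haralick_features(np.ones((1, 5)))


class TestAnnularFrequency:
    def test_constant_image_energy_in_dc_annulus(self):
        out = annular_frequency_features(np.full((32, 32), 4.0), n_annuli=8)
        assert out[0] > 0
        assert np.allclose(out[1:], 0.0, atol=1e-10)

    def test_planted_sinusoid_localized(self):
        n = 64
        f = 0.25  # cycles/pixel -> annulus index 5 of 10 (bins of width 0.05)
        x = np.cos(2 * np.pi * f * np.arange(n))
        img = np.tile(x, (n, 1))
        out = annular_frequency_features(img, n_annuli=10)
        assert np.argmax(out[2:]) + 2 == 5

    def test_translation_invariant(self, rng):
        img = rng.standard_normal((32, 32))
        a = annular_frequency_features(img, 10)
        b = annular_frequency_features(np.roll(img, (5, -7), axis=(0, 1)), 10)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_white_noise_flat_profile(self):
        cvs = []
        for seed in range(10):
            img = np.random.default_rng(seed).standard_normal((256, 256))
            out = annular_frequency_features(img, 10)[1:]  # skip DC annulus
            cvs.append(out.std() / out.mean())
        assert np.mean(cvs) < 0.2

    def test_fixed_size_contract(self):
        with pytest.raises(ParameterError):
            annular_frequency_features(np.ones((16, 16)), 10, expected_shape=(32, 32))


class TestAttenuation:
    def test_noiseless_exponential_recovered(self):
        vol = generate_oct_phantom(2.0, shape=(30, 30, 120), speckle=False, seed=0,
                                   noise_floor=1e-6)
        mu, _ = attenuation_coefficient(vol)
        assert mu == pytest.approx(2.0, rel=0.01)

    def test_constant_volume_gives_zero(self):
        vol = OCTVolume(np.ones((20, 20, 60)), pitch_um=(10, 10, 20))
        mu, _ = attenuation_coefficient(vol)
        assert mu == pytest.approx(0.0, abs=1e-6)

    def test_speckled_recovery_within_ten_percent(self):
        errors = []
        for seed in range(20):
            vol = generate_oct_phantom(2.0, shape=(100, 100, 120), speckle=True, seed=seed)
            mu, tile_mus = attenuation_coefficient(vol)
            assert tile_mus.size > 0
            errors.append(abs(mu - 2.0) / 2.0)
        assert np.mean(errors) < 0.10

    def test_scale_invariant(self):
        vol = generate_oct_phantom(1.5, shape=(30, 30, 120), seed=3)
        mu1, _ = attenuation_coefficient(vol)
        scaled = OCTVolume(vol.data * 37.0, pitch_um=vol.pitch_um)
        mu2, _ = attenuation_coefficient(scaled)
        assert mu2 == pytest.approx(mu1, rel=1e-9)

    def test_too_small_lateral_extent_rejected(self):
        vol = OCTVolume(np.ones((5, 5, 40)), pitch_um=(10, 10, 20))
        with pytest.raises(ParameterError):
            attenuation_coefficient(vol, tile=10)


class TestExtractOCT:
    def test_feature_inventory(self):
        vol = generate_oct_phantom(2.0, shape=(40, 40, 80), seed=1)
        feats = extract_oct_features(vol)
        assert len(feats) == 2 * 13 + 2 * 10 + 1

    def test_identical_plane_content_gives_identical_features(self):
        # data independent of row and depth: the XZ and XY planes carry the
        # same 2-D pattern, so per-plane features coincide
        pattern = np.random.default_rng(0).uniform(1, 2, 40)
        data = np.broadcast_to(pattern[None, :, None], (40, 40, 40)).copy()
        vol = OCTVolume(data, pitch_um=(10, 10, 20))
        feats = extract_oct_features(vol)
        for name in HARALICK_NAMES:
            a, b = feats[f"oct.xz_haralick_{name}"], feats[f"oct.xy_haralick_{name}"]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, rel=1e-9)

    def test_texture_scale_increases_haralick_correlation(self):
        diffs = []
        for seed in range(20):
            fine = generate_oct_phantom(2.0, texture_scale=1.0, shape=(30, 30, 80), seed=seed)
            coarse = generate_oct_phantom(2.0, texture_scale=2.0, shape=(30, 30, 80), seed=seed)
            fc = extract_oct_features(fine)["oct.xz_haralick_correlation"]
            cc = extract_oct_features(coarse)["oct.xz_haralick_correlation"]
            diffs.append(cc - fc)
        assert np.mean(diffs) > 0
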