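"""Analytic image, filterbank tiling, demodulation, dominant components."""

import numpy as np
import pytest
from scipy.signal import hilbert
from scipy.stats import spearmanr

import lungcad as lc
from lungcad.amfm import BAND_EDGES, SCALE_COMBINATIONS, halfplane_mask, if_spacing

INNER = (slice(16, -16), slice(16, -16))


class TestAnalyticImage:
    def test_real_part_equals_input(self):
        rng = np.random.default_rng(0)
        image = rng.normal(size=(48, 48))
        z = lc.analytic_image(image)
        np.testing.assert_allclose(z.real, image, rtol=0, atol=1e-9 * np.abs(image).max())

    def test_cosine_becomes_unit_magnitude_exponential(self):
        k1 = np.arange(64)[:, None] * np.ones((1, 64))
        z = lc.analytic_image(np.cos(np.pi / 4 * k1))
        np.testing.assert_allclose(np.abs(z), 1.0, atol=1e-9)

    def test_constant_image_has_zero_imaginary_part(self):
        z = lc.analytic_image(np.full((32, 32), 5.0))
        np.testing.assert_allclose(z.imag, 0.0, atol=1e-9)

    @pytest.mark.parametrize("shape", [(32, 32), (33, 47)])
    def test_matches_per_column_hilbert_construction(self, shape):
        rng = np.random.default_rng(1)
        image = rng.normal(size=shape)
        expected = hilbert(image, axis=0)  # 1D analytic signal down each column
        np.testing.assert_allclose(lc.analytic_image(image), expected, atol=1e-6)


class TestFilterbank:
    def test_25_filters_with_printed_scale_index_ranges(self):
        fb = lc.build_filterbank((64, 64))
        assert len(fb) == 25
        assert fb.scale_of[0] == "LPF"
        assert fb.scale_of[1:7] == ["H"] * 6
        assert fb.scale_of[7:13] == ["M"] * 6
        assert fb.scale_of[13:19] == ["L"] * 6
        assert fb.scale_of[19:25] == ["VL"] * 6

    def test_bandwidth_halves_per_scale(self):
        widths = [BAND_EDGES[s][1] - BAND_EDGES[s][0] for s in ("H", "M", "L", "VL")]
        for wide, narrow in zip(widths, widths[1:]):
            assert narrow / wide == pytest.approx(0.5)

    @pytest.mark.parametrize("shape", [(32, 32), (64, 48), (61, 67)])
    def test_supports_partition_the_halfplane(self, shape):
        fb = lc.build_filterbank(shape)
        union = np.sum([f for f in fb.filters], axis=0)
        half = halfplane_mask(shape)
        assert union.max() == 1.0  # disjoint
        assert np.array_equal(union.astype(bool), half)  # exhaustive

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            lc.build_filterbank((16, 64))

    def test_if_spacing_wider_for_lower_frequencies(self):
        fb = lc.build_filterbank((64, 64))
        s = {scale: if_spacing(fb.center_freq[i]) for i, scale in enumerate(fb.scale_of)}
        assert s["H"] == 1 and s["M"] == 1
        assert s["L"] > s["M"] and s["VL"] >= s["L"]
        assert 1 <= s["LPF"] <= 4


class TestDemodulateChannel:
    def test_zero_image_gives_null_estimates(self):
        fb = lc.build_filterbank((32, 32))
        est = lc.demodulate_channel(np.zeros((32, 32), complex), fb.filters[8], spacing=1)
        assert np.all(est.ia == 0)
        assert np.all(est.if_mag == 0)

    def test_pure_sinusoid_through_its_m_wedge(self):
        img = lc.make_amfm_image("sinusoid", size=128, omega=(np.pi / 4, 0.0))
        fb = lc.build_filterbank((128, 128))
        channels = lc.demodulate_all(img.pixels, fb)
        dom = lc.dominant_component(channels, fb, SCALE_COMBINATIONS[4])  # {M}
        assert np.median(np.abs(dom.if_mag[INNER] - np.pi / 4)) / (np.pi / 4) < 0.02
        assert np.median(np.abs(dom.ia[INNER] - 1.0)) < 0.05

    def test_radial_chirp_if_monotone_with_truth(self):
        img = lc.make_amfm_image("radial_chirp", size=128)
        fb = lc.build_filterbank((128, 128))
        channels = lc.demodulate_all(img.pixels, fb)
        dom = lc.dominant_component(channels, fb, SCALE_COMBINATIONS[5])  # all scales
        truth = np.hypot(img.if_true[0], img.if_true[1])
        rho = spearmanr(dom.if_mag[INNER].ravel(), truth[INNER].ravel()).statistic
        assert rho > 0.95

    def test_out_of_band_sinusoid_attenuated(self):
        lo, hi = BAND_EDGES["L"]
        img = lc.make_amfm_image("sinusoid", size=128, omega=((lo + hi) / 2, 0.0))
        fb = lc.build_filterbank((128, 128))
        channels = lc.demodulate_all(img.pixels, fb)
        dom = lc.dominant_component(channels, fb, SCALE_COMBINATIONS[9])  # {M, H}
        assert dom.ia.max() < 0.1  # vs unit sinusoid amplitude

    def test_shape_mismatch_rejected(self):
        fb = lc.build_filterbank((32, 32))
        with pytest.raises(ValueError):
            lc.demodulate_channel(np.zeros((64, 64), complex), fb.filters[0])


class TestDominantComponent:
    def test_single_channel_combo_is_identity(self):
        img = lc.make_amfm_image("sinusoid", size=64, omega=(np.pi / 32, 0.01))
        fb = lc.build_filterbank((64, 64))
        channels = lc.demodulate_all(img.pixels, fb)
        dom = lc.dominant_component(channels, fb, SCALE_COMBINATIONS[1])  # {LPF}
        lpf = channels[0]
        assert np.array_equal(dom.ia, lpf.ia)
        assert np.array_equal(dom.ip, lpf.ip)

    def test_dominant_ia_is_pointwise_max(self):
        a = lc.make_amfm_image("sinusoid", size=64, omega=(np.pi / 3, 0.0))
        b = lc.make_amfm_image("gaussian_am_sinusoid", size=64, omega=(np.pi / 10, 0.02))
        fb = lc.build_filterbank((64, 64))
        channels = lc.demodulate_all(a.pixels + b.pixels, fb)
        combo = SCALE_COMBINATIONS[0]  # {VL, L, M, H}
        dom = lc.dominant_component(channels, fb, combo)
        stack = np.stack([channels[i].ia for i in fb.indices_for(combo.scales)])
        assert np.array_equal(dom.ia, stack.max(axis=0))

    def test_empty_channel_list_rejected(self):
        with pytest.raises(ValueError):
            lc.dominant_component([])


class TestParameterRecovery:
    def test_random_single_component_images(self):
        """Seeded single-component images: dominant-channel IF within 5%,
        IA within 10% (median over gated interior pixels)."""
        rng = np.random.default_rng(42)
        if_errs, ia_errs = [], []
        for _ in range(3):
            scale = rng.choice(["VL", "L", "M", "H"])
            lo, hi = BAND_EDGES[scale]
            r = rng.uniform(lo + 0.3 * (hi - lo), lo + 0.7 * (hi - lo))
            th = -np.pi / 2 + (int(rng.integers(0, 6)) + 0.5) * np.pi / 6
            th = np.clip(th + rng.uniform(-np.pi / 36, np.pi / 36), -1.5, 1.5)
            img = lc.make_amfm_image(
                "gaussian_am_sinusoid", size=128,
                omega=(r * np.cos(th), r * np.sin(th)), am_sigma=48,
            )
            fb = lc.build_filterbank((128, 128))
            dom = lc.dominant_component(
                lc.demodulate_all(img.pixels, fb), fb, SCALE_COMBINATIONS[0]
            )
            m = np.zeros((128, 128), bool)
            m[INNER] = True
            m &= dom.ia > 0.1 * dom.ia.max()
            if_errs.append(np.median(np.abs(dom.if_mag[m] - r) / r))
            ia_errs.append(np.median(np.abs(dom.ia[m] - img.ia_true[m]) / img.ia_true[m]))
        assert np.median(if_errs) < 0.05
        assert np.median(ia_errs) < 0.10
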