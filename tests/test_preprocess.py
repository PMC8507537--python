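import numpy as np
import pytest

from maflim.core import BANDS, ConfigError, MaflimImage, MaskReason, PixelMask, ValidationError
from maflim.fitting import fit_biexp
from maflim.preprocess import (
    PreprocessConfig,
    apply_manual_mask,
    harmonize_sampling,
    mask_low_snr,
    mask_saturated,
    pixel_snr_db,
    preprocess,
    spatial_average,
    subtract_background,
)
from maflim.simulate import default_class_params, generate_scene, make_irf


def _image_from_traces(trace_fn, rows=6, cols=6, n_time=64, dt=0.25, full_scale=10.0):
    t = np.arange(n_time) * dt
    base = trace_fn(t)
    decay = {b: np.broadcast_to(base, (rows, cols, n_time)).copy() for b in BANDS}
    return MaflimImage(decay=decay, dt=dt, full_scale=full_scale)


class TestConfig:
    @pytest.mark.parametrize("kw", [
        {"kernel_size": 4}, {"kernel_size": 0},
        {"saturation_fraction": 0.0}, {"saturation_fraction": 1.5},
        {"baseline_window": 0},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            PreprocessConfig(**kw)


class TestBackgroundSubtraction:
    def test_constant_offset_removed(self):
        img = _image_from_traces(lambda t: np.exp(-np.maximum(t - 5, 0) / 2) + 7.0)
        cfg = PreprocessConfig(baseline_window=16)
        out = subtract_background(img, cfg)
        for b in BANDS:
            assert abs(out.decay[b][0, 0, :16].mean()) < 1e-12

    def test_all_zero_trace_stays_zero(self):
        img = _image_from_traces(lambda t: np.zeros_like(t))
        out = subtract_background(img, PreprocessConfig())
        for b in BANDS:
            np.testing.assert_array_equal(out.decay[b], 0.0)

    def test_noisy_offset_estimate_within_standard_error(self):
        rng = np.random.default_rng(0)
        t = np.arange(160) * 0.25
        sigma = 0.05
        offset = 3.2
        decay = {}
        for b in BANDS:
            clean = np.exp(-np.maximum(t - 6, 0) / 2)
            decay[b] = (clean + offset + rng.normal(0, sigma, (8, 8, 160)))
        img = MaflimImage(decay=decay, dt=0.25)
        cfg = PreprocessConfig(baseline_window=20)
        out = subtract_background(img, cfg)
        se = sigma / np.sqrt(20)
        for b in BANDS:
            resid = np.abs(out.decay[b][:, :, :20].mean(axis=2))
            assert resid.max() < 10 * se

    def test_window_too_long_rejected(self):
        img = _image_from_traces(lambda t: np.exp(-t))
        with pytest.raises(ConfigError):
            subtract_background(img, PreprocessConfig(baseline_window=64))


class TestSaturationMask:
    def test_clipped_pixels_masked_exactly(self):
        img = _image_from_traces(lambda t: 0.5 * np.exp(-np.maximum(t - 5, 0)))
        img.decay["b452"][2, 3, 30] = 10.0  # at full scale
        img.decay["b390"][4, 1, 10] = 9.9   # above 0.98 * 10
        mask = mask_saturated(img, PreprocessConfig())
        expected = np.zeros((6, 6), dtype=bool)
        expected[2, 3] = expected[4, 1] = True
        np.testing.assert_array_equal(~mask.valid, expected)
        assert set(mask.reason[~mask.valid]) == {int(MaskReason.SATURATED)}

    def test_low_amplitude_not_masked(self):
        img = _image_from_traces(lambda t: np.full_like(t, 1.0), full_scale=10.0)
        assert mask_saturated(img, PreprocessConfig()).n_valid == 36

    def test_unknown_full_scale_rejected(self):
        img = _image_from_traces(lambda t: np.exp(-t), full_scale=None)
        with pytest.raises(ConfigError):
            mask_saturated(img, PreprocessConfig())

    def test_injected_saturation_recovered_from_generator(self):
        h, _ = default_class_params("null")
        from dataclasses import replace
        sc = generate_scene(replace(h, sat_prob=0.05, tooth_prob=0.0),
                            rows=16, cols=16, dt=0.25, n_time=160, seed=5)
        mask = mask_saturated(sc.image, PreprocessConfig())
        np.testing.assert_array_equal(~mask.valid, sc.true_saturated)


class TestSpatialAverage:
    def test_constant_image_unchanged(self):
        img = _image_from_traces(lambda t: np.full_like(t, 3.0))
        out = spatial_average(img, PreprocessConfig(kernel_size=5))
        for b in BANDS:
            np.testing.assert_allclose(out.decay[b], 3.0, rtol=1e-12)

    def test_kernel_one_is_identity(self):
        img = _image_from_traces(lambda t: np.exp(-t))
        img.decay["b390"] += np.random.default_rng(1).random(img.decay["b390"].shape)
        out = spatial_average(img, PreprocessConfig(kernel_size=1))
        np.testing.assert_array_equal(out.decay["b390"], img.decay["b390"])

    def test_single_hot_pixel_spreads_to_kernel_mean(self):
        decay = {b: np.zeros((5, 5, 1)) for b in BANDS}
        for b in BANDS:
            decay[b][2, 2, 0] = 25.0
        img = MaflimImage(decay=decay, dt=0.25)
        out = spatial_average(img, PreprocessConfig(kernel_size=5))
        assert out.decay["b390"][2, 2, 0] == pytest.approx(1.0)

    def test_masked_neighbors_excluded(self):
        decay = {b: np.ones((5, 5, 1)) for b in BANDS}
        for b in BANDS:
            decay[b][0, 0, 0] = 100.0
        img = MaflimImage(decay=decay, dt=0.25)
        mask = PixelMask.all_valid((5, 5))
        hot = np.zeros((5, 5), dtype=bool)
        hot[0, 0] = True
        mask = mask.invalidate(hot, MaskReason.SATURATED)
        out = spatial_average(img, PreprocessConfig(kernel_size=3), mask=mask)
        # neighbor of the hot pixel sees only valid ones
        assert out.decay["b390"][1, 1, 0] == pytest.approx(1.0)

    def test_nonnegativity_and_mass_preservation_for_interior_support(self):
        rng = np.random.default_rng(3)
        decay = {b: np.zeros((12, 12, 2)) for b in BANDS}
        for b in BANDS:
            decay[b][4:8, 4:8, :] = rng.random((4, 4, 2))
        img = MaflimImage(decay=decay, dt=0.25)
        out = spatial_average(img, PreprocessConfig(kernel_size=5))
        for b in BANDS:
            assert out.decay[b].min() >= -1e-12  # up to filter roundoff
            np.testing.assert_allclose(out.decay[b].sum(), img.decay[b].sum(),
                                       rtol=1e-12)

    def test_image_smaller_than_kernel_rejected(self):
        decay = {b: np.ones((3, 3, 2)) for b in BANDS}
        img = MaflimImage(decay=decay, dt=0.25)
        with pytest.raises(ConfigError):
            spatial_average(img, PreprocessConfig(kernel_size=5))


class TestSnrMask:
    def _noisy_image(self, peak_over_noise, rng):
        t = np.arange(128) * 0.25
        clean = peak_over_noise * np.exp(-np.maximum(t - 6, 0) / 2)
        clean[t < 6] = peak_over_noise * np.exp(-((t[t < 6] - 6) ** 2))
        decay = {
            b: clean[None, None, :] + rng.normal(0, 1.0, (6, 6, 128)) for b in BANDS
        }
        return MaflimImage(decay=decay, dt=0.25)

    def test_40db_kept_0db_masked(self):
        rng = np.random.default_rng(0)
        cfg = PreprocessConfig(baseline_window=16)
        good = self._noisy_image(100.0, rng)   # 40 dB
        bad = self._noisy_image(1.0, rng)      # ~0 dB
        assert mask_low_snr(good, cfg).n_valid == 36
        assert mask_low_snr(bad, cfg).n_valid == 0

    def test_zero_noise_gives_infinite_snr_and_keeps_pixel(self):
        t = np.arange(64) * 0.25
        pulse = np.where(t < 5, 0.0, np.exp(-(t - 5) / 2))
        img = MaflimImage(
            decay={b: np.broadcast_to(pulse, (4, 4, 64)).copy() for b in BANDS},
            dt=0.25,
        )
        img = subtract_background(img, PreprocessConfig())
        snr = pixel_snr_db(img, PreprocessConfig())
        assert np.all(np.isinf(snr))
        assert mask_low_snr(img, PreprocessConfig()).n_valid == 16

    def test_masked_fraction_tracks_generator_noise(self):
        """With per-pixel noise tuned so ~20% of pixels sit below 15 dB,
        the masked fraction lands within a few percent of that."""
        rng = np.random.default_rng(7)
        t = np.arange(160) * 0.25
        clean = np.exp(-np.maximum(t - 6, 0) / 2.5)
        clean[t < 6] = np.exp(-((t[t < 6] - 6) ** 2) / 0.5)
        n = 50
        # 20% of pixels get SNR ~ 9 dB, the rest ~ 25 dB
        snr_db = np.where(rng.random((n, n)) < 0.2, 9.0, 25.0)
        sigma = 1.0 / 10 ** (snr_db / 20)
        decay = {
            b: clean[None, None, :] + rng.normal(0, 1, (n, n, 160)) * sigma[..., None]
            for b in BANDS
        }
        img = MaflimImage(decay=decay, dt=0.25)
        cfg = PreprocessConfig(baseline_window=16, kernel_size=1)
        masked_frac = 1 - mask_low_snr(img, cfg).n_valid / n**2
        assert abs(masked_frac - 0.2) < 0.03


class TestManualMask:
    def test_empty_region_list_is_identity(self):
        m = PixelMask.all_valid((6, 6))
        m2 = apply_manual_mask(m, [])
        np.testing.assert_array_equal(m2.valid, m.valid)

    def test_full_rectangle_masks_all(self):
        m = apply_manual_mask(
            PixelMask.all_valid((6, 6)),
            [{"type": "rect", "r0": 0, "c0": 0, "r1": 6, "c1": 6}],
        )
        assert m.n_valid == 0
        assert np.all(m.reason == int(MaskReason.MANUAL))

    def test_two_disjoint_rectangles_mask_exact_count(self):
        regions = [
            {"type": "rect", "r0": 0, "c0": 0, "r1": 2, "c1": 3},  # 6 pixels
            {"type": "rect", "r0": 4, "c0": 4, "r1": 6, "c1": 6},  # 4 pixels
        ]
        m = apply_manual_mask(PixelMask.all_valid((6, 6)), regions)
        assert 36 - m.n_valid == 10

    def test_idempotent(self):
        regions = [{"type": "rect", "r0": 1, "c0": 1, "r1": 3, "c1": 3}]
        m1 = apply_manual_mask(PixelMask.all_valid((6, 6)), regions)
        m2 = apply_manual_mask(m1, regions)
        np.testing.assert_array_equal(m1.valid, m2.valid)
        np.testing.assert_array_equal(m1.reason, m2.reason)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            apply_manual_mask(
                PixelMask.all_valid((6, 6)),
                [{"type": "rect", "r0": 0, "c0": 0, "r1": 7, "c1": 2}],
            )

    def test_polygon_region(self):
        m = apply_manual_mask(
            PixelMask.all_valid((8, 8)),
            [{"type": "poly", "vertices": [(1, 1), (1, 5), (5, 5), (5, 1)]}],
        )
        assert not m.valid[2, 2]
        assert m.valid[7, 7]


class TestHarmonizeSampling:
    def test_same_dt_is_identity(self, small_image, small_irf):
        img2, irf2 = harmonize_sampling(small_image, small_irf, 0.25)
        for b in BANDS:
            np.testing.assert_array_equal(img2.decay[b], small_image.decay[b])

    def test_constant_signal_preserved(self):
        img = _image_from_traces(lambda t: np.full_like(t, 2.5), dt=0.16)
        irf = make_irf(dt=0.16, n_time=64, peak_ns=3.0)
        img2, _ = harmonize_sampling(img, irf, 0.25)
        np.testing.assert_allclose(img2.decay["b390"], 2.5, rtol=1e-12)
        assert img2.dt == 0.25

    def test_upsampling_rejected(self, small_image, small_irf):
        with pytest.raises(ConfigError):
            harmonize_sampling(small_image, small_irf, 0.1)

    def test_fitted_lifetime_stable_across_resampling(self):
        """A tau = 3 ns decay sampled at 6.25 GS/s refits within 1% after
        resampling to the 4 GS/s grid.

        The IRF time-shift parameter is fitted here: interpolating onto a
        coarser grid changes the rectangle-rule quadrature bias by a
        fraction of a sample, which the shift absorbs.
        """
        from maflim.fitting import FitConfig, reconvolve
        from tests.conftest import biexp

        dt_fine = 0.16
        n = 250
        irf = make_irf(dt=dt_fine, n_time=n, peak_ns=4.0)
        truth = biexp(0.5, 3.0, 3.0 + 1e-9)
        y = reconvolve(truth, irf.u["b390"], dt_fine, n, scale=50.0)
        decay = {b: np.broadcast_to(y, (5, 5, n)).copy() for b in BANDS}
        img = MaflimImage(decay=decay, dt=dt_fine)
        cfg = FitConfig(fit_shift=True)
        fit_fine = fit_biexp(y, irf.u["b390"], dt_fine, cfg)
        img2, irf2 = harmonize_sampling(img, irf, 0.25)
        fit = fit_biexp(img2.decay["b390"][0, 0], irf2.u["b390"], 0.25, cfg)
        assert fit.tau_avg == pytest.approx(fit_fine.tau_avg, rel=0.01)
        assert fit.tau_avg == pytest.approx(3.0, rel=0.01)


class TestChain:
    def test_chain_masks_only_grow_and_decisions_stable(self):
        h, _ = default_class_params("null")
        from dataclasses import replace
        sc = generate_scene(replace(h, sat_prob=0.03, tooth_prob=1.0),
                            rows=16, cols=16, dt=0.25, n_time=160, seed=2)
        cfg = PreprocessConfig()
        img1, mask1 = preprocess(sc.image, cfg)
        assert (~mask1.valid[sc.true_saturated]).all()
        # second pass on its own output adds no new mask decisions
        img1.full_scale = sc.image.full_scale
        _, mask2 = preprocess(img1, cfg)
        assert mask2.n_valid >= mask1.n_valid * 0.98
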