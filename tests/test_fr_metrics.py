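import numpy as np
import pytest

from paiq import Image, validate_pair
from paiq.fr_metrics import (
    FRConfigs,
    GMSDConfig,
    METRIC_ORDER,
    MSSSIMConfig,
    S3IMConfig,
    SSIMConfig,
    compute_all_fr,
    fsim,
    gmsd,
    haarpsi,
    iw_ssim,
    ms_gmsd,
    ms_ssim,
    psnr,
    s3im,
    s3im_mask,
    s3im_neighborhood,
    ssim,
    ssim_with_map,
    uqi,
    vif_p,
)
from conftest import random_pair
import oracles


class TestPSNR:
    def test_identical_images_are_infinite(self, rng):
        img = Image(rng.random((32, 32)))
        assert psnr(validate_pair(img, img)).value == np.inf

    def test_uniform_offset_half(self):
        a = Image(np.full((32, 32), 0.2))
        b = Image(np.full((32, 32), 0.7))
        assert psnr(validate_pair(a, b)).value == pytest.approx(6.0206, abs=1e-4)

    def test_checkerboard_mse_001(self):
        base = np.full((32, 32), 0.5)
        checker = 0.1 * ((-1.0) ** (np.add.outer(np.arange(32), np.arange(32))))
        pair = validate_pair(Image(base), Image(base + checker))
        assert psnr(pair).value == pytest.approx(20.0, abs=1e-9)

    def test_matches_skimage(self, noisy_pair):
        from skimage.metrics import peak_signal_noise_ratio

        expected = peak_signal_noise_ratio(
            noisy_pair.reference.pixels, noisy_pair.test.pixels, data_range=1.0
        )
        assert psnr(noisy_pair).value == pytest.approx(expected, abs=1e-10)


class TestSSIM:
    def test_constant_vs_constant_closed_form(self):
        pair = validate_pair(Image(np.ones((32, 32))), Image(np.zeros((32, 32))))
        C1, C2 = 0.01**2, 0.03**2
        expected = (C1 * C2) / ((1 + C1) * C2)  # zero variances, means 1 and 0
        assert ssim(pair).value == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(9.999e-5, rel=1e-3)

    def test_matches_window_loop_oracle(self, rng):
        pair = random_pair(rng, size=40)
        expected = oracles.ssim_windows_loop(
            pair.reference.pixels, pair.test.pixels
        )
        assert ssim(pair).value == pytest.approx(expected, abs=1e-6)

    def test_matches_skimage(self, noisy_pair):
        from skimage.metrics import structural_similarity

        expected = structural_similarity(
            noisy_pair.reference.pixels, noisy_pair.test.pixels,
            win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0,
        )
        assert ssim(noisy_pair).value == pytest.approx(expected, abs=1e-9)

    def test_map_shape_is_valid_grid(self, noisy_pair):
        _, smap = ssim_with_map(noisy_pair)
        assert smap.shape == (118, 118)

    def test_too_small_image_raises(self, rng):
        img = Image(rng.random((9, 9)))
        with pytest.raises(ValueError, match="window"):
            ssim(validate_pair(img, img))


class TestMultiScale:
    def test_single_scale_reduces_to_ssim_map_product(self, rng):
        pair = random_pair(rng, size=48)
        cfg = MSSSIMConfig(scales=1, weights=(1.0,))
        assert ms_ssim(pair, cfg).value == pytest.approx(ssim(pair).value, abs=1e-9)

    def test_matches_literal_product_formula(self, rng):
        pair = random_pair(rng, size=128)
        weights = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
        x, y = pair.reference.pixels, pair.test.pixels
        expected = 1.0
        m = 4  # 128 px supports 4 scales with an 11-px window
        for j in range(m):
            smap, cs, _ = _ssim_maps_reference(x, y)
            expected *= (cs if j < m - 1 else smap) ** weights[j]
            x, y = oracles.meanpool2(x), oracles.meanpool2(y)
        with pytest.warns(UserWarning, match="scales"):
            got = ms_ssim(pair).value
        assert got == pytest.approx(expected, abs=1e-6)

    def test_iw_ssim_with_uniform_weights_equals_ms_ssim(self, rng):
        pair = random_pair(rng, size=128)
        with pytest.warns(UserWarning):
            a = iw_ssim(pair, uniform_weights=True).value
            b = ms_ssim(pair).value
        assert a == pytest.approx(b, abs=1e-6)

    def test_identity(self, vessel):
        pair = validate_pair(vessel, vessel)
        with pytest.warns(UserWarning):
            assert ms_ssim(pair).value == pytest.approx(1.0, abs=1e-9)
            assert iw_ssim(pair).value == pytest.approx(1.0, abs=1e-9)


def _ssim_maps_reference(x, y, data_range=1.0):
    """Scalar means of the SSIM/cs maps via the window-loop oracle machinery."""
    from scipy.signal import fftconvolve

    w = oracles.gaussian_window()
    C1, C2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    mx = fftconvolve(x, w, mode="valid")
    my = fftconvolve(y, w, mode="valid")
    vx = np.maximum(fftconvolve(x * x, w, mode="valid") - mx**2, 0)
    vy = np.maximum(fftconvolve(y * y, w, mode="valid") - my**2, 0)
    vxy = fftconvolve(x * y, w, mode="valid") - mx * my
    lum = (2 * mx * my + C1) / (mx**2 + my**2 + C1)
    cs = (2 * vxy + C2) / (vx + vy + C2)
    return float((lum * cs).mean()), float(cs.mean()), float(lum.mean())


class TestS3IM:
    def test_neighborhood_rule(self):
        assert s3im_neighborhood(128) == 17
        assert s3im_neighborhood(256) == 33
        assert s3im_neighborhood(20) == 3  # floor(20/16)*2+1 = 3

    def test_constant_image_has_empty_mask(self):
        mask = s3im_mask(Image(np.full((64, 64), 0.4)))
        assert not mask.any()

    def test_bright_line_masked_sparsely(self):
        px = np.zeros((128, 128))
        px[60:63, 10:118] = 1.0
        mask = s3im_mask(Image(px))
        assert mask[61, 64]  # the line itself is structure
        assert 0 < mask.mean() < 0.20

    def test_identical_images_give_one(self, vessel):
        assert s3im(validate_pair(vessel, vessel)).value == pytest.approx(1.0, abs=1e-9)

    def test_all_ones_mask_reduces_to_ssim(self, noisy_pair):
        full = np.ones(noisy_pair.reference.shape, dtype=bool)
        masked = s3im(noisy_pair, mask_override=full).value
        assert masked == pytest.approx(ssim(noisy_pair).value, abs=1e-9)

    def test_matches_masked_mean_recomputation(self, vessel, noisy_pair):
        from paiq.fr_metrics import _ssim_maps

        m1 = s3im_mask(noisy_pair.reference)
        m2 = s3im_mask(noisy_pair.test)
        mask = m1 | m2
        smap, _, _ = _ssim_maps(
            noisy_pair.reference.pixels * mask,
            noisy_pair.test.pixels * mask, 1.0, SSIMConfig(),
        )
        mv = mask[5:-5, 5:-5]
        expected = (smap * mv).sum() / mv.sum()
        assert s3im(noisy_pair).value == pytest.approx(expected, abs=1e-9)

    def test_empty_masks_warn_and_return_one(self):
        a = Image(np.full((64, 64), 0.2))
        b = Image(np.full((64, 64), 0.6))
        with pytest.warns(UserWarning, match="empty"):
            assert s3im(validate_pair(a, b)).value == 1.0


class TestGMSDFamily:
    def test_identity_is_zero(self, vessel):
        pair = validate_pair(vessel, vessel)
        assert gmsd(pair).value == 0.0
        assert ms_gmsd(pair).value == 0.0

    def test_two_value_similarity_map_std(self):
        # a map with values {1, 0.5} on equal halves has std 0.25
        vals = np.array([1.0] * 50 + [0.5] * 50)
        assert np.std(vals) == pytest.approx(0.25, abs=1e-12)

    def test_matches_literal_pipeline(self, rng):
        pair = random_pair(rng, size=48)
        expected = oracles.gmsd_literal(pair.reference.pixels, pair.test.pixels)
        assert gmsd(pair).value == pytest.approx(expected, abs=1e-9)

    def test_single_scale_equals_gmsd(self, rng):
        pair = random_pair(rng)
        cfg = GMSDConfig(scales=1)
        assert ms_gmsd(pair, cfg).value == pytest.approx(gmsd(pair, cfg).value, abs=1e-12)

    def test_ms_matches_multiscale_recomputation(self, rng):
        pair = random_pair(rng, size=128)
        x, y = pair.reference.pixels, pair.test.pixels
        vals = []
        for _ in range(4):
            vals.append(oracles.gmsd_literal(x, y))
            x, y = oracles.meanpool2(x), oracles.meanpool2(y)
        expected = np.sqrt(np.mean(np.square(vals)))
        assert ms_gmsd(pair).value == pytest.approx(expected, abs=1e-9)

    def test_variance_option(self, rng):
        pair = random_pair(rng)
        assert gmsd(pair, GMSDConfig(use_variance=True)).value == pytest.approx(
            gmsd(pair).value ** 2, abs=1e-12
        )


class TestVIFAndUQI:
    def test_identity_is_one(self, vessel, rng):
        pair = validate_pair(vessel, vessel)
        assert vif_p(pair).value == pytest.approx(1.0, abs=1e-6)
        # UQI maps fully-empty windows to 0 by its epsilon convention, so its
        # identity check uses an image with signal in every window
        img = Image(rng.random((64, 64)) * 0.8 + 0.1)
        assert uqi(validate_pair(img, img)).value == pytest.approx(1.0, abs=1e-6)

    def test_noise_reduces_vif(self, vessel, rng):
        noisy = Image(np.clip(vessel.pixels + rng.normal(0, 0.3, vessel.shape), 0, 1))
        assert vif_p(validate_pair(vessel, noisy)).value < 1.0

    def test_constant_reference_rejected(self, rng):
        const = Image(np.full((32, 32), 0.5))
        other = Image(rng.random((32, 32)))
        with pytest.raises(ValueError, match="constant"):
            vif_p(validate_pair(const, other))

    def test_vif_matches_window_loop(self, rng):
        pair = random_pair(rng, size=32)
        expected = oracles.vif_windows_loop(pair.reference.pixels, pair.test.pixels)
        assert vif_p(pair).value == pytest.approx(expected, abs=1e-6)

    def test_uqi_matches_window_loop(self, rng):
        pair = random_pair(rng, size=24)
        expected = oracles.uqi_windows_loop(pair.reference.pixels, pair.test.pixels)
        assert uqi(pair).value == pytest.approx(expected, abs=1e-9)

    def test_anticorrelated_uqi_negative(self, rng):
        x = rng.random((32, 32)) * 0.5 + 0.25
        y = 1.0 - x  # negative covariance in every window
        pair = validate_pair(Image(x), Image(y))
        assert uqi(pair).value < 0.0


class TestHaarPSIAndFSIM:
    def test_identity(self, vessel):
        pair = validate_pair(vessel, vessel)
        assert haarpsi(pair).value == pytest.approx(1.0, abs=1e-9)
        assert fsim(pair).value == pytest.approx(1.0, abs=1e-9)

    def test_bounded_on_random_pairs(self, rng):
        for _ in range(10):
            pair = random_pair(rng)
            assert 0.0 <= haarpsi(pair).value <= 1.0 + 1e-9
            assert 0.0 <= fsim(pair).value <= 1.0 + 1e-9

    def test_fsim_alpha_zero_depends_only_on_gradients(self, rng):
        from dataclasses import replace
        from paiq.fr_metrics import FSIMConfig, _phase_congruency, _scharr_magnitude

        pair = random_pair(rng)
        cfg = FSIMConfig(alpha=0.0)
        g1 = _scharr_magnitude(pair.reference.pixels)
        g2 = _scharr_magnitude(pair.test.pixels)
        T2 = cfg.T2
        sg = (2 * g1 * g2 + T2) / (g1**2 + g2**2 + T2)
        pc1 = _phase_congruency(pair.reference.pixels, cfg)
        pc2 = _phase_congruency(pair.test.pixels, cfg)
        pcm = np.maximum(pc1, pc2)
        expected = (sg * pcm).sum() / pcm.sum()
        assert fsim(pair, cfg).value == pytest.approx(expected, abs=1e-9)

    def test_haarpsi_worsens_with_noise(self, vessel, rng):
        small = Image(np.clip(vessel.pixels + rng.normal(0, 0.03, vessel.shape), 0, 1))
        large = Image(np.clip(vessel.pixels + rng.normal(0, 0.3, vessel.shape), 0, 1))
        assert (
            haarpsi(validate_pair(vessel, small)).value
            > haarpsi(validate_pair(vessel, large)).value
        )


class TestDispatcher:
    def test_eleven_results_in_canonical_order(self, noisy_pair):
        with pytest.warns(UserWarning):
            results = compute_all_fr(noisy_pair)
        assert [r.metric for r in results] == list(METRIC_ORDER)
        directions = {r.metric: r.higher_is_better for r in results}
        assert not directions["GMSD"] and not directions["MS-GMSD"]
        assert sum(directions.values()) == 9
        for r in results:
            assert np.isfinite(r.value)

    def test_symmetric_metrics_unchanged_when_pair_reversed(self, noisy_pair):
        from paiq import ImagePair

        reversed_pair = ImagePair(
            reference=noisy_pair.test, test=noisy_pair.reference
        )
        for fn in (psnr, ssim, gmsd, ms_gmsd, uqi):
            assert fn(noisy_pair).value == pytest.approx(
                fn(reversed_pair).value, abs=1e-9
            )

    def test_noise_monotonicity_of_means(self, vessel):
        """Means over replicates decrease (increase for GMSD) with noise level."""
        sigmas = [0.02, 0.05, 0.1, 0.2]
        means = {"SSIM": [], "GMSD": [], "HaarPSI": []}
        for sigma in sigmas:
            vals = {k: [] for k in means}
            for rep in range(5):
                r = np.random.default_rng(1000 + rep)
                noisy = Image(np.clip(vessel.pixels + r.normal(0, sigma, vessel.shape), 0, 1))
                pair = validate_pair(vessel, noisy)
                vals["SSIM"].append(ssim(pair).value)
                vals["GMSD"].append(gmsd(pair).value)
                vals["HaarPSI"].append(haarpsi(pair).value)
            for k in means:
                means[k].append(np.mean(vals[k]))
        assert all(a > b for a, b in zip(means["SSIM"], means["SSIM"][1:]))
        assert all(a > b for a, b in zip(means["HaarPSI"], means["HaarPSI"][1:]))
        assert all(a < b for a, b in zip(means["GMSD"], means["GMSD"][1:]))
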