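"""Wiener, principal-curvature and Otsu stages against brute-force oracles."""

import numpy as np
import pytest

from angioseg import phantom, preprocess
from angioseg.evaluate import dice_jaccard


# ---------------------------------------------------------------------------
# noise estimation


class TestNoiseEstimate:
    def test_constant_image_zero(self):
        assert preprocess.estimate_noise_power(np.full((32, 32), 42.0)) < 1e-9

    def test_recovers_known_sigma(self):
        errs = []
        for seed in range(10):
            noisy = phantom.add_noise(np.full((300, 300), 128.0), 10.0, seed=seed)
            errs.append(preprocess.estimate_noise_sigma(noisy))
        assert abs(np.mean(errs) - 10.0) / 10.0 < 0.2

    def test_doubling_sigma_doubles_estimate(self):
        base = np.full((300, 300), 128.0)
        e1 = preprocess.estimate_noise_sigma(phantom.add_noise(base, 5.0, seed=1))
        e2 = preprocess.estimate_noise_sigma(phantom.add_noise(base, 10.0, seed=1))
        assert 1.6 <= e2 / e1 <= 2.4

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess.estimate_noise_power(np.zeros((8, 8)))


# ---------------------------------------------------------------------------
# Wiener


class TestWiener:
    def test_zero_noise_power_identity(self, rng):
        img = rng.uniform(0, 255, size=(48, 64))
        out = preprocess.wiener_denoise(img, preprocess.WienerSpec(noise_power_estimate=0.0))
        assert np.max(np.abs(out - img)) / np.abs(img).max() < 1e-6

    def test_zero_signal_power_annihilates(self, rng):
        noise = rng.normal(0, 10, size=(64, 64))
        spec = preprocess.WienerSpec(noise_power_estimate=100.0, signal_power_estimate=0.0)
        out = preprocess.wiener_denoise(noise, spec)
        assert np.abs(out).max() < 1e-6 * np.abs(noise).max() + 1e-9

    def test_reduces_mse_on_noisy_phantom(self):
        cfg = phantom.PhantomConfig(size=96, noise_sigma=10.0)
        wins = 0
        for seed in range(10):
            s = phantom.generate_tree(cfg, seed=seed)
            den = preprocess.wiener_denoise(s.image)
            pre = np.mean((s.image - s.clean_image) ** 2)
            post = np.mean((den - s.clean_image) ** 2)
            wins += post < pre
        assert wins >= 9

    def test_nonfinite_input_rejected(self):
        bad = np.zeros((32, 32))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            preprocess.wiener_denoise(bad, preprocess.WienerSpec(noise_power_estimate=1.0))

    def test_gain_clamped(self, rng):
        # even with a wildly overestimated noise power the output is finite
        img = rng.uniform(0, 255, size=(32, 32))
        out = preprocess.wiener_denoise(
            img, preprocess.WienerSpec(noise_power_estimate=1e9)
        )
        assert np.all(np.isfinite(out))


# ---------------------------------------------------------------------------
# principal curvature


class TestCurvature:
    def test_constant_image_zero_curvature(self):
        curv = preprocess.curvature_field(np.full((32, 32), 100.0), 2.0)
        for arr in (curv.k11, curv.k22, curv.k12, curv.G, curv.M, curv.gamma_minus, curv.gamma_plus):
            assert np.abs(arr).max() < 1e-12

    def test_eigen_identities(self, rng):
        img = rng.uniform(0, 255, size=(64, 64))
        curv = preprocess.curvature_field(img, 2.0)
        np.testing.assert_allclose(curv.gamma_minus * curv.gamma_plus, curv.G, atol=1e-8)
        np.testing.assert_allclose(curv.gamma_minus + curv.gamma_plus, 2 * curv.M, atol=1e-8)
        assert np.all(curv.gamma_minus <= curv.gamma_plus + 1e-12)

    def test_eigenvalues_match_hessian_eigendecomposition(self, rng):
        img = rng.uniform(0, 255, size=(64, 64))
        curv = preprocess.curvature_field(img, 2.0)
        ys = rng.integers(0, 64, size=50)
        xs = rng.integers(0, 64, size=50)
        for y, x in zip(ys, xs):
            hess = np.array(
                [[curv.k11[y, x], curv.k12[y, x]], [curv.k12[y, x], curv.k22[y, x]]]
            )
            ev = np.linalg.eigvalsh(hess)
            assert abs(ev[0] - curv.gamma_minus[y, x]) < 1e-8
            assert abs(ev[1] - curv.gamma_plus[y, x]) < 1e-8

    def test_dark_ridge_response_peaks_on_centerline(self):
        # dark ridge of width ~2*sigma on bright background
        img = np.full((64, 64), 200.0)
        img[30:34, :] = 80.0
        enhanced, curv = preprocess.principal_curvature_enhance(img, scale_sigma=2.0)
        ridge_response = curv.gamma_plus[31:33, 10:54].mean()
        off_response = curv.gamma_plus[10:20, 10:54].mean()
        assert ridge_response > off_response
        # contrast ratio after enhancement exceeds the raw image's
        raw_contrast = img[10:20].mean() / img[31:33].mean()
        enh_contrast = (enhanced[31:33, 10:54].mean() + 1) / (enhanced[10:20, 10:54].mean() + 1)
        assert enh_contrast > raw_contrast

    def test_invalid_scale_raises(self):
        with pytest.raises(ValueError):
            preprocess.principal_curvature_enhance(np.zeros((32, 32)), scale_sigma=0.0)


# ---------------------------------------------------------------------------
# Otsu


def otsu_bruteforce(image):
    """Exhaustive-scan argmax of the between-class variance."""
    vals = np.rint(np.asarray(image, dtype=float)).astype(int)
    vmin, vmax = vals.min(), vals.max()
    best_t, best_score = None, -1.0
    n = vals.size
    for t in range(vmin, vmax + 2):
        c1 = vals[vals < t]
        c2 = vals[vals >= t]
        if len(c1) == 0 or len(c2) == 0:
            continue
        w1, w2 = len(c1) / n, len(c2) / n
        score = w1 * w2 * (c1.mean() - c2.mean()) ** 2
        if score > best_score + 1e-12:
            best_score, best_t = score, t
    return best_t


class TestOtsu:
    def test_bimodal_split_exact(self, rng):
        img = rng.choice([10, 200], p=[0.3, 0.7], size=(64, 64))
        t, binary, _ = preprocess.otsu_threshold(img)
        assert 10 < t <= 200
        np.testing.assert_array_equal(binary > 0, img == 200)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = np.clip(
            rng.normal(100, 40, size=(48, 48)) + 60 * (rng.uniform(size=(48, 48)) > 0.6),
            0,
            255,
        )
        t, _, _ = preprocess.otsu_threshold(img)
        assert t == otsu_bruteforce(img)

    def test_shift_equivariance(self, rng):
        img = rng.integers(0, 200, size=(32, 32)).astype(float)
        t0, _, _ = preprocess.otsu_threshold(img)
        t1, _, _ = preprocess.otsu_threshold(img + 37)
        assert t1 == t0 + 37

    def test_constant_image_degenerate(self):
        with pytest.warns(UserWarning):
            t, binary, state = preprocess.otsu_threshold(np.full((16, 16), 99.0))
        assert state.degenerate
        assert binary.sum() == 0

    def test_state_invariants(self, rng):
        img = rng.integers(0, 256, size=(64, 64))
        _, _, st = preprocess.otsu_threshold(img)
        np.testing.assert_allclose(st.w1 + st.w2, 1.0, atol=1e-12)
        np.testing.assert_allclose(
            st.w1 * st.mu1 + st.w2 * st.mu2, st.mu_total, atol=1e-9
        )
        # within- plus between-class variance is the total variance at all t
        np.testing.assert_allclose(
            st.within_var + st.between_var, st.total_var, atol=1e-8
        )


# ---------------------------------------------------------------------------
# pipeline


class TestPreprocessPipeline:
    def test_noiseless_vessel_dice(self, noiseless_vessel_sample):
        s = noiseless_vessel_sample
        res = preprocess.preprocess_pipeline(s.image)
        dice, _ = dice_jaccard(s.mask, res.binary)
        assert dice >= 0.8

    def test_all_background_low_foreground(self):
        cfg = phantom.PhantomConfig(size=96, n_branches=(0, 0), noise_sigma=5.0)
        s = phantom.generate_tree(cfg, seed=2)
        res = preprocess.preprocess_pipeline(s.image)
        assert res.binary.mean() < 0.01

    def test_deterministic(self, noisy_samples):
        img = noisy_samples[0].image
        a = preprocess.preprocess_pipeline(img)
        b = preprocess.preprocess_pipeline(img)
        np.testing.assert_array_equal(a.binary, b.binary)
        np.testing.assert_array_equal(a.denoised, b.denoised)

    def test_outputs_in_intensity_range(self, noisy_samples):
        res = preprocess.preprocess_pipeline(noisy_samples[1].image)
        for arr in (res.denoised, res.enhanced):
            assert arr.min() >= 0.0 and arr.max() <= 255.0
        assert set(np.unique(res.binary)) <= {0.0, 1.0}

    def test_stage_error_attribution(self):
        with pytest.raises(preprocess.StageError) as err:
            preprocess.preprocess_pipeline(np.full((8, 8), 1.0))  # too small for wiener
        assert err.value.stage == "wiener"
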