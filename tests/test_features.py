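"""Threefold features vs direct-summation and enumeration oracles."""

import numpy as np
import pytest

from angioseg import features, phantom, segnet


def disk_mask(size=64, radius=10, center=None):
    c = center or (size / 2, size / 2)
    ys, xs = np.mgrid[0:size, 0:size]
    return (xs - c[0]) ** 2 + (ys - c[1]) ** 2 <= radius**2


class TestDiameter:
    def test_pythagorean_triple(self):
        m = features.DiameterMeasurement.from_points((0, 0), (3, 4))
        assert m.d_m == 5.0

    def test_straight_branch_recovery(self):
        branch = phantom.straight_branch(96, 37.0, 8.0, center=(47.3, 48.6))
        mask = phantom.render_branches([branch], 96)
        assert abs(features.measure_diameter(mask).d_m - 8.0) <= 1.0

    def test_stenosis_minimum_width(self):
        branch = phantom.straight_branch(
            128, 20.0, 8.0, stenosis_fraction=0.5, length_frac=0.8
        )
        mask = phantom.render_branches([branch], 128)
        widths = [m.d_m for m in features.diameter_profile(mask)]
        assert abs(min(widths) - 4.0) <= 1.0

    def test_mean_absolute_error_over_seeded_branches(self):
        rng = np.random.default_rng(21)
        errs = []
        for _ in range(50):
            d = rng.uniform(3, 12)
            ang = rng.uniform(0, 180)
            c = (48 + rng.uniform(-4, 4), 48 + rng.uniform(-4, 4))
            branch = phantom.straight_branch(96, ang, d, center=c)
            mask = phantom.render_branches([branch], 96)
            errs.append(abs(features.measure_diameter(mask).d_m - d))
        assert np.mean(errs) <= 1.0

    def test_thin_region_flagged(self):
        m = np.zeros((16, 16), bool)
        m[8, 2:14] = True  # 1-px line
        profile = features.diameter_profile(m)
        assert profile  # does not crash; degenerate or ~1 px widths
        assert min(p.d_m for p in profile) <= 2.0

    def test_constriction_ratio_detects_stenosis(self):
        healthy = phantom.render_branches(
            [phantom.straight_branch(96, 30.0, 8.0)], 96
        )
        stenosed = phantom.render_branches(
            [phantom.straight_branch(96, 30.0, 8.0, stenosis_fraction=0.5)], 96
        )
        assert features.constriction_ratio(healthy) > 0.8
        assert features.constriction_ratio(stenosed) < 0.7


class TestColorFeatures:
    def test_constant_region(self):
        img = np.full((32, 32), 100.0)
        m = np.ones((32, 32), bool)
        cf = features.color_features(img, m)
        assert cf.mean == 100.0 and cf.standard_deviation == 0.0
        assert cf.skewness == 0.0 and cf.kurtosis == 3.0
        assert cf.constant_region

    def test_symmetric_distribution_low_skew(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 10, size=(128, 128))
        cf = features.color_features(img, np.ones((128, 128), bool))
        assert abs(cf.skewness) < 0.05

    def test_moments_match_loop_oracle(self, rng):
        img = rng.uniform(0, 255, size=(16, 16))
        m = rng.uniform(size=(16, 16)) > 0.3
        cf = features.color_features(img, m)
        vals = [img[i, j] for i in range(16) for j in range(16) if m[i, j]]
        n = len(vals)
        mu = sum(vals) / n
        var = sum((v - mu) ** 2 for v in vals) / n
        sd = var**0.5
        skew = sum(((v - mu) / sd) ** 3 for v in vals) / n
        kurt = sum(((v - mu) / sd) ** 4 for v in vals) / n
        assert cf.mean == pytest.approx(mu, abs=1e-9)
        assert cf.standard_deviation == pytest.approx(sd, abs=1e-9)
        assert cf.skewness == pytest.approx(skew, abs=1e-9)
        assert cf.kurtosis == pytest.approx(kurt, abs=1e-9)

    def test_local_intensity_contrast(self):
        img = np.full((32, 32), 50.0)
        m = disk_mask(32, 6)
        img[m] = 150.0
        cf = features.color_features(img, m)
        assert cf.local_intensity == pytest.approx(100.0)


class TestTextureFeatures:
    def test_constant_region(self):
        tf = features.texture_features(np.full((16, 16), 7.0), np.ones((16, 16), bool))
        assert tf.asm == 1.0 and tf.homogeneity == 1.0 and tf.entropy == 0.0

    def test_checkerboard_hand_oracle(self):
        """2-level checkerboard: horizontal pairs always alternate."""
        img = (np.indices((8, 8)).sum(axis=0) % 2).astype(float) * 100
        m = np.ones((8, 8), bool)
        p = features.glcm(img, m, levels=2, orientations=(0,))
        # every 0-degree pair is (0,1) or (1,0): symmetric matrix is
        # exactly [[0, .5], [.5, 0]]
        np.testing.assert_allclose(p, [[0.0, 0.5], [0.5, 0.0]], atol=1e-12)
        tf = features.texture_features(img, m, levels=2)
        # 4-orientation average: diagonal pairs are equal-valued
        assert 0.0 < tf.asm < 1.0

    def test_glcm_loop_oracle(self, rng):
        img = rng.integers(0, 4, size=(10, 10)).astype(float) * 80
        m = rng.uniform(size=(10, 10)) > 0.3
        levels = 4
        p = features.glcm(img, m, levels=levels, orientations=(0,))
        vals = img[m]
        lo, hi = vals.min(), vals.max()
        quant = np.clip(
            np.floor((img - lo) / (hi - lo) * levels), 0, levels - 1
        ).astype(int)
        counts = np.zeros((levels, levels))
        for i in range(10):
            for j in range(9):
                if m[i, j] and m[i, j + 1]:
                    counts[quant[i, j], quant[i, j + 1]] += 1
                    counts[quant[i, j + 1], quant[i, j]] += 1
        np.testing.assert_allclose(p, counts / counts.sum(), atol=1e-12)

    def test_shift_invariance(self, rng):
        img = rng.uniform(0, 200, size=(24, 24))
        m = disk_mask(24, 9, (12, 12))
        a = features.texture_features(img, m)
        b = features.texture_features(img + 55.0, m)
        for k in ("entropy", "correlation", "homogeneity", "asm"):
            assert getattr(a, k) == pytest.approx(getattr(b, k), abs=1e-12)

    def test_single_pixel_region_rejected(self):
        m = np.zeros((8, 8), bool)
        m[4, 4] = True
        with pytest.raises(ValueError):
            features.texture_features(np.zeros((8, 8)), m)


class TestShapeFeatures:
    def test_disk(self):
        sf = features.shape_features(disk_mask(64, 10))
        assert 0.85 <= sf.roundness <= 1.0
        assert sf.eccentricity < 0.1
        assert sf.solidity > 0.95
        assert sf.artery_area == disk_mask(64, 10).sum()

    def test_bar(self):
        m = np.zeros((128, 128), bool)
        m[60:66, 10:110] = True
        sf = features.shape_features(m)
        assert sf.eccentricity > 0.95
        assert min(sf.artery_angle, 180 - sf.artery_angle) <= 2.0
        assert abs(sf.artery_diameter - 6.0) <= 1.0

    def test_solidity_bounds_and_hull(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(size=(32, 32)) > 0.7
        m[10:20, 10:20] = True  # ensure a solid core
        sf = features.shape_features(m)
        assert 0.0 < sf.solidity <= 1.0
        from skimage.morphology import convex_hull_image

        hull = convex_hull_image(m)
        sf_hull = features.shape_features(hull)
        assert sf_hull.solidity == pytest.approx(1.0)

    def test_rotation_shifts_angle(self):
        base_angle = 20.0
        for rot in (30.0, 60.0):
            b1 = phantom.straight_branch(96, base_angle, 6.0)
            b2 = phantom.straight_branch(96, base_angle + rot, 6.0)
            a1 = features.shape_features(phantom.render_branches([b1], 96)).artery_angle
            a2 = features.shape_features(phantom.render_branches([b2], 96)).artery_angle
            diff = (a2 - a1) % 180
            assert min(abs(diff - rot), abs(180 - diff + rot)) <= 2.0


class TestExtraction:
    def test_all_features_finite_on_seeded_phantoms(self):
        cfg = phantom.PhantomConfig(size=64, noise_sigma=10.0)
        checked = 0
        for seed in range(40):
            s = phantom.generate_tree(cfg, seed=seed)
            vectors = features.extract_features(s.image, s.mask, sample_id=str(seed))
            for v in vectors:
                for key, value in v.as_dict().items():
                    if key == "sample_id":
                        continue
                    assert np.isfinite(float(value)), f"{key} not finite (seed {seed})"
                checked += 1
        assert checked > 20

    def test_feature_table_columns(self):
        cfg = phantom.PhantomConfig(size=64, noise_sigma=0.0, n_branches=(1, 1))
        s = phantom.generate_tree(cfg, seed=1)
        table = features.feature_table(
            features.extract_features(s.image, s.mask, sample_id="s1")
        )
        for col in ("mean", "entropy", "artery_diameter", "solidity", "sample_id"):
            assert col in table.columns

    def test_empty_region_list(self):
        assert features.extract_features(np.zeros((16, 16)), np.zeros((16, 16))) == []
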