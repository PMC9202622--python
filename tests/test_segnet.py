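"""Attention gate, nested U-Net, training and angle estimation."""

import numpy as np
import pytest

from angioseg import phantom, segnet
from angioseg._nn import Tensor
from angioseg.evaluate import dice_jaccard


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestAttentionGate:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.gate = segnet.AttentionGate(c_f=3, c_g=2, c_inter=4, rng=rng)
        self.F = np.random.default_rng(1).normal(size=(1, 3, 4, 4))
        self.G = np.random.default_rng(2).normal(size=(1, 2, 4, 4))

    def test_zero_theta_halves_features(self):
        self.gate.w_theta.weight.data[:] = 0.0
        self.gate.w_theta.bias.data[:] = 0.0
        out = segnet.attention_gate(self.F, self.G, self.gate)
        np.testing.assert_allclose(out, self.F / 2.0, atol=1e-12)

    def test_saturated_bias_passes_features_through(self):
        self.gate.w_theta.weight.data[:] = 0.0
        self.gate.w_theta.bias.data[:] = 50.0
        out = segnet.attention_gate(self.F, self.G, self.gate)
        np.testing.assert_allclose(out, self.F, atol=1e-6)

    def test_scalar_loop_oracle(self):
        """Gate output equals a per-pixel recomputation of its equations."""
        out = segnet.attention_gate(self.F, self.G, self.gate)
        wf = self.gate.w_f.weight.data[:, :, 0, 0]
        bf = self.gate.w_f.bias.data
        wg = self.gate.w_g.weight.data[:, :, 0, 0]
        bg = self.gate.w_g.bias.data
        wt = self.gate.w_theta.weight.data[:, :, 0, 0]
        bt = self.gate.w_theta.bias.data
        for y in range(4):
            for x in range(4):
                fvec = self.F[0, :, y, x]
                gvec = self.G[0, :, y, x]
                inner = np.maximum(wf @ fvec + bf, 0.0) + (wg @ gvec + bg)
                alpha = _sigmoid(wt @ inner + bt)[0]
                assert 0.0 < alpha < 1.0
                np.testing.assert_allclose(out[0, :, y, x], fvec * alpha, atol=1e-6)

    def test_alpha_strictly_in_unit_interval(self):
        alpha = self.gate.coefficients(Tensor(self.F), Tensor(self.G)).data
        assert np.all(alpha > 0.0) and np.all(alpha < 1.0)

    def test_spatial_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segnet.attention_gate(self.F, np.zeros((1, 2, 8, 8)), self.gate)


class TestBuildNetwork:
    def test_forward_shape_and_range(self):
        net = segnet.build_network(segnet.NestedUNetConfig(depth=2, base_channels=4, seed=0))
        prob = net.predict_proba(np.random.default_rng(0).normal(size=(1, 2, 64, 64)))
        assert prob.shape == (1, 1, 64, 64)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_seeded_builds_identical(self):
        cfg = segnet.NestedUNetConfig(seed=9)
        a, b = segnet.build_network(cfg), segnet.build_network(cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_attention_adds_parameters(self):
        base = dict(depth=3, base_channels=4, seed=0)
        without = segnet.build_network(
            segnet.NestedUNetConfig(attention_on_skips=False, **base)
        )
        with_gates = segnet.build_network(
            segnet.NestedUNetConfig(attention_on_skips=True, **base)
        )
        assert with_gates.n_parameters() > without.n_parameters()

    def test_depth_incompatible_input_raises(self):
        net = segnet.build_network(segnet.NestedUNetConfig(depth=3, base_channels=4))
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 2, 6, 6)))

    def test_plain_unet_fallback_runs(self):
        net = segnet.build_network(
            segnet.NestedUNetConfig(depth=3, base_channels=4, nested_skips=False, seed=0)
        )
        prob = net.predict_proba(np.zeros((1, 2, 32, 32)))
        assert prob.shape == (1, 1, 32, 32)

    def test_checkpoint_roundtrip(self, tmp_path):
        net = segnet.build_network(segnet.NestedUNetConfig(depth=2, base_channels=4, seed=3))
        x = np.random.default_rng(0).normal(size=(1, 2, 16, 16))
        before = net.predict_proba(x)
        segnet.save_checkpoint(net, tmp_path / "seg.npz")
        loaded = segnet.load_checkpoint(tmp_path / "seg.npz")
        np.testing.assert_array_equal(loaded.predict_proba(x), before)


@pytest.fixture(scope="module")
def train_set():
    cfg = phantom.PhantomConfig(size=48, n_branches=(1, 2), noise_sigma=5.0,
                                diameter_range=(3.0, 7.0))
    samples = [phantom.generate_tree(cfg, seed=300 + i) for i in range(8)]
    inputs = np.stack([segnet.sample_to_input(s) for s in samples])
    return samples, inputs


class TestTrainSegmenter:
    def test_loss_decreases_over_first_epochs(self, train_set):
        samples, inputs = train_set
        net = segnet.build_network(segnet.NestedUNetConfig(depth=2, base_channels=4, seed=0))
        _, losses = segnet.train_segmenter(
            net, samples, segnet.TrainConfig(epochs=5, seed=0), inputs=inputs
        )
        smoothed = np.convolve(losses, [0.5, 0.5], mode="valid")
        assert np.all(np.diff(smoothed) < 0)

    def test_single_sample_overfit(self):
        cfg = phantom.PhantomConfig(
            size=48, n_branches=(1, 1), noise_sigma=5.0, diameter_range=(6.0, 9.0)
        )
        s = phantom.generate_tree(cfg, seed=5)
        samples = [s] * 8
        inputs = np.stack([segnet.sample_to_input(s)] * 8)
        net = segnet.build_network(segnet.NestedUNetConfig(depth=3, base_channels=8, seed=0))
        net, _ = segnet.train_segmenter(
            net,
            samples,
            segnet.TrainConfig(epochs=50, learning_rate=3e-3, seed=0),
            inputs=inputs,
        )
        res = segnet.segment(s.image, inputs[0][0], net)
        dice, _ = dice_jaccard(s.mask, res.mask)
        assert dice >= 0.95

    def test_deterministic_loss_curves(self, train_set):
        samples, inputs = train_set
        curves = []
        for _ in range(2):
            net = segnet.build_network(
                segnet.NestedUNetConfig(depth=2, base_channels=4, seed=1)
            )
            _, losses = segnet.train_segmenter(
                net, samples, segnet.TrainConfig(epochs=3, seed=1), inputs=inputs
            )
            curves.append(losses)
        assert curves[0] == curves[1]

    def test_too_few_samples_rejected(self, train_set):
        samples, _ = train_set
        net = segnet.build_network(segnet.NestedUNetConfig(depth=2, base_channels=4))
        with pytest.raises(ValueError):
            segnet.train_segmenter(net, samples[:4])


class TestAngleEstimation:
    def test_single_branch_angle_recovery(self):
        for ang in (0.0, 30.0, 45.0, 90.0, 135.0, 179.0):
            branch = phantom.straight_branch(96, ang, 6.0)
            mask = phantom.render_branches([branch], 96)
            regions = segnet.estimate_artery_angles(mask)
            main = max(regions, key=lambda r: r.area_px)
            diff = abs(main.angle_deg - ang) % 180
            assert min(diff, 180 - diff) <= 2.0

    def test_orthogonal_crossing_split(self):
        b1 = phantom.straight_branch(96, 0.0, 6.0)
        b2 = phantom.straight_branch(96, 90.0, 6.0)
        mask = phantom.render_branches([b1, b2], 96)
        regions = segnet.estimate_artery_angles(mask)
        angles = sorted(r.angle_deg if r.angle_deg < 90 + 45 else 180 - r.angle_deg
                        for r in regions)
        assert len(regions) == 2
        assert min(a % 180 for a in angles) <= 5.0
        assert any(abs(a - 90) <= 5.0 for a in angles)

    def test_empty_mask_empty_list(self):
        assert segnet.estimate_artery_angles(np.zeros((32, 32))) == []

    def test_length_and_width_recovery(self):
        branch = phantom.straight_branch(96, 25.0, 8.0)
        mask = phantom.render_branches([branch], 96)
        region = max(segnet.estimate_artery_angles(mask), key=lambda r: r.area_px)
        assert abs(region.mean_width_px - 8.0) <= 1.5
        assert abs(region.length_px - branch.length_px) <= 0.15 * branch.length_px


class TestSegment:
    def test_zero_binary_short_circuits(self):
        net = segnet.build_network(segnet.NestedUNetConfig(depth=2, base_channels=4, seed=0))
        original = np.random.default_rng(0).uniform(0, 255, size=(32, 32))
        res = segnet.segment(original, np.zeros((32, 32)), net)
        assert res.mask.sum() == 0
        assert res.per_artery_regions == []
        assert res.masked_original.sum() == 0

    def test_masked_original_definition(self, train_set):
        samples, inputs = train_set
        net = segnet.build_network(segnet.NestedUNetConfig(depth=2, base_channels=4, seed=0))
        res = segnet.segment(samples[0].image, inputs[0][0], net)
        np.testing.assert_array_equal(
            res.masked_original, np.where(res.mask > 0, samples[0].image, 0.0)
        )

    def test_shape_mismatch_rejected(self, train_set):
        samples, inputs = train_set
        net = segnet.build_network(segnet.NestedUNetConfig(depth=2, base_channels=4))
        with pytest.raises(ValueError):
            segnet.segment(samples[0].image, np.zeros((8, 8)), net)
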