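"""Network architecture, multitask loss, gradients, and training behavior."""

import numpy as np
import pytest
from scipy import ndimage

from cowseg.nn import (ModelConfig, MultitaskOutput, TrainConfig, build_model,
                       dice_loss, multitask_loss, predict_volume, train)
from cowseg.preprocess import PatchSet
from cowseg.volume import Volume


def pixelwise_loss_oracle(I, S, O, F, B, eps=1e-6):
    """Brute-force per-pixel re-implementation with explicit Python loops."""
    nb = I.shape[0]
    recon_sum, dice_sum = 0.0, 0.0
    for b in range(nb):
        num, den = 0.0, 0.0
        for idx in np.ndindex(I.shape[1:]):
            i, s, o = I[b][idx], S[b][idx], O[b][idx]
            recon_sum += (i - (F[b][idx] * o + B[b][idx] * (1 - o))) ** 2
            num += 2 * o * s
            den += o * o + s * s
        dice_sum += 1 - (num + eps) / (den + eps)
    return recon_sum / I.size, dice_sum / nb


class TestArchitecture:
    def test_multitask_heads_share_input_shape(self):
        net = build_model(ModelConfig(base_filters=2))
        out = net.forward(np.zeros((1, 1, 16, 16), dtype=np.float32))
        for arr in (out.O, out.F, out.B):
            assert arr.shape == (1, 1, 16, 16)

    def test_singletask_has_one_head(self):
        net = build_model(ModelConfig(base_filters=2, heads="singletask"))
        out = net.forward(np.zeros((1, 1, 16, 16), dtype=np.float32))
        assert out.F is None and out.B is None
        assert out.O.shape == (1, 1, 16, 16)

    def test_zero_input_forward_is_finite(self):
        net = build_model(ModelConfig(base_filters=2))
        out = net.forward(np.zeros((2, 1, 16, 16), dtype=np.float32))
        for arr in (out.O, out.F, out.B):
            assert np.all(np.isfinite(arr))
        assert np.all((out.O >= 0) & (out.O <= 1))

    def test_parameter_count_reproducible(self):
        a = build_model(ModelConfig(base_filters=4), seed=0)
        b = build_model(ModelConfig(base_filters=4), seed=0)
        assert a.n_params() == b.n_params()
        for (la, na), (lb, nb) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(la.params[na], lb.params[nb])

    def test_indivisible_input_side_rejected(self):
        net = build_model(ModelConfig(base_filters=2))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 20, 20), dtype=np.float32))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(levels=0)
        with pytest.raises(ValueError):
            ModelConfig(aspp_dilations=(2, 1))
        with pytest.raises(ValueError):
            ModelConfig(heads="tritask")

    def test_conv_layer_matches_scipy_correlate(self, rng):
        """Independent forward oracle for the dilated convolution."""
        from cowseg.nn.layers import Conv2d
        for dil in (1, 2):
            conv = Conv2d(2, 3, kernel=3, dilation=dil,
                          rng=np.random.default_rng(5))
            x = rng.random((1, 2, 9, 9)).astype(np.float32)
            out = conv.forward(x)
            W = conv.params["W"].reshape(3, 2, 3, 3)
            expected = np.zeros((3, 9, 9))
            for f in range(3):
                for c in range(2):
                    kern = np.zeros((2 * dil + 1,) * 2)
                    kern[::dil, ::dil] = W[f, c]
                    expected[f] += ndimage.correlate(
                        x[0, c].astype(float), kern, mode="constant")
                expected[f] += conv.params["b"][f]
            np.testing.assert_allclose(out[0], expected, atol=1e-4)


class TestLoss:
    def test_perfect_prediction_gives_zero_total(self, rng):
        S = (rng.random((2, 1, 4, 4)) > 0.5).astype(np.float64)
        assert S.sum() > 0
        I = rng.random((2, 1, 4, 4))
        out = MultitaskOutput(O=S.copy(), F=I.copy(), B=I.copy())
        comps, _ = multitask_loss(I, S, out)
        assert comps.reconstruction == pytest.approx(0.0, abs=1e-10)
        assert comps.dice == pytest.approx(0.0, abs=1e-5)
        assert comps.total == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_prediction_dice_term_is_one(self):
        S = np.zeros((1, 1, 2, 2))
        S[0, 0, 0, :] = 1.0
        O = 1.0 - S
        val, _ = dice_loss(O, S)
        assert val == pytest.approx(1.0, abs=1e-5)

    def test_half_probability_dice_hand_case(self):
        # O = 0.5 everywhere, S = half ones on 2x2: 1 - (2*1)/(1+2) = 1/3
        S = np.zeros((1, 1, 2, 2))
        S[0, 0, 0, :] = 1.0
        O = np.full((1, 1, 2, 2), 0.5)
        val, _ = dice_loss(O, S)
        assert val == pytest.approx(1.0 / 3.0, abs=1e-5)

    def test_total_is_sum_of_components(self, rng):
        I = rng.random((3, 1, 4, 4))
        S = (rng.random((3, 1, 4, 4)) > 0.5).astype(float)
        out = MultitaskOutput(O=rng.random((3, 1, 4, 4)),
                              F=rng.random((3, 1, 4, 4)),
                              B=rng.random((3, 1, 4, 4)))
        comps, _ = multitask_loss(I, S, out)
        assert comps.total == pytest.approx(comps.reconstruction + comps.dice,
                                            rel=1e-12)

    def test_matches_pixelwise_oracle_on_random_4x4(self, rng):
        for _ in range(5):
            I = rng.random((2, 1, 4, 4))
            S = (rng.random((2, 1, 4, 4)) > 0.5).astype(float)
            O = rng.random((2, 1, 4, 4))
            F = rng.random((2, 1, 4, 4))
            B = rng.random((2, 1, 4, 4))
            comps, _ = multitask_loss(I, S, MultitaskOutput(O=O, F=F, B=B))
            recon_ref, dice_ref = pixelwise_loss_oracle(I, S, O, F, B)
            assert comps.reconstruction == pytest.approx(recon_ref, abs=1e-6)
            assert comps.dice == pytest.approx(dice_ref, abs=1e-6)

    def test_both_empty_masks_score_zero_dice(self):
        val, _ = dice_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 4, 4)))
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_reconstruction_invariant_where_weights_saturate(self, rng):
        I = rng.random((1, 1, 4, 4))
        S = np.ones((1, 1, 4, 4))
        O = np.ones((1, 1, 4, 4))  # O = 1: B cannot matter
        F = rng.random((1, 1, 4, 4))
        c1, _ = multitask_loss(I, S, MultitaskOutput(O=O, F=F, B=rng.random(I.shape)))
        c2, _ = multitask_loss(I, S, MultitaskOutput(O=O, F=F, B=rng.random(I.shape)))
        assert c1.reconstruction == pytest.approx(c2.reconstruction, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multitask_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 2, 2)),
                           MultitaskOutput(O=np.zeros((1, 1, 4, 4))))


class TestGradients:
    @pytest.mark.parametrize("heads", ["multitask", "singletask"])
    def test_analytic_matches_finite_differences(self, heads, rng):
        cfg = ModelConfig(levels=3, base_filters=2, aspp_dilations=(1, 2),
                          heads=heads)
        net = build_model(cfg, seed=1)
        for layer, name in net.parameters():
            layer.params[name] = layer.params[name].astype(np.float64)
        x = rng.random((2, 1, 8, 8))
        s = (rng.random((2, 1, 8, 8)) > 0.6).astype(float)

        def total():
            comps, grads = multitask_loss(x, s, net.forward(x, train=True))
            return comps.total, grads

        _, grads = total()
        net.backward(grads["dO"], grads["dF"], grads["dB"])
        analytic = {(id(l), n): l.grads[n].copy() for l, n in net.parameters()}
        eps = 1e-5
        check_rng = np.random.default_rng(7)
        for layer, name in net.parameters():
            flat = layer.params[name].reshape(-1)
            for idx in check_rng.choice(flat.size, min(2, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up, _ = total()
                flat[idx] = orig - eps
                dn, _ = total()
                flat[idx] = orig
                numeric = (up - dn) / (2 * eps)
                exact = analytic[(id(layer), name)].reshape(-1)[idx]
                assert abs(numeric - exact) <= 1e-6 + 1e-2 * max(abs(numeric), abs(exact)), \
                    f"{type(layer).__name__}.{name}: {numeric} vs {exact}"


def _trivial_patchset(n=32, side=16, rng=None):
    rng = rng or np.random.default_rng(0)
    patch = rng.random((side, side)).astype(np.float32)
    mask = (patch > 0.7).astype(np.float32)
    return PatchSet([patch.copy() for _ in range(n)],
                    [mask.copy() for _ in range(n)])


class TestTraining:
    def test_overfit_identical_patches_loss_decreases(self):
        ps = _trivial_patchset()
        net = build_model(ModelConfig(levels=3, base_filters=2,
                                      aspp_dilations=(1, 2)), seed=0)
        tc = TrainConfig(learning_rate=1e-3, epochs=5, batch_size=8, seed=0,
                         augment=False)
        net, hist = train(net, ps, tc)
        totals = [h.total for h in hist]
        assert totals[-1] <= totals[0]
        smoothed = np.convolve(totals, [0.5, 0.5], mode="valid")
        assert all(a >= b - 1e-3 for a, b in zip(smoothed, smoothed[1:]))

    def test_fixed_seed_reproducible_history(self):
        ps = _trivial_patchset()
        histories = []
        for _ in range(2):
            net = build_model(ModelConfig(levels=3, base_filters=2,
                                          aspp_dilations=(1, 2)), seed=3)
            _, hist = train(net, ps, TrainConfig(epochs=2, batch_size=8,
                                                 seed=3, augment=False))
            histories.append([h.total for h in hist])
        assert histories[0] == histories[1]

    def test_empty_patchset_rejected(self):
        net = build_model(ModelConfig(levels=2, base_filters=2,
                                      aspp_dilations=(1, 2)), seed=0)
        with pytest.raises(ValueError):
            train(net, PatchSet([], []), TrainConfig())

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestPredictVolume:
    def _net(self):
        return build_model(ModelConfig(levels=3, base_filters=2,
                                       aspp_dilations=(1, 2)), seed=0)

    def test_threshold_above_all_probabilities_gives_empty_mask(self, rng):
        v = Volume(rng.random((16, 16, 4)).astype(np.float32), (0.5, 0.5, 0.5))
        pred = predict_volume(self._net(), v, threshold=1.0)
        assert pred.data.sum() == 0

    def test_output_grid_matches_input(self, rng):
        v = Volume(rng.random((20, 14, 5)).astype(np.float32), (0.5, 0.5, 0.5))
        pred = predict_volume(self._net(), v)
        assert pred.shape == v.shape
        assert pred.spacing_mm == v.spacing_mm
        assert pred.data.dtype == bool

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = self._net()
        v = Volume(rng.random((16, 16, 3)).astype(np.float32), (0.5, 0.5, 0.5))
        before = predict_volume(net, v, threshold=0.4)
        path = tmp_path / "ckpt.npz"
        net.save(str(path))
        restored = type(net).load(str(path), net.cfg, seed=99)
        after = predict_volume(restored, v, threshold=0.4)
        np.testing.assert_array_equal(before.data, after.data)
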