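"""Segmentation network, weighted cross-entropy loss, and training loop."""

import math

import numpy as np
import pytest

import rvtrack.nn.layers as nnlayers
from rvtrack.nn import (
    LossConfig,
    NetworkConfig,
    RMSProp,
    build_network,
    fit,
    load_model,
    predict,
    save_model,
    train_epoch,
    weighted_ce_loss,
)
from rvtrack.nn.layers import Conv2d, ResidualBlock
from rvtrack.nn.loss import softmax


class TestLossClosedForms:
    def test_uniform_logits_binary_annular(self):
        # C=2, x=[0,0], true class annular, W=[0.2,0.8] -> 0.8*ln 2
        logits = np.zeros((1, 2))
        truth = np.array([1])
        loss = weighted_ce_loss(logits, truth, np.array([0.2, 0.8]))
        assert loss == pytest.approx(0.8 * math.log(2), abs=1e-12)

    def test_confident_true_logit_drives_loss_to_zero(self):
        logits = np.array([[50.0, 0.0, 0.0]])
        loss = weighted_ce_loss(logits, np.array([0]), np.array([0.2, 0.8, 0.8]))
        assert loss < 1e-12

    def test_zero_weight_for_true_class_gives_zero_loss(self, rng):
        logits = rng.normal(size=(5, 3))
        truth = np.full(5, 1)
        loss = weighted_ce_loss(logits, truth, np.array([1.0, 0.0, 1.0]))
        assert loss == 0.0

    def test_matches_closed_form_on_random_pixels(self, rng):
        logits = rng.normal(size=(7, 3))
        truth = rng.integers(0, 3, 7)
        w = np.array([0.2, 0.8, 0.8])
        expected = np.mean([
            -w[truth[i]] * math.log(
                math.exp(logits[i, truth[i]]) / np.exp(logits[i]).sum())
            for i in range(7)
        ])
        assert weighted_ce_loss(logits, truth, w) == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(2, 3, 4, 4))
        truth = rng.integers(0, 3, (2, 4, 4))
        w = LossConfig()
        loss, grad = weighted_ce_loss(logits, truth, w, return_grad=True)
        eps = 1e-6
        for _ in range(10):
            idx = tuple(rng.integers(0, s) for s in logits.shape)
            lp = logits.copy(); lp[idx] += eps
            lm = logits.copy(); lm[idx] -= eps
            num = (weighted_ce_loss(lp, truth, w) -
                   weighted_ce_loss(lm, truth, w)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, abs=1e-6)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="labels outside"):
            weighted_ce_loss(np.zeros((1, 2)), np.array([2]), np.array([1.0, 1.0]))

    def test_softmax_normalizes(self, rng):
        p = softmax(rng.normal(size=(2, 3, 5, 5)), axis=1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


class TestNetwork:
    def test_output_shape_contract(self):
        net = build_network(NetworkConfig(n_classes=3, depth=3,
                                          base_channels=2, input_size=32))
        out = net.forward(np.zeros((2, 32, 32)))
        assert out.shape == (2, 3, 32, 32)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(n_classes=3, depth=5, base_channels=4, input_size=100)

    def test_zeroed_head_gives_uniform_class_probabilities(self, rng):
        net = build_network(NetworkConfig(3, 3, 2, 32), seed=0)
        net.head.weight[...] = 0.0
        net.head.bias[...] = 0.0
        logits = net.forward(rng.random((1, 32, 32)))
        p = softmax(logits, axis=1)
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-7)

    def test_doubling_base_channels_quadruples_block_params(self):
        def conv_params(block):
            return sum(p.size for n, p, _ in block.named_params() if "conv" in n
                       and n.endswith("weight"))
        small = ResidualBlock(8, 8, rng=np.random.default_rng(0))
        big = ResidualBlock(16, 16, rng=np.random.default_rng(0))
        assert conv_params(big) == 4 * conv_params(small)

    def test_backward_matches_finite_differences(self, rng):
        # end-to-end analytic gradients vs central differences in float64
        old = nnlayers.DTYPE
        nnlayers.DTYPE = np.float64
        try:
            net = build_network(NetworkConfig(3, 2, 2, 8), seed=1)
            for _, bn in net.batchnorms():
                bn.momentum = 0.0
            x = rng.normal(size=(2, 8, 8))
            y = rng.integers(0, 3, (2, 8, 8))
            w = LossConfig()
            _, g = weighted_ce_loss(net.forward(x, train=True), y, w,
                                    return_grad=True)
            net.backward(g)
            checked = 0
            for name, p, grad in net.named_params():
                if "conv" in name and name.endswith("bias"):
                    continue  # exactly zero through the following BN
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps, orig = 1e-6, p[idx]
                p[idx] = orig + eps
                lp = weighted_ce_loss(net.forward(x, train=True), y, w)
                p[idx] = orig - eps
                lm = weighted_ce_loss(net.forward(x, train=True), y, w)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                if max(abs(num), abs(grad[idx])) > 1e-7:
                    assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)
                    checked += 1
            assert checked >= 10
        finally:
            nnlayers.DTYPE = old

    def test_save_load_roundtrip(self, rng, tmp_path):
        net = build_network(NetworkConfig(3, 2, 2, 16), seed=5)
        x = rng.random((2, 16, 16)).astype(np.float32)
        before = net.forward(x)
        save_model(net, tmp_path / "model.npz")
        loaded = load_model(tmp_path / "model.npz")
        np.testing.assert_array_equal(loaded.forward(x), before)


def _one_easy_batch(rng, size=32):
    """A bright disk on dark background, labelled class 1."""
    img = rng.random((1, size, size)).astype(np.float32) * 0.1
    mask = np.zeros((1, size, size), dtype=np.uint8)
    rr, cc = np.mgrid[0:size, 0:size]
    disk = (rr - 16) ** 2 + (cc - 20) ** 2 <= 9
    img[0][disk] = 0.9
    mask[0][disk] = 1
    return img, mask


class TestTraining:
    def test_loss_drops_below_uniform_baseline(self, rng):
        img, mask = _one_easy_batch(rng)
        net = build_network(NetworkConfig(3, 2, 4, 32), seed=2)
        history = fit(net, img, mask, epochs=50, batch_size=1, lr=3e-3, seed=0)
        # uniform-logit baseline: every pixel pays -W[i]*ln(1/3)
        w = np.array([0.2, 0.8, 0.8])
        frac1 = (mask == 1).mean()
        baseline = math.log(3) * (0.2 * (1 - frac1) + 0.8 * frac1)
        assert history[-1] < 0.2 * baseline

    def test_overfit_one_batch_segments_the_disk(self, rng):
        img, mask = _one_easy_batch(rng)
        net = build_network(NetworkConfig(3, 2, 4, 32), seed=2)
        fit(net, img, mask, epochs=60, batch_size=1, lr=3e-3, seed=0)
        pred = net.forward(img, train=True).argmax(axis=1)
        agree = (pred == mask).mean()
        assert agree > 0.98

    def test_zero_learning_rate_leaves_parameters_unchanged(self, rng):
        img, mask = _one_easy_batch(rng)
        net = build_network(NetworkConfig(3, 2, 2, 32), seed=3)
        before = {n: p.copy() for n, p, _ in net.named_params()}
        fit(net, img, mask, epochs=2, batch_size=1, lr=0.0, seed=0)
        for n, p, _ in net.named_params():
            np.testing.assert_array_equal(p, before[n])

    def test_training_is_deterministic_under_seed(self, rng):
        img, mask = _one_easy_batch(rng)
        losses = []
        for _ in range(2):
            net = build_network(NetworkConfig(3, 2, 2, 32), seed=4)
            losses.append(fit(net, img, mask, epochs=3, batch_size=1,
                              lr=1e-3, seed=9)[-1])
        assert losses[0] == losses[1]

    def test_nonfinite_loss_aborts_with_guidance(self, rng):
        img, mask = _one_easy_batch(rng)
        net = build_network(NetworkConfig(3, 2, 2, 32), seed=3)
        net.head.weight[...] = 1e30  # force an overflow into inf/nan
        net.head.bias[...] = np.inf
        opt = RMSProp(net, lr=1.0)
        with pytest.raises(RuntimeError, match="learning rate"):
            train_epoch(net, [(img, mask)], LossConfig(), opt)

    def test_inference_deterministic(self, rng):
        net = build_network(NetworkConfig(3, 2, 2, 32), seed=6)
        x = rng.random((3, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(predict(net, x), predict(net, x))
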