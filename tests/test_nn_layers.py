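"""Analytic-vs-numerical gradient checks for the hand-written CNN layers."""

import numpy as np
import pytest

from cimphase.nn.layers import BatchNorm2d, Conv2d, ConvTranspose2, Dropout, MaxPool2, ReLU
from cimphase.nn.unet import ResidualBlock, count_parameters


def numerical_grad(f, arr, idx, eps=1e-6):
    old = arr[idx]
    arr[idx] = old + eps
    lp = f()
    arr[idx] = old - eps
    lm = f()
    arr[idx] = old
    return (lp - lm) / (2 * eps)


def check_param_grads(layer, x, n_checks=6, tol=1e-4):
    rng = np.random.default_rng(0)
    t = rng.standard_normal(layer.forward(x, training=True).shape)

    def loss():
        return float(np.mean((layer.forward(x, training=True) - t) ** 2))

    out = layer.forward(x, training=True)
    layer.backward(2 * (out - t) / out.size)
    grads = {k: v.copy() for k, v in layer.grads.items()}
    for pname, arr in layer.params.items():
        for _ in range(n_checks):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            num = numerical_grad(loss, arr, idx)
            ana = grads[pname][idx]
            assert num == pytest.approx(ana, rel=tol, abs=1e-9), f"{layer.name}/{pname}"


def check_input_grad(layer, x, tol=1e-4, **fwd):
    rng = np.random.default_rng(1)
    t = rng.standard_normal(layer.forward(x.copy(), training=True, **fwd).shape)
    out = layer.forward(x.copy(), training=True, **fwd)
    gx = layer.backward(2 * (out - t) / out.size)
    for _ in range(6):
        idx = tuple(rng.integers(0, s) for s in x.shape)

        def loss(x=x, idx=idx):
            return float(np.mean((layer.forward(x, training=True, **fwd) - t) ** 2))

        num = numerical_grad(loss, x, idx)
        assert num == pytest.approx(gx[idx], rel=tol, abs=1e-9)


@pytest.fixture
def x_small():
    return np.random.default_rng(2).standard_normal((2, 3, 8, 8))


class TestConv2d:
    def test_parameter_counts(self):
        assert count_parameters(Conv2d("c", 1, 16, 3)) == 3 * 3 * 1 * 16 + 16
        assert count_parameters(Conv2d("c", 16, 32, 1, bias=False)) == 16 * 32

    def test_gradients(self, x_small):
        conv = Conv2d("c", 3, 5, 3, rng=np.random.default_rng(3))
        check_param_grads(conv, x_small)
        check_input_grad(conv, x_small)

    def test_1x1_gradients(self, x_small):
        conv = Conv2d("c", 3, 4, 1, rng=np.random.default_rng(4))
        check_param_grads(conv, x_small)
        check_input_grad(conv, x_small)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            Conv2d("c", 1, 1, 2)


class TestBatchNorm:
    def test_normalizes_batch_statistics(self, x_small):
        bn = BatchNorm2d("bn", 3)
        y = bn.forward(x_small, training=True)
        assert np.allclose(y.mean(axis=(0, 2, 3)), 0, atol=1e-7)
        assert np.allclose(y.var(axis=(0, 2, 3)), 1, atol=1e-2)

    def test_gradients(self, x_small):
        bn = BatchNorm2d("bn", 3)
        bn.params["bn_gamma"] = np.random.default_rng(5).uniform(0.5, 1.5, 3)
        check_param_grads(bn, x_small, tol=1e-3)
        check_input_grad(bn, x_small, tol=1e-3)

    def test_eval_uses_running_stats(self, x_small):
        bn = BatchNorm2d("bn", 3)
        for _ in range(50):
            bn.forward(x_small, training=True)
        y = bn.forward(x_small, training=False)
        assert np.allclose(y.mean(axis=(0, 2, 3)), 0, atol=0.1)


class TestPoolAndUpsample:
    def test_maxpool_forward_and_gradient(self):
        x = np.random.default_rng(6).standard_normal((1, 2, 4, 4))
        pool = MaxPool2()
        y = pool.forward(x, training=True)
        assert y.shape == (1, 2, 2, 2)
        assert y[0, 0, 0, 0] == x[0, 0, :2, :2].max()
        g = pool.backward(np.ones_like(y))
        assert g.sum() == y.size  # one unit of gradient per pooled window
        assert np.count_nonzero(g) == y.size

    def test_transposed_conv_shape_and_gradients(self, x_small):
        up = ConvTranspose2("up", 3, 4, rng=np.random.default_rng(7))
        y = up.forward(x_small, training=True)
        assert y.shape == (2, 4, 16, 16)
        check_param_grads(up, x_small)
        check_input_grad(up, x_small)


class TestDropout:
    def test_inactive_at_inference(self, x_small):
        d = Dropout("d", 0.5)
        assert np.array_equal(d.forward(x_small, training=False), x_small)

    def test_preserves_expectation(self):
        d = Dropout("d", 0.25)
        x = np.ones((1, 1, 64, 64))
        y = d.forward(x, training=True, rng=np.random.default_rng(8))
        assert y.mean() == pytest.approx(1.0, abs=0.05)

    def test_gradient_masks_match(self):
        d = Dropout("d", 0.4)
        x = np.random.default_rng(9).standard_normal((1, 1, 16, 16))
        y = d.forward(x, training=True, rng=np.random.default_rng(10))
        mask = (y != 0)
        g = d.backward(np.ones_like(y))
        assert np.array_equal(g != 0, mask)


class TestResidualBlock:
    def test_gradients_through_block(self):
        x = np.random.default_rng(11).standard_normal((2, 3, 8, 8))
        block = ResidualBlock("rb", 3, 4, 3, True, np.random.default_rng(12))

        rng = np.random.default_rng(13)
        t = rng.standard_normal(block.forward(x, training=True).shape)

        def loss():
            return float(np.mean((block.forward(x, training=True) - t) ** 2))

        out = block.forward(x, training=True)
        block.backward(2 * (out - t) / out.size)
        grads = {f"{l.name}/{p}": g.copy() for l in block.layers() for p, g in l.grads.items()}
        for layer in block.layers():
            for pname, arr in layer.params.items():
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                num = numerical_grad(loss, arr, idx)
                assert num == pytest.approx(grads[f"{layer.name}/{pname}"][idx],
                                            rel=1e-3, abs=1e-9)
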