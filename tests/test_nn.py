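"""Gradient and oracle checks for the autodiff engine and layers."""

import numpy as np
import pytest
from scipy import signal

from stomakit.nn import (BasicBlock, BatchNorm2d, CBAM, Conv2d, DeformConv2d,
                         Module, Tensor, batch_norm, conv2d, gather_centers,
                         no_grad, upsample_nearest2x)


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar fn at x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        up = fn()
        x[idx] = orig - eps
        down = fn()
        x[idx] = orig
        g[idx] = (up - down) / (2 * eps)
    return g


def check_gradients(build_loss, tensors, tol=2e-2):
    loss = build_loss()
    loss.backward()
    for t in tensors:
        analytic = t.grad.copy()
        numeric = numeric_grad(lambda: float(build_loss().data), t.data)
        scale = max(1.0, np.abs(numeric).max())
        assert np.allclose(analytic, numeric, atol=tol * scale), \
            f"gradient mismatch: max err " \
            f"{np.abs(analytic - numeric).max():.2e}"


class TestElementwiseOps:
    def test_arithmetic_graph_gradients(self, rng):
        x = Tensor(rng.normal(size=(3, 4)).astype(np.float32), True)
        y = Tensor(rng.normal(size=(4,)).astype(np.float32) + 2.0, True)

        def loss():
            z = (x * y + 1.5) / (y ** 2) - x.abs() * 0.3
            return (z.sigmoid() + z.relu() * 0.1).sum()

        check_gradients(loss, [x, y])

    def test_log_exp_softplus_clip(self, rng):
        x = Tensor(rng.uniform(0.2, 2.0, (5,)).astype(np.float32), True)

        def loss():
            return (x.log() + x.exp() * 0.01 + x.softplus()
                    + x.clip(0.5, 1.5)).sum()

        check_gradients(loss, [x])

    def test_reduce_and_matmul(self, rng):
        a = Tensor(rng.normal(size=(3, 5)).astype(np.float32), True)
        b = Tensor(rng.normal(size=(5, 2)).astype(np.float32), True)

        def loss():
            return ((a @ b).mean(axis=0).sum() + a.max(axis=1).sum()
                    + a.mean())

        check_gradients(loss, [a, b])

    def test_numpy_defers_to_tensor_ops(self):
        x = Tensor(np.ones(3, np.float32), True)
        out = np.array([1.0, 2.0, 3.0], np.float32) * x + np.ones(3)
        assert isinstance(out, Tensor)
        assert out.data.tolist() == [2.0, 3.0, 4.0]


class TestConv2d:
    def test_forward_matches_scipy_correlate(self, rng):
        x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        w = rng.normal(size=(4, 3, 3, 3)).astype(np.float32)
        out = conv2d(Tensor(x), Tensor(w), None, stride=1, padding=1).data
        for n in range(2):
            for f in range(4):
                ref = sum(signal.correlate2d(x[n, c], w[f, c], mode="same")
                          for c in range(3))
                assert np.allclose(out[n, f], ref, atol=1e-4)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_gradients(self, rng, stride):
        x = Tensor(rng.normal(size=(2, 2, 6, 6)).astype(np.float32), True)
        w = Tensor(rng.normal(size=(3, 2, 3, 3)).astype(np.float32), True)
        b = Tensor(rng.normal(size=(3,)).astype(np.float32), True)

        def loss():
            return (conv2d(x, w, b, stride=stride).sigmoid()).sum()

        check_gradients(loss, [x, w, b])


class TestBatchNorm:
    def test_train_mode_normalizes(self, rng):
        x = Tensor(rng.normal(2.0, 3.0, (4, 3, 5, 5)).astype(np.float32))
        bn = BatchNorm2d(3)
        out = bn(x).data
        assert np.allclose(out.mean(axis=(0, 2, 3)), 0, atol=1e-5)
        assert np.allclose(out.std(axis=(0, 2, 3)), 1, atol=1e-3)

    def test_gradients_train_and_eval(self, rng):
        for training in (True, False):
            x = Tensor(rng.normal(size=(2, 2, 4, 4)).astype(np.float32), True)
            g = Tensor(np.ones(2, np.float32) * 1.3, True)
            b = Tensor(np.zeros(2, np.float32), True)
            rm = np.zeros(2, np.float32)
            rv = np.ones(2, np.float32)

            def loss():
                return batch_norm(x, g, b, rm.copy(), rv.copy(),
                                  training).sigmoid().sum()

            check_gradients(loss, [x, g, b])


class TestStructuralOps:
    def test_upsample_nearest_and_gradient(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 3, 3)).astype(np.float32), True)
        out = upsample_nearest2x(x)
        assert out.data.shape == (1, 2, 6, 6)
        assert np.array_equal(out.data[0, 0, :2, :2],
                              np.full((2, 2), x.data[0, 0, 0, 0]))
        check_gradients(lambda: upsample_nearest2x(x).sigmoid().sum(), [x])

    def test_upsample_bilinear_values_and_gradient(self, rng):
        from stomakit.nn import upsample_bilinear2x

        x = Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32), True)
        out = upsample_bilinear2x(x)
        assert out.data.shape == (1, 2, 8, 8)
        # interior sample: out[2i+1] = 0.75 x[i] + 0.25 x[i+1] along each axis
        want = (0.75 * (0.75 * x.data[0, 0, 1, 1] + 0.25 * x.data[0, 0, 1, 2])
                + 0.25 * (0.75 * x.data[0, 0, 2, 1]
                          + 0.25 * x.data[0, 0, 2, 2]))
        assert out.data[0, 0, 3, 3] == pytest.approx(want, abs=1e-6)
        check_gradients(lambda: upsample_bilinear2x(x).sigmoid().sum(), [x])

    def test_gather_centers(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 4, 4)).astype(np.float32), True)
        n = np.array([0, 1, 1])
        ys = np.array([1, 2, 2])
        xs = np.array([0, 3, 2])
        out = gather_centers(x, n, ys, xs)
        assert out.data.shape == (3, 3)
        assert np.allclose(out.data[1], x.data[1, :, 2, 3])
        check_gradients(lambda: gather_centers(x, n, ys, xs).sigmoid().sum(),
                        [x])

    def test_no_grad_suppresses_graph(self):
        x = Tensor(np.ones(3, np.float32), True)
        with no_grad():
            y = (x * 2).sum()
        assert y._backward is None and not y.requires_grad


class TestCompositeModules:
    def test_basic_block_gradcheck(self, rng):
        block = BasicBlock(np.random.default_rng(0), 2, 3, stride=2)
        x = Tensor(rng.normal(size=(1, 2, 6, 6)).astype(np.float32), True)
        params = block.parameters()

        def loss():
            return block(x).sigmoid().sum()

        check_gradients(loss, [x] + params[:2])

    def test_cbam_gates_and_gradients(self, rng):
        cbam = CBAM(np.random.default_rng(0), 4)
        x = Tensor(rng.normal(size=(2, 4, 5, 5)).astype(np.float32), True)
        out = cbam(x)
        assert out.data.shape == x.data.shape
        zero = cbam(Tensor(np.zeros((1, 4, 5, 5), np.float32)))
        assert np.allclose(zero.data, 0.0)
        check_gradients(lambda: cbam(x).sum(), [x])

    def test_deformable_conv_gradients(self, rng):
        layer = DeformConv2d(np.random.default_rng(0), 2, 3)
        # give offsets a nonzero start so their gradient path is exercised
        layer.offset_conv.weight.data += \
            rng.normal(0, 0.05, layer.offset_conv.weight.data.shape) \
            .astype(np.float32)
        x = Tensor(rng.normal(size=(1, 2, 5, 5)).astype(np.float32), True)
        params = [layer.weight, layer.bias, layer.offset_conv.weight]

        def loss():
            return layer(x).sigmoid().sum()

        check_gradients(loss, [x] + params, tol=5e-2)

    def test_state_dict_round_trip(self, rng):
        block = BasicBlock(np.random.default_rng(3), 2, 2)
        x = Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))
        block.eval()
        before = block(x).data.copy()
        state = block.state_dict()
        other = BasicBlock(np.random.default_rng(99), 2, 2)
        other.load_state_dict(state)
        other.eval()
        assert np.allclose(other(x).data, before)
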