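"""Checks of the neural-network engine: convolution against an
independent dilated-correlation oracle, every backward pass against
central finite differences, and the optimizer update rule."""

import numpy as np
import pytest

from rdpnet import nn


def numeric_grad(f, arr, indices, h=1e-2):
    """Central finite difference of scalar f at selected flat indices."""
    grads = []
    flat = arr.reshape(-1)
    for i in indices:
        orig = flat[i]
        flat[i] = orig + h
        fp = f()
        flat[i] = orig - h
        fm = f()
        flat[i] = orig
        grads.append((fp - fm) / (2 * h))
    return np.array(grads)


def check_input_grad(layer, x, atol=2e-3, rtol=5e-2, train=True):
    """Backward dx against finite differences of sum(y * G)."""
    layer.train() if train else layer.eval()
    rng = np.random.default_rng(0)
    y = layer.forward(x.copy())
    G = rng.standard_normal(y.shape).astype(np.float32)

    def loss():
        return float((layer.forward(x) * G).sum())

    layer.forward(x)
    dx = layer.backward(G)
    idx = rng.choice(x.size, size=min(20, x.size), replace=False)
    num = numeric_grad(loss, x, idx)
    assert dx.reshape(-1)[idx] == pytest.approx(num, abs=atol, rel=rtol)


class TestConv1d:
    def test_matches_dilated_correlation_oracle(self):
        """Single-channel forward equals correlation with a kernel whose
        taps are spaced by the dilation (zero-stuffed oracle)."""
        rng = np.random.default_rng(1)
        for stride, dilation, pad in [(1, 1, 0), (1, 2, 4), (2, 1, 2),
                                      (1, 4, 8)]:
            conv = nn.Conv1d(1, 1, 5, stride=stride, dilation=dilation,
                             padding=pad, rng=rng)
            x = rng.standard_normal((1, 1, 64)).astype(np.float32)
            y = conv.forward(x)
            w = conv.weight.data[0, 0]
            stuffed = np.zeros((5 - 1) * dilation + 1, dtype=np.float32)
            stuffed[::dilation] = w
            xp = np.pad(x[0, 0], pad)
            ref = np.correlate(xp, stuffed, mode="valid")[::stride]
            assert y[0, 0] == pytest.approx(ref, abs=1e-4)

    def test_impulse_response_of_box_kernel(self):
        # all-ones kernel on a centered impulse -> 5-tap box
        conv = nn.Conv1d(1, 1, 5, padding=2)
        conv.weight.data[:] = 1.0
        x = np.zeros((1, 1, 11), dtype=np.float32)
        x[0, 0, 5] = 1.0
        y = conv.forward(x)
        assert y[0, 0].tolist() == [0, 0, 0, 1, 1, 1, 1, 1, 0, 0, 0]

    def test_output_length_contract(self):
        conv = nn.Conv1d(2, 3, 5, stride=2, padding=2)
        x = np.zeros((1, 2, 512), dtype=np.float32)
        assert conv.forward(x).shape == (1, 3, 256)

    def test_channel_mismatch_rejected(self):
        conv = nn.Conv1d(2, 3, 5)
        with pytest.raises(ValueError, match="channels"):
            conv.forward(np.zeros((1, 4, 32), dtype=np.float32))

    @pytest.mark.parametrize("stride,dilation", [(1, 1), (2, 1), (1, 3)])
    def test_gradients(self, stride, dilation):
        rng = np.random.default_rng(2)
        conv = nn.Conv1d(2, 3, 3, stride=stride, dilation=dilation,
                         padding=dilation, rng=rng)
        x = rng.standard_normal((2, 2, 16)).astype(np.float32)
        check_input_grad(conv, x)
        # weight gradient
        G = rng.standard_normal(conv.forward(x).shape).astype(np.float32)

        def loss():
            return float((conv.forward(x) * G).sum())

        conv.zero_grad()
        conv.forward(x)
        conv.backward(G)
        idx = rng.choice(conv.weight.data.size, 10, replace=False)
        num = numeric_grad(loss, conv.weight.data, idx)
        assert conv.weight.grad.reshape(-1)[idx] == pytest.approx(
            num, abs=2e-3, rel=5e-2)


class TestBatchNorm:
    def test_normalizes_batch_statistics(self):
        rng = np.random.default_rng(3)
        bn = nn.BatchNorm(4)
        x = (rng.standard_normal((8, 4, 16)) * 3 + 5).astype(np.float32)
        y = bn.forward(x)
        assert y.mean(axis=(0, 2)) == pytest.approx([0] * 4, abs=1e-5)
        assert y.std(axis=(0, 2)) == pytest.approx([1] * 4, abs=1e-3)

    def test_eval_uses_running_statistics(self):
        bn = nn.BatchNorm(2)
        x = np.ones((4, 2, 8), dtype=np.float32)
        bn.eval()
        y = bn.forward(x)  # running mean 0, var 1 -> identity-ish
        assert y == pytest.approx(x, abs=1e-4)

    def test_gradients_3d_and_2d(self):
        rng = np.random.default_rng(4)
        bn = nn.BatchNorm(3)
        check_input_grad(bn, rng.standard_normal((4, 3, 8)).astype(np.float32))
        bn2 = nn.BatchNorm(5)
        check_input_grad(bn2, rng.standard_normal((6, 5)).astype(np.float32))


class TestPoolsAndActivations:
    def test_relu_and_dropout_grads(self):
        rng = np.random.default_rng(5)
        check_input_grad(nn.ReLU(),
                         rng.standard_normal((3, 4, 8)).astype(np.float32))
        drop = nn.Dropout(0.5)
        drop.eval()
        x = rng.standard_normal((3, 8)).astype(np.float32)
        assert drop.forward(x) is x

    def test_dropout_scales_to_preserve_mean(self):
        drop = nn.Dropout(0.25)
        drop.rng = np.random.default_rng(6)
        x = np.ones((200, 100), dtype=np.float32)
        y = drop.forward(x)
        assert y.mean() == pytest.approx(1.0, abs=0.02)

    def test_global_max_pool_grad_routes_to_argmax(self):
        x = np.array([[[1.0, 5.0, 2.0], [3.0, 0.0, -1.0]]], dtype=np.float32)
        pool = nn.GlobalMaxPool()
        y = pool.forward(x)
        assert y.tolist() == [[5.0, 3.0]]
        dx = pool.backward(np.array([[2.0, 7.0]], dtype=np.float32))
        assert dx.tolist() == [[[0, 2, 0], [7, 0, 0]]]

    def test_entropy_pool_grad(self):
        rng = np.random.default_rng(7)
        pool = nn.DifferentialEntropyPool(1e-6)
        check_input_grad(pool,
                         rng.standard_normal((3, 4, 32)).astype(np.float32),
                         atol=5e-3)

    def test_linear_grad(self):
        rng = np.random.default_rng(8)
        lin = nn.Linear(6, 4, rng=rng)
        check_input_grad(lin, rng.standard_normal((5, 6)).astype(np.float32))


class TestOptim:
    def test_clip_reduces_global_norm(self):
        p = nn.Parameter(np.zeros(10, dtype=np.float32))
        p.grad[:] = 3.0
        norm = nn.clip_grad_norm([p], 1.0)
        assert norm == pytest.approx(3.0 * np.sqrt(10))
        assert np.linalg.norm(p.grad) == pytest.approx(1.0, rel=1e-5)

    def test_adam_first_step_size(self):
        # with a constant gradient the first Adam step is ~lr in magnitude
        p = nn.Parameter(np.ones(4, dtype=np.float32))
        p.grad[:] = 0.5
        opt = nn.Adam([p], lr=1e-3)
        opt.step()
        assert p.data == pytest.approx(1.0 - 1e-3, abs=1e-5)

    def test_clipped_step_is_bounded(self):
        # step-size bound: |delta| <= lr * clipped-gradient scale
        rng = np.random.default_rng(9)
        p = nn.Parameter(rng.standard_normal(100).astype(np.float32))
        p.grad[:] = rng.standard_normal(100).astype(np.float32) * 1e3
        before = p.data.copy()
        nn.clip_grad_norm([p], 1e-6)
        opt = nn.Adam([p], lr=5e-4)
        opt.step()
        # Adam normalizes by sqrt(v), so the per-step change is at most lr
        assert np.abs(p.data - before).max() <= 5e-4 + 1e-7
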