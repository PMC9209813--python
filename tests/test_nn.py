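"""NumPy layer engine: forward vs naive oracles, backward vs finite differences."""

import numpy as np
import pytest

from patkit.nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Parameter, ReduceLROnPlateau
from patkit.nn import functional as F


def naive_conv(x, w, b, s, d, p):
    n, c, h, wd = x.shape
    o, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    ho = F.conv_out_size(h, k, s, d, p)
    wo = F.conv_out_size(wd, k, s, d, p)
    y = np.zeros((n, o, ho, wo))
    for nn in range(n):
        for oo in range(o):
            for i in range(ho):
                for j in range(wo):
                    acc = b[oo]
                    for cc in range(c):
                        for u in range(k):
                            for v in range(k):
                                acc += xp[nn, cc, i * s + u * d, j * s + v * d] * w[oo, cc, u, v]
                    y[nn, oo, i, j] = acc
    return y


def naive_conv_transpose(x, w, b, s, p, op):
    cin, cout, k, _ = w.shape
    n, _, h, wd = x.shape
    ho = (h - 1) * s - 2 * p + k + op
    wo = (wd - 1) * s - 2 * p + k + op
    y = np.zeros((n, cout, ho, wo))
    for nn in range(n):
        for c in range(cin):
            for i in range(h):
                for j in range(wd):
                    for o in range(cout):
                        for u in range(k):
                            for v in range(k):
                                r, cc = s * i + u - p, s * j + v - p
                                if 0 <= r < ho and 0 <= cc < wo:
                                    y[nn, o, r, cc] += x[nn, c, i, j] * w[c, o, u, v]
    return y + b[None, :, None, None]


@pytest.mark.parametrize("s, d, p, k", [(1, 1, 1, 3), (2, 1, 1, 3), (1, 2, 2, 3), (1, 1, 0, 1)])
class TestConvForward:
    def test_matches_naive_loop(self, s, d, p, k):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 9, 9))
        w = rng.normal(size=(4, 3, k, k))
        b = rng.normal(size=4)
        np.testing.assert_allclose(F.conv2d(x, w, b, s, d, p), naive_conv(x, w, b, s, d, p), atol=1e-12)


@pytest.mark.parametrize("s, d, p, k", [(1, 1, 1, 3), (2, 1, 1, 3), (1, 2, 2, 3)])
class TestConvBackward:
    def test_input_and_weight_grads_match_finite_differences(self, s, d, p, k):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 3, 8, 8))
        w = rng.normal(size=(4, 3, k, k))
        b = rng.normal(size=4)
        y, cols = F.conv2d(x, w, b, s, d, p, return_cols=True)
        dy = rng.normal(size=y.shape)
        dx = F.conv2d_dx(dy, w, s, d, p, 8, 8)
        dw = F.conv2d_dw(cols, dy, w.shape)
        eps = 1e-6
        for idx in [(0, 1, 2, 3), (1, 2, 7, 7), (0, 0, 0, 0)]:
            xp = x.copy()
            xp[idx] += eps
            num = (np.sum(F.conv2d(xp, w, b, s, d, p) * dy) - np.sum(y * dy)) / eps
            assert dx[idx] == pytest.approx(num, rel=1e-4, abs=1e-6)
        widx = (1, 2, k - 1, 0)
        wp = w.copy()
        wp[widx] += eps
        num = (np.sum(F.conv2d(x, wp, b, s, d, p) * dy) - np.sum(y * dy)) / eps
        assert dw[widx] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestConvTranspose:
    def test_forward_matches_naive_scatter(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 3, 5, 5))
        w = rng.normal(size=(3, 4, 3, 3))
        b = rng.normal(size=4)
        y = F.conv_transpose2d(x, w, b, 2, 1, 1)
        np.testing.assert_allclose(y, naive_conv_transpose(x, w, b, 2, 1, 1), atol=1e-12)
        assert y.shape == (2, 4, 10, 10)  # doubles spatial size

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 2, 4, 4))
        w = rng.normal(size=(2, 3, 3, 3))
        b = rng.normal(size=3)
        y, cols = F.conv_transpose2d(x, w, b, 2, 1, 1, return_cols=True)
        dy = rng.normal(size=y.shape)
        dx = F.conv_transpose2d_dx(dy, w, 2, 1)
        dw = F.conv_transpose2d_dw(cols, dy, w.shape)
        eps = 1e-6
        xp = x.copy()
        xp[0, 1, 2, 2] += eps
        num = (np.sum(F.conv_transpose2d(xp, w, b, 2, 1, 1) * dy) - np.sum(y * dy)) / eps
        assert dx[0, 1, 2, 2] == pytest.approx(num, rel=1e-4)
        wp = w.copy()
        wp[1, 2, 0, 1] += eps
        num = (np.sum(F.conv_transpose2d(x, wp, b, 2, 1, 1) * dy) - np.sum(y * dy)) / eps
        assert dw[1, 2, 0, 1] == pytest.approx(num, rel=1e-4)


class TestBatchNorm:
    def test_train_mode_standardizes_channels(self):
        rng = np.random.default_rng(4)
        bn = BatchNorm2d(3)
        x = (rng.normal(size=(4, 3, 8, 8)) * 5 + 2).astype(np.float32)
        y = bn(x)
        assert np.allclose(y.mean(axis=(0, 2, 3)), 0.0, atol=1e-4)
        assert np.allclose(y.std(axis=(0, 2, 3)), 1.0, atol=1e-3)

    def test_eval_mode_uses_running_stats(self):
        rng = np.random.default_rng(5)
        bn = BatchNorm2d(2)
        for _ in range(50):
            bn(rng.normal(size=(4, 2, 6, 6)).astype(np.float32) * 2 + 1)
        bn.eval()
        x = rng.normal(size=(4, 2, 6, 6)).astype(np.float32) * 2 + 1
        y = bn(x)
        # running stats approximate the generating distribution
        assert np.allclose(y.mean(axis=(0, 2, 3)), 0.0, atol=0.3)

    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        dy = rng.normal(size=x.shape).astype(np.float32)
        bn = BatchNorm2d(3)
        y = bn(x)
        dx = bn.backward(dy)
        eps = 1e-3
        idx = (1, 2, 3, 0)
        xp = x.copy()
        xp[idx] += eps
        num = (np.sum(BatchNorm2d(3)(xp) * dy) - np.sum(BatchNorm2d(3)(x) * dy)) / eps
        assert dx[idx] == pytest.approx(num, rel=0.05, abs=1e-3)


class TestOptim:
    def test_adam_first_step_has_lr_magnitude(self):
        p = Parameter(np.zeros(3))
        p.grad[...] = np.array([1.0, -2.0, 0.5])
        opt = Adam([p], lr=0.01)
        opt.step()
        # first Adam step moves each coordinate by ~lr against the gradient sign
        np.testing.assert_allclose(p.data, [-0.01, 0.01, -0.01], atol=1e-6)

    def test_plateau_scheduler_halves_after_patience(self):
        p = Parameter(np.zeros(1))
        opt = Adam([p], lr=0.001)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=3)
        sched.step(1.0)  # best
        cut = [sched.step(1.0) for _ in range(3)]
        assert cut == [False, False, True]
        assert opt.lr == pytest.approx(0.0005)

    def test_min_lr_floor(self):
        p = Parameter(np.zeros(1))
        opt = Adam([p], lr=2e-6)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=1, min_lr=1e-6)
        sched.step(1.0)
        sched.step(1.0)
        assert opt.lr == pytest.approx(1e-6)
        sched.step(1.0)
        assert opt.lr == pytest.approx(1e-6)
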