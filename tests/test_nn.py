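"""Layer-level checks: adjoint consistency for the linear operators,
finite-difference gradients for the nonlinear ones, and optimizer math."""

import numpy as np
import pytest

from druseg import nn


@pytest.fixture
def x4(rng):
    return (rng.standard_normal((6, 4, 8, 3)) * 0.5).astype(np.float32)


class TestGemmAcc:
    def test_accumulates(self, rng):
        a = rng.standard_normal((5, 7)).astype(np.float32)
        b = rng.standard_normal((7, 3)).astype(np.float32)
        c = rng.standard_normal((5, 3)).astype(np.float32)
        want = c + a @ b
        nn.gemm_acc(a, b, c)
        np.testing.assert_allclose(c, want, atol=1e-5)

    def test_transposed_operands(self, rng):
        a = rng.standard_normal((7, 5)).astype(np.float32)
        b = rng.standard_normal((3, 7)).astype(np.float32)
        c = np.zeros((5, 3), dtype=np.float32)
        nn.gemm_acc(a.T, b.T, c)
        np.testing.assert_allclose(c, a.T @ b.T, atol=1e-5)

    def test_beta_zero_overwrites(self, rng):
        a = rng.standard_normal((4, 4)).astype(np.float32)
        b = rng.standard_normal((4, 4)).astype(np.float32)
        c = np.full((4, 4), 99.0, dtype=np.float32)
        nn.gemm_acc(a, b, c, beta=0.0)
        np.testing.assert_allclose(c, a @ b, atol=1e-5)


def _adjoint_check(layer, x, rng, atol=1e-3):
    """<f(x) - f(0), dy> must equal <x, f^T(dy)> for a linear layer."""
    y = layer.forward(x)
    y0 = layer.forward(np.zeros_like(x))
    dy = rng.standard_normal(y.shape).astype(np.float32)
    layer.forward(x)
    dx = layer.backward(dy.copy())
    lhs = float(((y - y0) * dy).sum())
    rhs = float((x.astype(np.float64) * dx).sum())
    assert lhs == pytest.approx(rhs, rel=1e-3, abs=atol)


class TestLinearLayers:
    def test_conv1x1_adjoint(self, rng, x4):
        _adjoint_check(nn.Conv1x1(3, 5, rng), x4, rng)

    def test_downconv_adjoint(self, rng, x4):
        _adjoint_check(nn.DownConv2(3, 6, rng), x4, rng)

    def test_upconv_adjoint(self, rng, x4):
        _adjoint_check(nn.UpConv2(3, 2, rng), x4, rng)

    def test_down_then_up_restores_shape(self, rng, x4):
        down = nn.DownConv2(3, 6, rng)
        up = nn.UpConv2(6, 3, rng)
        assert up.forward(down.forward(x4)).shape == x4.shape

    def test_down_halves_up_doubles(self, rng, x4):
        assert nn.DownConv2(3, 6, rng).forward(x4).shape == (3, 2, 4, 6)
        assert nn.UpConv2(3, 2, rng).forward(x4).shape == (12, 8, 16, 2)

    def test_down_rejects_odd_dims(self, rng):
        with pytest.raises(ValueError, match="even"):
            nn.DownConv2(2, 4, rng).forward(
                np.zeros((5, 4, 4, 2), dtype=np.float32))

    def test_down_rejects_degenerate_input(self, rng):
        with pytest.raises(ValueError):
            nn.DownConv2(1, 2, rng).forward(
                np.zeros((1, 1, 1, 1), dtype=np.float32))

    def test_weight_grads_match_fd(self, rng, x4):
        from .oracles import fd_param_grad
        layer = nn.DownConv2(3, 4, rng)
        dy = rng.standard_normal((3, 2, 4, 4)).astype(np.float32)
        layer.forward(x4)
        layer.backward(dy.copy())

        def loss():
            return float((layer.forward(x4) * dy).sum())

        for p in layer.params():
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            num = fd_param_grad(p.value, idx, loss)
            assert p.grad[idx] == pytest.approx(num, rel=1e-2, abs=1e-2)


class TestGroupNorm:
    @pytest.mark.parametrize("leading", [False, True])
    def test_normalizes_groups(self, rng, leading):
        gn = nn.GroupNorm(4, 2, channels_leading=leading)
        if leading:
            x = rng.standard_normal((4, 100)).astype(np.float32) * 3 + 1
        else:
            x = rng.standard_normal((5, 5, 4, 4)).astype(np.float32) * 3 + 1
        y = gn.forward(x)
        yg = gn._grouped(y)
        np.testing.assert_allclose(yg.mean(axis=1), 0.0, atol=1e-4)
        np.testing.assert_allclose(yg.std(axis=1), 1.0, atol=1e-2)

    @pytest.mark.parametrize("leading", [False, True])
    def test_gradients_match_fd(self, rng, leading):
        from .oracles import fd_param_grad
        gn = nn.GroupNorm(4, 2, channels_leading=leading)
        shape = (4, 60) if leading else (3, 4, 5, 4)
        x = rng.standard_normal(shape).astype(np.float32)
        dy = rng.standard_normal(shape).astype(np.float32)
        gn.forward(x)
        dx = gn.backward(dy.copy())

        def loss_x():
            return float((gn.forward(xv) * dy).sum())

        eps = 1e-3
        for _ in range(5):
            i = tuple(rng.integers(0, s) for s in shape)
            xv = x.copy()
            xv[i] = np.float32(x[i] + eps)
            lp = loss_x()
            xv[i] = np.float32(x[i] - eps)
            lm = loss_x()
            num = (lp - lm) / (float(np.float32(x[i] + eps))
                               - float(np.float32(x[i] - eps)))
            assert dx[i] == pytest.approx(num, rel=2e-2, abs=1e-2)

        xv = x
        for p in gn.params():
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            num = fd_param_grad(p.value, idx, loss_x)
            assert p.grad[idx] == pytest.approx(num, rel=1e-2, abs=1e-2)

    def test_rejects_indivisible_groups(self):
        with pytest.raises(ValueError):
            nn.GroupNorm(6, 4)


class TestActivations:
    def test_leaky_relu_values_and_grad(self, rng):
        act = nn.LeakyReLU(0.01)
        x = np.array([[-2.0, 3.0]], dtype=np.float32)
        np.testing.assert_allclose(act.forward(x), [[-0.02, 3.0]])
        np.testing.assert_allclose(act.backward(np.ones_like(x)),
                                   [[0.01, 1.0]])

    def test_sigmoid_range_and_grad(self, rng):
        act = nn.Sigmoid()
        x = rng.standard_normal((50,)).astype(np.float32) * 3
        y = act.forward(x)
        assert ((y > 0) & (y < 1)).all()
        dy = np.ones_like(x)
        dx = act.backward(dy)
        np.testing.assert_allclose(dx, y * (1 - y), atol=1e-6)

    def test_sigmoid_extreme_logits_stay_finite(self):
        act = nn.Sigmoid()
        y = act.forward(np.array([-500.0, 500.0], dtype=np.float32))
        assert np.isfinite(y).all()


class TestAdam:
    def test_first_step_is_lr_sized(self):
        p = nn.Param(np.zeros(3))
        opt = nn.Adam([p], lr=0.1)
        p.grad[:] = [1.0, -2.0, 0.5]
        opt.step()
        # bias-corrected first step moves by ~lr in the gradient direction
        np.testing.assert_allclose(p.value, [-0.1, 0.1, -0.1], atol=1e-6)

    def test_matches_reference_updates(self, rng):
        p = nn.Param(rng.standard_normal(4))
        opt = nn.Adam([p], lr=1e-2)
        ref = p.value.astype(np.float64).copy()
        m = np.zeros(4)
        v = np.zeros(4)
        for t in range(1, 6):
            g = rng.standard_normal(4).astype(np.float32)
            p.zero_grad()
            p.grad += g
            opt.step()
            m = 0.9 * m + 0.1 * g
            v = 0.999 * v + 0.001 * g * g
            ref -= 1e-2 * (m / (1 - 0.9 ** t)) \
                / (np.sqrt(v / (1 - 0.999 ** t)) + 1e-8)
            np.testing.assert_allclose(p.value, ref, atol=1e-5)
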