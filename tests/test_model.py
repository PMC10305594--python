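import numpy as np
import pytest

from druseg.losses import dbce_loss
from druseg.model import (DenseResidualBlock, NetworkConfig,
                          TransitionDown, TransitionUp, build_drunet,
                          load_checkpoint, save_checkpoint)

from .oracles import fd_param_grad, naive_dense_block_forward


def _dense_block_param_count(cin, cout, units, gn_params=True):
    total = 0
    for i in range(units):
        ci = cin + i * cout
        total += 27 * ci * cout + cout          # conv weight + bias
        if gn_params:
            total += 2 * cout                   # gamma + beta
    total += cin * cout + cout                  # 1x1x1 skip path
    return total


def _transition_param_count(cin, cout):
    return 8 * cin * cout + cout + 2 * cout     # strided conv + GN


class TestDenseResidualBlock:
    def test_forward_matches_naive_float64_reference(self, rng):
        cfg = NetworkConfig(base_width=4, units_per_block=3, seed=1)
        blk = DenseResidualBlock(3, 4, cfg, rng)
        x = (rng.standard_normal((6, 4, 8, 3)) * 0.4).astype(np.float32)
        fast = blk.forward(x)
        ref = naive_dense_block_forward(blk, x)
        np.testing.assert_allclose(fast, ref, atol=1e-4)

    def test_gradients_match_fd_of_naive_reference(self, rng):
        cfg = NetworkConfig(base_width=4, units_per_block=3, seed=1)
        blk = DenseResidualBlock(3, 4, cfg, rng)
        x = (rng.standard_normal((4, 4, 6, 3)) * 0.4).astype(np.float32)
        y = blk.forward(x)
        dy = rng.standard_normal(y.shape).astype(np.float32)
        blk.forward(x)
        dx = blk.backward(dy.copy())

        def loss():
            return float((naive_dense_block_forward(blk, x) * dy).sum())

        eps = 1e-5
        for _ in range(5):
            i = tuple(rng.integers(0, s) for s in x.shape)
            xp = x.astype(np.float64)
            xp[i] += eps
            xm = x.astype(np.float64)
            xm[i] -= eps
            num = (float((naive_dense_block_forward(blk, xp) * dy).sum())
                   - float((naive_dense_block_forward(blk, xm)
                            * dy).sum())) / (2 * eps)
            assert dx[i] == pytest.approx(num, rel=1e-3, abs=1e-3)
        for p in blk.params():
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            num = fd_param_grad(p.value, idx, loss, eps=1e-6)
            assert p.grad[idx] == pytest.approx(num, rel=1e-3, abs=1e-3)

    def test_dense_connectivity_unit_input_widths(self, rng):
        cfg = NetworkConfig(units_per_block=4, seed=0)
        blk = DenseResidualBlock(5, 8, cfg, rng)
        assert [w.value.shape[1] for w in blk.unit_w] == [5, 13, 21, 29]


class TestTransitions:
    def test_down_halves_space_doubles_channels(self, rng):
        cfg = NetworkConfig(seed=0)
        td = TransitionDown(16, cfg, rng)
        y = td.forward(np.zeros((32, 32, 16, 16), dtype=np.float32))
        assert y.shape == (16, 16, 8, 32)

    def test_up_doubles_space_halves_channels(self, rng):
        cfg = NetworkConfig(seed=0)
        tu = TransitionUp(32, cfg, rng)
        y = tu.forward(np.zeros((16, 16, 8, 32), dtype=np.float32))
        assert y.shape == (32, 32, 16, 16)

    def test_up_after_down_restores_shape(self, rng):
        cfg = NetworkConfig(seed=0)
        x = rng.standard_normal((8, 4, 6, 4)).astype(np.float32)
        y = TransitionUp(8, cfg, rng).forward(
            TransitionDown(4, cfg, rng).forward(x))
        assert y.shape == x.shape

    def test_down_rejects_odd_and_degenerate_dims(self, rng):
        cfg = NetworkConfig(seed=0)
        td = TransitionDown(2, cfg, rng)
        with pytest.raises(ValueError):
            td.forward(np.zeros((3, 4, 4, 2), dtype=np.float32))
        with pytest.raises(ValueError):
            td.forward(np.zeros((1, 1, 1, 2), dtype=np.float32))


class TestDRUNet:
    @pytest.mark.parametrize("shape", [(16, 16, 16), (32, 16, 16),
                                       (48, 32, 16)])
    def test_output_shape_equals_input(self, shape):
        net = build_drunet(NetworkConfig(base_width=4, seed=0))
        out = net.predict(np.random.default_rng(0).uniform(
            0, 1, shape).astype(np.float32))
        assert out.shape == shape
        assert ((out > 0) & (out < 1)).all()

    def test_bottleneck_spatial_size_is_input_over_16(self):
        net = build_drunet(NetworkConfig(base_width=4, seed=0))
        x = np.zeros((32, 32, 16, 1), dtype=np.float32)
        for enc, down in zip(net.encoders, net.downs):
            x = down.forward(enc.forward(x))
        assert x.shape[:3] == (2, 2, 1)
        assert x.shape[3] == 4 * 2 ** 4  # channels double at each level

    def test_single_level_network_preserves_shape(self):
        net = build_drunet(NetworkConfig(base_width=4, levels=1, seed=0))
        out = net.predict(np.zeros((6, 4, 8), dtype=np.float32))
        assert out.shape == (6, 4, 8)

    def test_indivisible_shape_reports_divisibility(self):
        net = build_drunet(NetworkConfig(base_width=4, seed=0))
        with pytest.raises(ValueError, match="16"):
            net.forward(np.zeros((20, 16, 16), dtype=np.float32))

    def test_non_3d_input_rejected(self):
        net = build_drunet(NetworkConfig(base_width=4, seed=0))
        with pytest.raises(ValueError, match="3D"):
            net.forward(np.zeros((16, 16), dtype=np.float32))

    def test_all_zero_input_finite(self):
        net = build_drunet(NetworkConfig(base_width=4, seed=0))
        assert np.isfinite(net.predict(
            np.zeros((16, 16, 16), dtype=np.float32))).all()

    def test_inference_is_deterministic(self, rng):
        net = build_drunet(NetworkConfig(base_width=4, seed=3))
        x = rng.uniform(0, 1, (16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(net.predict(x), net.predict(x))

    def test_same_seed_same_initialization(self):
        a = build_drunet(NetworkConfig(base_width=4, seed=5))
        b = build_drunet(NetworkConfig(base_width=4, seed=5))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_parameter_count_closed_form(self):
        cfg = NetworkConfig(base_width=8, levels=2, units_per_block=4,
                            in_channels=1, seed=0)
        net = build_drunet(cfg)
        widths = [8, 16]
        want = 0
        cin = 1
        for w in widths:
            want += _dense_block_param_count(cin, w, 4)
            want += _transition_param_count(w, 2 * w)
            cin = 2 * w
        want += _dense_block_param_count(cin, cin, 4)     # bottleneck
        for w in reversed(widths):
            want += 8 * (2 * w) * w + w + 2 * w           # transition up
            want += _dense_block_param_count(2 * w, w, 4)
        want += 8 * 1 + 1                                 # sigmoid head
        assert net.num_parameters() == want

    def test_every_parameter_receives_gradient(self, rng):
        """Dense + residual + skip connectivity must reach all weights."""
        net = build_drunet(NetworkConfig(base_width=4, seed=2))
        reached = [False] * len(net.parameters())
        for trial in range(5):
            x = rng.uniform(0, 1, (16, 16, 16)).astype(np.float32)
            g = (rng.uniform(0, 1, (16, 16, 16)) < 0.1).astype(np.uint8)
            net.zero_grad()
            prob = net.forward(x)
            _, grad = dbce_loss(prob, g, with_grad=True)
            net.backward(grad.astype(np.float32))
            for i, p in enumerate(net.parameters()):
                assert np.isfinite(p.grad).all()
                if np.abs(p.grad).max() > 0:
                    reached[i] = True
            if all(reached):
                break
        assert all(reached)


class TestCheckpoint:
    def test_roundtrip_reproduces_predictions(self, tmp_path, rng):
        net = build_drunet(NetworkConfig(base_width=4, seed=9))
        x = rng.uniform(0, 1, (16, 16, 16)).astype(np.float32)
        want = net.predict(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        back = load_checkpoint(path)
        assert back.config == net.config
        np.testing.assert_array_equal(back.predict(x), want)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"levels": 0}, {"units_per_block": 0}, {"base_width": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkConfig(**kwargs)

    def test_group_count_reduced_to_divide_channels(self):
        cfg = NetworkConfig(gn_groups=8)
        assert cfg.norm_groups(12) == 6
        assert cfg.norm_groups(8) == 8
        assert cfg.norm_groups(3) == 3
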