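"""Dense Residual U-Net (DRU-Net) for 3D vessel segmentation.

The network is an encoder--decoder with four resolution levels.  Feature
extraction happens in *dense residual blocks*: four serial units (3x3x3
convolution -> group normalization -> leaky ReLU) where unit ``i`` consumes
the concatenation of the block input and all previous unit outputs, plus a
parallel 1x1x1 convolution that transforms the block input's channels before
an element-wise addition with the last unit's output.  Between blocks,
learned strided operators replace pooling: a transition-down (2x2x2 stride-2
convolution) halves every spatial dimension and doubles the channel count; a
transition-up (2x2x2 stride-2 transposed convolution) does the reverse.
Decoder features are concatenated with the matching encoder output before
each decoder block.  A 1x1x1 convolution followed by a sigmoid produces a
voxelwise foreground probability map at the input resolution.

Implementation note: a dense block never materializes the growing channel
concatenations.  Each feature piece (the block input or a unit output) is
padded once and convolved into the pre-activations of *all* units that
consume it with stacked weights, which turns the dense connectivity into a
few wide BLAS products instead of many narrow ones.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, asdict
from typing import List, Tuple

import numpy as np

from . import nn
from .nn import Param, gemm_acc, pad_spatial, shift_slab, add_shifted

__all__ = [
    "NetworkConfig",
    "DenseResidualBlock",
    "TransitionDown",
    "TransitionUp",
    "DRUNet",
    "build_drunet",
    "save_checkpoint",
    "load_checkpoint",
]

_F32 = np.float32


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``base_width`` is the channel count at the finest level; channels double
    at each of the ``levels`` transitions down.  ``gn_groups`` is an upper
    bound — it is reduced to the largest divisor of the channel count.
    """

    in_channels: int = 1
    base_width: int = 16
    levels: int = 4
    units_per_block: int = 4
    gn_groups: int = 8
    lrelu_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.units_per_block < 1:
            raise ValueError("units_per_block must be >= 1")
        if self.base_width < 1 or self.in_channels < 1:
            raise ValueError("channel counts must be positive")

    def norm_groups(self, channels: int) -> int:
        g = min(self.gn_groups, channels)
        while channels % g:
            g -= 1
        return g


class DenseResidualBlock:
    """Densely connected unit stack merged with a 1x1x1-transformed skip.

    Unit ``i`` convolves ``in_channels + i * out_channels`` input channels
    (the block input plus all earlier unit outputs); the block output is
    ``last_unit_output + skip(input)``.  Weights for unit ``i`` are stored as
    ``(27, in_channels + i*out_channels, out_channels)`` — one row block per
    3x3x3 kernel offset.
    """

    def __init__(self, cin: int, cout: int, cfg: NetworkConfig,
                 rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.n_units = cfg.units_per_block
        self.unit_w: List[Param] = []
        self.unit_b: List[Param] = []
        self.norms: List[nn.GroupNorm] = []
        self.acts: List[nn.LeakyReLU] = []
        for i in range(self.n_units):
            ci = cin + i * cout
            self.unit_w.append(Param(
                nn.he_normal(rng, (27, ci, cout), 27 * ci, cfg.lrelu_slope)))
            self.unit_b.append(Param(np.zeros(cout, dtype=_F32)))
            self.norms.append(nn.GroupNorm(cout, cfg.norm_groups(cout),
                                           channels_leading=True))
            self.acts.append(nn.LeakyReLU(cfg.lrelu_slope))
        self.skip = nn.Conv1x1(cin, cout, rng, cfg.lrelu_slope)
        self._xps: List[np.ndarray] = []

    def params(self):
        for i in range(self.n_units):
            yield self.unit_w[i]
            yield self.unit_b[i]
            yield from self.norms[i].params()
        yield from self.skip.params()

    def _piece_rows(self, j: int) -> slice:
        """Row slice of piece ``j`` inside the weight array of any unit that
        consumes it (piece 0 is the block input)."""
        if j == 0:
            return slice(0, self.cin)
        return slice(self.cin + (j - 1) * self.cout,
                     self.cin + j * self.cout)

    def _stacked_weights(self, j: int) -> np.ndarray:
        """(27, (n_units - j) * cout, c_j): piece j's kernels for every unit
        it feeds, stacked along the output-channel axis."""
        sl = self._piece_rows(j)
        parts = [self.unit_w[i].value[:, sl, :].transpose(0, 2, 1)
                 for i in range(j, self.n_units)]
        return np.ascontiguousarray(np.concatenate(parts, axis=1))

    def _scatter_weight_grad(self, j: int, dwcat: np.ndarray) -> None:
        sl = self._piece_rows(j)
        co = self.cout
        for i in range(j, self.n_units):
            block = dwcat[:, (i - j) * co:(i - j + 1) * co, :]
            self.unit_w[i].grad[:, sl, :] += block.transpose(0, 2, 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        d, h, w, _ = x.shape
        n = d * h * w
        u, co = self.n_units, self.cout
        pret = np.empty((u * co, n), dtype=_F32)
        for i in range(u):
            pret[i * co:(i + 1) * co] = self.unit_b[i].value[:, None]
        self._xps = []
        piece = np.ascontiguousarray(x)
        for j in range(u):
            xp = pad_spatial(piece)
            self._xps.append(xp)
            wcat = self._stacked_weights(j)
            target = pret[j * co:]
            for k in range(27):
                gemm_acc(wcat[k], shift_slab(xp, k).T, target)
            pre = np.ascontiguousarray(pret[j * co:(j + 1) * co])
            act = self.acts[j].forward(self.norms[j].forward(pre))
            piece = act.T.reshape(d, h, w, co)
        return piece + self.skip.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d, h, w, co = dy.shape
        n = d * h * w
        u = self.n_units
        dx_skip = self.skip.backward(dy)
        dpret = np.zeros((u * co, n), dtype=_F32)
        dout = np.ascontiguousarray(dy.reshape(n, co).T)
        for i in range(u - 1, -1, -1):
            dpre = self.norms[i].backward(self.acts[i].backward(dout))
            dpret[i * co:(i + 1) * co] = dpre
            self.unit_b[i].grad += dpre.sum(axis=1)
            xp = self._xps[i]
            cj = xp.shape[-1]
            wcat = self._stacked_weights(i)
            dwcat = np.zeros_like(wcat)
            dp = dpret[i * co:]
            dxp = np.zeros_like(xp)
            dxs = np.empty((n, cj), dtype=_F32)
            for k in range(27):
                xs = shift_slab(xp, k)
                gemm_acc(dp, xs, dwcat[k])
                gemm_acc(dp.T, wcat[k], dxs, beta=0.0)
                add_shifted(dxp, k, dxs)
            self._scatter_weight_grad(i, dwcat)
            dpiece = dxp[1:-1, 1:-1, 1:-1, :]
            if i == 0:
                self._xps = []
                return dx_skip + dpiece
            dout = np.ascontiguousarray(dpiece.reshape(n, cj).T)
        raise AssertionError("unreachable")  # pragma: no cover


class TransitionDown:
    """Strided 2x2x2 convolution doubling channels, with norm + activation."""

    def __init__(self, cin: int, cfg: NetworkConfig, rng: np.random.Generator):
        cout = 2 * cin
        self.conv = nn.DownConv2(cin, cout, rng, cfg.lrelu_slope)
        self.norm = nn.GroupNorm(cout, cfg.norm_groups(cout))
        self.act = nn.LeakyReLU(cfg.lrelu_slope)

    def params(self):
        yield from self.conv.params()
        yield from self.norm.params()

    def forward(self, x):
        return self.act.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, dy):
        return self.conv.backward(self.norm.backward(self.act.backward(dy)))


class TransitionUp:
    """Strided 2x2x2 transposed convolution halving channels."""

    def __init__(self, cin: int, cfg: NetworkConfig, rng: np.random.Generator):
        cout = cin // 2
        self.conv = nn.UpConv2(cin, cout, rng, cfg.lrelu_slope)
        self.norm = nn.GroupNorm(cout, cfg.norm_groups(cout))
        self.act = nn.LeakyReLU(cfg.lrelu_slope)

    def params(self):
        yield from self.conv.params()
        yield from self.norm.params()

    def forward(self, x):
        return self.act.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, dy):
        return self.conv.backward(self.norm.backward(self.act.backward(dy)))


class DRUNet:
    """The full encoder--decoder with dense residual blocks.

    ``forward`` takes a 3D array in [0, 1] whose every spatial dimension is
    a multiple of ``2**levels`` and returns a same-shaped probability map
    with values strictly in (0, 1).
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cfg = config
        widths = [cfg.base_width * 2 ** i for i in range(cfg.levels)]
        self.encoders: List[DenseResidualBlock] = []
        self.downs: List[TransitionDown] = []
        cin = cfg.in_channels
        for wi in widths:
            self.encoders.append(DenseResidualBlock(cin, wi, cfg, rng))
            self.downs.append(TransitionDown(wi, cfg, rng))
            cin = 2 * wi
        self.bottleneck = DenseResidualBlock(cin, cin, cfg, rng)
        self.ups: List[TransitionUp] = []
        self.decoders: List[DenseResidualBlock] = []
        for wi in reversed(widths):
            self.ups.append(TransitionUp(2 * wi, cfg, rng))
            self.decoders.append(DenseResidualBlock(2 * wi, wi, cfg, rng))
        self.head = nn.Conv1x1(widths[0], 1, rng)
        self.out_act = nn.Sigmoid()
        self._skips: List[np.ndarray] = []

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        yield from self.encoders
        yield from self.downs
        yield self.bottleneck
        yield from self.ups
        yield from self.decoders
        yield self.head

    def parameters(self) -> List[Param]:
        out: List[Param] = []
        for m in self._modules():
            out.extend(m.params())
        return out

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- forward / backward -------------------------------------------------
    def _check_shape(self, shape: Tuple[int, ...]) -> None:
        div = 2 ** self.config.levels
        if len(shape) != 3:
            raise ValueError(f"expected a 3D volume, got shape {shape}")
        if any(s % div or s < div for s in shape):
            raise ValueError(
                f"spatial dims {shape} must all be positive multiples of "
                f"{div} (= 2**levels) for a {self.config.levels}-level "
                f"network")

    def forward(self, volume: np.ndarray) -> np.ndarray:
        self._check_shape(volume.shape)
        x = np.ascontiguousarray(volume, dtype=_F32)[..., None]
        self._skips = []
        for enc, down in zip(self.encoders, self.downs):
            x = enc.forward(x)
            self._skips.append(x)
            x = down.forward(x)
        x = self.bottleneck.forward(x)
        for up, dec, skip in zip(self.ups, self.decoders,
                                 reversed(self._skips)):
            x = up.forward(x)
            x = np.concatenate([x, skip], axis=-1)
            x = dec.forward(x)
        logits = self.head.forward(x)
        return self.out_act.forward(logits)[..., 0]

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(probability map); accumulates parameter
        gradients and returns d(loss)/d(input)."""
        dy = self.out_act.backward(
            np.asarray(dprob, dtype=_F32)[..., None])
        dy = self.head.backward(dy)
        dskips = [None] * len(self.encoders)
        m = len(self.decoders)
        for i in range(m - 1, -1, -1):
            dcat = self.decoders[i].backward(dy)
            half = dcat.shape[-1] - self._skips[m - 1 - i].shape[-1]
            dskips[m - 1 - i] = np.ascontiguousarray(dcat[..., half:])
            dy = self.ups[i].backward(np.ascontiguousarray(dcat[..., :half]))
        dy = self.bottleneck.backward(dy)
        for i in range(len(self.encoders) - 1, -1, -1):
            dy = self.downs[i].backward(dy)
            dy = self.encoders[i].backward(dy + dskips[i])
        self._skips = []
        return dy[..., 0]

    def predict(self, volume: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass (caches released afterwards)."""
        out = self.forward(volume)
        self._skips = []
        return out


def build_drunet(config: NetworkConfig | None = None) -> DRUNet:
    """Construct a DRU-Net with finite, seeded initial parameters."""
    net = DRUNet(config or NetworkConfig())
    for p in net.parameters():
        if not np.all(np.isfinite(p.value)):  # pragma: no cover
            raise RuntimeError("non-finite parameter after initialization")
    return net


# -- checkpoint I/O ---------------------------------------------------------

def save_checkpoint(net: DRUNet, path) -> None:
    """Save parameters plus the embedded NetworkConfig (an ``.npz`` archive
    with a JSON config entry)."""
    arrays = {f"p{i}": p.value for i, p in enumerate(net.parameters())}
    np.savez_compressed(path, **arrays)
    with zipfile.ZipFile(path, "a") as zf:
        zf.writestr("config.json", json.dumps(asdict(net.config)))


def load_checkpoint(path) -> DRUNet:
    with zipfile.ZipFile(path) as zf:
        config = NetworkConfig(**json.loads(zf.read("config.json")))
    net = DRUNet(config)
    with np.load(path) as data:
        for i, p in enumerate(net.parameters()):
            val = data[f"p{i}"]
            if val.shape != p.value.shape:
                raise ValueError("checkpoint does not match architecture")
            p.value[...] = val
    return net
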