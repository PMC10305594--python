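"""Independent reference implementations used as test oracles.

Everything here is deliberately brute-force and kept separate from the
package code paths it checks: direct-loop convolutions in float64, explicit
channel concatenation for dense blocks, and O(|X|*|Y|) pairwise surface
distances.
"""

from __future__ import annotations

import numpy as np


def naive_dense_block_forward(blk, x: np.ndarray,
                              dtype=np.float64) -> np.ndarray:
    """Reference dense-residual-block forward: explicit concatenation and
    offset-by-offset 3x3x3 convolution."""
    x = x.astype(dtype)
    d, h, w, _ = x.shape
    feats = [x]
    co = blk.cout
    for i in range(blk.n_units):
        xin = np.concatenate(feats, axis=-1)
        wgt = blk.unit_w[i].value.astype(dtype)  # (27, ci, co)
        xp = np.pad(xin, ((1, 1), (1, 1), (1, 1), (0, 0)))
        pre = np.zeros((d, h, w, co), dtype)
        k = 0
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    pre += xp[a:a + d, b:b + h, c:c + w] @ wgt[k]
                    k += 1
        pre += blk.unit_b[i].value.astype(dtype)
        gn = blk.norms[i]
        g = gn.groups
        xg = pre.reshape(-1, g, co // g).transpose(1, 0, 2).reshape(g, -1)
        xhat = (xg - xg.mean(1, keepdims=True)) \
            / np.sqrt(xg.var(1, keepdims=True) + gn.eps)
        y = xhat.reshape(g, -1, co // g).transpose(1, 0, 2)
        y = y.reshape(d, h, w, co)
        y = y * gn.gamma.value.astype(dtype) + gn.beta.value.astype(dtype)
        y = np.where(y < 0, y * blk.acts[i].slope, y)
        feats.append(y)
    skip = (x.reshape(-1, blk.cin) @ blk.skip.w.value.astype(dtype)
            + blk.skip.b.value.astype(dtype)).reshape(d, h, w, co)
    return feats[-1] + skip


def brute_surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one background 6-neighbour (edge
    voxels count), found by explicit neighbour checks."""
    m = mask.astype(bool)
    out = []
    shape = m.shape
    for idx in np.argwhere(m):
        x, y, z = idx
        boundary = False
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (0 <= nx < shape[0] and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2]):
                boundary = True
                break
            if not m[nx, ny, nz]:
                boundary = True
                break
        if boundary:
            out.append((x, y, z))
    return np.asarray(out, dtype=np.float64)


def brute_hd95(pred: np.ndarray, gt: np.ndarray, spacing=(1.0, 1.0, 1.0),
               percentile: float = 95.0) -> float:
    """O(|X|*|Y|) percentile Hausdorff distance with the same per-direction
    percentile-then-max rule as the package implementation."""
    sp = np.asarray(spacing, dtype=np.float64)
    xs = brute_surface_voxels(pred) * sp
    ys = brute_surface_voxels(gt) * sp
    d = np.sqrt(((xs[:, None, :] - ys[None, :, :]) ** 2).sum(-1))
    d_xy = d.min(axis=1)
    d_yx = d.min(axis=0)
    return float(max(np.percentile(d_xy, percentile),
                     np.percentile(d_yx, percentile)))


def brute_dsc(pred: np.ndarray, gt: np.ndarray) -> float:
    p = pred.astype(bool)
    g = gt.astype(bool)
    if not p.any() and not g.any():
        return 1.0
    return 2.0 * float((p & g).sum()) / (float(p.sum()) + float(g.sum()))


def fd_param_grad(param_array: np.ndarray, index, loss_fn,
                  eps: float = 1e-3) -> float:
    """Central finite difference of ``loss_fn()`` w.r.t. one float32 entry,
    using the step actually realized after float32 rounding."""
    orig = param_array[index].copy()
    hi = np.float32(orig + eps)
    lo = np.float32(orig - eps)
    param_array[index] = hi
    lp = loss_fn()
    param_array[index] = lo
    lm = loss_fn()
    param_array[index] = orig
    return (lp - lm) / (float(hi) - float(lo))
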