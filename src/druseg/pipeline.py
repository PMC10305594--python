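"""Training, prediction, and cross-validation orchestration.

The training protocol mirrors standard patch-based 3D segmentation practice:
scans are split into k folds (seeded shuffle + round-robin), image/mask
patches from the training folds are optionally rotation-augmented in the
axial plane, and the network is optimized with Adam (defaults: lr 1e-4,
batch size 1, loss = DBCE hybrid).  Prediction runs the full chain
clip -> normalize -> patch -> forward -> fuse -> threshold -> component
filter and returns a mask in the source frame with the input's metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import losses as losses_mod
from .metrics import dsc, evaluate_pair
from .model import DRUNet, NetworkConfig, build_drunet
from .nn import Adam
from .postprocess import PostprocessConfig, postprocess_prediction
from .preprocess import PreprocessConfig, preprocess_scan
from .volume_io import BinaryMask, CTVolume

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "TrainingHistory",
    "TrainingDivergedError",
    "make_folds",
    "augment_rotate",
    "train",
    "predict_scan",
    "run_cross_validation",
    "loss_ablation",
    "load_manifest",
]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 200
    folds: int = 10
    seed: int = 0
    loss: str = "dbce"
    augment_max_angle_deg: float = 15.0
    adam_betas: Tuple[float, float] = (0.9, 0.999)

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in losses_mod.LOSSES:
            raise ValueError(f"loss must be one of {sorted(losses_mod.LOSSES)}")


@dataclass
class FoldSplit:
    fold_assignments: Dict[str, int]
    folds: int

    def fold_ids(self, k: int) -> List[str]:
        return [s for s, f in self.fold_assignments.items() if f == k]


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    val_dsc: List[float] = field(default_factory=list)
    seed: int = 0
    config: Optional[dict] = None


def make_folds(scan_ids: Sequence[str], folds: int, seed: int) -> FoldSplit:
    """Seeded shuffle then round-robin: fold sizes differ by at most one."""
    ids = list(scan_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("scan ids must be unique")
    if len(ids) < folds:
        raise ValueError(f"need at least {folds} scans, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    return FoldSplit({ids[j]: i % folds for i, j in enumerate(order)}, folds)


def augment_rotate(patch: np.ndarray, mask: np.ndarray,
                   max_angle_deg: float, seed,
                   angle: Optional[float] = None
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Apply one shared random in-plane (axial) rotation to an aligned pair.

    The image is interpolated linearly, the mask by nearest neighbour so it
    stays binary.  ``seed`` may be an int or a Generator; a max angle of 0
    is the identity.  Pass ``angle`` to force a specific rotation.
    """
    if angle is None:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        angle = float(rng.uniform(-max_angle_deg, max_angle_deg))
    if angle == 0.0:
        return patch, mask
    img = ndimage.rotate(patch, angle, axes=(0, 1), reshape=False, order=1,
                         mode="grid-constant", cval=0.0)
    lab = ndimage.rotate(mask, angle, axes=(0, 1), reshape=False, order=0,
                         mode="grid-constant", cval=0)
    return np.clip(img, 0.0, 1.0).astype(np.float32), lab.astype(mask.dtype)


def _mean_val_dsc(net: DRUNet, val_pairs, threshold: float = 0.5) -> float:
    scores = []
    for img, lab in val_pairs:
        pred = (net.predict(img) > threshold).astype(np.uint8)
        scores.append(dsc(pred, lab))
    return float(np.mean(scores)) if scores else float("nan")


def train(train_pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
          val_pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
          net_config: NetworkConfig, train_config: TrainConfig,
          log_fn=None) -> Tuple[DRUNet, TrainingHistory]:
    """Optimize a fresh DRU-Net on (image patch, mask patch) pairs.

    Returns the network with the best-validation-DSC parameters restored
    (final-epoch parameters when there is no validation set) together with
    the per-epoch history.  Raises :class:`TrainingDivergedError` on a
    non-finite loss, reporting epoch, batch and loss value.
    """
    if not train_pairs:
        raise ValueError("empty training set")
    net = build_drunet(net_config)
    opt = Adam(net.parameters(), lr=train_config.learning_rate,
               betas=train_config.adam_betas)
    rng = np.random.default_rng(train_config.seed)
    history = TrainingHistory(seed=train_config.seed,
                              config=asdict(train_config))
    best = (-1.0, None)
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(train_pairs))
        epoch_losses = []
        opt.zero_grad()
        pending = 0
        for bi, idx in enumerate(order):
            img, lab = train_pairs[idx]
            if train_config.augment_max_angle_deg > 0:
                img, lab = augment_rotate(
                    img, lab, train_config.augment_max_angle_deg, rng)
            prob = net.forward(img)
            value, grad = losses_mod.loss_and_grad(train_config.loss, prob, lab)
            if not np.isfinite(value):
                raise TrainingDivergedError(
                    f"non-finite {train_config.loss} loss {value} at epoch "
                    f"{epoch}, batch {bi}")
            net.backward(grad.astype(np.float32))
            epoch_losses.append(value)
            pending += 1
            if pending == train_config.batch_size:
                if train_config.batch_size > 1:
                    for p in net.parameters():
                        p.grad /= train_config.batch_size
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            opt.step()
            opt.zero_grad()
        history.train_loss.append(float(np.mean(epoch_losses)))
        val = _mean_val_dsc(net, val_pairs)
        history.val_dsc.append(val)
        if val_pairs and val >= best[0]:
            best = (val, [p.value.copy() for p in net.parameters()])
        if log_fn is not None:
            log_fn({"epoch": epoch, "train_loss": history.train_loss[-1],
                    "val_dsc": val})
    if best[1] is not None:
        for p, v in zip(net.parameters(), best[1]):
            p.value[...] = v
    return net, history


def predict_scan(net: DRUNet, volume: CTVolume,
                 pre_config: Optional[PreprocessConfig] = None,
                 post_config: Optional[PostprocessConfig] = None
                 ) -> BinaryMask:
    """Segment one scan: preprocess, run every patch through the network,
    fuse, threshold, and filter components."""
    pre_config = pre_config or PreprocessConfig()
    post_config = post_config or PostprocessConfig()
    image_patches, _ = preprocess_scan(volume, None, pre_config)
    for rec in image_patches:
        rec.patch = net.predict(rec.patch.astype(np.float32))
    mask = postprocess_prediction(image_patches, post_config)
    mask.spacing = volume.spacing
    mask.affine = volume.affine
    mask.id = volume.id
    return mask


def load_manifest(path) -> List[dict]:
    """Read a dataset manifest (JSON with a ``scans`` list of
    {id, image_path, mask_path}); relative paths resolve against the
    manifest's directory."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    scans = doc["scans"] if isinstance(doc, dict) else doc
    root = path.parent
    out = []
    for entry in scans:
        e = dict(entry)
        for key in ("image_path", "mask_path"):
            if key in e and e[key] is not None:
                p = Path(e[key])
                e[key] = str(p if p.is_absolute() else root / p)
        out.append(e)
    return out


def _collect_pairs(scans, pre_config) -> List[Tuple[np.ndarray, np.ndarray]]:
    pairs = []
    for vol, mask in scans:
        imgs, labs = preprocess_scan(vol, mask, pre_config)
        pairs.extend((i.patch, l.patch) for i, l in zip(imgs, labs))
    return pairs


def run_cross_validation(scans: Sequence[Tuple[CTVolume, BinaryMask]],
                         net_config: NetworkConfig,
                         train_config: TrainConfig,
                         pre_config: Optional[PreprocessConfig] = None,
                         post_config: Optional[PostprocessConfig] = None,
                         log_fn=None) -> List[dict]:
    """k-fold cross-validation over (volume, mask) pairs.

    For each fold the network is trained from scratch on the other folds'
    patches and evaluated on the held-out scans.  Returns one row per fold
    (mean DSC, mean HD95 over its scans) plus a final ``"mean"`` row.
    """
    pre_config = pre_config or PreprocessConfig()
    post_config = post_config or PostprocessConfig()
    ids = [v.id for v, _ in scans]
    split = make_folds(ids, train_config.folds, train_config.seed)
    by_id = {v.id: (v, m) for v, m in scans}
    rows = []
    for k in range(train_config.folds):
        held = split.fold_ids(k)
        train_scans = [by_id[i] for i in ids if i not in held]
        pairs = _collect_pairs(train_scans, pre_config)
        net, _ = train(pairs, [], net_config, train_config, log_fn=log_fn)
        reports = []
        for scan_id in held:
            vol, gt = by_id[scan_id]
            pred = predict_scan(net, vol, pre_config, post_config)
            reports.append(evaluate_pair(pred, gt, scan_id))
        hd = [r.hd95_mm for r in reports if np.isfinite(r.hd95_mm)]
        rows.append({
            "fold": k,
            "n_scans": len(held),
            "dsc": float(np.mean([r.dsc for r in reports])),
            "hd95_mm": float(np.mean(hd)) if hd else float("nan"),
        })
    hd = [r["hd95_mm"] for r in rows if np.isfinite(r["hd95_mm"])]
    rows.append({
        "fold": "mean",
        "n_scans": sum(r["n_scans"] for r in rows),
        "dsc": float(np.mean([r["dsc"] for r in rows])),
        "hd95_mm": float(np.mean(hd)) if hd else float("nan"),
    })
    return rows


def loss_ablation(scans: Sequence[Tuple[CTVolume, BinaryMask]],
                  net_config: NetworkConfig, train_config: TrainConfig,
                  pre_config: Optional[PreprocessConfig] = None,
                  post_config: Optional[PostprocessConfig] = None
                  ) -> List[dict]:
    """Train/evaluate under each loss (dice, bce, dbce) with otherwise
    identical folds and seeds; one comparable row per loss."""
    rows = []
    for name in ("dice", "bce", "dbce"):
        cfg = TrainConfig(**{**asdict(train_config), "loss": name})
        cv = run_cross_validation(scans, net_config, cfg, pre_config,
                                  post_config)
        mean_row = cv[-1]
        rows.append({"loss": name, "dsc": mean_row["dsc"],
                     "hd95_mm": mean_row["hd95_mm"]})
    return rows
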