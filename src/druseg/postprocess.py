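"""Patch fusion, thresholding, and small-object cleanup.

Predicted probability patches are placed back at their recorded origins and
overlaps are fused by averaging, the fused map is thresholded (strictly
greater than), and small connected components are removed in 3D: foreground
components below a voxel-count threshold are deleted (area-opening analogue)
and, optionally, background holes below the same threshold are filled
(area-closing analogue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .preprocess import PatchSet
from .volume_io import BinaryMask, ValidationError

__all__ = ["PostprocessConfig", "reconstruct_volume", "binarize",
           "remove_small_components", "postprocess_prediction"]


@dataclass
class PostprocessConfig:
    threshold: float = 0.5
    min_component_voxels: int = 64
    connectivity: int = 26
    fill_holes: bool = True

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


def reconstruct_volume(patches: PatchSet) -> np.ndarray:
    """Reassemble patch predictions into the source-volume frame.

    Every covered voxel is the arithmetic mean of all patch values covering
    it; an uncovered voxel or inconsistent source shapes raise.
    """
    if not len(patches):
        raise ValidationError("empty patch set")
    shapes = {r.source_shape for r in patches}
    if len(shapes) != 1:
        raise ValidationError(f"inconsistent source shapes: {shapes}")
    shape = shapes.pop()
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.int32)
    for r in patches:
        x, y, z = r.origin
        px, py, pz = r.patch.shape
        acc[x:x + px, y:y + py, z:z + pz] += r.patch
        cnt[x:x + px, y:y + py, z:z + pz] += 1
    if (cnt == 0).any():
        n = int((cnt == 0).sum())
        raise ValidationError(f"coverage violated: {n} voxels not covered by "
                              "any patch")
    return (acc / cnt).astype(np.float32)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Voxel = 1 iff probability > threshold (strict, so exact ties go to
    background)."""
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValidationError("probabilities must lie in [0, 1]")
    return (prob > threshold).astype(np.uint8)


def _structure(connectivity: int):
    return ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)


def remove_small_components(mask, config: Optional[PostprocessConfig] = None
                            ) -> np.ndarray:
    """Drop foreground components smaller than ``min_component_voxels`` and
    (if ``fill_holes``) fill equally small enclosed background holes.

    Idempotent; never grows foreground beyond hole filling, never invents
    voxels outside existing background holes.
    """
    config = config or PostprocessConfig()
    if isinstance(mask, BinaryMask):
        data = mask.data.astype(bool)
        wrap = mask
    else:
        data = np.asarray(mask).astype(bool)
        wrap = None
    struct = _structure(config.connectivity)
    labels, n = ndimage.label(data, structure=struct)
    if n:
        sizes = np.bincount(labels.ravel())
        kill = np.flatnonzero(sizes < config.min_component_voxels)
        data = data & ~np.isin(labels, kill[kill > 0])
    if config.fill_holes:
        # complementary connectivity for the background phase
        bg_struct = _structure(6 if config.connectivity == 26 else 26)
        bg_labels, nb = ndimage.label(~data, structure=bg_struct)
        if nb:
            sizes = np.bincount(bg_labels.ravel())
            border = np.unique(np.concatenate([
                bg_labels[0].ravel(), bg_labels[-1].ravel(),
                bg_labels[:, 0].ravel(), bg_labels[:, -1].ravel(),
                bg_labels[:, :, 0].ravel(), bg_labels[:, :, -1].ravel()]))
            small = set(np.flatnonzero(
                sizes < config.min_component_voxels).tolist())
            holes = sorted((small - set(border.tolist())) - {0})
            if holes:
                data = data | np.isin(bg_labels, holes)
    out = data.astype(np.uint8)
    if wrap is not None:
        return BinaryMask(out, wrap.spacing, wrap.affine, wrap.id)
    return out


def postprocess_prediction(patches: PatchSet,
                           config: Optional[PostprocessConfig] = None
                           ) -> BinaryMask:
    """reconstruct -> binarize -> component filter, with metadata carried
    over from the patch set."""
    config = config or PostprocessConfig()
    prob = reconstruct_volume(patches)
    mask = remove_small_components(binarize(prob, config.threshold), config)
    source_id = patches.records[0].source_id
    return BinaryMask(mask, patches.spacing, patches.affine, source_id)
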