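"""Intensity preprocessing and patch extraction.

The pipeline is: clip intensities to a fixed HU window (default [-800, 500],
the range that covers lung parenchyma through contrast-filled vessels),
min--max normalize with the clip bounds to [0, 1], then cut each scan into a
fixed number of in-plane patches that span the full slice axis.

Patch origins are drawn uniformly at random over the valid offsets (seeded,
reproducible); if the random draw leaves any in-plane voxel uncovered, the
last nine origins are replaced by a deterministic 3x3 anchor grid at stride
``(dim - patch_xy) / 2`` per axis so that whole-volume reconstruction is
always well defined.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .volume_io import BinaryMask, CTVolume, ValidationError

__all__ = [
    "PreprocessConfig",
    "PatchRecord",
    "PatchSet",
    "clip_hu",
    "normalize_01",
    "extract_patches",
    "preprocess_scan",
]


@dataclass
class PreprocessConfig:
    hu_low: float = -800.0
    hu_high: float = 500.0
    patches_per_volume: int = 9
    patch_xy: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.hu_low >= self.hu_high:
            raise ValueError(
                f"hu_low ({self.hu_low}) must be < hu_high ({self.hu_high})")
        if self.patches_per_volume < 1 or self.patch_xy < 1:
            raise ValueError("patches_per_volume and patch_xy must be >= 1")


@dataclass
class PatchRecord:
    """One sub-volume plus enough placement metadata to put it back."""

    patch: np.ndarray
    origin: Tuple[int, int, int]
    source_shape: Tuple[int, int, int]
    source_id: str = ""

    def __post_init__(self):
        for o, p, s in zip(self.origin, self.patch.shape, self.source_shape):
            if o < 0 or o + p > s:
                raise ValidationError(
                    f"patch at origin {self.origin} with shape "
                    f"{self.patch.shape} exceeds source {self.source_shape}")


@dataclass
class PatchSet:
    records: List[PatchRecord]
    config: PreprocessConfig
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def clip_hu(volume: CTVolume, low: float = -800.0,
            high: float = 500.0) -> CTVolume:
    """Clip intensities to [low, high] HU; in-range voxels are unchanged."""
    if low >= high:
        raise ValueError(f"low ({low}) must be < high ({high})")
    return CTVolume(np.clip(volume.data, low, high), volume.spacing,
                    volume.affine, volume.id)


def normalize_01(volume: CTVolume, low: float = -800.0,
                 high: float = 500.0) -> CTVolume:
    """Map [low, high] linearly onto [0, 1].  The volume must already be
    clipped; out-of-range values raise."""
    data = volume.data
    if data.min() < low - 1e-3 or data.max() > high + 1e-3:
        raise ValidationError(
            f"volume not clipped to [{low}, {high}]: "
            f"range [{data.min()}, {data.max()}]")
    out = (data - np.float32(low)) / np.float32(high - low)
    return CTVolume(np.clip(out, 0.0, 1.0), volume.spacing, volume.affine,
                    volume.id)


def _anchor_origins(nx: int, ny: int, p: int) -> List[Tuple[int, int]]:
    """Deterministic 3x3 grid of origins at half-stride per axis."""
    def axis(d):
        m = d - p
        return sorted({0, m // 2, m})
    return [(x, y) for x in axis(nx) for y in axis(ny)]


def _covered(origins, nx, ny, p) -> bool:
    cov = np.zeros((nx, ny), dtype=bool)
    for x, y in origins:
        cov[x:x + p, y:y + p] = True
    return bool(cov.all())


def _plan_origins(shape, config: PreprocessConfig,
                  source_id: str) -> List[Tuple[int, int]]:
    nx, ny = shape[0], shape[1]
    p = config.patch_xy
    if nx < p or ny < p:
        raise ValidationError(
            f"in-plane dims {(nx, ny)} smaller than patch size {p}")
    n = config.patches_per_volume
    # per-scan stream: reproducible for a fixed (seed, scan id)
    tag = zlib.crc32(source_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, tag]))
    origins = [(int(rng.integers(0, nx - p + 1)),
                int(rng.integers(0, ny - p + 1))) for _ in range(n)]
    if not _covered(origins, nx, ny, p):
        anchors = _anchor_origins(nx, ny, p)
        if len(anchors) > n:
            raise ValidationError(
                f"cannot guarantee coverage: {n} patches of {p}x{p} over "
                f"{(nx, ny)} (need at least {len(anchors)} anchor patches)")
        origins[n - len(anchors):] = anchors
        if not _covered(origins, nx, ny, p):
            raise ValidationError(
                f"anchor grid cannot cover {(nx, ny)} with {p}x{p} patches "
                f"(in-plane dims must be <= 3 * patch_xy)")
    return origins


def extract_patches(volume: CTVolume | BinaryMask,
                    config: PreprocessConfig) -> PatchSet:
    """Cut ``patches_per_volume`` full-depth in-plane patches.

    Deterministic for a fixed (config.seed, volume.id); the union of patch
    footprints always covers every in-plane voxel.
    """
    origins = _plan_origins(volume.data.shape, config, volume.id)
    p = config.patch_xy
    records = [
        PatchRecord(volume.data[x:x + p, y:y + p, :].copy(), (x, y, 0),
                    tuple(volume.data.shape), volume.id)
        for x, y in origins
    ]
    return PatchSet(records, config, volume.spacing, volume.affine)


def preprocess_scan(volume: CTVolume, mask: Optional[BinaryMask],
                    config: PreprocessConfig
                    ) -> Tuple[PatchSet, Optional[PatchSet]]:
    """Clip -> normalize -> patch; the mask (if given) is patched with the
    same origins so image/mask pairs stay aligned."""
    if mask is not None and mask.data.shape != volume.data.shape:
        raise ValidationError(
            f"mask shape {mask.data.shape} != volume shape {volume.data.shape}")
    normalized = normalize_01(clip_hu(volume, config.hu_low, config.hu_high),
                              config.hu_low, config.hu_high)
    image_patches = extract_patches(normalized, config)
    if mask is None:
        return image_patches, None
    p = config.patch_xy
    mask_records = [
        PatchRecord(mask.data[r.origin[0]:r.origin[0] + p,
                              r.origin[1]:r.origin[1] + p, :].copy(),
                    r.origin, r.source_shape, r.source_id)
        for r in image_patches
    ]
    mask_patches = PatchSet(mask_records, config, mask.spacing, mask.affine)
    return image_patches, mask_patches
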