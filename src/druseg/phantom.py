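"""Synthetic vascular CT phantoms.

Each phantom is a recursive bifurcating tree of capsules (line segments with
a radius that shrinks by ``radius_decay`` per generation) rasterized into a
binary mask, embedded in an image that emulates contrast-enhanced chest CT on
the Hounsfield scale: lung-like background (default -850 +/- 40 HU, straddling
the -800 HU clip floor used downstream), an ellipsoidal soft-tissue blob
(40 +/- 20 HU) standing in for the mediastinum, vessel voxels at 300 +/- 30 HU
(contrast-filled arteries), plus additive Gaussian noise.  Optional distractor
trees share the vessel intensity but are excluded from the mask, mimicking the
artery/vein ambiguity of real angiograms.

Everything is driven by one seeded generator, so a given (spec, seed) is
bit-reproducible.  Foreground occupies a few percent of the voxels at the
default geometry, matching the strong class imbalance of pulmonary-artery
segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .volume_io import BinaryMask, CTVolume, write_nifti

__all__ = ["PhantomSpec", "PhantomError", "generate_phantom",
           "generate_dataset"]


class PhantomError(RuntimeError):
    """Raised when no tree fits the requested volume."""


@dataclass
class PhantomSpec:
    shape: Tuple[int, int, int] = (64, 64, 32)
    spacing: Tuple[float, float, float] = (0.7, 0.7, 1.0)
    n_trees: int = 1
    branching_depth: int = 3
    root_radius: float = 2.8
    radius_decay: float = 0.72
    vessel_hu: Tuple[float, float] = (300.0, 30.0)
    lung_hu: Tuple[float, float] = (-850.0, 40.0)
    soft_tissue_hu: Tuple[float, float] = (40.0, 20.0)
    noise_sd: float = 15.0
    n_distractor_trees: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.root_radius < 1.0:
            raise ValueError("root_radius must be >= 1 voxel")
        if self.branching_depth < 0:
            raise ValueError("branching_depth must be >= 0")
        if not 0.0 < self.radius_decay < 1.0:
            raise ValueError("radius_decay must lie in (0, 1)")
        for sd in (self.vessel_hu[1], self.lung_hu[1],
                   self.soft_tissue_hu[1], self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector orthogonal to v."""
    while True:
        r = rng.normal(size=3)
        r -= r.dot(v) * v
        n = np.linalg.norm(r)
        if n > 1e-6:
            return r / n


def _grow_tree(start: np.ndarray, direction: np.ndarray, length: float,
               radius: float, decay: float, depth: int,
               rng: np.random.Generator
               ) -> List[Tuple[np.ndarray, np.ndarray, float]]:
    """Recursive bifurcation; returns capsules as (a, b, radius).

    Children shrink: radius by ``decay`` per generation, length by a jittered
    factor around 0.72.
    """
    end = start + length * direction
    segments = [(start, end, radius)]
    if depth > 0:
        axis = _perp(direction, rng)
        for sign in (+1.0, -1.0):
            angle = np.radians(rng.uniform(20.0, 40.0))
            child_dir = _unit(np.cos(angle) * direction
                              + sign * np.sin(angle) * axis)
            segments.extend(_grow_tree(
                end, child_dir, length * rng.uniform(0.65, 0.8),
                radius * decay, decay, depth - 1, rng))
    return segments


def _tree_segments(spec: PhantomSpec, rng: np.random.Generator,
                   max_retries: int = 10):
    """Grow a tree and shrink segment lengths until it fits the volume."""
    shape = np.asarray(spec.shape, dtype=float)
    margin = 1.0
    start = np.array([
        rng.uniform(0.30, 0.70) * shape[0],
        rng.uniform(0.30, 0.70) * shape[1],
        margin + spec.root_radius,
    ])
    direction = _unit(np.array([rng.normal(0, 0.25), rng.normal(0, 0.25), 1.0]))
    base_len = 0.30 * float(shape.min())
    state = rng.bit_generator.state
    for attempt in range(max_retries):
        rng.bit_generator.state = state  # same tree topology, shorter limbs
        scale = 0.8 ** attempt
        segs = _grow_tree(start, direction, base_len * scale,
                          spec.root_radius, spec.radius_decay,
                          spec.branching_depth, rng)
        lo = min(min(a.min(), b.min()) - r for a, b, r in segs)
        his = np.max([[max(a[i], b[i]) + r for i in range(3)]
                      for a, b, r in segs], axis=0)
        if lo >= 0.0 and (his <= shape - 1.0).all():
            return segs
    raise PhantomError(
        f"tree does not fit volume {spec.shape} after {max_retries} retries")


def _rasterize(segments, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for a, b, r in segments:
        lo = np.maximum(np.floor(np.minimum(a, b) - r).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(a, b) + r).astype(int) + 1,
                        np.asarray(shape))
        if (hi <= lo).any():
            continue
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                            indexing="ij")
        pts = np.stack([g.astype(float) for g in grids], axis=-1)
        ab = b - a
        denom = float(ab.dot(ab))
        t = np.clip(((pts - a) @ ab) / denom if denom > 0 else 0.0, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d2 = ((pts - closest) ** 2).sum(axis=-1)
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= d2 <= r * r
    return mask


def generate_phantom(spec: PhantomSpec) -> Tuple[CTVolume, BinaryMask]:
    """One synthetic scan/mask pair; bit-reproducible for a given spec."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_trees):
        mask |= _rasterize(_tree_segments(spec, rng), shape)
    distractor = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_distractor_trees):
        distractor |= _rasterize(_tree_segments(spec, rng), shape)

    image = rng.normal(spec.lung_hu[0], spec.lung_hu[1],
                       size=shape).astype(np.float32)
    # ellipsoidal soft-tissue blob (mediastinum stand-in)
    center = np.array([rng.uniform(0.25, 0.75) * s for s in shape])
    radii = np.array([rng.uniform(0.12, 0.2) * s for s in shape])
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij")
    inside = sum(((g - c) / r) ** 2
                 for g, c, r in zip(grids, center, radii)) <= 1.0
    image[inside] = rng.normal(spec.soft_tissue_hu[0], spec.soft_tissue_hu[1],
                               size=int(inside.sum()))
    vessels = mask | distractor
    image[vessels] = rng.normal(spec.vessel_hu[0], spec.vessel_hu[1],
                                size=int(vessels.sum()))
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    vol_id = f"phantom-{spec.seed}"
    volume = CTVolume(image, spec.spacing, id=vol_id)
    return volume, BinaryMask(mask.astype(np.uint8), spec.spacing,
                              volume.affine, vol_id)


def generate_dataset(n: int, spec: PhantomSpec, out_dir,
                     prefix: str = "phantom") -> dict:
    """Write ``n`` image/mask NIfTI pairs plus a manifest JSON.

    Scan ``i`` uses a child seed derived from (spec.seed, i), so datasets are
    reproducible and scans are independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n):
        child_seed = int(
            np.random.SeedSequence([spec.seed, i]).generate_state(1)[0]
            & 0x7FFFFFFF)
        vol, mask = generate_phantom(replace(spec, seed=child_seed))
        scan_id = f"{prefix}-{i:03d}"
        vol.id = mask.id = scan_id
        image_path = out_dir / f"{scan_id}_image.nii.gz"
        mask_path = out_dir / f"{scan_id}_mask.nii.gz"
        write_nifti(vol, image_path)
        write_nifti(mask, mask_path)
        entries.append({"id": scan_id,
                        "image_path": image_path.name,
                        "mask_path": mask_path.name})
    manifest = {"root": str(out_dir), "scans": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
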