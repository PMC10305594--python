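"""Overlap and surface-distance metrics in physical units.

DSC = 2|P∩G| / (|P| + |G|) is dimensionless; HD95 is computed on boundary
voxels (foreground voxels with at least one background 6-neighbour; grid-edge
voxels count as boundary), whose centre coordinates are scaled by the voxel
spacing so the result is in mm.  The 95th percentile is taken per direction
(linear interpolation between order statistics) and the two directed values
are combined with ``max`` — the usual medical-segmentation convention.  Only
the spacing enters the distances: a rigid rotation of the frame (the affine)
cannot change them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_io import BinaryMask, ValidationError

__all__ = ["SurfacePointSet", "MetricsReport", "dsc", "extract_surface",
           "hd95", "evaluate_pair", "EmptyMaskError"]


class EmptyMaskError(ValueError):
    """Surface distances are undefined for an empty mask."""


@dataclass
class SurfacePointSet:
    """Physical (mm) coordinates of a mask's boundary voxel centres."""

    points: np.ndarray  # (n, 3) float
    spacing: Tuple[float, float, float]


@dataclass
class MetricsReport:
    dsc: float
    hd95_mm: float
    scan_id: str = ""


def _as_bool(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    if data.ndim != 3:
        raise ValidationError(f"expected 3D mask, got {data.ndim} axes")
    bad = np.setdiff1d(np.unique(data), [0, 1])
    if bad.size:
        raise ValidationError(f"mask must be binary; found {bad[:10]}")
    return data.astype(bool)


def dsc(pred, gt) -> float:
    """Dice similarity coefficient.  Defined as 1.0 when both masks are
    empty and 0.0 when exactly one is."""
    p = _as_bool(pred)
    g = _as_bool(gt)
    if p.shape != g.shape:
        raise ValidationError(f"shape mismatch: {p.shape} vs {g.shape}")
    total = int(p.sum()) + int(g.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / total


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def extract_surface(mask, spacing=(1.0, 1.0, 1.0)) -> SurfacePointSet:
    """Boundary voxels: foreground with >= 1 background 6-neighbour (voxels
    on the grid edge count as boundary), scaled by spacing to mm."""
    if isinstance(mask, BinaryMask):
        spacing = mask.spacing
    m = _as_bool(mask)
    if not m.any():
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(m, _STRUCT6, border_value=0)
    surface = m & ~interior
    pts = np.argwhere(surface).astype(np.float64) * np.asarray(spacing)
    return SurfacePointSet(pts, tuple(float(s) for s in spacing))


def hd95(pred, gt, spacing: Optional[Tuple[float, float, float]] = None,
         percentile: float = 95.0) -> float:
    """Symmetric percentile Hausdorff distance in mm.

    The stated percentile of each directed surface-distance distribution is
    taken separately, then the larger of the two is returned.  With
    ``percentile=100`` this is the classical Hausdorff distance.
    """
    if spacing is None:
        if isinstance(pred, BinaryMask):
            spacing = pred.spacing
        else:
            spacing = (1.0, 1.0, 1.0)
    if not (0.0 < percentile <= 100.0):
        raise ValueError("percentile must be in (0, 100]")
    sp = extract_surface(pred, spacing)
    sg = extract_surface(gt, spacing)
    d_pg = cKDTree(sg.points).query(sp.points, k=1)[0]
    d_gp = cKDTree(sp.points).query(sg.points, k=1)[0]
    return float(max(np.percentile(d_pg, percentile),
                     np.percentile(d_gp, percentile)))


def evaluate_pair(pred: BinaryMask, gt: BinaryMask,
                  scan_id: str = "") -> MetricsReport:
    """DSC plus HD95 for one prediction/ground-truth pair.

    HD95 is reported as NaN when either mask is empty (the distance is
    undefined there, and silently reporting 0 would flatter failures).
    """
    score = dsc(pred, gt)
    try:
        h = hd95(pred, gt, pred.spacing)
    except EmptyMaskError:
        h = float("nan")
    return MetricsReport(score, h, scan_id or pred.id)
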