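"""Metabolic quantification: move depot masks onto the PET grid by
nearest-neighbor resampling in world coordinates, then compute slice-wise
and global SUVmean.

The mask is resampled to PET resolution (never the PET values to the MRI
grid), so no activity values are ever interpolated. The headline global
SUVmean is the unweighted mean of the per-slice means over slices with at
least one voxel; the voxel-weighted pooled mean is also reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .roi_core import BinaryMask3D, GridGeometry, VolumeImage

__all__ = ["SuvResult", "resample_mask_to_pet", "suv_mean"]

logger = logging.getLogger(__name__)


@dataclass
class SuvResult:
    """Per-slice and global SUVmean over a PET-grid mask.

    ``per_slice`` holds ``(pet_slice_index, suv_mean, voxel_count)`` for
    slices with at least one mask voxel. ``global_mean`` is their unweighted
    average (NaN for an empty mask); ``pooled_mean`` weights by voxel count.
    """

    per_slice: list[tuple[int, float, int]] = field(default_factory=list)
    global_mean: float = math.nan
    pooled_mean: float = math.nan


def _nearest_index(
    pet_centers: np.ndarray, origin: float, spacing: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest source-voxel index along one axis for each target center.

    Ties (target center exactly between two source centers) go to the lower
    index. Returns (indices, in_fov) where in_fov marks centers within the
    source grid's voxel-edge bounding box.
    """
    t = (pet_centers - origin) / spacing
    idx = np.ceil(t - 0.5).astype(np.int64)  # round half down
    in_fov = (idx >= 0) & (idx <= n - 1)
    return np.clip(idx, 0, n - 1), in_fov


def resample_mask_to_pet(
    mask: BinaryMask3D,
    mask_geom: GridGeometry,
    pet_geom: GridGeometry,
) -> BinaryMask3D:
    """Nearest-neighbor resample of a mask onto the PET grid.

    Each PET voxel takes the value of the source voxel whose center is
    nearest in world mm; PET voxels whose centers fall outside the source
    field of view are false.
    """
    if mask.data.shape != tuple(mask_geom.shape):
        raise GeometryError(
            f"mask shape {mask.data.shape} does not match its stated geometry {mask_geom.shape}"
        )
    idx = []
    fov = []
    for axis in range(3):
        centers = pet_geom.voxel_centers_world(axis)
        i, ok = _nearest_index(
            centers, mask_geom.origin[axis], mask_geom.spacing[axis], mask_geom.shape[axis]
        )
        idx.append(i)
        fov.append(ok)
    if not all(f.any() for f in fov):
        logger.warning("PET and source fields of view do not overlap; result is all-false")
        return BinaryMask3D(
            np.zeros(pet_geom.shape, dtype=bool), pet_geom.spacing, label=mask.label
        )
    data = mask.data[np.ix_(idx[0], idx[1], idx[2])]
    data &= fov[0][:, None, None] & fov[1][None, :, None] & fov[2][None, None, :]
    return BinaryMask3D(data, pet_geom.spacing, label=mask.label)


def suv_mean(pet: VolumeImage, pet_mask: BinaryMask3D) -> SuvResult:
    """Slice-wise SUVmean over the mask, averaged (unweighted) into a global
    value; slices without mask voxels are skipped, not counted as zero."""
    if pet.data.shape != pet_mask.data.shape or not np.allclose(
        pet.spacing, pet_mask.spacing
    ):
        raise GeometryError(
            f"PET {pet.data.shape}/{pet.spacing} and mask "
            f"{pet_mask.data.shape}/{pet_mask.spacing} geometry mismatch"
        )
    per_slice: list[tuple[int, float, int]] = []
    total = 0.0
    total_n = 0
    for z in range(pet.data.shape[0]):
        m = pet_mask.data[z]
        n = int(m.sum())
        if n == 0:
            continue
        s = float(pet.data[z][m].sum())
        per_slice.append((z, s / n, n))
        total += s
        total_n += n
    if not per_slice:
        return SuvResult()
    global_mean = float(np.mean([v for _, v, _ in per_slice]))
    return SuvResult(per_slice=per_slice, global_mean=global_mean, pooled_mean=total / total_n)
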