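"""Segmentation accuracy metrics: mask Dice and contour Dice.

Contours are extracted per 2-D slice with a morphological gradient
(dilation minus erosion) using a 3x3 square kernel; borders are treated as
false. Dice is pooled over the whole volume by default (intersections and
sizes summed across slices before dividing); slice-averaged Dice is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .roi_core import BinaryMask3D

__all__ = ["DiceReport", "dice", "extract_contour", "contour_dice", "evaluate_masks"]

_KERNEL = np.ones((3, 3), dtype=bool)


@dataclass
class DiceReport:
    label: str
    mask_dice: float
    contour_dice: float
    pooled: bool = True


def _check(a: BinaryMask3D, b: BinaryMask3D) -> None:
    if not a.same_geometry(b):
        raise GeometryError(
            f"mask geometry mismatch: {a.data.shape}/{a.spacing} vs {b.data.shape}/{b.spacing}"
        )


def _dice_counts(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0  # perfect agreement on absence
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice(a: BinaryMask3D, b: BinaryMask3D, pooled: bool = True) -> float:
    """Dice similarity 2|a&b| / (|a|+|b|); both-empty defined as 1.0.

    ``pooled=False`` averages per-slice Dice over slices where either mask
    has voxels instead of pooling counts across the volume.
    """
    _check(a, b)
    if pooled:
        return _dice_counts(a.data, b.data)
    vals = [
        _dice_counts(a.data[z], b.data[z])
        for z in range(a.data.shape[0])
        if a.data[z].any() or b.data[z].any()
    ]
    return float(np.mean(vals)) if vals else 1.0


def extract_contour(mask: BinaryMask3D) -> BinaryMask3D:
    """Morphological gradient per slice: dilation(3x3) AND NOT erosion(3x3)."""
    out = np.zeros_like(mask.data)
    for z in range(mask.data.shape[0]):
        sl = mask.data[z]
        if not sl.any():
            continue
        dil = ndimage.binary_dilation(sl, structure=_KERNEL)
        ero = ndimage.binary_erosion(sl, structure=_KERNEL, border_value=0)
        out[z] = dil & ~ero
    return BinaryMask3D(out, mask.spacing, label=f"{mask.label}-contour" if mask.label else "contour")


def contour_dice(a: BinaryMask3D, b: BinaryMask3D, pooled: bool = True) -> float:
    """Dice between the morphological-gradient contours of two masks."""
    _check(a, b)
    return dice(extract_contour(a), extract_contour(b), pooled=pooled)


def evaluate_masks(
    truth: dict[str, BinaryMask3D],
    pred: dict[str, BinaryMask3D],
    pooled: bool = True,
) -> list[DiceReport]:
    """Per-label mask and contour Dice for matching label keys in ``truth``."""
    reports = []
    for label, t in truth.items():
        p = pred.get(label)
        if p is None:
            p = BinaryMask3D(np.zeros_like(t.data), t.spacing, label=label)
        reports.append(
            DiceReport(
                label=label,
                mask_dice=dice(t, p, pooled=pooled),
                contour_dice=contour_dice(t, p, pooled=pooled),
                pooled=pooled,
            )
        )
    return reports
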