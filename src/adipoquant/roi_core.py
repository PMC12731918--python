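"""Geometry substrate: volumes, contours, rasterization and mask algebra.

Conventions used throughout the package:

* Arrays are indexed ``(slice, row, col)`` — i.e. ``(z, y, x)``. Converters
  to/from on-disk layouts live only at the I/O boundary.
* Voxel coordinates are 0-based with pixel centers at integer coordinates;
  polygon vertices live in continuous ``(row, col)`` voxel space.
* Polygon fill is even–odd with a boundary-inclusive pixel-center test: a
  pixel is inside if its center is strictly interior (odd crossing count)
  or lies exactly on a polygon edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

from .errors import (
    GeometryError,
    InvalidAnnotationError,
    OutOfBoundsError,
)

__all__ = [
    "Label",
    "Modality",
    "GridGeometry",
    "VolumeImage",
    "Contour",
    "ROISet",
    "BinaryMask3D",
    "fill_polygon",
    "rasterize",
    "mask_and_not",
    "load_roiset",
    "save_roiset",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
]

_EPS = 1e-9


class Label(str, Enum):
    """Annotation labels: external body outline, internal abdominal wall,
    and exclusion organs (kidneys, spinal bone marrow)."""

    EXT = "EXT"
    INT = "INT"
    EXC = "EXC"


class Modality(str, Enum):
    MRI = "MRI"
    PET = "PET"


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and world origin of a regular 3-D grid.

    ``shape`` is ``(nz, ny, nx)``, ``spacing`` is ``(dz, dy, dx)`` in mm and
    ``origin`` is the world position (mm) of voxel ``(0, 0, 0)``'s center.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise GeometryError(f"grid shape must be three dims >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(not s > 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def voxel_centers_world(self, axis: int) -> np.ndarray:
        """World-mm coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


@dataclass
class VolumeImage:
    """A 3-D scalar image with per-axis spacing, origin and modality tag."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.MRI

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"volume must be 3-D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(not s > 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        self.modality = Modality(self.modality)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.data.shape, self.spacing, self.origin)


@dataclass
class Contour:
    """A closed planar polygon on one slice, in (row, col) voxel coordinates.

    The polygon is implicitly closed: the last vertex connects back to the
    first. At least three vertices are required.
    """

    slice_index: int
    vertices: np.ndarray
    label: Label

    def __post_init__(self) -> None:
        self.slice_index = int(self.slice_index)
        if self.slice_index < 0:
            raise InvalidAnnotationError(f"slice_index must be >= 0, got {self.slice_index}")
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise InvalidAnnotationError("vertices must be an (n, 2) array of (row, col)")
        if self.vertices.shape[0] < 3:
            raise InvalidAnnotationError(
                f"polygon needs >= 3 vertices, got {self.vertices.shape[0]}"
            )
        if not np.all(np.isfinite(self.vertices)):
            raise InvalidAnnotationError("polygon vertices must be finite")
        self.label = Label(self.label)


@dataclass
class ROISet:
    """Per-slice contour annotations over an inclusive slice range.

    At most one EXT and one INT contour per slice; any number of EXC
    contours per slice (the kidneys are two separate polygons).
    """

    contours: list[Contour]
    slice_range: tuple[int, int]
    grid_shape: tuple[int, int, int]
    grid_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.slice_range = (int(self.slice_range[0]), int(self.slice_range[1]))
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.grid_spacing = tuple(float(s) for s in self.grid_spacing)
        first, last = self.slice_range
        if first > last:
            raise InvalidAnnotationError(f"slice_range {self.slice_range} has first > last")
        if first < 0 or last >= self.grid_shape[0]:
            raise InvalidAnnotationError(
                f"slice_range {self.slice_range} outside grid of {self.grid_shape[0]} slices"
            )
        seen: dict[tuple[int, Label], int] = {}
        for c in self.contours:
            if not (first <= c.slice_index <= last):
                raise InvalidAnnotationError(
                    f"contour on slice {c.slice_index} outside slice_range {self.slice_range}"
                )
            if c.label in (Label.EXT, Label.INT):
                key = (c.slice_index, c.label)
                seen[key] = seen.get(key, 0) + 1
                if seen[key] > 1:
                    raise InvalidAnnotationError(
                        f"multiple {c.label.value} contours on slice {c.slice_index}"
                    )

    def contours_on(self, slice_index: int, label: Label | None = None) -> list[Contour]:
        out = [c for c in self.contours if c.slice_index == slice_index]
        if label is not None:
            label = Label(label)
            out = [c for c in out if c.label == label]
        return out

    @property
    def annotated_slices(self) -> list[int]:
        return sorted({c.slice_index for c in self.contours})


@dataclass
class BinaryMask3D:
    """Boolean grid sharing a source volume's geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise GeometryError(f"mask must be 3-D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(not s > 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def same_geometry(self, other: "BinaryMask3D") -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.spacing, other.spacing
        )


# ---------------------------------------------------------------------------
# Rasterization


def fill_polygon(shape: tuple[int, int], vertices: np.ndarray) -> np.ndarray:
    """Fill one polygon on a 2-D grid of the given (rows, cols) shape.

    Even–odd rule on pixel centers, boundary-inclusive: pixels whose center
    lies exactly on an edge are set. Vectorized over the polygon's integer
    bounding box.
    """
    ny, nx = shape
    v = np.asarray(vertices, dtype=np.float64)
    # drop exactly-repeated consecutive vertices (incl. explicit closure)
    keep = np.any(v != np.roll(v, -1, axis=0), axis=1)
    if keep.sum() < 3:
        return np.zeros(shape, dtype=bool)
    v = v[keep]

    r0 = max(0, int(np.floor(v[:, 0].min())))
    r1 = min(ny - 1, int(np.ceil(v[:, 0].max())))
    c0 = max(0, int(np.floor(v[:, 1].min())))
    c1 = min(nx - 1, int(np.ceil(v[:, 1].max())))
    out = np.zeros(shape, dtype=bool)
    if r0 > r1 or c0 > c1:
        return out

    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    py = rr.ravel().astype(np.float64)[:, None]  # (N, 1)
    px = cc.ravel().astype(np.float64)[:, None]

    ra, ca = v[:, 0], v[:, 1]
    rb, cb = np.roll(ra, -1), np.roll(ca, -1)

    # even-odd crossing count of a horizontal ray toward +col
    crosses = (ra > py) != (rb > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        cint = ca + (py - ra) * (cb - ca) / (rb - ra)
    inside = (np.sum(crosses & (px < cint), axis=1) % 2) == 1

    # boundary-inclusive: pixel center exactly on a segment
    er, ec = rb - ra, cb - ca
    len2 = er * er + ec * ec
    cross = er * (px - ca) - ec * (py - ra)
    dot = (py - ra) * er + (px - ca) * ec
    scale = np.maximum(len2, 1.0)
    on_edge = np.any(
        (np.abs(cross) <= _EPS * scale) & (dot >= -_EPS) & (dot <= len2 + _EPS),
        axis=1,
    )

    out[r0 : r1 + 1, c0 : c1 + 1] = (inside | on_edge).reshape(rr.shape)
    return out


def rasterize(
    roiset: ROISet,
    label: Label | str,
    geometry: GridGeometry | None = None,
) -> BinaryMask3D:
    """Rasterize every contour of ``label`` onto the grid.

    Multiple same-label polygons on a slice are OR-ed. Slices with no
    contour of the label are all-false. A vertex outside the grid bounds
    raises :class:`OutOfBoundsError` — there is no silent clipping.
    """
    label = Label(label)
    if geometry is None:
        geometry = GridGeometry(roiset.grid_shape, roiset.grid_spacing)
    if tuple(geometry.shape) != tuple(roiset.grid_shape):
        raise GeometryError(
            f"ROI grid {roiset.grid_shape} does not match target grid {geometry.shape}"
        )
    nz, ny, nx = geometry.shape
    data = np.zeros((nz, ny, nx), dtype=bool)
    for c in roiset.contours:
        if c.label != label:
            continue
        r, col = c.vertices[:, 0], c.vertices[:, 1]
        if r.min() < 0 or r.max() > ny - 1 or col.min() < 0 or col.max() > nx - 1:
            raise OutOfBoundsError(
                f"{label.value} contour on slice {c.slice_index} has vertices outside "
                f"the {ny}x{nx} grid"
            )
        data[c.slice_index] |= fill_polygon((ny, nx), c.vertices)
    return BinaryMask3D(data, geometry.spacing, label=label.value)


def mask_and_not(a: BinaryMask3D, b: BinaryMask3D) -> BinaryMask3D:
    """Voxelwise ``a AND NOT b``; the SAT/VAT subtraction primitive."""
    if not a.same_geometry(b):
        raise GeometryError(
            f"mask geometry mismatch: {a.data.shape}/{a.spacing} vs {b.data.shape}/{b.spacing}"
        )
    return BinaryMask3D(a.data & ~b.data, a.spacing, label=a.label)


# ---------------------------------------------------------------------------
# ROI JSON I/O
#
# Schema:
#   {"grid": {"dims": [nz, ny, nx], "spacing_mm": [dz, dy, dx]},
#    "slice_range": [first, last],
#    "contours": [{"slice": int, "label": "EXT|INT|EXC",
#                  "vertices": [[row, col], ...]}, ...]}


def save_roiset(roiset: ROISet, path: str | Path) -> None:
    doc = {
        "grid": {
            "dims": list(roiset.grid_shape),
            "spacing_mm": list(roiset.grid_spacing),
        },
        "slice_range": list(roiset.slice_range),
        "contours": [
            {
                "slice": c.slice_index,
                "label": c.label.value,
                "vertices": [[float(r), float(col)] for r, col in c.vertices],
            }
            for c in roiset.contours
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise InvalidAnnotationError(f"ROI JSON missing field '{key}' in {where}")
    return doc[key]


def load_roiset(path: str | Path) -> ROISet:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise InvalidAnnotationError(f"ROI JSON is not valid JSON: {e}") from e
    grid = _require(doc, "grid", "top level")
    dims = _require(grid, "dims", "grid")
    spacing = _require(grid, "spacing_mm", "grid")
    slice_range = _require(doc, "slice_range", "top level")
    raw = _require(doc, "contours", "top level")
    contours = []
    for i, c in enumerate(raw):
        where = f"contours[{i}]"
        contours.append(
            Contour(
                slice_index=_require(c, "slice", where),
                vertices=np.asarray(_require(c, "vertices", where), dtype=np.float64),
                label=Label(_require(c, "label", where)),
            )
        )
    return ROISet(
        contours=contours,
        slice_range=tuple(slice_range),
        grid_shape=tuple(dims),
        grid_spacing=tuple(spacing),
    )


# ---------------------------------------------------------------------------
# NIfTI I/O
#
# On disk NIfTI stores (x, y, z); internally we use (z, y, x). We assume an
# axis-aligned affine (no oblique acquisitions) and transpose axes; spacing
# comes from the header zooms, origin from the affine translation.


def _to_disk_order(data: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(data, (2, 1, 0)))


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]):
    dz, dy, dx = spacing
    oz, oy, ox = origin
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = (ox, oy, oz)
    return aff


def save_volume(vol: VolumeImage, path: str | Path) -> None:
    img = nib.Nifti1Image(_to_disk_order(vol.data).astype(np.float32), _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def load_volume(path: str | Path, modality: Modality | str = Modality.MRI) -> VolumeImage:
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(np.float64)
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    ox, oy, oz = (float(t) for t in img.affine[:3, 3])
    return VolumeImage(data, spacing=(dz, dy, dx), origin=(oz, oy, ox), modality=Modality(modality))


def save_mask(mask: BinaryMask3D, path: str | Path, origin=(0.0, 0.0, 0.0)) -> None:
    img = nib.Nifti1Image(
        _to_disk_order(mask.data.astype(np.uint8)), _affine(mask.spacing, origin)
    )
    nib.save(img, str(path))


def load_mask(path: str | Path, label: str = "") -> BinaryMask3D:
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)) > 0
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    return BinaryMask3D(data, spacing=(dz, dy, dx), label=label)
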