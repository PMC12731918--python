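"""Seeded synthetic abdominal PET/MR phantoms with ground truth.

Each phantom is a bright-fat / dark-lean fat-phase MR volume plus a
co-registered coarser PET volume, together with the exact EXT/INT/EXC
polygon annotations and a voxel tissue label map. Anatomy per annotated
slice: an outer body ellipse (EXT) and an inner abdominal-wall ellipse
(INT) enclosing a subcutaneous fat ring, scattered visceral fat blobs
inside INT, two kidney-like ellipsoids and one spine-like cylinder marked
for exclusion (EXC). PET uptake is constant per tissue, higher in visceral
than subcutaneous fat.

The label map is derived from the *rasterized* polygons, so ROI-vs-label
consistency is exact by construction, and with zero intensity noise the
quantification pipeline at the matched threshold policy recovers the
generator's voxel counts and uptake constants exactly.

Intensity defaults (fat 900, lean 100, sigma 50) are artifact-level
choices that make the mean-based threshold analytically clean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .errors import ConfigError
from .pet_suv import _nearest_index
from .roi_core import (
    BinaryMask3D,
    Contour,
    GridGeometry,
    Label,
    Modality,
    ROISet,
    VolumeImage,
    rasterize,
)

__all__ = [
    "Tissue",
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "perturb_roi",
    "make_validation_cohort",
]


class Tissue(IntEnum):
    BACKGROUND = 0
    SAT = 1
    VAT = 2
    LEAN = 3
    ORGAN = 4  # EXC: kidneys + spine marrow analog


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of the generator; defaults are desk-scale test sizes."""

    dims: tuple[int, int, int] = (40, 96, 120)
    mri_spacing: tuple[float, float, float] = (2.09, 1.39, 1.39)
    pet_inplane_factor: int = 2
    slice_margin: int = 2
    body_semiaxes: tuple[float, float] | None = None  # (ry, rx); default from dims
    taper: float = 0.12  # semiaxis shrink factor at the end slices
    sat_thickness: float = 7.0  # voxels between EXT and INT
    n_vat_blobs: int = 10  # first n_vat_tubes are z-tubes, the rest spheres
    n_vat_tubes: int = 6
    vat_tube_radius_frac: float = 0.24  # of the min inner-wall semiaxis
    vat_blob_radius: tuple[float, float] = (3.0, 7.0)
    n_contour_vertices: int = 48
    mu_fat: float = 900.0
    mu_lean: float = 100.0
    mu_organ: float = 900.0  # marrow-like organs are bright on fat-phase MRI
    noise_sd: float = 50.0
    uptake: dict = field(
        default_factory=lambda: {
            Tissue.BACKGROUND: 0.0,
            Tissue.SAT: 0.24,
            Tissue.VAT: 0.75,
            Tissue.LEAN: 0.05,
            Tissue.ORGAN: 2.0,
        }
    )
    pet_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nz, ny, nx = self.dims
        if nz < 2 * self.slice_margin + 3:
            raise ConfigError(f"dims {self.dims}: too few slices for margin {self.slice_margin}")
        by, bx = self.resolved_body_semiaxes
        if by + 1 >= ny / 2 or bx + 1 >= nx / 2:
            raise ConfigError(f"body semiaxes ({by}, {bx}) do not fit inside {ny}x{nx} slices")
        inner = (min(by, bx)) * (1 - self.taper) - self.sat_thickness
        if inner < 10:
            raise ConfigError(
                f"infeasible geometry: inner-wall semiaxis {inner:.1f} voxels is too small "
                f"for organs (need >= 10); reduce sat_thickness or taper, or enlarge the body"
            )
        if not self.mu_fat > self.mu_lean:
            raise ConfigError("mu_fat must exceed mu_lean")

    @property
    def resolved_body_semiaxes(self) -> tuple[float, float]:
        if self.body_semiaxes is not None:
            return self.body_semiaxes
        _, ny, nx = self.dims
        return 0.40 * ny, 0.42 * nx

    @property
    def slice_range(self) -> tuple[int, int]:
        return self.slice_margin, self.dims[0] - 1 - self.slice_margin

    @property
    def mri_geometry(self) -> GridGeometry:
        return GridGeometry(self.dims, self.mri_spacing)

    @property
    def pet_geometry(self) -> GridGeometry:
        nz, ny, nx = self.dims
        dz, dy, dx = self.mri_spacing
        f = self.pet_inplane_factor
        return GridGeometry(
            (nz, ny // f, nx // f),
            (dz, f * dy, f * dx),
            (0.0, (f - 1) * dy / 2.0, (f - 1) * dx / 2.0),
        )


@dataclass
class PhantomCase:
    """A generated phantom: images, exact annotations, and the label map."""

    mri: VolumeImage
    pet: VolumeImage
    truth_rois: ROISet
    truth_labels: np.ndarray  # int array of Tissue values, MRI grid
    spec: PhantomSpec

    def tissue_mask(self, tissue: Tissue) -> BinaryMask3D:
        return BinaryMask3D(
            self.truth_labels == int(tissue), self.mri.spacing, label=Tissue(tissue).name
        )

    def tissue_count(self, tissue: Tissue) -> int:
        return int((self.truth_labels == int(tissue)).sum())


def _ellipse_polygon(cy: float, cx: float, ry: float, rx: float, n: int) -> np.ndarray:
    theta = 2 * math.pi * np.arange(n) / n
    return np.column_stack([cy + ry * np.sin(theta), cx + rx * np.cos(theta)])


def _taper_scale(z: int, first: int, last: int, taper: float) -> float:
    mid = (first + last) / 2.0
    half = max((last - first) / 2.0, 1.0)
    return 1.0 - taper * ((z - mid) / half) ** 2


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Deterministically generate one phantom from its spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.dims
    first, last = spec.slice_range
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    by, bx = spec.resolved_body_semiaxes
    nvert = spec.n_contour_vertices

    # inner-wall semiaxes at mid-slice, used to anchor organ geometry
    iy_mid, ix_mid = by - spec.sat_thickness, bx - spec.sat_thickness

    contours: list[Contour] = []
    kid_r = 0.16 * min(iy_mid, ix_mid)
    kid_rz = 0.45 * (last - first) / 2.0
    kid_cz = (first + last) / 2.0
    spine_r = 0.13 * iy_mid

    for z in range(first, last + 1):
        s = _taper_scale(z, first, last, spec.taper)
        ery, erx = by * s, bx * s
        iry, irx = ery - spec.sat_thickness, erx - spec.sat_thickness
        contours.append(Contour(z, _ellipse_polygon(cy, cx, ery, erx, nvert), Label.EXT))
        contours.append(Contour(z, _ellipse_polygon(cy, cx, iry, irx, nvert), Label.INT))
        # spine-like cylinder, posterior midline, all annotated slices
        contours.append(
            Contour(
                z,
                _ellipse_polygon(cy + 0.55 * iry, cx, spine_r, spine_r, max(24, nvert // 2)),
                Label.EXC,
            )
        )
        # two kidney-like ellipsoids around the mid-slice
        if abs(z - kid_cz) < kid_rz:
            f = math.sqrt(1.0 - ((z - kid_cz) / kid_rz) ** 2)
            if f * kid_r >= 1.5:
                for side in (-1.0, 1.0):
                    contours.append(
                        Contour(
                            z,
                            _ellipse_polygon(
                                cy + 0.15 * iry,
                                cx + side * 0.45 * irx,
                                f * kid_r,
                                f * kid_r * 1.2,
                                max(24, nvert // 2),
                            ),
                            Label.EXC,
                        )
                    )

    rois = ROISet(
        contours=contours,
        slice_range=(first, last),
        grid_shape=spec.dims,
        grid_spacing=spec.mri_spacing,
    )
    geom = spec.mri_geometry
    ext = rasterize(rois, Label.EXT, geom).data
    int_ = rasterize(rois, Label.INT, geom).data
    exc = rasterize(rois, Label.EXC, geom).data

    # visceral fat: z-tubes spanning the slice range (so every annotated
    # slice carries fat inside INT and the fat fraction there is large
    # enough for the mean-based threshold to sit between the two intensity
    # modes even under noise), plus random spheres
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float64)
    vat = np.zeros(spec.dims, dtype=bool)
    n_tubes = min(spec.n_vat_tubes, spec.n_vat_blobs)
    tube_r = max(1.8, spec.vat_tube_radius_frac * min(iy_mid, ix_mid))
    for j in range(n_tubes):
        ang = 2 * math.pi * (j + 0.5) / max(n_tubes, 1)
        r_j = tube_r * rng.uniform(0.85, 1.15)
        tc = (cy + 0.45 * iy_mid * math.sin(ang), cx + 0.45 * ix_mid * math.cos(ang))
        vat |= ((yy - tc[0]) ** 2 + (xx - tc[1]) ** 2) <= r_j**2
    rmin, rmax = spec.vat_blob_radius
    for _ in range(max(0, spec.n_vat_blobs - n_tubes)):
        r = rng.uniform(rmin, rmax)
        bz = rng.uniform(first + 1, last - 1)
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(0, 0.7)
        bcy = cy + rad * iy_mid * math.sin(ang)
        bcx = cx + rad * ix_mid * math.cos(ang)
        vat |= (
            ((zz - bz) * spec.mri_spacing[0] / spec.mri_spacing[1]) ** 2
            + (yy - bcy) ** 2
            + (xx - bcx) ** 2
        ) <= r**2
    vat &= int_ & ~exc

    labels = np.zeros(spec.dims, dtype=np.int8)
    labels[ext & ~int_] = int(Tissue.SAT)
    labels[vat] = int(Tissue.VAT)
    labels[int_ & ~exc & ~vat] = int(Tissue.LEAN)
    labels[exc] = int(Tissue.ORGAN)

    # bright organs keep the INT-region intensity statistics bimodal even
    # when little visceral fat is present (and motivate their exclusion)
    mri_data = np.zeros(spec.dims, dtype=np.float64)
    mri_data[(labels == int(Tissue.SAT)) | (labels == int(Tissue.VAT))] = spec.mu_fat
    mri_data[labels == int(Tissue.LEAN)] = spec.mu_lean
    mri_data[labels == int(Tissue.ORGAN)] = spec.mu_organ
    if spec.noise_sd > 0:
        mri_data += spec.noise_sd * rng.standard_normal(spec.dims)

    pet_geom = spec.pet_geometry
    idx = []
    for axis in range(3):
        centers = pet_geom.voxel_centers_world(axis)
        i, _ = _nearest_index(centers, geom.origin[axis], geom.spacing[axis], geom.shape[axis])
        idx.append(i)
    labels_on_pet = labels[np.ix_(idx[0], idx[1], idx[2])]
    uptake_lut = np.zeros(max(int(t) for t in Tissue) + 1, dtype=np.float64)
    for t, u in spec.uptake.items():
        uptake_lut[int(t)] = u
    pet_data = uptake_lut[labels_on_pet]
    if spec.pet_noise_sd > 0:
        pet_data = pet_data + spec.pet_noise_sd * rng.standard_normal(pet_geom.shape)

    mri = VolumeImage(mri_data, spec.mri_spacing, modality=Modality.MRI)
    pet = VolumeImage(pet_data, pet_geom.spacing, origin=pet_geom.origin, modality=Modality.PET)
    return PhantomCase(mri=mri, pet=pet, truth_rois=rois, truth_labels=labels, spec=spec)


def _smooth_circular(noise: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.exp(-0.5 * (np.arange(-width, width + 1) / (width / 2.0)) ** 2)
    kernel /= kernel.sum()
    n = noise.size
    idx = (np.arange(n)[:, None] + np.arange(-width, width + 1)[None, :]) % n
    return (noise[idx] * kernel[None, :]).sum(axis=1)


def perturb_roi(rois: ROISet, magnitude: float, seed: int) -> ROISet:
    """Smooth random radial displacement of every contour's vertices.

    The maximum vertex displacement equals ``magnitude`` voxels (0 returns
    an identical copy). Radial perturbation about the contour centroid
    preserves vertex angular order, so star-shaped polygons stay simple.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return ROISet(
            contours=[Contour(c.slice_index, c.vertices.copy(), c.label) for c in rois.contours],
            slice_range=rois.slice_range,
            grid_shape=rois.grid_shape,
            grid_spacing=rois.grid_spacing,
        )
    rng = np.random.default_rng(seed)
    _, ny, nx = rois.grid_shape
    out = []
    for c in rois.contours:
        v = c.vertices
        centroid = v.mean(axis=0)
        rel = v - centroid
        dist = np.linalg.norm(rel, axis=1)
        dist = np.maximum(dist, 1e-6)
        offsets = _smooth_circular(rng.standard_normal(v.shape[0]))
        peak = np.abs(offsets).max()
        if peak > 0:
            offsets = offsets / peak * magnitude
        new_dist = np.maximum(dist + offsets, 0.5)
        nv = centroid + rel * (new_dist / dist)[:, None]
        nv[:, 0] = np.clip(nv[:, 0], 0.0, ny - 1.0)
        nv[:, 1] = np.clip(nv[:, 1], 0.0, nx - 1.0)
        out.append(Contour(c.slice_index, nv, c.label))
    return ROISet(
        contours=out,
        slice_range=rois.slice_range,
        grid_shape=rois.grid_shape,
        grid_spacing=rois.grid_spacing,
    )


def _vary_spec(template: PhantomSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """Jitter body size and fat load so a cohort has between-scan variance."""
    by, bx = template.resolved_body_semiaxes
    scale = rng.uniform(0.80, 1.14)
    # keep the jittered spec feasible: the inner wall must leave room for organs
    max_thickness = min(by, bx) * scale * (1 - template.taper) - 10.5
    thickness = min(template.sat_thickness * rng.uniform(0.85, 1.2), max_thickness)
    return replace(
        template,
        body_semiaxes=(by * scale, bx * scale),
        sat_thickness=max(1.0, thickness),
        n_vat_blobs=int(rng.integers(3, max(4, template.n_vat_blobs + 3))),
        seed=seed,
    )


def make_validation_cohort(
    n: int,
    template: PhantomSpec | None = None,
    seed: int = 0,
    perturb_magnitude: float = 1.0,
) -> list[tuple[PhantomCase, ROISet]]:
    """n seeded phantoms, each paired with a perturbed 'predicted' ROI set."""
    if n < 2:
        raise ValueError(f"cohort needs n >= 2, got {n}")
    template = template or PhantomSpec()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        case_seed = int(rng.integers(0, 2**31 - 1))
        case = generate_phantom(_vary_spec(template, rng, case_seed))
        predicted = perturb_roi(case.truth_rois, perturb_magnitude, seed=case_seed + 1)
        cohort.append((case, predicted))
    return cohort
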