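import json

import numpy as np
import pytest

from adipoquant.errors import (
    GeometryError,
    InvalidAnnotationError,
    OutOfBoundsError,
)
from adipoquant.roi_core import (
    BinaryMask3D,
    Contour,
    GridGeometry,
    Label,
    Modality,
    ROISet,
    VolumeImage,
    fill_polygon,
    load_mask,
    load_roiset,
    load_volume,
    mask_and_not,
    rasterize,
    save_mask,
    save_roiset,
    save_volume,
)
from conftest import make_mask


# -- independent oracle: scalar per-pixel even-odd + on-segment test --------


def _point_on_segment(py, px, ay, ax, by, bx, eps=1e-9):
    cross = (by - ay) * (px - ax) - (bx - ax) * (py - ay)
    if abs(cross) > eps * max(1.0, (by - ay) ** 2 + (bx - ax) ** 2):
        return False
    dot = (py - ay) * (by - ay) + (px - ax) * (bx - ax)
    return -eps <= dot <= (by - ay) ** 2 + (bx - ax) ** 2 + eps


def oracle_point_in_polygon(py, px, verts):
    """Classic scalar crossing-number test, boundary-inclusive."""
    n = len(verts)
    inside = False
    for i in range(n):
        ay, ax = verts[i]
        by, bx = verts[(i + 1) % n]
        if ay == by and ax == bx:
            continue
        if _point_on_segment(py, px, ay, ax, by, bx):
            return True
        if (ay > py) != (by > py):
            xint = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < xint:
                inside = not inside
    return inside


def oracle_fill(shape, verts):
    out = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            out[r, c] = oracle_point_in_polygon(r, c, verts)
    return out


def _roiset_one(contour, shape=(1, 20, 20), spacing=(1.0, 1.0, 1.0)):
    return ROISet([contour], (0, shape[0] - 1), shape, spacing)


# -- types ------------------------------------------------------------------


class TestTypes:
    def test_volume_invariants(self):
        with pytest.raises(GeometryError):
            VolumeImage(np.zeros((4, 4)), (1, 1, 1))
        with pytest.raises(GeometryError):
            VolumeImage(np.zeros((2, 4, 4)), (1, -1, 1))
        with pytest.raises(GeometryError):
            VolumeImage(np.full((2, 4, 4), np.nan), (1, 1, 1))
        v = VolumeImage(np.zeros((2, 4, 4)), (2.09, 1.39, 1.39), modality="PET")
        assert v.modality is Modality.PET

    def test_contour_needs_three_vertices(self):
        with pytest.raises(InvalidAnnotationError):
            Contour(0, [[1, 1], [2, 2]], Label.EXT)

    def test_contour_rejects_nonfinite(self):
        with pytest.raises(InvalidAnnotationError):
            Contour(0, [[1, 1], [2, np.inf], [3, 1]], Label.EXT)

    def test_roiset_rejects_duplicate_ext_on_slice(self):
        tri = [[1, 1], [1, 5], [5, 5]]
        with pytest.raises(InvalidAnnotationError):
            ROISet(
                [Contour(0, tri, Label.EXT), Contour(0, tri, Label.EXT)],
                (0, 0),
                (1, 10, 10),
                (1, 1, 1),
            )

    def test_roiset_allows_multiple_exc_on_slice(self):
        tri = [[1, 1], [1, 5], [5, 5]]
        rs = ROISet(
            [Contour(0, tri, Label.EXC), Contour(0, tri, Label.EXC)],
            (0, 0),
            (1, 10, 10),
            (1, 1, 1),
        )
        assert len(rs.contours_on(0, Label.EXC)) == 2

    def test_roiset_slice_out_of_range(self):
        tri = [[1, 1], [1, 5], [5, 5]]
        with pytest.raises(InvalidAnnotationError):
            ROISet([Contour(3, tri, Label.EXT)], (0, 2), (4, 10, 10), (1, 1, 1))

    def test_grid_geometry_voxel_volume(self):
        g = GridGeometry((2, 3, 4), (2.0, 0.5, 0.25))
        assert g.voxel_volume_mm3 == pytest.approx(0.25)


# -- rasterize --------------------------------------------------------------


class TestRasterize:
    def test_axis_aligned_square_121_pixels(self):
        # brute-force point-in-polygon over all 400 centers gives 121
        verts = [[2, 2], [2, 12], [12, 12], [12, 2]]
        rs = _roiset_one(Contour(0, verts, Label.EXT))
        mask = rasterize(rs, Label.EXT)
        assert mask.count == 121
        assert np.array_equal(mask.data[0], oracle_fill((20, 20), verts))

    def test_no_contours_of_label(self):
        rs = _roiset_one(Contour(0, [[2, 2], [2, 12], [12, 12]], Label.EXT))
        assert rasterize(rs, Label.INT).count == 0

    def test_two_disjoint_exc_squares_union(self):
        sq1 = [[1, 1], [1, 6], [6, 6], [6, 1]]  # 36 pixels
        sq2 = [[10, 10], [10, 15], [15, 15], [15, 10]]
        rs = ROISet(
            [Contour(0, sq1, Label.EXC), Contour(0, sq2, Label.EXC)],
            (0, 0),
            (1, 20, 20),
            (1, 1, 1),
        )
        mask = rasterize(rs, Label.EXC)
        assert mask.count == 72
        expected = oracle_fill((20, 20), sq1) | oracle_fill((20, 20), sq2)
        assert np.array_equal(mask.data[0], expected)

    def test_vertex_out_of_bounds_raises(self):
        rs = _roiset_one(Contour(0, [[2, 2], [2, 25], [12, 12]], Label.EXT))
        with pytest.raises(OutOfBoundsError):
            rasterize(rs, Label.EXT)

    def test_grid_mismatch_raises(self):
        rs = _roiset_one(Contour(0, [[2, 2], [2, 12], [12, 12]], Label.EXT))
        with pytest.raises(GeometryError):
            rasterize(rs, Label.EXT, GridGeometry((1, 30, 30), (1, 1, 1)))

    @pytest.mark.parametrize("seed", range(40))
    def test_random_convex_polygons_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
        radius = rng.uniform(2, 8)
        cy, cx = rng.uniform(8, 12, 2)
        verts = np.column_stack(
            [cy + radius * np.sin(angles), cx + radius * np.cos(angles)]
        )
        verts = np.clip(verts, 0, 19)
        assert np.array_equal(fill_polygon((20, 20), verts), oracle_fill((20, 20), verts))

    @pytest.mark.parametrize("seed", range(40, 100))
    def test_random_star_polygons_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 14))
        angles = 2 * np.pi * np.arange(n) / n
        radii = rng.uniform(1.5, 8.5, n)
        cy, cx = rng.uniform(9, 11, 2)
        verts = np.column_stack(
            [cy + radii * np.sin(angles), cx + radii * np.cos(angles)]
        )
        verts = np.clip(verts, 0, 19)
        assert np.array_equal(fill_polygon((20, 20), verts), oracle_fill((20, 20), verts))

    def test_translation_equivariance(self, rng):
        angles = 2 * np.pi * np.arange(7) / 7
        radii = rng.uniform(2, 5, 7)
        base = np.column_stack([8 + radii * np.sin(angles), 8 + radii * np.cos(angles)])
        a = fill_polygon((30, 30), base)
        b = fill_polygon((30, 30), base + np.array([4.0, 7.0]))
        assert np.array_equal(np.roll(np.roll(a, 4, axis=0), 7, axis=1), b)

    def test_shapely_cross_check(self):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Point, Polygon

        rng = np.random.default_rng(77)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            angles = 2 * np.pi * np.arange(n) / n
            radii = rng.uniform(2, 8, n)
            verts = np.column_stack(
                [10 + radii * np.sin(angles), 10 + radii * np.cos(angles)]
            )
            poly = Polygon([(c, r) for r, c in verts])
            ours = fill_polygon((20, 20), verts)
            for r in range(20):
                for c in range(20):
                    assert ours[r, c] == poly.covers(Point(c, r)), (r, c, verts)


# -- mask algebra -----------------------------------------------------------


class TestMaskAndNot:
    def test_self_subtraction_empty(self):
        a = make_mask(np.ones((2, 4, 4)))
        assert mask_and_not(a, a).count == 0

    def test_empty_b_is_identity(self):
        a = make_mask(np.ones((2, 4, 4)))
        b = make_mask(np.zeros((2, 4, 4)))
        assert np.array_equal(mask_and_not(a, b).data, a.data)

    def test_annulus_by_enumeration(self):
        yy, xx = np.mgrid[0:30, 0:30]
        outer = ((yy - 15) ** 2 + (xx - 15) ** 2 <= 100)[None]
        inner = ((yy - 15) ** 2 + (xx - 15) ** 2 <= 36)[None]
        result = mask_and_not(make_mask(outer), make_mask(inner))
        # independent voxel enumeration of the set difference
        expected = int(np.sum(outer & ~inner))
        assert result.count == expected
        assert expected == int(outer.sum()) - int(inner.sum())  # inner within outer

    def test_idempotent_in_b(self, rng):
        a = make_mask(rng.random((3, 8, 8)) > 0.5)
        b = make_mask(rng.random((3, 8, 8)) > 0.5)
        once = mask_and_not(a, b)
        twice = mask_and_not(once, b)
        assert np.array_equal(once.data, twice.data)

    def test_dim_mismatch(self):
        a = make_mask(np.ones((2, 4, 4)))
        b = make_mask(np.ones((2, 4, 5)))
        with pytest.raises(GeometryError):
            mask_and_not(a, b)


# -- I/O round-trips --------------------------------------------------------


class TestIO:
    def test_roi_json_round_trip(self, tmp_path):
        rs = ROISet(
            [
                Contour(1, [[2.5, 2.0], [2.5, 12.0], [12.0, 7.5]], Label.EXT),
                Contour(1, [[4, 4], [4, 9], [9, 9], [9, 4]], Label.INT),
                Contour(2, [[5, 5], [5, 7], [7, 7]], Label.EXC),
            ],
            (1, 2),
            (4, 20, 20),
            (2.09, 1.39, 1.39),
        )
        p = tmp_path / "rois.json"
        save_roiset(rs, p)
        back = load_roiset(p)
        assert back.slice_range == rs.slice_range
        assert back.grid_shape == rs.grid_shape
        assert back.grid_spacing == pytest.approx(rs.grid_spacing)
        assert len(back.contours) == 3
        for a, b in zip(rs.contours, back.contours):
            assert a.label == b.label and a.slice_index == b.slice_index
            assert np.allclose(a.vertices, b.vertices)

    def test_roi_json_schema_fields(self, tmp_path):
        rs = ROISet(
            [Contour(0, [[1, 1], [1, 3], [3, 3]], Label.EXT)], (0, 0), (1, 5, 5), (1, 1, 1)
        )
        p = tmp_path / "rois.json"
        save_roiset(rs, p)
        doc = json.loads(p.read_text())
        assert set(doc) == {"grid", "slice_range", "contours"}
        assert set(doc["grid"]) == {"dims", "spacing_mm"}
        assert set(doc["contours"][0]) == {"slice", "label", "vertices"}

    def test_roi_json_missing_field_named(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"grid": {"dims": [1, 5, 5]}, "slice_range": [0, 0], "contours": []}')
        with pytest.raises(InvalidAnnotationError, match="spacing_mm"):
            load_roiset(p)

    def test_nifti_volume_round_trip(self, tmp_path, rng):
        vol = VolumeImage(
            rng.random((4, 6, 8)), (2.09, 1.39, 1.39), origin=(1.0, 2.0, 3.0)
        )
        p = tmp_path / "vol.nii.gz"
        save_volume(vol, p)
        back = load_volume(p)
        assert back.data.shape == vol.data.shape
        assert back.spacing == pytest.approx(vol.spacing, rel=1e-5)
        assert back.origin == pytest.approx(vol.origin, rel=1e-5)
        assert np.allclose(back.data, vol.data, atol=1e-6)

    def test_nifti_mask_round_trip(self, tmp_path, rng):
        mask = make_mask(rng.random((3, 5, 7)) > 0.5, spacing=(2.0, 1.5, 1.0))
        p = tmp_path / "mask.nii.gz"
        save_mask(mask, p)
        back = load_mask(p, label="SAT")
        assert np.array_equal(back.data, mask.data)
        assert back.spacing == pytest.approx(mask.spacing, rel=1e-5)
        assert back.label == "SAT"
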