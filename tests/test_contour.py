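"""Contour extraction, orientation, resampling and the shape signature."""

import numpy as np
import pytest

from otoshape import (
    Contour,
    canonical_orientation,
    extract_contour,
    otolith_length,
    polygon_centroid,
    resample_equidistant,
    signature,
)
from otoshape.contour import _signed_area


class TestExtractContour:
    def test_disk_boundary_radii(self):
        yy, xx = np.mgrid[0:120, 0:120]
        mask = (xx - 60) ** 2 + (yy - 60) ** 2 <= 50**2
        c = extract_contour(mask)
        r = np.hypot(c.vertices[:, 0] - 60, c.vertices[:, 1] - (119 - 60))
        assert np.all(np.abs(r - 50) <= 1.0)

    def test_largest_component_wins(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[10:50, 10:35] = True  # 1000 px
        mask[70:75, 70:72] = True  # 10 px
        c = extract_contour(mask)
        assert c.vertices[:, 0].max() < 40  # boundary of the big blob only

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty mask"):
            extract_contour(np.zeros((10, 10), dtype=bool))

    def test_counterclockwise_output(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:30, 8:35] = True
        c = extract_contour(mask)
        assert _signed_area(c.vertices) > 0

    def test_holes_ignored(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 10:50] = True
        mask[25:35, 25:35] = False  # interior hole
        c = extract_contour(mask)
        # boundary follows the outer square, not the hole
        assert c.vertices[:, 0].max() > 45


class TestPolygonCentroid:
    def test_unit_square(self, square_contour):
        assert polygon_centroid(square_contour) == pytest.approx((0.5, 0.5))

    def test_right_triangle(self):
        tri = Contour(np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]]))
        assert polygon_centroid(tri) == pytest.approx((1.0, 1.0))

    def test_matches_raster_mass_center(self, rng):
        # random star-shaped polygon vs dense pixel-count oracle
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        r = 1.0 + 0.3 * np.cos(3 * th) + 0.1 * np.sin(5 * th)
        poly = Contour(np.column_stack([3 + r * np.cos(th), 2 + r * np.sin(th)]))
        cx, cy = polygon_centroid(poly)
        n = 2000
        xs = np.linspace(1.5, 4.5, n)
        ys = np.linspace(0.5, 3.5, n)
        X, Y = np.meshgrid(xs, ys)
        ang = np.arctan2(Y - 2, X - 3)
        rad = np.hypot(X - 3, Y - 2)
        inside = rad <= np.interp(np.mod(ang, 2 * np.pi), th, r, period=2 * np.pi)
        assert cx == pytest.approx(X[inside].mean(), abs=1e-3)
        assert cy == pytest.approx(Y[inside].mean(), abs=1e-3)

    def test_degenerate_polygon_errors(self):
        flat = Contour(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 1e-18]]))
        with pytest.raises(ValueError, match="degenerate"):
            polygon_centroid(flat)


class TestResampleEquidistant:
    def test_circle_radii_and_spacing(self, circle_contour):
        rs = resample_equidistant(circle_contour, 512)
        assert rs.n_vertices == 512
        r = np.hypot(*rs.vertices.T)
        assert np.all(np.abs(r - 1.0) < 1e-4)
        closed = np.vstack([rs.vertices, rs.vertices[:1]])
        spacing = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        assert np.ptp(spacing) / spacing.mean() < 1e-4

    def test_square_exact_spacing(self, square_contour):
        rs = resample_equidistant(square_contour, 512)
        closed = np.vstack([rs.vertices, rs.vertices[:1]])
        spacing = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        assert np.allclose(spacing, 4.0 / 512, rtol=1e-9)
        # 128 points per unit-length side
        on_bottom = np.isclose(rs.vertices[:, 1], 0.0)
        assert on_bottom.sum() == 129  # both corners of the side included

    def test_ellipse_matches_dense_arc_table(self, ellipse_contour):
        rs = resample_equidistant(ellipse_contour, 512)
        # oracle: cumulative arc length from a 200k-point subdivision
        t = np.linspace(0, 2 * np.pi, 200_000, endpoint=False)
        dense = np.column_stack([2 * np.cos(t), np.sin(t)])
        seg = np.linalg.norm(np.diff(np.vstack([dense, dense[:1]]), axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        perim = cum[-1]
        x_o = np.interp(np.arange(512) * perim / 512, cum, np.append(dense[:, 0], dense[0, 0]))
        assert np.abs(rs.vertices[:, 0] - x_o).max() < 1e-3 * perim

    def test_too_few_points_errors(self, circle_contour):
        with pytest.raises(ValueError):
            resample_equidistant(circle_contour, 2)


class TestSignature:
    def test_circle_all_ones(self, circle_contour):
        with pytest.warns(UserWarning):  # every vertex ties for the maximum
            sig = signature(resample_equidistant(circle_contour, 512))
        assert np.allclose(sig.distances, 1.0, atol=1e-5)
        assert sig.distances.mean() == pytest.approx(1.0, abs=1e-12)

    def test_ellipse_start_on_major_axis_and_symmetry(self, ellipse_contour):
        sig = signature(resample_equidistant(ellipse_contour, 512))
        assert sig.distances[0] == sig.distances.max()
        # index 0 lies on the major axis; reversal symmetry of the sequence
        rev = np.concatenate([[sig.distances[0]], sig.distances[1:][::-1]])
        assert np.abs(sig.distances - rev).max() < 1e-6

    def test_scale_and_translation_invariance(self, otolith_contour):
        base = signature(resample_equidistant(otolith_contour, 512)).distances
        v = otolith_contour.vertices * 10.0 + np.array([123.0, -45.0])
        moved = signature(resample_equidistant(Contour(v), 512)).distances
        assert np.abs(base - moved).max() < 1e-12

    def test_start_vertex_invariance(self, otolith_contour):
        # rotation of the starting vertex of an already-equidistant polygon
        # leaves the signature untouched (samples land on the same points)
        rs = resample_equidistant(otolith_contour, 512)
        base = signature(rs).distances
        rolled = Contour(np.roll(rs.vertices, 301, axis=0))
        other = signature(resample_equidistant(rolled, 512)).distances
        # exact in the continuum; discretely limited by second-order
        # interpolation error of the 512-point sampling
        assert np.abs(base - other).max() < 1e-4

    def test_element_zero_is_global_max(self, otolith_contour, rng):
        sig = signature(resample_equidistant(otolith_contour, 512))
        assert sig.distances[0] == sig.distances.max()
        assert len(sig) == 512


class TestCanonicalOrientation:
    def test_left_unchanged(self, otolith_contour):
        out = canonical_orientation(otolith_contour)
        assert np.allclose(out.vertices, otolith_contour.vertices)

    def test_mirror_involution(self, otolith_contour):
        right = Contour(otolith_contour.vertices.copy(), side="right")
        once = canonical_orientation(right)
        twice = canonical_orientation(Contour(once.vertices, side="right"))
        assert np.abs(twice.vertices - right.vertices).max() < 1e-12
        assert once.side == "left"

    def test_mirrored_signature_matches_reversed(self, otolith_contour):
        rs = resample_equidistant(otolith_contour, 512)
        base = signature(rs).distances
        mirrored = canonical_orientation(Contour(rs.vertices, side="right"))
        msig = signature(resample_equidistant(mirrored, 512)).distances
        # mirror reverses traversal; from the (unique) farthest point the
        # distance sequence of the mirror is the reversal of the original
        rev = np.concatenate([[base[0]], base[1:][::-1]])
        # reversal identity holds up to the same discretization error
        assert np.abs(msig - rev).max() < 1e-4

    def test_unknown_side_errors(self, otolith_contour):
        anon = Contour(otolith_contour.vertices, side=None)
        with pytest.raises(ValueError, match="side unknown"):
            canonical_orientation(anon)
        assert canonical_orientation(anon, assume_left=True).side == "left"


class TestOtolithLength:
    def test_ellipse_major_extent(self):
        t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        ell = Contour(np.column_stack([2.0 * np.cos(t), 1.1 * np.sin(t)]))
        assert otolith_length(ell) == pytest.approx(4.0, abs=1e-4)

    def test_px_without_scale_errors(self, otolith_contour):
        c = Contour(otolith_contour.vertices, units="px")
        with pytest.raises(ValueError, match="px_per_mm"):
            otolith_length(c)
        c2 = Contour(otolith_contour.vertices, units="px", px_per_mm=2.0)
        assert otolith_length(c2) == pytest.approx(otolith_length(otolith_contour) / 2.0)
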