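"""Affine and projective map recovery checked against independent dense
linear-system (6x6 / 8x8 DLT) solves, plus tessellation geometry."""

import numpy as np
import pytest

from chemmorph.errors import DegenerateError, DomainError, HorizonError
from chemmorph.mapping import (
    UNIT_SQUARE,
    AffineMap,
    ProjectiveMap,
    affine_from_triplet,
    apply_map,
    cell_map,
    projective_from_quads,
    square_to_quad,
    tessellate_region,
)
from chemmorph.model import Point2


def affine_oracle(src, dst):
    """Independent 6x6 dense solve for the affine coefficients."""
    A = np.zeros((6, 6))
    b = np.zeros(6)
    for k, (s, d) in enumerate(zip(src, dst)):
        A[2 * k, 0:3] = [s.x, s.y, 1.0]
        A[2 * k + 1, 3:6] = [s.x, s.y, 1.0]
        b[2 * k], b[2 * k + 1] = d.x, d.y
    return np.linalg.solve(A, b)


def dlt_oracle(src, dst):
    """Independent 8x8 direct-linear-transform solve for the homography."""
    A, b = [], []
    for s, d in zip(src, dst):
        A.append([s.x, s.y, 1, 0, 0, 0, -d.x * s.x, -d.x * s.y])
        A.append([0, 0, 0, s.x, s.y, 1, -d.y * s.x, -d.y * s.y])
        b.extend([d.x, d.y])
    h = np.linalg.solve(np.array(A, float), np.array(b, float))
    return np.array([[h[0], h[1], h[2]], [h[3], h[4], h[5]], [h[6], h[7], 1.0]])


def random_quad(rng, spread=0.2):
    """A convex-ish quad: unit square corners plus bounded jitter."""
    return [
        Point2(c.x + float(rng.uniform(-spread, spread)), c.y + float(rng.uniform(-spread, spread)))
        for c in UNIT_SQUARE
    ]


class TestAffine:
    def test_identity_triplet(self):
        tri = [Point2(0, 0), Point2(1, 0), Point2(0, 1)]
        m = affine_from_triplet(tri, tri)
        assert (m.a, m.b, m.c, m.d, m.e, m.f) == pytest.approx((1, 0, 0, 0, 1, 0), abs=1e-12)

    def test_pure_scaling(self):
        src = [Point2(0, 0), Point2(1, 0), Point2(0, 1)]
        dst = [p.scaled(2.0) for p in src]
        m = affine_from_triplet(src, dst)
        for s, d in zip(src, dst):
            got = m.apply(s)
            assert (got.x, got.y) == pytest.approx((d.x, d.y), abs=1e-12)

    def test_matches_dense_solve_oracle(self, rng):
        for _ in range(200):
            src = [Point2(*rng.uniform(-5, 5, 2)) for _ in range(3)]
            dst = [Point2(*rng.uniform(-5, 5, 2)) for _ in range(3)]
            area = (src[1].x - src[0].x) * (src[2].y - src[0].y) - (
                src[1].y - src[0].y
            ) * (src[2].x - src[0].x)
            if abs(area) < 1e-3:
                continue
            m = affine_from_triplet(src, dst)
            expect = affine_oracle(src, dst)
            assert np.allclose([m.a, m.b, m.c, m.d, m.e, m.f], expect, atol=1e-8)
            for s, d in zip(src, dst):
                got = m.apply(s)
                assert abs(got.x - d.x) < 1e-9 and abs(got.y - d.y) < 1e-9

    def test_collinear_source_rejected(self):
        with pytest.raises(DegenerateError):
            affine_from_triplet(
                [Point2(0, 0), Point2(1, 1), Point2(2, 2)],
                [Point2(0, 0), Point2(1, 0), Point2(0, 1)],
            )

    def test_singular_map_rejected(self):
        with pytest.raises(DegenerateError):
            AffineMap(1, 1, 0, 1, 1, 0)

    def test_inverse_composes_to_identity(self, rng):
        m = AffineMap(2.0, 0.5, 1.0, -0.25, 1.5, -3.0)
        inv = m.inverse()
        for _ in range(20):
            p = Point2(*rng.uniform(-10, 10, 2))
            q = inv.apply(m.apply(p))
            assert abs(q.x - p.x) < 1e-9 and abs(q.y - p.y) < 1e-9


class TestSquareToQuad:
    def test_unit_square_gives_identity(self):
        m = square_to_quad(UNIT_SQUARE)
        assert np.allclose(m.H, np.eye(3), atol=1e-12)

    def test_parallelogram_degenerates_to_affine(self):
        quad = [Point2(0, 0), Point2(2, 0), Point2(3, 1), Point2(1, 1)]
        m = square_to_quad(quad)
        assert m.H[2, 0] == 0.0 and m.H[2, 1] == 0.0
        assert m.is_affine()

    def test_general_quad_matches_dlt(self):
        quad = [Point2(0, 0), Point2(1, 0), Point2(2, 2), Point2(0, 1)]
        m = square_to_quad(quad)
        expect = dlt_oracle(UNIT_SQUARE, quad)
        for c, q in zip(UNIT_SQUARE, quad):
            got = m.apply(c)
            assert abs(got.x - q.x) < 1e-9 and abs(got.y - q.y) < 1e-9
        assert np.allclose(m.H, expect, atol=1e-9)

    def test_collinear_corners_rejected(self):
        with pytest.raises(DegenerateError):
            square_to_quad([Point2(0, 0), Point2(1, 0), Point2(2, 0), Point2(0, 1)])


class TestProjectiveFromQuads:
    def test_same_quad_gives_identity(self, rng):
        for _ in range(50):
            q = random_quad(rng)
            m = projective_from_quads(q, q)
            assert np.allclose(m.H, np.eye(3), atol=1e-8)

    def test_translated_square_gives_pure_translation(self):
        dst = [Point2(c.x + 3.0, c.y - 2.0) for c in UNIT_SQUARE]
        m = projective_from_quads(UNIT_SQUARE, dst)
        expect = np.array([[1, 0, 3.0], [0, 1, -2.0], [0, 0, 1]])
        assert np.allclose(m.H, expect, atol=1e-12)

    def test_corners_map_within_dlt_tolerance(self, rng):
        for _ in range(200):
            src, dst = random_quad(rng), random_quad(rng)
            m = projective_from_quads(src, dst)
            expect = dlt_oracle(src, dst)
            for s, d in zip(src, dst):
                got = m.apply(s)
                assert abs(got.x - d.x) < 1e-9 and abs(got.y - d.y) < 1e-9
            assert np.allclose(m.H, expect, atol=1e-7)

    def test_composition_property(self, rng):
        for _ in range(50):
            a, b, c = random_quad(rng), random_quad(rng), random_quad(rng)
            ab = projective_from_quads(a, b)
            bc = projective_from_quads(b, c)
            ac = projective_from_quads(a, c)
            for p, expect in zip(a, c):
                via = bc.apply(ab.apply(p))
                direct = ac.apply(p)
                assert abs(via.x - direct.x) < 1e-8 and abs(via.y - direct.y) < 1e-8
                assert abs(direct.x - expect.x) < 1e-8


class TestApplyMap:
    def test_identity_maps(self):
        p = Point2(3.5, -1.25)
        assert apply_map(AffineMap.identity(), p) == p
        got = apply_map(ProjectiveMap.identity(), p)
        assert (got.x, got.y) == pytest.approx((p.x, p.y), abs=1e-15)

    def test_scaling_affine(self):
        m = AffineMap(2, 0, 0, 0, 2, 0)
        assert apply_map(m, Point2(1, 1)) == Point2(2, 2)

    def test_matches_direct_formula(self, rng):
        H = np.array([[1.2, 0.1, 0.5], [-0.2, 0.9, 1.0], [0.05, -0.03, 1.0]])
        m = ProjectiveMap(H)
        for _ in range(50):
            x, y = rng.uniform(-2, 2, 2)
            w = H[2, 0] * x + H[2, 1] * y + 1.0
            got = apply_map(m, Point2(float(x), float(y)))
            assert abs(got.x - (H[0, 0] * x + H[0, 1] * y + H[0, 2]) / w) < 1e-12
            assert abs(got.y - (H[1, 0] * x + H[1, 1] * y + H[1, 2]) / w) < 1e-12

    def test_horizon_point_rejected(self):
        m = ProjectiveMap(np.array([[1, 0, 0], [0, 1, 0], [1.0, 0, 1]]))
        with pytest.raises(HorizonError):
            m.apply(Point2(-1.0, 0.0))


class TestTessellation:
    def test_single_square_is_bbox(self):
        mesh = tessellate_region((0, 0, 4, 2), "squares", 1)
        assert len(mesh.cells) == 1
        corners = mesh.cell_corners(mesh.cells[0])
        assert corners == (Point2(0, 0), Point2(4, 0), Point2(4, 2), Point2(0, 2))

    def test_triangle_count_and_area(self):
        mesh = tessellate_region((0, 0, 3, 3), "triangles", 2)
        assert len(mesh.cells) == 8
        total = sum(abs(mesh.cell_area(c)) for c in mesh.cells)
        assert total == pytest.approx(9.0, abs=1e-9)

    def test_squares_counting(self):
        mesh = tessellate_region((0, 0, 1, 1), "squares", 3)
        assert len(mesh.cells) == 9
        assert len(mesh.vertices) == 16

    @pytest.mark.parametrize("mode", ["triangles", "squares"])
    def test_area_conservation(self, mode):
        bbox = (-2.0, 1.0, 5.5, 4.0)
        mesh = tessellate_region(bbox, mode, 5)
        total = sum(abs(mesh.cell_area(c)) for c in mesh.cells)
        assert total == pytest.approx((5.5 + 2.0) * 3.0, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            tessellate_region((0, 0, 1, 1), "squares", 0)
        with pytest.raises(DomainError):
            tessellate_region((0, 0, 0, 1), "squares", 2)
        with pytest.raises(DomainError):
            tessellate_region((0, 0, 1, 1), "hexes", 2)

    def test_cell_map_sends_cells_onto_cells(self):
        src = tessellate_region((0, 0, 2, 2), "squares", 2)
        dst = tessellate_region((1, 1, 5, 3), "squares", 2)
        m = cell_map(src, dst, 0)
        for s, d in zip(src.cell_corners(src.cells[0]), dst.cell_corners(dst.cells[0])):
            got = m.apply(s)
            assert abs(got.x - d.x) < 1e-9 and abs(got.y - d.y) < 1e-9
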