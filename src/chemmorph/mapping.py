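"""Affine (three-point) and projective (four-point) 2D mappings.

The morphing engine warps scene regions with two classical constructions:

* an affine map is the unique linear-plus-translation transform fixed by
  three non-collinear point correspondences (triangular sections);
* a projective map (homography) is fixed by four correspondences and is
  built here by the unit-squares method: factor the quad-to-quad map through
  maps between the unit square and each quadrilateral, where the
  square-to-quad direction has a closed form (Heckbert's construction) with
  an exact affine shortcut when the quad is a parallelogram.

Corner convention throughout: counter-clockwise starting at the bottom-left,
i.e. the unit square is (0,0), (1,0), (1,1), (0,1).

Degeneracy (collinear control points, vanishing determinants) is detected at
an absolute threshold of 1e-12 on triangle areas and determinants, matched to
scene coordinates of magnitude ~1-100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .errors import DegenerateError, DomainError, HorizonError
from .model import Point2

#: Absolute area/determinant threshold below which control points are degenerate.
DEGENERACY_EPS = 1e-12

#: Unit-square corners, counter-clockwise from the bottom-left.
UNIT_SQUARE = (Point2(0.0, 0.0), Point2(1.0, 0.0), Point2(1.0, 1.0), Point2(0.0, 1.0))


def _signed_area(p: Point2, q: Point2, r: Point2) -> float:
    """Twice the signed triangle area — zero iff the points are collinear."""
    return (q.x - p.x) * (r.y - p.y) - (q.y - p.y) * (r.x - p.x)


@dataclass(frozen=True)
class AffineMap:
    """(x, y) -> (a x + b y + c, d x + e y + f); must be invertible."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        if abs(self.a * self.e - self.b * self.d) < DEGENERACY_EPS:
            raise DegenerateError("affine map is singular")

    def apply(self, p: Point2) -> Point2:
        return Point2(self.a * p.x + self.b * p.y + self.c, self.d * p.x + self.e * p.y + self.f)

    def inverse(self) -> "AffineMap":
        det = self.a * self.e - self.b * self.d
        ia, ib = self.e / det, -self.b / det
        id_, ie = -self.d / det, self.a / det
        return AffineMap(ia, ib, -(ia * self.c + ib * self.f), id_, ie, -(id_ * self.c + ie * self.f))

    @staticmethod
    def identity() -> "AffineMap":
        return AffineMap(1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


@dataclass(frozen=True)
class ProjectiveMap:
    """Homography (x, y) -> ((h11 x + h12 y + h13) / w, (h21 x + h22 y + h23) / w)
    with w = h31 x + h32 y + 1. Stored as a 3x3 matrix normalised to h33 = 1."""

    H: np.ndarray

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        if H.shape != (3, 3):
            raise DomainError(f"homography must be 3x3, got {H.shape}")
        if abs(H[2, 2]) < DEGENERACY_EPS:
            raise DegenerateError("homography has h33 ~ 0; cannot normalise")
        H = H / H[2, 2]
        if abs(np.linalg.det(H)) < DEGENERACY_EPS:
            raise DegenerateError("homography is singular")
        object.__setattr__(self, "H", H)
        self.H.setflags(write=False)

    def apply(self, p: Point2) -> Point2:
        H = self.H
        w = H[2, 0] * p.x + H[2, 1] * p.y + 1.0
        if abs(w) < DEGENERACY_EPS:
            raise HorizonError(f"point ({p.x}, {p.y}) maps to infinity")
        return Point2(
            (H[0, 0] * p.x + H[0, 1] * p.y + H[0, 2]) / w,
            (H[1, 0] * p.x + H[1, 1] * p.y + H[1, 2]) / w,
        )

    def inverse(self) -> "ProjectiveMap":
        return ProjectiveMap(np.linalg.inv(self.H))

    def is_affine(self, tol: float = 1e-12) -> bool:
        return abs(self.H[2, 0]) <= tol and abs(self.H[2, 1]) <= tol

    @staticmethod
    def identity() -> "ProjectiveMap":
        return ProjectiveMap(np.eye(3))


AnyMap = Union[AffineMap, ProjectiveMap]


def affine_from_triplet(src: Sequence[Point2], dst: Sequence[Point2]) -> AffineMap:
    """The affine map sending three non-collinear points onto three others.

    Solves the two independent 3x3 linear systems in (a,b,c) and (d,e,f).
    """
    if len(src) != 3 or len(dst) != 3:
        raise DomainError("affine_from_triplet needs exactly 3 source and 3 target points")
    if abs(_signed_area(*src)) < DEGENERACY_EPS:
        raise DegenerateError("source points are collinear")
    M = np.array([[p.x, p.y, 1.0] for p in src])
    abc = np.linalg.solve(M, np.array([p.x for p in dst]))
    def_ = np.linalg.solve(M, np.array([p.y for p in dst]))
    return AffineMap(abc[0], abc[1], abc[2], def_[0], def_[1], def_[2])


def square_to_quad(quad: Sequence[Point2]) -> ProjectiveMap:
    """Homography taking the unit square onto ``quad`` (corners in CCW order).

    Closed-form unit-squares construction: writing the corner sums
    sx = x0 - x1 + x2 - x3 (and sy likewise), a parallelogram has sx = sy = 0
    and the map is exactly affine (h31 = h32 = 0); otherwise the two
    projective coefficients come from a 2x2 solve on the corner differences.
    """
    if len(quad) != 4:
        raise DomainError("square_to_quad needs exactly 4 corners")
    p0, p1, p2, p3 = quad
    for tri in ((p0, p1, p2), (p1, p2, p3), (p2, p3, p0), (p3, p0, p1)):
        if abs(_signed_area(*tri)) < DEGENERACY_EPS:
            raise DegenerateError("three quad corners are collinear")

    sx = p0.x - p1.x + p2.x - p3.x
    sy = p0.y - p1.y + p2.y - p3.y
    if abs(sx) < DEGENERACY_EPS and abs(sy) < DEGENERACY_EPS:
        # Parallelogram: affine case, projective row exactly zero.
        H = np.array(
            [
                [p1.x - p0.x, p3.x - p0.x, p0.x],
                [p1.y - p0.y, p3.y - p0.y, p0.y],
                [0.0, 0.0, 1.0],
            ]
        )
        return ProjectiveMap(H)

    dx1, dy1 = p1.x - p2.x, p1.y - p2.y
    dx2, dy2 = p3.x - p2.x, p3.y - p2.y
    den = dx1 * dy2 - dx2 * dy1
    if abs(den) < DEGENERACY_EPS:
        raise DegenerateError("quad is degenerate (difference vectors collinear)")
    g = (sx * dy2 - sy * dx2) / den
    h = (dx1 * sy - dy1 * sx) / den
    H = np.array(
        [
            [p1.x - p0.x + g * p1.x, p3.x - p0.x + h * p3.x, p0.x],
            [p1.y - p0.y + g * p1.y, p3.y - p0.y + h * p3.y, p0.y],
            [g, h, 1.0],
        ]
    )
    return ProjectiveMap(H)


def projective_from_quads(src: Sequence[Point2], dst: Sequence[Point2]) -> ProjectiveMap:
    """Homography sending quad ``src`` onto quad ``dst`` corner by corner.

    Composed through the unit square: square_to_quad(dst) o square_to_quad(src)^-1.
    """
    A = square_to_quad(src)
    B = square_to_quad(dst)
    H = B.H @ np.linalg.inv(A.H)
    if abs(H[2, 2]) < DEGENERACY_EPS:
        raise DegenerateError("composed homography cannot be normalised")
    return ProjectiveMap(H)


def apply_map(m: AnyMap, p: Point2) -> Point2:
    """Evaluate an affine or projective map at a point."""
    return m.apply(p)


@dataclass(frozen=True)
class RegionMesh:
    """A tessellation of a rectangle: shared vertices plus index cells
    (triangles or quads, consistently one kind per mesh)."""

    vertices: tuple[Point2, ...]
    cells: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", tuple(self.vertices))
        object.__setattr__(self, "cells", tuple(tuple(c) for c in self.cells))
        n = len(self.vertices)
        for cell in self.cells:
            if any(not (0 <= i < n) for i in cell):
                raise DomainError(f"cell {cell} references a vertex outside 0..{n - 1}")
            if abs(self.cell_area(cell)) < DEGENERACY_EPS:
                raise DegenerateError(f"cell {cell} is degenerate (zero area)")

    def cell_corners(self, cell: Sequence[int]) -> tuple[Point2, ...]:
        return tuple(self.vertices[i] for i in cell)

    def cell_area(self, cell: Sequence[int]) -> float:
        pts = [self.vertices[i] for i in cell]
        s = 0.0
        for i in range(len(pts)):
            j = (i + 1) % len(pts)
            s += pts[i].x * pts[j].y - pts[j].x * pts[i].y
        return 0.5 * s


def tessellate_region(
    bbox: Sequence[float], mode: str, n: int
) -> RegionMesh:
    """Tile ``bbox = (xmin, ymin, xmax, ymax)`` with an n-by-n grid.

    ``mode='squares'`` yields n^2 axis-aligned quad cells; ``mode='triangles'``
    splits each square along its main (bottom-left to top-right) diagonal into
    2 n^2 triangles. Cells are CCW; vertices are shared row-major.
    """
    if n < 1:
        raise DomainError(f"grid resolution must be >= 1, got {n}")
    xmin, ymin, xmax, ymax = (float(v) for v in bbox)
    if not (xmax > xmin and ymax > ymin):
        raise DomainError(f"degenerate bbox {bbox!r}")
    if mode not in ("triangles", "squares"):
        raise DomainError(f"unknown tessellation mode {mode!r}")

    xs = np.linspace(xmin, xmax, n + 1)
    ys = np.linspace(ymin, ymax, n + 1)
    vertices = tuple(Point2(float(x), float(y)) for y in ys for x in xs)

    def vid(ix: int, iy: int) -> int:
        return iy * (n + 1) + ix

    cells: list[tuple[int, ...]] = []
    for iy in range(n):
        for ix in range(n):
            v00, v10 = vid(ix, iy), vid(ix + 1, iy)
            v11, v01 = vid(ix + 1, iy + 1), vid(ix, iy + 1)
            if mode == "squares":
                cells.append((v00, v10, v11, v01))
            else:
                cells.append((v00, v10, v11))
                cells.append((v00, v11, v01))
    return RegionMesh(vertices=vertices, cells=tuple(cells))


def locate_cell(mesh_bbox: Sequence[float], mode: str, n: int, p: Point2) -> int:
    """Index of the tessellation cell containing ``p`` (clamped into the bbox).

    Grid geometry makes this O(1); points on shared edges go to the cell with
    the lower index, points outside the bbox to the nearest boundary cell.
    """
    xmin, ymin, xmax, ymax = (float(v) for v in mesh_bbox)
    ix = int(np.clip((p.x - xmin) / (xmax - xmin) * n, 0, n - 1e-9))
    iy = int(np.clip((p.y - ymin) / (ymax - ymin) * n, 0, n - 1e-9))
    square = iy * n + ix
    if mode == "squares":
        return square
    # triangles: lower-right triangle first, upper-left second
    fx = (p.x - xmin) / (xmax - xmin) * n - ix
    fy = (p.y - ymin) / (ymax - ymin) * n - iy
    return 2 * square + (0 if fy <= fx else 1)


def cell_map(src_mesh: RegionMesh, dst_mesh: RegionMesh, cell_index: int) -> AnyMap:
    """Map taking one source cell onto the matching destination cell.

    Triangles get the affine three-point map; quads the projective
    four-point map. Both meshes must share topology.
    """
    src = src_mesh.cell_corners(src_mesh.cells[cell_index])
    dst = dst_mesh.cell_corners(dst_mesh.cells[cell_index])
    if len(src) != len(dst):
        raise DomainError("meshes have mismatched cell arities")
    if len(src) == 3:
        return affine_from_triplet(src, dst)
    return projective_from_quads(src, dst)
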