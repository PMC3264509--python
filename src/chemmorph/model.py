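"""Chemical-drawing data model.

A :class:`Drawing` is a 2D scene of atoms, bonds and annotations with an
optional raster background — the in-memory representation every other module
(molfile I/O, morphing, rendering) operates on. Coordinates are real-valued
scene units with y increasing upward; no pixel grid is imposed.

Drawings are value-like: the mutating operations (:func:`add_atom`,
:func:`add_bond`, :func:`translate`, ...) return a new ``Drawing`` and leave
their argument untouched, so morph frames can share atoms freely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import (
    CapacityError,
    DanglingBondError,
    DomainError,
    DuplicateIdError,
    EmptyDrawingError,
    SelfBondError,
)

#: Hard upper bound on the number of atoms a drawing may hold.
ATOM_CAPACITY = 100000

RGB = tuple[int, int, int]

BLACK: RGB = (0, 0, 0)


def _check_rgb(color: Sequence[int], what: str) -> RGB:
    r, g, b = color
    for c in (r, g, b):
        if not (0 <= int(c) <= 255):
            raise DomainError(f"{what} channel {c} outside 0..255")
    return (int(r), int(g), int(b))


@dataclass(frozen=True)
class Point2:
    """A point in scene coordinates (y up). Both coordinates must be finite."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DomainError(f"non-finite coordinates ({self.x}, {self.y})")

    def __add__(self, other: "Point2") -> "Point2":
        return Point2(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "Point2") -> "Point2":
        return Point2(self.x - other.x, self.y - other.y)

    def scaled(self, s: float) -> "Point2":
        return Point2(self.x * s, self.y * s)

    def distance_to(self, other: "Point2") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class ShellStyle:
    """Concentric electron-shell circles around an atom.

    ``radii`` are scene units, strictly increasing; ``gradient`` is the
    (inner, outer) RGB pair of the radial fill.
    """

    radii: tuple[float, ...]
    gradient: tuple[RGB, RGB] = (BLACK, (255, 255, 255))

    def __post_init__(self) -> None:
        if len(self.radii) == 0:
            raise DomainError("shell needs at least one radius")
        prev = 0.0
        for r in self.radii:
            if r <= prev:
                raise DomainError(f"shell radii must be positive and strictly increasing: {self.radii}")
            prev = r
        object.__setattr__(self, "radii", tuple(float(r) for r in self.radii))
        inner, outer = self.gradient
        object.__setattr__(self, "gradient", (_check_rgb(inner, "gradient"), _check_rgb(outer, "gradient")))


@dataclass(frozen=True)
class Atom:
    """An atom: element symbol, 2D position and display state.

    ``mass_number``/``atomic_number_display`` drive isotope labels;
    ``opacity`` exists so morphing can cross-dissolve unmatched atoms.
    """

    id: int
    element: str
    position: Point2
    charge: int = 0
    mass_number: Optional[int] = None
    atomic_number_display: Optional[int] = None
    color: RGB = BLACK
    opacity: float = 1.0
    shell: Optional[ShellStyle] = None

    def __post_init__(self) -> None:
        if self.id < 0:
            raise DomainError(f"atom id must be >= 0, got {self.id}")
        if not self.element:
            raise DomainError("atom element symbol must be non-empty")
        if not (0.0 <= self.opacity <= 1.0):
            raise DomainError(f"opacity {self.opacity} outside [0, 1]")
        if self.mass_number is not None and self.mass_number <= 0:
            raise DomainError("mass_number must be positive")
        if self.atomic_number_display is not None and self.atomic_number_display <= 0:
            raise DomainError("atomic_number_display must be positive")
        if (
            self.mass_number is not None
            and self.atomic_number_display is not None
            and self.mass_number < self.atomic_number_display
        ):
            raise DomainError("mass_number must be >= atomic number")
        object.__setattr__(self, "color", _check_rgb(self.color, "atom color"))

    def moved_to(self, p: Point2) -> "Atom":
        return replace(self, position=p)


class BondKind(str, Enum):
    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    WEDGE = "wedge"
    HASH = "hash"
    AROMATIC = "aromatic"


@dataclass(frozen=True)
class Bond:
    """A bond between two atom ids. ``a1 != a2``; ids must resolve in the owning drawing."""

    a1: int
    a2: int
    kind: BondKind = BondKind.SINGLE
    color: RGB = BLACK
    opacity: float = 1.0

    def __post_init__(self) -> None:
        if self.a1 == self.a2:
            raise SelfBondError(f"bond joins atom {self.a1} to itself")
        if not (0.0 <= self.opacity <= 1.0):
            raise DomainError(f"opacity {self.opacity} outside [0, 1]")
        object.__setattr__(self, "kind", BondKind(self.kind))
        object.__setattr__(self, "color", _check_rgb(self.color, "bond color"))

    def endpoints(self) -> tuple[int, int]:
        return (self.a1, self.a2)


class AnnotationShape(str, Enum):
    ARROW = "arrow"
    BRACKET = "bracket"
    ELLIPSE = "ellipse"
    CLUB = "club"
    BANANA = "banana"
    TEXT = "text"


@dataclass(frozen=True)
class Annotation:
    """A non-chemical scene element: arrows, brackets, orbital shapes, text."""

    shape: AnnotationShape
    outline: tuple[Point2, ...]
    gradient: Optional[tuple[RGB, RGB]] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", AnnotationShape(self.shape))
        object.__setattr__(self, "outline", tuple(self.outline))
        if self.shape is not AnnotationShape.TEXT and len(self.outline) == 0:
            raise DomainError(f"{self.shape.value} annotation needs a non-empty outline")
        if self.gradient is not None:
            a, b = self.gradient
            object.__setattr__(self, "gradient", (_check_rgb(a, "gradient"), _check_rgb(b, "gradient")))


@dataclass(frozen=True)
class BackgroundSpec:
    """Background raster reference. ``brightness`` 1 leaves the image unchanged;
    values > 1 wash it out (watermark effect)."""

    image_path: str
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.brightness < 0:
            raise DomainError(f"brightness must be >= 0, got {self.brightness}")


@dataclass(frozen=True)
class Drawing:
    """An immutable 2D chemical scene.

    Invariants (checked on construction): atom ids unique, atom count within
    :data:`ATOM_CAPACITY`, every bond endpoint resolves to an atom.
    """

    atoms: tuple[Atom, ...] = ()
    bonds: tuple[Bond, ...] = ()
    annotations: tuple[Annotation, ...] = ()
    background: Optional[BackgroundSpec] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(self, "bonds", tuple(self.bonds))
        object.__setattr__(self, "annotations", tuple(self.annotations))
        if len(self.atoms) > ATOM_CAPACITY:
            raise CapacityError(
                f"{len(self.atoms)} atoms exceeds the capacity of {ATOM_CAPACITY}"
            )
        ids = {a.id for a in self.atoms}
        if len(ids) != len(self.atoms):
            seen: set[int] = set()
            for a in self.atoms:
                if a.id in seen:
                    raise DuplicateIdError(f"duplicate atom id {a.id}")
                seen.add(a.id)
        for b in self.bonds:
            for end in b.endpoints():
                if end not in ids:
                    raise DanglingBondError(f"bond endpoint {end} not in drawing")

    # -- lookups ----------------------------------------------------------

    def atom_ids(self) -> set[int]:
        return {a.id for a in self.atoms}

    def atom(self, atom_id: int) -> Atom:
        for a in self.atoms:
            if a.id == atom_id:
                return a
        raise KeyError(f"no atom with id {atom_id}")

    def next_id(self) -> int:
        return max((a.id for a in self.atoms), default=-1) + 1

    def degree(self, atom_id: int) -> int:
        return sum(1 for b in self.bonds if atom_id in b.endpoints())

    def neighbors(self, atom_id: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a1 == atom_id:
                out.append(b.a2)
            elif b.a2 == atom_id:
                out.append(b.a1)
        return out

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over atoms and annotation outlines."""
        pts = [a.position for a in self.atoms]
        for ann in self.annotations:
            pts.extend(ann.outline)
        if not pts:
            raise EmptyDrawingError("bounding box of an empty drawing")
        xs = [p.x for p in pts]
        ys = [p.y for p in pts]
        return (min(xs), min(ys), max(xs), max(ys))


# -- operations -----------------------------------------------------------


def add_atom(drawing: Drawing, atom: Atom) -> Drawing:
    """Return a new drawing with ``atom`` appended.

    Raises :class:`CapacityError` past 100000 atoms and
    :class:`DuplicateIdError` on an id clash.
    """
    if len(drawing.atoms) + 1 > ATOM_CAPACITY:
        raise CapacityError(f"adding atom would exceed capacity {ATOM_CAPACITY}")
    if atom.id in drawing.atom_ids():
        raise DuplicateIdError(f"atom id {atom.id} already in drawing")
    return replace(drawing, atoms=drawing.atoms + (atom,))


def add_atoms(drawing: Drawing, atoms: Iterable[Atom]) -> Drawing:
    """Bulk append; one capacity/uniqueness check for the whole batch."""
    new = tuple(atoms)
    if len(drawing.atoms) + len(new) > ATOM_CAPACITY:
        raise CapacityError(
            f"{len(drawing.atoms)} + {len(new)} atoms exceeds capacity {ATOM_CAPACITY}"
        )
    clash = drawing.atom_ids() & {a.id for a in new}
    if clash:
        raise DuplicateIdError(f"atom ids already in drawing: {sorted(clash)[:5]}")
    return replace(drawing, atoms=drawing.atoms + new)


def add_bond(drawing: Drawing, bond: Bond) -> Drawing:
    """Return a new drawing with ``bond`` appended (endpoints must exist)."""
    ids = drawing.atom_ids()
    for end in bond.endpoints():
        if end not in ids:
            raise DanglingBondError(f"bond endpoint {end} not in drawing")
    return replace(drawing, bonds=drawing.bonds + (bond,))


def leftmost_atom(drawing: Drawing) -> int:
    """Id of the atom with the smallest x-coordinate (the coupling atom).

    Ties are broken by smallest y, then lowest id, so the result is a total
    order and deterministic.
    """
    if not drawing.atoms:
        raise EmptyDrawingError("leftmost_atom of an empty drawing")
    best = min(drawing.atoms, key=lambda a: (a.position.x, a.position.y, a.id))
    return best.id


def translate(drawing: Drawing, delta: Point2) -> Drawing:
    """Shift every atom and annotation point by ``delta``; topology unchanged."""
    atoms = tuple(a.moved_to(a.position + delta) for a in drawing.atoms)
    annotations = tuple(
        replace(ann, outline=tuple(p + delta for p in ann.outline))
        for ann in drawing.annotations
    )
    return replace(drawing, atoms=atoms, annotations=annotations)
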