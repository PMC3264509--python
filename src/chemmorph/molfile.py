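"""MDL MOL V2000 connection-table reader/writer and insert/attach operations.

The V2000 format is a fixed-column text layout: three header lines, a counts
line tagged ``V2000``, an atom block (``x y z symbol`` at 10.4 fixed width),
a bond block (``a1 a2 type stereo``), optional property lines and a final
``M  END``. Only 2D content is kept: z coordinates are read and discarded and
written back as ``0.0000``.

Charges are written as modern ``M  CHG`` property lines; the legacy
charge column in the atom block is also understood on read. Isotope mass
numbers travel in ``M  ISO`` lines.

The V2000 record format only defines 3-digit atom/bond counts (999 each).
Export deliberately does not enforce that limit — callers get the file plus a
:class:`~chemmorph.errors.CompatibilityWarning` per breached limit and decide
for themselves whether the file must interoperate with stricter readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import (
    CapacityError,
    CompatibilityWarning,
    EmptyDrawingError,
    FormatError,
    UnsupportedVersionError,
)
from .model import (
    ATOM_CAPACITY,
    Atom,
    Bond,
    BondKind,
    Drawing,
    Point2,
    add_bond,
    leftmost_atom,
    translate,
)

#: Largest atom/bond count representable in a V2000 counts line.
V2000_LIMIT = 999

#: Bond length used when attaching a guest structure to a host atom.
ATTACH_BOND_LENGTH = 1.5

# V2000 bond-type codes <-> drawing bond kinds. Wedge/hash are type 1 bonds
# with stereo flags 1/6.
_BOND_TYPE_TO_KIND = {1: BondKind.SINGLE, 2: BondKind.DOUBLE, 3: BondKind.TRIPLE, 4: BondKind.AROMATIC}
_KIND_TO_TYPE_STEREO = {
    BondKind.SINGLE: (1, 0),
    BondKind.DOUBLE: (2, 0),
    BondKind.TRIPLE: (3, 0),
    BondKind.AROMATIC: (4, 0),
    BondKind.WEDGE: (1, 1),
    BondKind.HASH: (1, 6),
}

# Legacy counts-field charge codes (atom block column 4): code -> charge.
_LEGACY_CHARGE = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}


@dataclass(frozen=True)
class MolfileDocument:
    """A parsed molfile: three header lines plus the drawing itself."""

    drawing: Drawing
    title: str = ""
    program_line: str = "  chemmorph        2D"
    comment: str = ""


def _int_field(line: str, start: int, end: int, what: str) -> int:
    raw = line[start:end].strip()
    try:
        return int(raw)
    except ValueError as exc:
        raise FormatError(f"non-numeric {what}: {raw!r}") from exc


def _float_field(line: str, start: int, end: int, what: str) -> float:
    raw = line[start:end].strip()
    try:
        return float(raw)
    except ValueError as exc:
        raise FormatError(f"non-numeric {what}: {raw!r}") from exc


def read_molfile(text: str) -> MolfileDocument:
    """Parse a V2000 connection table into a :class:`MolfileDocument`.

    Atom order is preserved: MOL's 1-based atom indices become drawing ids
    0..n-1. Raises :class:`FormatError` on structural problems and
    :class:`UnsupportedVersionError` on a V3000 tag.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise FormatError("molfile shorter than header + counts line")
    title, program_line, comment = lines[0], lines[1], lines[2]
    counts = lines[3]
    if "V3000" in counts:
        raise UnsupportedVersionError("V3000 connection tables are not supported")
    if "V2000" not in counts:
        raise FormatError("counts line lacks the V2000 version tag")
    n_atoms = _int_field(counts, 0, 3, "atom count")
    n_bonds = _int_field(counts, 3, 6, "bond count")
    if n_atoms < 0 or n_bonds < 0:
        raise FormatError("negative counts")

    body = lines[4:]
    if len(body) < n_atoms + n_bonds:
        raise FormatError(
            f"counts line promises {n_atoms} atoms / {n_bonds} bonds "
            f"but only {len(body)} lines follow"
        )

    atoms: list[Atom] = []
    for i in range(n_atoms):
        line = body[i]
        if len(line) < 34:
            raise FormatError(f"atom line {i + 1} too short: {line!r}")
        x = _float_field(line, 0, 10, "x coordinate")
        y = _float_field(line, 10, 20, "y coordinate")
        _float_field(line, 20, 30, "z coordinate")  # parsed, dropped (2D model)
        element = line[31:34].strip()
        if not element:
            raise FormatError(f"atom line {i + 1} has an empty element symbol")
        charge = 0
        if len(line) >= 39:
            raw = line[36:39].strip()
            if raw.isdigit():
                charge = _LEGACY_CHARGE.get(int(raw), 0)
        atoms.append(Atom(id=i, element=element, position=Point2(x, y), charge=charge))

    bonds: list[Bond] = []
    for i in range(n_bonds):
        line = body[n_atoms + i]
        a1 = _int_field(line, 0, 3, "bond atom 1")
        a2 = _int_field(line, 3, 6, "bond atom 2")
        btype = _int_field(line, 6, 9, "bond type")
        stereo = 0
        if len(line) >= 12 and line[9:12].strip():
            stereo = _int_field(line, 9, 12, "bond stereo")
        if not (1 <= a1 <= n_atoms and 1 <= a2 <= n_atoms):
            raise FormatError(f"bond line {i + 1} references atom outside 1..{n_atoms}")
        if btype == 1 and stereo == 1:
            kind = BondKind.WEDGE
        elif btype == 1 and stereo == 6:
            kind = BondKind.HASH
        elif btype in _BOND_TYPE_TO_KIND:
            kind = _BOND_TYPE_TO_KIND[btype]
        else:
            raise FormatError(f"unsupported bond type {btype}")
        bonds.append(Bond(a1=a1 - 1, a2=a2 - 1, kind=kind))

    # Property block: M  CHG / M  ISO override per-atom fields; M  END closes.
    saw_end = False
    charges: dict[int, int] = {}
    isotopes: dict[int, int] = {}
    m_chg_seen = False
    for line in body[n_atoms + n_bonds:]:
        if line.startswith("M  END"):
            saw_end = True
            break
        if line.startswith("M  CHG") or line.startswith("M  ISO"):
            target = charges if line.startswith("M  CHG") else isotopes
            if line.startswith("M  CHG"):
                m_chg_seen = True
            n = _int_field(line, 6, 9, "property count")
            for k in range(n):
                base = 9 + 8 * k
                idx = _int_field(line, base, base + 4, "property atom index")
                val = _int_field(line, base + 4, base + 8, "property value")
                if not (1 <= idx <= n_atoms):
                    raise FormatError(f"property references atom {idx} outside 1..{n_atoms}")
                target[idx - 1] = val
    if not saw_end:
        raise FormatError('molfile not terminated by "M  END"')

    if m_chg_seen:
        # Spec of the format: M  CHG supersedes all legacy charge columns.
        atoms = [replace(a, charge=0) for a in atoms]
    for idx, chg in charges.items():
        atoms[idx] = replace(atoms[idx], charge=chg)
    for idx, mass in isotopes.items():
        atoms[idx] = replace(atoms[idx], mass_number=mass)

    return MolfileDocument(
        drawing=Drawing(atoms=tuple(atoms), bonds=tuple(bonds)),
        title=title,
        program_line=program_line,
        comment=comment,
    )


def write_molfile(doc: MolfileDocument) -> tuple[str, list[CompatibilityWarning]]:
    """Serialise to V2000 text; returns ``(text, warnings)``.

    The output re-parses to an equal drawing (elements, 2D coordinates to four
    decimals, bond kinds, charges, isotopes). Counts beyond 999 atoms or 999
    bonds are still written but produce one :class:`CompatibilityWarning`
    each — compliance with stricter readers is left to the caller.
    """
    drawing = doc.drawing
    warnings: list[CompatibilityWarning] = []
    n_atoms, n_bonds = len(drawing.atoms), len(drawing.bonds)
    if n_atoms > V2000_LIMIT:
        warnings.append(
            CompatibilityWarning(
                "V2000_ATOM_LIMIT",
                f"atom count {n_atoms} exceeds the V2000 record limit of {V2000_LIMIT} atoms",
            )
        )
    if n_bonds > V2000_LIMIT:
        warnings.append(
            CompatibilityWarning(
                "V2000_BOND_LIMIT",
                f"bond count {n_bonds} exceeds the V2000 record limit of {V2000_LIMIT} bonds",
            )
        )

    # MOL indices are positional: id -> 1-based position in the atom block.
    index_of = {a.id: i + 1 for i, a in enumerate(drawing.atoms)}

    out: list[str] = [doc.title, doc.program_line, doc.comment]
    out.append(f"{n_atoms:3d}{n_bonds:3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in drawing.atoms:
        out.append(
            f"{a.position.x:10.4f}{a.position.y:10.4f}{0.0:10.4f} {a.element:<3s}"
            " 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for b in drawing.bonds:
        btype, stereo = _KIND_TO_TYPE_STEREO[b.kind]
        out.append(f"{index_of[b.a1]:3d}{index_of[b.a2]:3d}{btype:3d}{stereo:3d}  0  0  0")

    charged = [(index_of[a.id], a.charge) for a in drawing.atoms if a.charge != 0]
    for start in range(0, len(charged), 8):
        chunk = charged[start : start + 8]
        out.append("M  CHG" + f"{len(chunk):3d}" + "".join(f"{i:4d}{c:4d}" for i, c in chunk))
    isotopes = [(index_of[a.id], a.mass_number) for a in drawing.atoms if a.mass_number is not None]
    for start in range(0, len(isotopes), 8):
        chunk = isotopes[start : start + 8]
        out.append("M  ISO" + f"{len(chunk):3d}" + "".join(f"{i:4d}{m:4d}" for i, m in chunk))
    out.append("M  END")
    return "\n".join(out) + "\n", warnings


def _renumbered_guest(host: Drawing, guest: Drawing) -> tuple[list[Atom], list[Bond], dict[int, int]]:
    """Guest atoms/bonds with ids shifted to follow the host's ids."""
    base = host.next_id()
    mapping = {a.id: base + i for i, a in enumerate(guest.atoms)}
    atoms = [replace(a, id=mapping[a.id]) for a in guest.atoms]
    bonds = [replace(b, a1=mapping[b.a1], a2=mapping[b.a2]) for b in guest.bonds]
    return atoms, bonds, mapping


def insert_molfile(host: Drawing, guest: MolfileDocument, offset: Point2) -> Drawing:
    """Place the guest structure into ``host`` shifted by ``offset``.

    Pure insertion: no bond is created between host and guest.
    """
    g = translate(guest.drawing, offset)
    if len(host.atoms) + len(g.atoms) > ATOM_CAPACITY:
        raise CapacityError(
            f"{len(host.atoms)} + {len(g.atoms)} atoms exceeds capacity {ATOM_CAPACITY}"
        )
    atoms, bonds, _ = _renumbered_guest(host, g)
    return Drawing(
        atoms=host.atoms + tuple(atoms),
        bonds=host.bonds + tuple(bonds),
        annotations=host.annotations + g.annotations,
        background=host.background,
    )


def attach_molfile(host: Drawing, guest: MolfileDocument, target_atom: int) -> Drawing:
    """Couple the guest structure onto ``host`` at ``target_atom``.

    The guest's coupling atom — its atom with the smallest x-coordinate — is
    translated to sit one standard bond length (1.5 scene units) in +x of the
    target atom, and a new single bond joins target and coupling atom.
    """
    if not guest.drawing.atoms:
        raise EmptyDrawingError("cannot attach an empty guest structure")
    target = host.atom(target_atom)  # raises KeyError if absent
    coupling_id = leftmost_atom(guest.drawing)
    coupling_pos = guest.drawing.atom(coupling_id).position
    dest = Point2(target.position.x + ATTACH_BOND_LENGTH, target.position.y)
    g = translate(guest.drawing, dest - coupling_pos)
    if len(host.atoms) + len(g.atoms) > ATOM_CAPACITY:
        raise CapacityError(
            f"{len(host.atoms)} + {len(g.atoms)} atoms exceeds capacity {ATOM_CAPACITY}"
        )
    atoms, bonds, mapping = _renumbered_guest(host, g)
    combined = Drawing(
        atoms=host.atoms + tuple(atoms),
        bonds=host.bonds + tuple(bonds),
        annotations=host.annotations + g.annotations,
        background=host.background,
    )
    return add_bond(combined, Bond(a1=target_atom, a2=mapping[coupling_id], kind=BondKind.SINGLE))
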