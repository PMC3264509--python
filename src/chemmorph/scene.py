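"""JSON scene format — serialisation of :class:`~chemmorph.model.Drawing`.

The on-disk layout mirrors the data model field-for-field::

    {"format_version": 1,
     "atoms": [{"id": 0, "element": "O", "position": {"x": 0.0, "y": 0.0}, ...}],
     "bonds": [{"a1": 0, "a2": 1, "kind": "single", ...}],
     "annotations": [...],
     "background": {"image_path": "...", "brightness": 1.0} | null}

Optional atom fields (``mass_number``, ``shell``, ...) are omitted when unset
so files stay small and diffs stay readable.
"""

from __future__ import annotations

import json
from typing import Any

from .errors import FormatError
from .model import (
    Annotation,
    AnnotationShape,
    Atom,
    BackgroundSpec,
    Bond,
    BondKind,
    Drawing,
    Point2,
    ShellStyle,
)

FORMAT_VERSION = 1


def _point_to_dict(p: Point2) -> dict[str, float]:
    return {"x": p.x, "y": p.y}


def _point_from_dict(d: Any) -> Point2:
    try:
        return Point2(float(d["x"]), float(d["y"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"bad point {d!r}") from exc


def _atom_to_dict(a: Atom) -> dict[str, Any]:
    d: dict[str, Any] = {
        "id": a.id,
        "element": a.element,
        "position": _point_to_dict(a.position),
        "charge": a.charge,
        "color": list(a.color),
        "opacity": a.opacity,
    }
    if a.mass_number is not None:
        d["mass_number"] = a.mass_number
    if a.atomic_number_display is not None:
        d["atomic_number_display"] = a.atomic_number_display
    if a.shell is not None:
        d["shell"] = {
            "radii": list(a.shell.radii),
            "gradient": [list(a.shell.gradient[0]), list(a.shell.gradient[1])],
        }
    return d


def _atom_from_dict(d: Any) -> Atom:
    shell = None
    if d.get("shell") is not None:
        s = d["shell"]
        shell = ShellStyle(
            radii=tuple(float(r) for r in s["radii"]),
            gradient=(tuple(s["gradient"][0]), tuple(s["gradient"][1])),
        )
    try:
        return Atom(
            id=int(d["id"]),
            element=str(d["element"]),
            position=_point_from_dict(d["position"]),
            charge=int(d.get("charge", 0)),
            mass_number=d.get("mass_number"),
            atomic_number_display=d.get("atomic_number_display"),
            color=tuple(d.get("color", (0, 0, 0))),
            opacity=float(d.get("opacity", 1.0)),
            shell=shell,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"bad atom record: {exc}") from exc


def drawing_to_dict(drawing: Drawing) -> dict[str, Any]:
    bg = None
    if drawing.background is not None:
        bg = {
            "image_path": drawing.background.image_path,
            "brightness": drawing.background.brightness,
        }
    return {
        "format_version": FORMAT_VERSION,
        "atoms": [_atom_to_dict(a) for a in drawing.atoms],
        "bonds": [
            {
                "a1": b.a1,
                "a2": b.a2,
                "kind": b.kind.value,
                "color": list(b.color),
                "opacity": b.opacity,
            }
            for b in drawing.bonds
        ],
        "annotations": [
            {
                "shape": ann.shape.value,
                "outline": [_point_to_dict(p) for p in ann.outline],
                "gradient": None
                if ann.gradient is None
                else [list(ann.gradient[0]), list(ann.gradient[1])],
                "label": ann.label,
            }
            for ann in drawing.annotations
        ],
        "background": bg,
    }


def drawing_from_dict(data: Any) -> Drawing:
    if not isinstance(data, dict):
        raise FormatError("scene root must be a JSON object")
    version = data.get("format_version")
    if version != FORMAT_VERSION:
        raise FormatError(f"unsupported scene format_version {version!r}")
    atoms = tuple(_atom_from_dict(a) for a in data.get("atoms", []))
    try:
        bonds = tuple(
            Bond(
                a1=int(b["a1"]),
                a2=int(b["a2"]),
                kind=BondKind(b.get("kind", "single")),
                color=tuple(b.get("color", (0, 0, 0))),
                opacity=float(b.get("opacity", 1.0)),
            )
            for b in data.get("bonds", [])
        )
        annotations = tuple(
            Annotation(
                shape=AnnotationShape(a["shape"]),
                outline=tuple(_point_from_dict(p) for p in a.get("outline", [])),
                gradient=None
                if a.get("gradient") is None
                else (tuple(a["gradient"][0]), tuple(a["gradient"][1])),
                label=a.get("label"),
            )
            for a in data.get("annotations", [])
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"bad scene record: {exc}") from exc
    bg = None
    if data.get("background") is not None:
        b = data["background"]
        bg = BackgroundSpec(
            image_path=str(b["image_path"]), brightness=float(b.get("brightness", 1.0))
        )
    return Drawing(atoms=atoms, bonds=bonds, annotations=annotations, background=bg)


def dumps(drawing: Drawing, *, indent: int | None = 2) -> str:
    return json.dumps(drawing_to_dict(drawing), indent=indent, sort_keys=False)


def loads(text: str) -> Drawing:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON scene: {exc}") from exc
    return drawing_from_dict(data)
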