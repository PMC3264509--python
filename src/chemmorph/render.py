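"""Deterministic rendering of drawings to SVG, raster frames and animated GIF.

SVG emission is plain XML with a fixed attribute order and %.3f coordinate
formatting, so identical drawings yield byte-identical documents — a property
the morph pipeline relies on for reproducible output. Scene coordinates are
y-up; the renderer flips to the y-down convention of SVG/raster at the last
moment.

Depiction vocabulary: single/double/triple/aromatic bond lines, wedge and
hash stereo triangles, long-form labels (every atom) or short skeletal form
(carbons unlabelled, C-bonded hydrogens folded away, heteroatoms with an
implicit-H suffix), isotope super/subscripts, concentric gradient-filled
atomic shells, gradient annotations, and a background raster that can be
brightened into a watermark.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .errors import DomainError, EmptyDrawingError, EmptyInputError
from .model import (
    Annotation,
    AnnotationShape,
    Atom,
    Bond,
    BondKind,
    Drawing,
    Point2,
)


@dataclass(frozen=True)
class RenderStyle:
    """Visual parameters. Lengths are pixels; ``scale`` converts scene units
    to pixels. ``center`` pins the scene point mapped to the canvas centre —
    leave None to auto-centre on the drawing's bounding box (frame renderers
    set it so all frames share one camera)."""

    bond_width: float = 2.0
    double_bond_offset: float = 5.0
    font_size: float = 14.0
    formula_form: str = "long"  # "long" | "short"
    show_isotopes: bool = False
    canvas: tuple[int, int] = (400, 300)
    scale: float = 40.0
    center: Optional[tuple[float, float]] = None
    background_color: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if self.bond_width <= 0 or self.double_bond_offset <= 0 or self.font_size <= 0:
            raise DomainError("bond_width, double_bond_offset and font_size must be positive")
        if self.scale <= 0:
            raise DomainError("scale must be positive")
        w, h = self.canvas
        if w < 1 or h < 1:
            raise DomainError(f"canvas must be at least 1x1, got {self.canvas}")
        if self.formula_form not in ("long", "short"):
            raise DomainError(f"formula_form must be 'long' or 'short', got {self.formula_form!r}")


def _auto_center(drawing: Drawing) -> tuple[float, float]:
    try:
        xmin, ymin, xmax, ymax = drawing.bounding_box()
    except EmptyDrawingError:
        return (0.0, 0.0)
    return ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)


class _Camera:
    """Scene (y-up) to pixel (y-down) transform shared by SVG and raster paths."""

    def __init__(self, style: RenderStyle, drawing: Drawing) -> None:
        self.scale = style.scale
        self.w, self.h = style.canvas
        self.cx, self.cy = style.center if style.center is not None else _auto_center(drawing)

    def to_px(self, p: Point2) -> tuple[float, float]:
        return (
            self.w / 2.0 + self.scale * (p.x - self.cx),
            self.h / 2.0 - self.scale * (p.y - self.cy),
        )


def _fmt(v: float) -> str:
    return f"{v:.3f}"


def _rgb_css(c: Sequence[int]) -> str:
    return f"rgb({c[0]},{c[1]},{c[2]})"


def _visible_labels(drawing: Drawing, style: RenderStyle) -> dict[int, str]:
    """atom id -> label text, applying the long/short formula convention.

    Long form labels every atom with its element symbol. Short (skeletal)
    form hides carbon labels, folds hydrogens bonded to carbon into the
    skeleton (no label), and annotates heteroatoms with their bonded-H count
    (e.g. ``OH``, ``NH2``).
    """
    labels: dict[int, str] = {}
    if style.formula_form == "long":
        for a in drawing.atoms:
            labels[a.id] = a.element
        return labels
    for a in drawing.atoms:
        if a.element == "C":
            continue
        if a.element == "H":
            neighbors = [drawing.atom(n).element for n in drawing.neighbors(a.id)]
            if neighbors:  # bonded H folds into its heavy atom's label
                continue
            labels[a.id] = "H"
            continue
        n_h = sum(1 for n in drawing.neighbors(a.id) if drawing.atom(n).element == "H")
        if n_h == 0:
            labels[a.id] = a.element
        elif n_h == 1:
            labels[a.id] = f"{a.element}H"
        else:
            labels[a.id] = f"{a.element}H{n_h}"
    return labels


def _charge_suffix(charge: int) -> str:
    if charge == 0:
        return ""
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return sign if mag == 1 else f"{mag}{sign}"


def _bond_geometry(p1: tuple[float, float], p2: tuple[float, float]):
    dx, dy = p2[0] - p1[0], p2[1] - p1[1]
    length = math.hypot(dx, dy)
    if length < 1e-9:
        return (0.0, 0.0), (0.0, 0.0), 0.0
    return (dx / length, dy / length), (-dy / length, dx / length), length


def render_svg(drawing: Drawing, style: RenderStyle | None = None) -> str:
    """Emit the drawing as an SVG document string.

    Deterministic: fixed element order (defs, annotations, shells, bonds,
    labels), fixed attribute order, all floats formatted %.3f.
    """
    style = style or RenderStyle()
    cam = _Camera(style, drawing)
    w, h = style.canvas
    parts: list[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">',
    ]

    defs: list[str] = []
    for a in drawing.atoms:
        if a.shell is not None:
            inner, outer = a.shell.gradient
            defs.append(
                f'<radialGradient id="shellgrad-{a.id}">'
                f'<stop offset="0" stop-color="{_rgb_css(inner)}"/>'
                f'<stop offset="1" stop-color="{_rgb_css(outer)}"/>'
                "</radialGradient>"
            )
    for i, ann in enumerate(drawing.annotations):
        if ann.gradient is not None:
            g0, g1 = ann.gradient
            defs.append(
                f'<linearGradient id="anngrad-{i}">'
                f'<stop offset="0" stop-color="{_rgb_css(g0)}"/>'
                f'<stop offset="1" stop-color="{_rgb_css(g1)}"/>'
                "</linearGradient>"
            )
    if defs:
        parts.append("<defs>" + "".join(defs) + "</defs>")

    # annotations under the structure
    for i, ann in enumerate(drawing.annotations):
        pts = [cam.to_px(p) for p in ann.outline]
        if ann.shape is AnnotationShape.TEXT:
            x, y = pts[0] if pts else (cam.w / 2.0, cam.h / 2.0)
            label = ann.label or ""
            parts.append(
                f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="{_fmt(style.font_size)}" '
                f'fill="rgb(0,0,0)">{label}</text>'
            )
            continue
        fill = f"url(#anngrad-{i})" if ann.gradient is not None else "none"
        points = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)
        closed = ann.shape in (AnnotationShape.ELLIPSE, AnnotationShape.CLUB, AnnotationShape.BANANA)
        tag = "polygon" if closed else "polyline"
        parts.append(
            f'<{tag} points="{points}" fill="{fill}" stroke="rgb(0,0,0)" '
            f'stroke-width="{_fmt(style.bond_width)}"/>'
        )

    # atomic shells, outermost circle first so inner rings stay visible
    for a in drawing.atoms:
        if a.shell is None:
            continue
        x, y = cam.to_px(a.position)
        for r in reversed(a.shell.radii):
            parts.append(
                f'<circle cx="{_fmt(x)}" cy="{_fmt(y)}" r="{_fmt(r * style.scale)}" '
                f'fill="url(#shellgrad-{a.id})" stroke="{_rgb_css(a.color)}" '
                f'stroke-width="1.000" opacity="{_fmt(a.opacity)}"/>'
            )

    positions = {a.id: a.position for a in drawing.atoms}
    for b in drawing.bonds:
        p1 = cam.to_px(positions[b.a1])
        p2 = cam.to_px(positions[b.a2])
        (ux, uy), (nx, ny), length = _bond_geometry(p1, p2)
        color = _rgb_css(b.color)
        common = (
            f'stroke="{color}" stroke-width="{_fmt(style.bond_width)}" '
            f'opacity="{_fmt(b.opacity)}"'
        )

        def line(q1, q2, extra: str = "") -> str:
            return (
                f'<line x1="{_fmt(q1[0])}" y1="{_fmt(q1[1])}" '
                f'x2="{_fmt(q2[0])}" y2="{_fmt(q2[1])}" {common}{extra}/>'
            )

        def offset_pts(d: float):
            return (p1[0] + nx * d, p1[1] + ny * d), (p2[0] + nx * d, p2[1] + ny * d)

        if b.kind is BondKind.SINGLE:
            parts.append(line(p1, p2))
        elif b.kind is BondKind.DOUBLE:
            d = style.double_bond_offset / 2.0
            parts.append(line(*offset_pts(-d)))
            parts.append(line(*offset_pts(d)))
        elif b.kind is BondKind.TRIPLE:
            d = style.double_bond_offset
            parts.append(line(p1, p2))
            parts.append(line(*offset_pts(-d)))
            parts.append(line(*offset_pts(d)))
        elif b.kind is BondKind.AROMATIC:
            parts.append(line(p1, p2))
            q1, q2 = offset_pts(style.double_bond_offset)
            parts.append(line(q1, q2, ' stroke-dasharray="4 3"'))
        elif b.kind is BondKind.WEDGE:
            half = style.double_bond_offset
            tri = (
                p1,
                (p2[0] + nx * half, p2[1] + ny * half),
                (p2[0] - nx * half, p2[1] - ny * half),
            )
            points = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in tri)
            parts.append(
                f'<polygon points="{points}" fill="{color}" stroke="none" '
                f'opacity="{_fmt(b.opacity)}"/>'
            )
        elif b.kind is BondKind.HASH:
            n_ticks = 6
            for k in range(1, n_ticks + 1):
                f = k / float(n_ticks)
                cx_, cy_ = p1[0] + ux * length * f, p1[1] + uy * length * f
                half = style.double_bond_offset * f
                parts.append(
                    line((cx_ - nx * half, cy_ - ny * half), (cx_ + nx * half, cy_ + ny * half))
                )

    labels = _visible_labels(drawing, style)
    for a in drawing.atoms:
        label = labels.get(a.id)
        if label is None:
            continue
        x, y = cam.to_px(a.position)
        tspans = ""
        if style.show_isotopes and (a.mass_number is not None or a.atomic_number_display is not None):
            small = _fmt(style.font_size * 0.6)
            if a.mass_number is not None:
                tspans += f'<tspan font-size="{small}" baseline-shift="super">{a.mass_number}</tspan>'
            if a.atomic_number_display is not None:
                tspans += (
                    f'<tspan font-size="{small}" baseline-shift="sub">{a.atomic_number_display}</tspan>'
                )
        text = f"{tspans}{label}{_charge_suffix(a.charge)}"
        parts.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="{_fmt(style.font_size)}" '
            f'text-anchor="middle" dominant-baseline="central" fill="{_rgb_css(a.color)}" '
            f'opacity="{_fmt(a.opacity)}">{text}</text>'
        )

    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def apply_brightness(image: Image.Image, factor: float) -> Image.Image:
    """Scale every colour channel by ``factor`` with clamping to 0..255.

    Factor 1 is the identity; factors > 1 wash the image toward white, which
    is how a background photograph becomes a watermark. Alpha is untouched.
    """
    if factor < 0:
        raise DomainError(f"brightness factor must be >= 0, got {factor}")
    arr = np.asarray(image.convert("RGBA") if image.mode not in ("RGB", "RGBA") else image)
    arr = arr.astype(np.float64)
    rgb = arr[..., :3]
    out = arr.copy()
    out[..., :3] = np.clip(np.floor(rgb * factor + 0.5), 0, 255)
    return Image.fromarray(out.astype(np.uint8), mode="RGBA" if arr.shape[-1] == 4 else "RGB")


def _rasterize(drawing: Drawing, style: RenderStyle) -> Image.Image:
    cam = _Camera(style, drawing)
    w, h = style.canvas
    base = Image.new("RGB", (w, h), style.background_color)

    if drawing.background is not None:
        try:
            bg = Image.open(drawing.background.image_path).convert("RGB")
        except OSError:
            bg = None
        if bg is not None:
            bg = bg.resize((w, h))
            bg = apply_brightness(bg, drawing.background.brightness)
            base.paste(bg.convert("RGB"), (0, 0))

    overlay = Image.new("RGBA", (w, h), (0, 0, 0, 0))
    draw = ImageDraw.Draw(overlay)

    def ink(color, opacity: float):
        return (color[0], color[1], color[2], int(round(255 * opacity)))

    for ann in drawing.annotations:
        pts = [cam.to_px(p) for p in ann.outline]
        if ann.shape is AnnotationShape.TEXT:
            if pts:
                draw.text(pts[0], ann.label or "", fill=(0, 0, 0, 255))
            continue
        if len(pts) >= 2:
            fill = ink(ann.gradient[0], 1.0) if ann.gradient is not None else None
            if fill is not None and len(pts) >= 3:
                draw.polygon(pts, fill=fill, outline=(0, 0, 0, 255))
            else:
                draw.line(pts, fill=(0, 0, 0, 255), width=max(1, int(style.bond_width)))

    for a in drawing.atoms:
        if a.shell is None:
            continue
        x, y = cam.to_px(a.position)
        for r in reversed(a.shell.radii):
            rp = r * style.scale
            draw.ellipse(
                [x - rp, y - rp, x + rp, y + rp],
                outline=ink(a.color, a.opacity),
                width=1,
            )

    positions = {a.id: a.position for a in drawing.atoms}
    width_px = max(1, int(round(style.bond_width)))
    for b in drawing.bonds:
        p1, p2 = cam.to_px(positions[b.a1]), cam.to_px(positions[b.a2])
        (ux, uy), (nx, ny), length = _bond_geometry(p1, p2)
        color = ink(b.color, b.opacity)

        def off(d):
            return [(p1[0] + nx * d, p1[1] + ny * d), (p2[0] + nx * d, p2[1] + ny * d)]

        if b.kind is BondKind.DOUBLE:
            d = style.double_bond_offset / 2.0
            draw.line(off(-d), fill=color, width=width_px)
            draw.line(off(d), fill=color, width=width_px)
        elif b.kind is BondKind.TRIPLE:
            draw.line([p1, p2], fill=color, width=width_px)
            draw.line(off(-style.double_bond_offset), fill=color, width=width_px)
            draw.line(off(style.double_bond_offset), fill=color, width=width_px)
        elif b.kind is BondKind.WEDGE:
            half = style.double_bond_offset
            draw.polygon(
                [p1, (p2[0] + nx * half, p2[1] + ny * half), (p2[0] - nx * half, p2[1] - ny * half)],
                fill=color,
            )
        elif b.kind is BondKind.HASH:
            for k in range(1, 7):
                f = k / 6.0
                cx_, cy_ = p1[0] + ux * length * f, p1[1] + uy * length * f
                half = style.double_bond_offset * f
                draw.line(
                    [(cx_ - nx * half, cy_ - ny * half), (cx_ + nx * half, cy_ + ny * half)],
                    fill=color,
                    width=width_px,
                )
        else:  # single / aromatic main line
            draw.line([p1, p2], fill=color, width=width_px)
            if b.kind is BondKind.AROMATIC:
                draw.line(off(style.double_bond_offset), fill=color, width=width_px)

    labels = _visible_labels(drawing, style)
    for a in drawing.atoms:
        label = labels.get(a.id)
        if label is None:
            continue
        x, y = cam.to_px(a.position)
        text = label + _charge_suffix(a.charge)
        if style.show_isotopes and a.mass_number is not None:
            text = f"{a.mass_number}{text}"
        draw.text((x, y), text, fill=ink(a.color, a.opacity), anchor="mm")

    return Image.alpha_composite(base.convert("RGBA"), overlay).convert("RGB")


def render_frames(frames: Sequence[Drawing], style: RenderStyle | None = None) -> list[Image.Image]:
    """Rasterise morph frames with one shared camera so they align.

    The camera centre is the centre of the union of all frames' bounding
    boxes unless the style pins one explicitly.
    """
    if not frames:
        raise EmptyInputError("render_frames needs at least one frame")
    style = style or RenderStyle()
    if style.center is None:
        boxes = []
        for f in frames:
            try:
                boxes.append(f.bounding_box())
            except EmptyDrawingError:
                pass
        if boxes:
            xmin = min(b[0] for b in boxes)
            ymin = min(b[1] for b in boxes)
            xmax = max(b[2] for b in boxes)
            ymax = max(b[3] for b in boxes)
            style = RenderStyle(
                **{**style.__dict__, "center": ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)}
            )
    return [_rasterize(f, style) for f in frames]


def export_gif(rasters: Sequence[Image.Image], delay_ms: int = 100, loop: bool = True) -> bytes:
    """Encode rasters as an animated GIF byte stream.

    ``delay_ms`` is the per-frame delay (>= 10 ms, the GIF timing
    resolution); ``loop=True`` sets infinite repeat.
    """
    if not rasters:
        raise EmptyInputError("export_gif needs at least one raster")
    if delay_ms < 10:
        raise DomainError(f"GIF frame delay must be >= 10 ms, got {delay_ms}")
    buf = io.BytesIO()
    first, rest = rasters[0], list(rasters[1:])
    kwargs = dict(
        format="GIF",
        save_all=True,
        append_images=rest,
        duration=delay_ms,
        disposal=2,
    )
    if loop:
        kwargs["loop"] = 0
    first.save(buf, **kwargs)
    return buf.getvalue()
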