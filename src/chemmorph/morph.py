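"""Stepwise morphing between two chemical drawings.

Morphing brings a source and a target drawing together: paired atoms and
bonds travel along straight lines while their colours blend, and elements
present in only one drawing cross-dissolve — the vanishing element fades out
with opacity 1-t as its counterpart fades in with opacity t. Only the bond
and atom areas of the structures are put into correspondence; annotation
outlines and the background can additionally be warped through piecewise
affine (triangular sections) or projective (square areas) region maps.

The frame parameter grid is t_k = k/(n_frames-1): frame 0 reproduces the
source exactly and the last frame the target. Steps chain into sequences
(step i's target is step i+1's source), which is how reaction mechanisms —
e.g. the two-step SN2 animation — are built. Vibration presets (symmetric /
asymmetric stretch, scissoring) displace a bent triatomic's geometry and
return a there-and-back sequence so the animation oscillates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from .errors import (
    ChainError,
    CorrespondenceError,
    DomainError,
    TopologyError,
)
from .mapping import RegionMesh, cell_map, locate_cell, tessellate_region
from .model import (
    Annotation,
    Atom,
    BackgroundSpec,
    Bond,
    Drawing,
    Point2,
)

_JUNCTION_TOL = 1e-9


class MappingMode(str, Enum):
    """How non-structural content is carried between frames.

    ``pointwise`` interpolates coordinates directly; ``triangles`` and
    ``squares`` warp annotation outlines/background through per-cell
    affine or projective maps over the drawings' bounding boxes.
    """

    POINTWISE = "pointwise"
    TRIANGLES = "triangles"
    SQUARES = "squares"


class Easing(str, Enum):
    LINEAR = "linear"
    PING_PONG = "ping_pong"


class FadeMode(str, Enum):
    """Unmatched elements either fade in place or shrink toward the drawing
    centroid while fading ("reduces in dimensions")."""

    FADE = "fade"
    SHRINK = "shrink"


@dataclass(frozen=True)
class Correspondence:
    """Pairing of source/target atoms (by id) and bonds (by index),
    plus the unmatched leftovers on each side."""

    atom_pairs: tuple[tuple[int, int], ...] = ()
    bond_pairs: tuple[tuple[int, int], ...] = ()
    unmatched_source_atoms: tuple[int, ...] = ()
    unmatched_target_atoms: tuple[int, ...] = ()
    unmatched_source_bonds: tuple[int, ...] = ()
    unmatched_target_bonds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "atom_pairs",
            "bond_pairs",
            "unmatched_source_atoms",
            "unmatched_target_atoms",
            "unmatched_source_bonds",
            "unmatched_target_bonds",
        ):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        src_atoms = [p[0] for p in self.atom_pairs] + list(self.unmatched_source_atoms)
        tgt_atoms = [p[1] for p in self.atom_pairs] + list(self.unmatched_target_atoms)
        if len(src_atoms) != len(set(src_atoms)) or len(tgt_atoms) != len(set(tgt_atoms)):
            raise CorrespondenceError("an atom id appears twice in the correspondence")
        src_bonds = [p[0] for p in self.bond_pairs] + list(self.unmatched_source_bonds)
        tgt_bonds = [p[1] for p in self.bond_pairs] + list(self.unmatched_target_bonds)
        if len(src_bonds) != len(set(src_bonds)) or len(tgt_bonds) != len(set(tgt_bonds)):
            raise CorrespondenceError("a bond index appears twice in the correspondence")

    def target_of(self, source_atom: int) -> Optional[int]:
        for s, t in self.atom_pairs:
            if s == source_atom:
                return t
        return None


def identity_correspondence(drawing: Drawing) -> Correspondence:
    """Pair every atom and bond of a drawing with itself (for presets where
    source and target share ids)."""
    return Correspondence(
        atom_pairs=tuple((a.id, a.id) for a in drawing.atoms),
        bond_pairs=tuple((i, i) for i in range(len(drawing.bonds))),
    )


def auto_correspond(source: Drawing, target: Drawing) -> Correspondence:
    """Deterministic automatic pairing of the two drawings' atom/bond areas.

    Atoms are grouped by element symbol; within each element, source and
    target atoms are paired greedily by smallest Euclidean distance (ties by
    lowest source id, then lowest target id). Leftover atoms on either side
    go to the unmatched lists. A bond is paired when both its endpoint atoms
    are paired; among candidate target bonds one of the same kind is
    preferred, otherwise a sole candidate of any kind is accepted.
    """
    by_element_src: dict[str, list[Atom]] = {}
    by_element_tgt: dict[str, list[Atom]] = {}
    for a in source.atoms:
        by_element_src.setdefault(a.element, []).append(a)
    for a in target.atoms:
        by_element_tgt.setdefault(a.element, []).append(a)

    atom_pairs: list[tuple[int, int]] = []
    unmatched_src: list[int] = []
    unmatched_tgt: list[int] = []
    for element in sorted(set(by_element_src) | set(by_element_tgt)):
        srcs = by_element_src.get(element, [])
        tgts = by_element_tgt.get(element, [])
        candidates = sorted(
            ((s.position.distance_to(t.position), s.id, t.id) for s in srcs for t in tgts),
        )
        used_s: set[int] = set()
        used_t: set[int] = set()
        for _, sid, tid in candidates:
            if sid in used_s or tid in used_t:
                continue
            atom_pairs.append((sid, tid))
            used_s.add(sid)
            used_t.add(tid)
        unmatched_src.extend(s.id for s in srcs if s.id not in used_s)
        unmatched_tgt.extend(t.id for t in tgts if t.id not in used_t)
    atom_pairs.sort()
    paired_t_of_s = dict(atom_pairs)

    bond_pairs: list[tuple[int, int]] = []
    used_target_bonds: set[int] = set()
    unmatched_src_bonds: list[int] = []
    for i, sb in enumerate(source.bonds):
        t1 = paired_t_of_s.get(sb.a1)
        t2 = paired_t_of_s.get(sb.a2)
        candidates_idx = []
        if t1 is not None and t2 is not None:
            want = {t1, t2}
            candidates_idx = [
                j
                for j, tb in enumerate(target.bonds)
                if j not in used_target_bonds and set(tb.endpoints()) == want
            ]
        same_kind = [j for j in candidates_idx if target.bonds[j].kind == sb.kind]
        if same_kind:
            j = same_kind[0]
        elif len(candidates_idx) == 1:
            j = candidates_idx[0]
        else:
            unmatched_src_bonds.append(i)
            continue
        bond_pairs.append((i, j))
        used_target_bonds.add(j)
    unmatched_tgt_bonds = [j for j in range(len(target.bonds)) if j not in used_target_bonds]

    return Correspondence(
        atom_pairs=tuple(atom_pairs),
        bond_pairs=tuple(bond_pairs),
        unmatched_source_atoms=tuple(sorted(unmatched_src)),
        unmatched_target_atoms=tuple(sorted(unmatched_tgt)),
        unmatched_source_bonds=tuple(unmatched_src_bonds),
        unmatched_target_bonds=tuple(unmatched_tgt_bonds),
    )


def _lerp(a: float, b: float, t: float) -> float:
    return (1.0 - t) * a + t * b


def _lerp_channel(c0: int, c1: int, t: float) -> int:
    # round-half-up keeps channel blending monotone in t
    return int(math.floor(_lerp(float(c0), float(c1), t) + 0.5))


def _lerp_rgb(c0, c1, t: float):
    return tuple(_lerp_channel(a, b, t) for a, b in zip(c0, c1))


def interpolate_atom(a0: Atom, a1: Atom, t: float) -> Atom:
    """Blend two paired atoms at parameter ``t`` in [0, 1].

    Position and opacity interpolate linearly; RGB channels interpolate and
    round; discrete fields (element, charge, isotope labels, shell) switch
    from the source to the target at t = 0.5, since text cannot blend.
    The endpoints are exact: t=0 returns ``a0``, t=1 returns ``a1``.
    """
    if not (0.0 <= t <= 1.0):
        raise DomainError(f"interpolation parameter {t} outside [0, 1]")
    if t == 0.0:
        return a0
    if t == 1.0:
        return a1
    discrete = a0 if t < 0.5 else a1
    return Atom(
        id=a0.id,
        element=discrete.element,
        position=Point2(
            _lerp(a0.position.x, a1.position.x, t), _lerp(a0.position.y, a1.position.y, t)
        ),
        charge=discrete.charge,
        mass_number=discrete.mass_number,
        atomic_number_display=discrete.atomic_number_display,
        color=_lerp_rgb(a0.color, a1.color, t),
        opacity=_lerp(a0.opacity, a1.opacity, t),
        shell=discrete.shell,
    )


def interpolate_bond(b0: Bond, b1: Bond, t: float, a1: int, a2: int) -> Bond:
    """Blend paired bonds: colour/opacity interpolate, kind switches at 0.5.
    Endpoints are the frame ids the caller resolved."""
    kind = b0.kind if t < 0.5 else b1.kind
    return Bond(a1=a1, a2=a2, kind=kind, color=_lerp_rgb(b0.color, b1.color, t), opacity=_lerp(b0.opacity, b1.opacity, t))


@dataclass(frozen=True)
class MorphStep:
    """A parameterised transition from ``source`` to ``target``.

    ``n_frames >= 2`` frames at t_k = k/(n_frames-1). If ``correspondence``
    is None it is computed by :func:`auto_correspond`.
    """

    source: Drawing
    target: Drawing
    correspondence: Optional[Correspondence] = None
    n_frames: int = 9
    mapping_mode: MappingMode = MappingMode.POINTWISE
    easing: Easing = Easing.LINEAR
    fade_mode: FadeMode = FadeMode.FADE
    mesh_resolution: int = 4

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise DomainError(f"n_frames must be >= 2, got {self.n_frames}")
        object.__setattr__(self, "mapping_mode", MappingMode(self.mapping_mode))
        object.__setattr__(self, "easing", Easing(self.easing))
        object.__setattr__(self, "fade_mode", FadeMode(self.fade_mode))

    def resolved_correspondence(self) -> Correspondence:
        if self.correspondence is not None:
            return self.correspondence
        return auto_correspond(self.source, self.target)


@dataclass(frozen=True)
class MorphSequence:
    """An ordered chain of morph steps; consecutive steps must share their
    junction drawing."""

    steps: tuple[MorphStep, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        if not self.steps:
            raise DomainError("a morph sequence needs at least one step")


def _validate_correspondence(step: MorphStep, corr: Correspondence) -> None:
    src_ids = step.source.atom_ids()
    tgt_ids = step.target.atom_ids()
    for s, t in corr.atom_pairs:
        if s not in src_ids or t not in tgt_ids:
            raise CorrespondenceError(f"atom pair ({s}, {t}) references an absent atom")
    for s in corr.unmatched_source_atoms:
        if s not in src_ids:
            raise CorrespondenceError(f"unmatched source atom {s} absent from source")
    for t in corr.unmatched_target_atoms:
        if t not in tgt_ids:
            raise CorrespondenceError(f"unmatched target atom {t} absent from target")
    ns, nt = len(step.source.bonds), len(step.target.bonds)
    for i, j in corr.bond_pairs:
        if not (0 <= i < ns and 0 <= j < nt):
            raise CorrespondenceError(f"bond pair ({i}, {j}) out of range")
    paired = dict(corr.atom_pairs)
    for i, j in corr.bond_pairs:
        sb, tb = step.source.bonds[i], step.target.bonds[j]
        if {paired.get(sb.a1), paired.get(sb.a2)} != set(tb.endpoints()):
            raise CorrespondenceError(
                f"bond pair ({i}, {j}) lacks matching endpoint atom pairs"
            )


def _eased_t(step: MorphStep, k: int) -> float:
    u = k / (step.n_frames - 1)
    if step.easing is Easing.PING_PONG:
        return 1.0 - abs(2.0 * u - 1.0)
    return u


def _shrink_outline(outline: tuple[Point2, ...], factor: float) -> tuple[Point2, ...]:
    if not outline:
        return outline
    cx = sum(p.x for p in outline) / len(outline)
    cy = sum(p.y for p in outline) / len(outline)
    return tuple(Point2(cx + (p.x - cx) * factor, cy + (p.y - cy) * factor) for p in outline)


class _RegionWarp:
    """Piecewise warp of the scene rectangle: source cells -> cells
    interpolated between the source and target tessellations."""

    def __init__(self, src_bbox, dst_bbox, mode: MappingMode, n: int) -> None:
        self.mode = "triangles" if mode is MappingMode.TRIANGLES else "squares"
        self.n = n
        self.src_bbox = src_bbox
        self.dst_bbox = dst_bbox
        self.src_mesh = tessellate_region(src_bbox, self.mode, n)
        self.dst_mesh = tessellate_region(dst_bbox, self.mode, n)

    def at(self, t: float) -> "_FrameWarp":
        verts = tuple(
            Point2(_lerp(s.x, d.x, t), _lerp(s.y, d.y, t))
            for s, d in zip(self.src_mesh.vertices, self.dst_mesh.vertices)
        )
        mid_mesh = RegionMesh(vertices=verts, cells=self.src_mesh.cells)
        return _FrameWarp(self, mid_mesh)


class _FrameWarp:
    def __init__(self, warp: _RegionWarp, mid_mesh: RegionMesh) -> None:
        self._warp = warp
        self._mid = mid_mesh
        self._maps: dict[int, object] = {}

    def apply(self, p: Point2) -> Point2:
        idx = locate_cell(self._warp.src_bbox, self._warp.mode, self._warp.n, p)
        m = self._maps.get(idx)
        if m is None:
            m = cell_map(self._warp.src_mesh, self._mid, idx)
            self._maps[idx] = m
        return m.apply(p)


def _warp_or_lerp_annotations(
    step: MorphStep, t: float, warp: Optional[_FrameWarp], warp_rev: Optional[_FrameWarp]
) -> tuple[Annotation, ...]:
    src_anns, tgt_anns = step.source.annotations, step.target.annotations
    paired = (
        len(src_anns) == len(tgt_anns)
        and all(
            a.shape == b.shape and len(a.outline) == len(b.outline)
            for a, b in zip(src_anns, tgt_anns)
        )
    )
    if paired:
        out = []
        for a, b in zip(src_anns, tgt_anns):
            outline = tuple(
                Point2(_lerp(p.x, q.x, t), _lerp(p.y, q.y, t))
                for p, q in zip(a.outline, b.outline)
            )
            disc = a if t < 0.5 else b
            out.append(replace(disc, outline=outline))
        return tuple(out)
    # Unpaired: warp (or carry) the side that is currently shown. Endpoints
    # are returned verbatim so frame 0 / frame N-1 match source/target exactly.
    if t == 0.0:
        return src_anns
    if t == 1.0:
        return tgt_anns
    if t < 0.5:
        anns, w, fade = src_anns, warp, 1.0 - t
    else:
        anns, w, fade = tgt_anns, warp_rev, t
    out = []
    for a in anns:
        outline = a.outline
        if w is not None:
            outline = tuple(w.apply(p) for p in outline)
        if step.fade_mode is FadeMode.SHRINK:
            outline = _shrink_outline(outline, fade)
        out.append(replace(a, outline=outline))
    return tuple(out)


def _interp_background(
    src: Optional[BackgroundSpec], tgt: Optional[BackgroundSpec], t: float
) -> Optional[BackgroundSpec]:
    if src is None and tgt is None:
        return None
    if src is not None and tgt is not None:
        return BackgroundSpec(
            image_path=src.image_path if t < 0.5 else tgt.image_path,
            brightness=_lerp(src.brightness, tgt.brightness, t),
        )
    return src if t < 0.5 else tgt


def make_frames(step: MorphStep) -> list[Drawing]:
    """Render a morph step into its ``n_frames`` intermediate drawings.

    Paired atoms/bonds interpolate; unmatched source content fades out with
    opacity (1-t) (or shrinks, per ``fade_mode``) while unmatched target
    content fades in with opacity t. Elements whose opacity reaches exactly 0
    are dropped from the frame, so with linear easing frame 0 equals the
    source and the last frame equals the target exactly. Unmatched target
    atoms are renumbered past the source ids so frame ids never clash.
    """
    corr = step.resolved_correspondence()
    _validate_correspondence(step, corr)
    source, target = step.source, step.target

    paired_t_of_s = dict(corr.atom_pairs)
    offset = max((a.id for a in source.atoms), default=-1) + 1
    # id an atom carries inside a frame: source ids stay; unmatched target
    # atoms are shifted past them.
    frame_id_of_target = {t: s for s, t in corr.atom_pairs}
    for t_id in corr.unmatched_target_atoms:
        frame_id_of_target[t_id] = offset + t_id

    if step.mapping_mode is not MappingMode.POINTWISE:
        need_warp = any(
            len(a.outline) > 0 for a in source.annotations + target.annotations
        )
        if need_warp and source.atoms and target.atoms:
            src_bbox = _padded(source.bounding_box())
            tgt_bbox = _padded(target.bounding_box())
            mode, n = step.mapping_mode, step.mesh_resolution
            fwd = _RegionWarp(src_bbox, tgt_bbox, mode, n)
            rev = _RegionWarp(tgt_bbox, src_bbox, mode, n)
            warp_builder, warp_rev_builder = fwd, rev
        else:
            warp_builder = warp_rev_builder = None
    else:
        warp_builder = warp_rev_builder = None

    frames: list[Drawing] = []
    for k in range(step.n_frames):
        t = _eased_t(step, k)
        fw = warp_builder.at(t) if warp_builder is not None else None
        fw_rev = warp_rev_builder.at(1.0 - t) if warp_rev_builder is not None else None

        atoms: list[Atom] = []
        for a in source.atoms:
            partner = paired_t_of_s.get(a.id)
            if partner is not None:
                atoms.append(interpolate_atom(a, target.atom(partner), t))
            else:
                fade = a.opacity * (1.0 - t)
                atoms.append(replace(a, opacity=fade))
        for t_id in corr.unmatched_target_atoms:
            a = target.atom(t_id)
            atoms.append(replace(a, id=frame_id_of_target[t_id], opacity=a.opacity * t))

        bonds: list[Bond] = []
        paired_tb_of_sb = dict(corr.bond_pairs)
        for i, sb in enumerate(source.bonds):
            j = paired_tb_of_sb.get(i)
            if j is not None:
                bonds.append(interpolate_bond(sb, target.bonds[j], t, sb.a1, sb.a2))
            else:
                bonds.append(replace(sb, opacity=sb.opacity * (1.0 - t)))
        for j in corr.unmatched_target_bonds:
            tb = target.bonds[j]
            bonds.append(
                Bond(
                    a1=frame_id_of_target[tb.a1],
                    a2=frame_id_of_target[tb.a2],
                    kind=tb.kind,
                    color=tb.color,
                    opacity=tb.opacity * t,
                )
            )

        # Fully transparent content is dropped: frames then equal the source
        # at t=0 and the target at t=1 structurally, not just visually.
        bonds = [b for b in bonds if b.opacity > 0.0]
        referenced = {e for b in bonds for e in b.endpoints()}
        atoms = [a for a in atoms if a.opacity > 0.0 or a.id in referenced]

        annotations = _warp_or_lerp_annotations(step, t, fw, fw_rev)
        background = _interp_background(source.background, target.background, t)
        frames.append(
            Drawing(
                atoms=tuple(atoms),
                bonds=tuple(bonds),
                annotations=annotations,
                background=background,
            )
        )
    return frames


def _padded(bbox, pad: float = 0.5):
    xmin, ymin, xmax, ymax = bbox
    if xmax - xmin < 1e-9:
        xmax += 1.0
        xmin -= 1.0
    if ymax - ymin < 1e-9:
        ymax += 1.0
        ymin -= 1.0
    return (xmin - pad, ymin - pad, xmax + pad, ymax + pad)


def _junction_matches(a: Drawing, b: Drawing) -> bool:
    if len(a.atoms) != len(b.atoms):
        return False
    bs = {atom.id: atom for atom in b.atoms}
    for atom in a.atoms:
        other = bs.get(atom.id)
        if other is None or atom.element != other.element:
            return False
        if atom.position.distance_to(other.position) > _JUNCTION_TOL:
            return False
    return True


def run_sequence(seq: MorphSequence) -> list[Drawing]:
    """Concatenate the frames of all steps, dropping duplicate junction frames.

    Total frame count is sum(n_frames) - (len(steps) - 1). Raises
    :class:`ChainError` when a step's target does not match the next step's
    source (atom ids/elements/positions within 1e-9).
    """
    for i in range(len(seq.steps) - 1):
        if not _junction_matches(seq.steps[i].target, seq.steps[i + 1].source):
            raise ChainError(f"steps {i} and {i + 1} do not share their junction drawing")
    frames: list[Drawing] = []
    for i, step in enumerate(seq.steps):
        fs = make_frames(step)
        frames.extend(fs if i == 0 else fs[1:])
    return frames


def vibration_preset(
    molecule: Drawing, mode: str, amplitude: float, n_frames: int = 9
) -> MorphSequence:
    """Build an oscillating vibration animation for a bent triatomic.

    The molecule must have exactly three atoms and two bonds meeting in one
    central atom. A displaced geometry is constructed —

    * ``symmetric_stretch``: both bonds lengthen by ``amplitude`` (scene
      units) along their own axes;
    * ``asymmetric_stretch``: the terminal with the lower id lengthens by
      ``amplitude`` while the other shortens by the same amount;
    * ``scissoring``: the bond angle opens by ``amplitude`` (radians), each
      terminal rotating amplitude/2 away from the bisector at fixed bond
      length —

    and the result is the two-step there-and-back sequence
    source -> displaced -> source.
    """
    if mode not in ("symmetric_stretch", "asymmetric_stretch", "scissoring"):
        raise DomainError(f"unknown vibration mode {mode!r}")
    if len(molecule.atoms) != 3 or len(molecule.bonds) != 2:
        raise TopologyError("vibration presets need a triatomic with exactly 2 bonds")
    centers = [a.id for a in molecule.atoms if molecule.degree(a.id) == 2]
    if len(centers) != 1:
        raise TopologyError("vibration presets need exactly one 2-bonded central atom")
    center = molecule.atom(centers[0])
    terminals = sorted(
        (molecule.atom(i) for i in molecule.neighbors(center.id)), key=lambda a: a.id
    )

    def unit(v: Point2) -> Point2:
        n = math.hypot(v.x, v.y)
        if n < 1e-12:
            raise TopologyError("zero-length bond in vibration preset")
        return Point2(v.x / n, v.y / n)

    new_pos: dict[int, Point2] = {}
    if mode in ("symmetric_stretch", "asymmetric_stretch"):
        signs = (1.0, 1.0) if mode == "symmetric_stretch" else (1.0, -1.0)
        for term, sign in zip(terminals, signs):
            u = unit(term.position - center.position)
            new_pos[term.id] = term.position + u.scaled(sign * amplitude)
    else:  # scissoring
        angles = [
            math.atan2(t.position.y - center.position.y, t.position.x - center.position.x)
            for t in terminals
        ]
        # rotate each arm amplitude/2 away from the other, preserving lengths
        diff = math.atan2(math.sin(angles[1] - angles[0]), math.cos(angles[1] - angles[0]))
        direction = 1.0 if diff > 0 else -1.0
        deltas = (-direction * amplitude / 2.0, direction * amplitude / 2.0)
        for term, ang, dlt in zip(terminals, angles, deltas):
            r = term.position.distance_to(center.position)
            new_pos[term.id] = Point2(
                center.position.x + r * math.cos(ang + dlt),
                center.position.y + r * math.sin(ang + dlt),
            )

    displaced = replace(
        molecule,
        atoms=tuple(a.moved_to(new_pos.get(a.id, a.position)) for a in molecule.atoms),
    )
    corr = identity_correspondence(molecule)
    fwd = MorphStep(source=molecule, target=displaced, correspondence=corr, n_frames=n_frames)
    back = MorphStep(source=displaced, target=molecule, correspondence=corr, n_frames=n_frames)
    return MorphSequence(steps=(fwd, back))
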