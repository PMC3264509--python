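"""Morphing engine: correspondence, interpolation, frame generation,
sequences and vibration presets."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from chemmorph.errors import (
    ChainError,
    CorrespondenceError,
    DomainError,
    TopologyError,
)
from chemmorph.fixtures import methane, scissor_pair, sn2_post, sn2_pre, stretch_pair, water
from chemmorph.model import Atom, Bond, BondKind, Drawing, Point2
from chemmorph.morph import (
    Correspondence,
    MorphSequence,
    MorphStep,
    auto_correspond,
    identity_correspondence,
    interpolate_atom,
    make_frames,
    run_sequence,
    vibration_preset,
)

from conftest import matched_pair, random_drawing


def bond_length(d: Drawing, b: Bond) -> float:
    return d.atom(b.a1).position.distance_to(d.atom(b.a2).position)


def bend_angle(d: Drawing) -> float:
    """H-X-H angle of a triatomic with central atom id 0."""
    c, p, q = d.atom(0).position, d.atom(1).position, d.atom(2).position
    v1, v2 = (p.x - c.x, p.y - c.y), (q.x - c.x, q.y - c.y)
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    return math.acos(dot / (math.hypot(*v1) * math.hypot(*v2)))


class TestAutoCorrespond:
    def test_identical_drawings_pair_everything_with_itself(self):
        d = methane()
        corr = auto_correspond(d, d)
        assert corr.atom_pairs == tuple((a.id, a.id) for a in d.atoms)
        assert corr.bond_pairs == tuple((i, i) for i in range(len(d.bonds)))
        assert corr.unmatched_source_atoms == ()
        assert corr.unmatched_target_atoms == ()

    def test_displaced_water_pairs_by_nearest_position(self):
        src = water()
        tgt = Drawing(
            atoms=tuple(
                a.moved_to(a.position + Point2(0.1, 0.0)) if a.element == "O" else a
                for a in src.atoms
            ),
            bonds=src.bonds,
        )
        corr = auto_correspond(src, tgt)
        # brute-force oracle: <=3 atoms per element, enumerate all assignments
        assert dict(corr.atom_pairs) == {0: 0, 1: 1, 2: 2}

    def test_element_grouping_leaves_mismatches_unmatched(self):
        src = methane()  # C + 4 H
        tgt_atoms = (
            Atom(id=0, element="C", position=Point2(0, 0)),
            Atom(id=1, element="H", position=Point2(0, 1)),
            Atom(id=2, element="H", position=Point2(1, 0)),
            Atom(id=3, element="H", position=Point2(0, -1)),
            Atom(id=4, element="Cl", position=Point2(-1.2, 0)),
        )
        tgt = Drawing(atoms=tgt_atoms, bonds=tuple(Bond(0, i) for i in range(1, 5)))
        corr = auto_correspond(src, tgt)
        paired = dict(corr.atom_pairs)
        assert paired[0] == 0  # C <-> C
        assert len(corr.unmatched_source_atoms) == 1  # one H left over
        assert corr.unmatched_target_atoms == (4,)  # the Cl

    def test_symmetric_up_to_role_swap(self, rng):
        src, tgt = matched_pair(rng, 20)
        fwd = auto_correspond(src, tgt)
        rev = auto_correspond(tgt, src)
        assert set(fwd.atom_pairs) == {(t, s) for s, t in rev.atom_pairs}

    def test_bond_kind_compatibility(self):
        a = (Atom(id=0, element="C", position=Point2(0, 0)), Atom(id=1, element="C", position=Point2(1, 0)))
        src = Drawing(atoms=a, bonds=(Bond(0, 1, kind=BondKind.SINGLE),))
        tgt = Drawing(atoms=a, bonds=(Bond(0, 1, kind=BondKind.DOUBLE),))
        corr = auto_correspond(src, tgt)
        # sole candidate of another kind is still accepted
        assert corr.bond_pairs == ((0, 0),)


class TestInterpolateAtom:
    def setup_method(self):
        self.a0 = Atom(id=0, element="C", position=Point2(0, 0), color=(0, 0, 0))
        self.a1 = Atom(id=0, element="N", position=Point2(2, 0), color=(255, 0, 0))

    def test_endpoints_exact(self):
        assert interpolate_atom(self.a0, self.a1, 0.0) == self.a0
        assert interpolate_atom(self.a0, self.a1, 1.0) == self.a1

    def test_linear_midpoint(self):
        mid = interpolate_atom(self.a0, self.a1, 0.5)
        assert mid.position == Point2(1.0, 0.0)

    def test_channel_rounding(self):
        # round((1-0.25)*0 + 0.25*255) = round(63.75) = 64
        got = interpolate_atom(self.a0, self.a1, 0.25)
        assert got.color == (64, 0, 0)

    def test_element_switches_at_half(self):
        assert interpolate_atom(self.a0, self.a1, 0.49).element == "C"
        assert interpolate_atom(self.a0, self.a1, 0.5).element == "N"

    @given(t=st.floats(min_value=0, max_value=1))
    def test_opacity_within_bounds(self, t):
        faded = Atom(id=0, element="C", position=Point2(0, 0), opacity=0.25)
        got = interpolate_atom(faded, self.a1, t)
        assert 0.0 <= got.opacity <= 1.0

    @pytest.mark.parametrize("t", [-0.1, 1.01])
    def test_out_of_domain_rejected(self, t):
        with pytest.raises(DomainError):
            interpolate_atom(self.a0, self.a1, t)


class TestMakeFrames:
    def test_two_frames_are_source_and_target(self, rng):
        src, tgt = matched_pair(rng, 10)
        frames = make_frames(MorphStep(source=src, target=tgt, n_frames=2))
        assert frames[0] == src
        assert frames[1] == tgt

    def test_single_atom_t_grid(self):
        src = Drawing(atoms=(Atom(id=0, element="C", position=Point2(0, 0)),))
        tgt = Drawing(atoms=(Atom(id=0, element="C", position=Point2(4, 0)),))
        frames = make_frames(MorphStep(source=src, target=tgt, n_frames=5))
        assert [f.atom(0).position.x for f in frames] == [0.0, 1.0, 2.0, 3.0, 4.0]

    def test_cross_dissolve_at_midpoint(self):
        src = methane()
        tgt_atoms = src.atoms[:4] + (Atom(id=4, element="Cl", position=Point2(-1.2, 0)),)
        tgt = Drawing(atoms=tgt_atoms, bonds=src.bonds[:3] + (Bond(0, 4),))
        frames = make_frames(MorphStep(source=src, target=tgt, n_frames=3))
        mid = frames[1]
        leaving_h = mid.atom(4)
        incoming_cl = [a for a in mid.atoms if a.element == "Cl"][0]
        assert leaving_h.opacity == pytest.approx(0.5)
        assert incoming_cl.opacity == pytest.approx(0.5)
        # cross-dissolve conserves paired opacity
        assert leaving_h.opacity + incoming_cl.opacity == pytest.approx(1.0)

    def test_endpoint_identity_and_segment_linearity(self, rng):
        src, tgt = matched_pair(rng, 30)
        n = 7
        frames = make_frames(MorphStep(source=src, target=tgt, n_frames=n))
        assert frames[0] == src and frames[-1] == tgt
        for k, frame in enumerate(frames):
            t = k / (n - 1)
            for a in src.atoms:
                p0 = a.position
                p1 = tgt.atom(a.id).position
                got = frame.atom(a.id).position
                assert abs(got.x - ((1 - t) * p0.x + t * p1.x)) < 1e-12
                assert abs(got.y - ((1 - t) * p0.y + t * p1.y)) < 1e-12

    def test_bad_correspondence_rejected(self):
        src = water()
        corr = Correspondence(atom_pairs=((0, 99),))
        with pytest.raises(CorrespondenceError):
            make_frames(MorphStep(source=src, target=src, correspondence=corr, n_frames=3))

    def test_n_frames_below_two_rejected(self):
        with pytest.raises(DomainError):
            MorphStep(source=water(), target=water(), n_frames=1)

    def test_region_modes_still_hit_endpoints(self, rng):
        from chemmorph.model import Annotation

        src, tgt = matched_pair(rng, 8)
        ann = Annotation(shape="arrow", outline=(Point2(0, 0), Point2(1, 1)))
        src = Drawing(atoms=src.atoms, bonds=src.bonds, annotations=(ann,))
        for mode in ("triangles", "squares"):
            frames = make_frames(
                MorphStep(source=src, target=tgt, n_frames=4, mapping_mode=mode)
            )
            assert frames[0] == src
            assert frames[-1] == tgt


class TestRunSequence:
    def test_single_step_equals_make_frames(self, rng):
        src, tgt = matched_pair(rng, 10)
        step = MorphStep(source=src, target=tgt, n_frames=5)
        assert run_sequence(MorphSequence(steps=(step,))) == make_frames(step)

    def test_two_steps_drop_junction_frame(self, rng):
        a, b = matched_pair(rng, 10)
        c = Drawing(
            atoms=tuple(x.moved_to(x.position + Point2(1, 0)) for x in b.atoms), bonds=b.bonds
        )
        s1 = MorphStep(source=a, target=b, n_frames=5)
        s2 = MorphStep(source=b, target=c, n_frames=5)
        frames = run_sequence(MorphSequence(steps=(s1, s2)))
        assert len(frames) == 9

    def test_frame_count_arithmetic(self, rng):
        drawings = [random_drawing(rng, 6)]
        counts = [3, 5, 4, 6]
        for _ in counts:
            prev = drawings[-1]
            drawings.append(
                Drawing(
                    atoms=tuple(a.moved_to(a.position + Point2(0.5, 0)) for a in prev.atoms),
                    bonds=prev.bonds,
                )
            )
        steps = tuple(
            MorphStep(source=drawings[i], target=drawings[i + 1], n_frames=counts[i])
            for i in range(len(counts))
        )
        frames = run_sequence(MorphSequence(steps=steps))
        assert len(frames) == sum(counts) - (len(counts) - 1)

    def test_junction_mismatch_raises(self, rng):
        a, b = matched_pair(rng, 8)
        other = random_drawing(rng, 8)
        s1 = MorphStep(source=a, target=b, n_frames=3)
        s2 = MorphStep(source=other, target=a, n_frames=3)
        with pytest.raises(ChainError):
            run_sequence(MorphSequence(steps=(s1, s2)))


class TestVibrationPresets:
    def test_zero_amplitude_all_frames_equal_source(self):
        w = water()
        frames = run_sequence(vibration_preset(w, "symmetric_stretch", 0.0, n_frames=4))
        assert all(f == w for f in frames)

    def test_symmetric_stretch_lengthens_both_bonds(self):
        w = water()
        seq = vibration_preset(w, "symmetric_stretch", 0.2, n_frames=3)
        displaced = seq.steps[0].target
        for b in displaced.bonds:
            assert bond_length(displaced, b) == pytest.approx(1.2, abs=1e-9)

    def test_asymmetric_stretch_opposite_signs(self):
        w = water()
        displaced = vibration_preset(w, "asymmetric_stretch", 0.15, n_frames=3).steps[0].target
        lengths = sorted(bond_length(displaced, b) for b in displaced.bonds)
        assert lengths[0] == pytest.approx(0.85, abs=1e-9)
        assert lengths[1] == pytest.approx(1.15, abs=1e-9)

    def test_scissoring_opens_angle_at_fixed_lengths(self):
        w = water()
        displaced = vibration_preset(w, "scissoring", 0.1, n_frames=3).steps[0].target
        assert bend_angle(displaced) == pytest.approx(bend_angle(w) + 0.1, abs=1e-9)
        for b in displaced.bonds:
            assert bond_length(displaced, b) == pytest.approx(1.0, abs=1e-9)

    def test_sequence_is_there_and_back(self):
        w = water()
        seq = vibration_preset(w, "scissoring", 0.1, n_frames=5)
        frames = run_sequence(seq)
        assert len(frames) == 9
        assert frames[0] == w and frames[-1] == w

    def test_non_triatomic_rejected(self):
        with pytest.raises(TopologyError):
            vibration_preset(methane(), "symmetric_stretch", 0.1)
        linear = Drawing(
            atoms=(
                Atom(id=0, element="C", position=Point2(0, 0)),
                Atom(id=1, element="O", position=Point2(1, 0)),
                Atom(id=2, element="O", position=Point2(2, 0)),
            ),
            bonds=(Bond(0, 1), Bond(1, 2)),
        )
        # valid topology (central atom id 1); no error expected
        vibration_preset(linear, "symmetric_stretch", 0.1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(DomainError):
            vibration_preset(water(), "wag", 0.1)


class TestFixturePairs:
    def test_stretch_pair_geometry(self):
        src, dst = stretch_pair(0.2)
        assert src == water()
        for b in dst.bonds:
            assert bond_length(dst, b) == pytest.approx(1.2, abs=1e-9)

    def test_scissor_pair_geometry(self):
        src, dst = scissor_pair(0.3)
        assert bend_angle(dst) == pytest.approx(bend_angle(src) + 0.3, abs=1e-9)

    def test_sn2_pair_is_chainable_morph_material(self):
        pre, post = sn2_pre(), sn2_post()
        corr = auto_correspond(pre, post)
        assert len(corr.atom_pairs) == 6  # full pairing: same composition
        s1 = MorphStep(source=pre, target=post, n_frames=5)
        s2 = MorphStep(source=post, target=pre, n_frames=5)
        frames = run_sequence(MorphSequence(steps=(s1, s2)))
        assert len(frames) == 9
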