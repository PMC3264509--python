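"""Deterministic example drawings: small molecules, chains, vibration pairs
and the SN2 reaction endpoints.

Every geometry is constructed from documented coordinates (bond length 1.0
scene units, 104.5 degree H-O-H angle for water), so tests and the CLI run
without any external files. There is no randomness anywhere in this module.
"""

from __future__ import annotations

import math
from dataclasses import replace

from .errors import DomainError
from .model import Atom, Bond, BondKind, Drawing, Point2

WATER_ANGLE_DEG = 104.5
BOND_LENGTH = 1.0
CHAIN_SPACING = 1.5


def water() -> Drawing:
    """Bent H2O: O at the origin, O-H length 1.0, H-O-H angle 104.5 degrees,
    arms symmetric about the -y axis (hydrogens below the oxygen)."""
    half = math.radians(WATER_ANGLE_DEG) / 2.0
    o = Atom(id=0, element="O", position=Point2(0.0, 0.0))
    h1 = Atom(id=1, element="H", position=Point2(-BOND_LENGTH * math.sin(half), -BOND_LENGTH * math.cos(half)))
    h2 = Atom(id=2, element="H", position=Point2(BOND_LENGTH * math.sin(half), -BOND_LENGTH * math.cos(half)))
    return Drawing(atoms=(o, h1, h2), bonds=(Bond(0, 1), Bond(0, 2)))


def methane() -> Drawing:
    """2D cross depiction of CH4: C at the origin, 4 H at unit distance N/E/S/W."""
    c = Atom(id=0, element="C", position=Point2(0.0, 0.0))
    hs = tuple(
        Atom(id=i + 1, element="H", position=Point2(x, y))
        for i, (x, y) in enumerate([(0.0, 1.0), (1.0, 0.0), (0.0, -1.0), (-1.0, 0.0)])
    )
    return Drawing(atoms=(c,) + hs, bonds=tuple(Bond(0, i + 1) for i in range(4)))


def chain(n: int) -> Drawing:
    """A straight carbon chain of ``n`` atoms spaced 1.5 units apart on the
    x-axis, joined by n-1 single bonds."""
    if n < 1:
        raise DomainError(f"chain length must be >= 1, got {n}")
    atoms = tuple(Atom(id=i, element="C", position=Point2(i * CHAIN_SPACING, 0.0)) for i in range(n))
    bonds = tuple(Bond(i, i + 1) for i in range(n - 1))
    return Drawing(atoms=atoms, bonds=bonds)


def _ch3_core(offset_x: float = 0.0) -> tuple[tuple[Atom, ...], tuple[Bond, ...]]:
    c = Atom(id=0, element="C", position=Point2(offset_x, 0.0))
    hs = tuple(
        Atom(id=i + 1, element="H", position=Point2(offset_x + x, y))
        for i, (x, y) in enumerate([(0.0, 1.0), (-0.5, -0.87), (0.5, -0.87)])
    )
    return (c,) + hs, tuple(Bond(0, i + 1) for i in range(3))


def sn2_pre() -> Drawing:
    """SN2 starting point: chloride nucleophile approaching CH3-Br.

    Cl- sits 3 units to the left of the carbon; Br is bonded 1.5 units to
    the right (the leaving group still attached)."""
    atoms, bonds = _ch3_core()
    cl = Atom(id=4, element="Cl", position=Point2(-3.0, 0.0), charge=-1)
    br = Atom(id=5, element="Br", position=Point2(1.5, 0.0))
    return Drawing(atoms=atoms + (cl, br), bonds=bonds + (Bond(0, 5),))


def sn2_post() -> Drawing:
    """SN2 end point: Cl-CH3 formed, bromide departed 3 units to the right."""
    atoms, bonds = _ch3_core()
    cl = Atom(id=4, element="Cl", position=Point2(-1.5, 0.0))
    br = Atom(id=5, element="Br", position=Point2(3.0, 0.0), charge=-1)
    return Drawing(atoms=atoms + (cl, br), bonds=bonds + (Bond(0, 4),))


def _displaced_water(mode: str, amplitude: float) -> Drawing:
    from .morph import vibration_preset  # local import to avoid a cycle

    seq = vibration_preset(water(), mode, amplitude, n_frames=2)
    return seq.steps[0].target


def stretch_pair(amplitude: float = 0.2) -> tuple[Drawing, Drawing]:
    """Water and its symmetric-stretch displaced geometry (both O-H bonds
    lengthened by ``amplitude``)."""
    return water(), _displaced_water("symmetric_stretch", amplitude)


def scissor_pair(amplitude: float = 0.2) -> tuple[Drawing, Drawing]:
    """Water and its scissoring displaced geometry (H-O-H angle opened by
    ``amplitude`` radians, bond lengths fixed)."""
    return water(), _displaced_water("scissoring", amplitude)


def generate_fixture(name: str, **params):
    """Dispatch by fixture name: water, methane, chain (``n=``), sn2_pre,
    sn2_post, stretch_pair / scissor_pair (``amplitude=``)."""
    table = {
        "water": water,
        "methane": methane,
        "chain": lambda: chain(int(params.get("n", 1))),
        "sn2_pre": sn2_pre,
        "sn2_post": sn2_post,
        "stretch_pair": lambda: stretch_pair(float(params.get("amplitude", 0.2))),
        "scissor_pair": lambda: scissor_pair(float(params.get("amplitude", 0.2))),
    }
    if name not in table:
        raise DomainError(f"unknown fixture {name!r}; choose from {sorted(table)}")
    return table[name]()
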