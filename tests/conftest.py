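"""Shared test fixtures: deterministic random-drawing generators and a
hand-written methane molfile."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chemmorph.model import Atom, Bond, BondKind, Drawing, Point2

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

ELEMENTS = ["C", "H", "O", "N", "Cl", "Br", "S", "P"]
KINDS = list(BondKind)


def random_drawing(
    rng: np.random.Generator,
    n_atoms: int,
    with_charges: bool = True,
    with_isotopes: bool = False,
) -> Drawing:
    """A connected-ish random drawing expressible in V2000 (coordinates within
    the 10.4 fixed-column range, integer charges, unique atom ids)."""
    atoms = []
    for i in range(n_atoms):
        atoms.append(
            Atom(
                id=i,
                element=ELEMENTS[int(rng.integers(len(ELEMENTS)))],
                position=Point2(
                    float(np.round(rng.uniform(-50, 50), 4)),
                    float(np.round(rng.uniform(-50, 50), 4)),
                ),
                charge=int(rng.integers(-3, 4)) if with_charges else 0,
                mass_number=(
                    int(rng.integers(1, 250)) if with_isotopes and rng.random() < 0.3 else None
                ),
            )
        )
    bonds = []
    seen = set()
    for i in range(1, n_atoms):
        j = int(rng.integers(i))  # spanning tree keeps endpoints valid
        bonds.append(Bond(a1=j, a2=i, kind=KINDS[int(rng.integers(len(KINDS)))]))
        seen.add((j, i))
    return Drawing(atoms=tuple(atoms), bonds=tuple(bonds))


def matched_pair(rng: np.random.Generator, n_atoms: int) -> tuple[Drawing, Drawing]:
    """Source drawing plus a target with identical composition/topology but
    jittered positions — every atom and bond should pair under
    auto-correspondence."""
    src = random_drawing(rng, n_atoms, with_charges=False)
    tgt_atoms = tuple(
        a.moved_to(a.position + Point2(float(rng.uniform(-0.3, 0.3)), float(rng.uniform(-0.3, 0.3))))
        for a in src.atoms
    )
    return src, Drawing(atoms=tgt_atoms, bonds=src.bonds)


# Hand-written from the published V2000 column layout: cross-shaped methane,
# C at the origin, four unit-distance hydrogens, four single bonds.
METHANE_MOL = """methane
  chemmorph        2D
hand-written fixture
  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  1  3  1  0  0  0  0
  1  4  1  0  0  0  0
  1  5  1  0  0  0  0
M  END
"""

EMPTY_MOL = """empty

0 atoms, 0 bonds
  0  0  0  0  0  0  0  0  0  0999 V2000
M  END
"""


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture
def methane_text() -> str:
    return METHANE_MOL


@pytest.fixture
def empty_mol_text() -> str:
    return EMPTY_MOL
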