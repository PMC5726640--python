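import numpy as np
import pytest

import glycotop as gt


@pytest.fixture(scope="session")
def bundle() -> gt.FixtureBundle:
    """The schematic pyranose bundle; treated as read-only by all tests."""
    return gt.make_pyranose(0)


@pytest.fixture(scope="session")
def atom_names(bundle):
    return [a.name for a in bundle.molecule.atoms]


@pytest.fixture(scope="session")
def ring_indices(atom_names):
    return [atom_names.index(n) for n in ("O5", "C1", "C2", "C3", "C4", "C5")]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


TOY_RESTRAINT_TABLE = """\
! toy NOE table: two restraints cross the sugar/protein divide
assign (segid A and resid 1 and name H1) (segid A and resid 50 and name HA) 3.0 0.5 0.5
assign (resid 1 and name H8)
       (resid 51 and name HB#) 4.0 1.0 1.0
assign (resid 50 and name HN) (resid 51 and name HA) 2.8 0.3 0.3
"""


@pytest.fixture(scope="session")
def toy_restraint_roster():
    return [
        gt.AtomMeta("A", 1, "A2G", "H1", "H", het=True),
        gt.AtomMeta("A", 1, "A2G", "H8", "H", het=True),
        gt.AtomMeta("A", 50, "ALA", "HA", "H"),
        gt.AtomMeta("A", 50, "ALA", "HN", "H"),
        gt.AtomMeta("A", 51, "LEU", "HB1", "H"),
        gt.AtomMeta("A", 51, "LEU", "HA", "H"),
    ]
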