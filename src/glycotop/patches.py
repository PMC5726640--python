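"""Glycosylation and glycosidic-linkage patch catalogue.

Sixteen patches cover O-glycosylation to Ser/Thr, S-glycosylation to Cys,
and beta(1,3)/beta(1,6) sugar-sugar linkages, each in alpha/beta anomeric
form and for both D- and L-saccharides (the ``L`` suffix).  Every patch
forms one new bond from the sugar anomeric carbon C1 to the acceptor atom,
removes the atoms eliminated by the condensation (the sugar anomeric
hydroxyl O1/HO1 and the acceptor hydroxyl/thiol hydrogen), and installs a
single four-vertex chirality improper at C1 whose signed target encodes the
anomeric configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .forcefield import PatchAtomRef, PatchDef, TopologySet, write_topology

#: |improper| over the four substituents of an ideal tetrahedral center
#: with equal bond lengths: arccos(1/3) = 70.5288... degrees.
TETRAHEDRAL_IMPROPER_DEG = math.degrees(math.acos(1.0 / 3.0))

#: Sign convention fixed once for the whole package: a D-sugar in the
#: alpha configuration gives a negative (H1, O5, C2, X) improper at C1;
#: beta gives positive; L-sugars are the mirror images.
ANOMERIC_SIGN = {("alpha", "D"): -1.0, ("beta", "D"): +1.0,
                 ("alpha", "L"): +1.0, ("beta", "L"): -1.0}


@dataclass(frozen=True)
class LinkageSpec:
    """One glycosidic/glycosylation linkage to realize with a patch:
    which residue donates C1, which accepts, and the patch to use."""

    donor_residue_index: int
    acceptor_residue_index: int
    patch_name: str

    def __post_init__(self) -> None:
        if self.donor_residue_index == self.acceptor_residue_index:
            raise ValueError("donor and acceptor residues must differ")

    def mapping(self) -> dict[int, int]:
        """Patch group mapping: group 1 = sugar donor, group 2 = acceptor."""
        return {1: self.donor_residue_index, 2: self.acceptor_residue_index}


# (code stem, anomer, acceptor atom, acceptor hydrogen removed)
_CATALOGUE = [
    ("A1S", "alpha", "OG",  "HG"),    # -> Ser
    ("B1S", "beta",  "OG",  "HG"),
    ("A1T", "alpha", "OG1", "HG1"),   # -> Thr
    ("B1T", "beta",  "OG1", "HG1"),
    ("A1C", "alpha", "SG",  "HG"),    # -> Cys
    ("B1C", "beta",  "SG",  "HG"),
    ("B13", "beta",  "O3",  "HO3"),   # -> sugar O3
    ("B16", "beta",  "O6",  "HO6"),   # -> sugar O6
]

GLYCOSYLATION_PATCH_NAMES = tuple(
    stem + suffix for stem, _, _, _ in _CATALOGUE for suffix in ("", "L"))


def _make_patch(name: str, anomer: str, hand: str,
                acceptor_atom: str, acceptor_h: str) -> PatchDef:
    sign = ANOMERIC_SIGN[(anomer, hand)]
    r1 = lambda n: PatchAtomRef(1, n)
    r2 = lambda n: PatchAtomRef(2, n)
    return PatchDef(
        name=name,
        deleted_atoms=[r1("O1"), r1("HO1"), r2(acceptor_h)],
        added_bonds=[(r1("C1"), r2(acceptor_atom))],
        added_impropers=[((r1("H1"), r1("O5"), r1("C2"), r2(acceptor_atom)),
                          sign * TETRAHEDRAL_IMPROPER_DEG)],
    )


def generate_glycosylation_patches() -> list[PatchDef]:
    """The full 16-patch catalogue (8 D-saccharide codes + 8 ``L`` variants).

    Alpha/beta and D/L variants of the same linkage differ only in the sign
    of the chirality improper installed at C1.
    """
    patches = []
    for stem, anomer, acc_atom, acc_h in _CATALOGUE:
        patches.append(_make_patch(stem, anomer, "D", acc_atom, acc_h))
        patches.append(_make_patch(stem + "L", anomer, "L", acc_atom, acc_h))
    return patches


def patch_catalogue_text() -> str:
    """The catalogue as a PRESidue-only topology section, appendable to any
    topology file."""
    tset = TopologySet()
    for p in generate_glycosylation_patches():
        tset.patches[p.name] = p
    return write_topology(tset, header="glycotop glycosylation patch catalogue")
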