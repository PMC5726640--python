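"""Chirality enforcement for tetrahedral carbons.

The failure mode this module exists for: if the chirality of a sugar carbon
is enforced by an improper over the central carbon and its *heavy-atom*
neighbours only, the position of the bonded hydrogen carries no improper
energy.  Reflecting the hydrogen through the carbon along the C-H line then
leaves every improper unchanged and only crosses a bond-energy barrier, so
annealing can trap the hydrogen on the wrong side and emit a mirror-flipped
center.  Defining the improper over the *four tetrahedral vertex atoms*
(hydrogen included, center excluded) makes the flipped position energetically
wrong and removes the local minimum.

Functions here find stereocenters on a molecule graph, rewrite heavy-atom
impropers into the four-vertex form with targets measured from a reference
conformation, and diagnose flipped centers in coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .forcefield import TopologySet
from .geometry import signed_dihedral, wrap_deg
from .molecule import MoleculeGraph, atomic_number, element_of

DEFAULT_TOLERANCE_DEG = 25.0


class ChiralityError(ValueError):
    pass


@dataclass(frozen=True)
class ChiralCenter:
    """A tetrahedral stereocenter: the central atom, its four substituent
    vertices (hydrogen included), and the signed improper target measured
    over the vertices on reference geometry."""

    center_atom: int
    vertices: tuple[int, int, int, int]
    target_improper: float     # degrees, signed

    def __post_init__(self) -> None:
        if not 0.0 < abs(self.target_improper) < 180.0:
            raise ChiralityError(
                f"target improper must lie in (0, 180) in magnitude, "
                f"got {self.target_improper}")


@dataclass(frozen=True)
class ChiralityViolation:
    center_atom: int
    center_name: str
    measured: float
    target: float
    sign_flip: bool


# ---------------------------------------------------------------------------
# stereocenter detection
# ---------------------------------------------------------------------------

def _substituent_signature(mol: MoleculeGraph, root: int, exclude: int,
                           depth: int = 3) -> tuple:
    """Hashable environment signature of the branch rooted at ``root`` when
    walking away from ``exclude``; used only to decide whether the four
    substituents of a carbon are mutually distinct."""
    layer = {root}
    seen = {exclude, root}
    sig = [element_of(mol.atoms[root].name)]
    adj = mol._adjacency()
    for _ in range(depth):
        nxt = set()
        for i in layer:
            for j in adj[i]:
                if j not in seen:
                    nxt.add(j)
                    seen.add(j)
        if not nxt:
            break
        sig.append(tuple(sorted(element_of(mol.atoms[j].name) for j in nxt)))
        layer = nxt
    return tuple(sig)


def find_stereocenters(mol: MoleculeGraph, ring_only: bool = False) -> list[int]:
    """Indices of tetravalent carbons whose four substituents have mutually
    distinct environment signatures.  ``ring_only`` restricts to carbons
    lying on a cycle of the bond graph."""
    out = []
    for i, a in enumerate(mol.atoms):
        if a.element != "C":
            continue
        nb = mol.neighbors(i)
        if len(nb) != 4:
            continue
        sigs = [_substituent_signature(mol, j, i) for j in nb]
        if len(set(sigs)) == 4:
            if ring_only and not _on_ring(mol, i):
                continue
            out.append(i)
    return out


def _on_ring(mol: MoleculeGraph, i: int) -> bool:
    """True if atom i lies on a cycle: removing it must not disconnect all
    of its neighbours from each other."""
    adj = mol._adjacency()
    nb = set(adj[i])
    for start in nb:
        seen = {i, start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for j in adj[cur]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
            if len(nb & seen) > 1:
                return True
    return False


def vertex_order(mol: MoleculeGraph, center: int) -> tuple[int, int, int, int]:
    """Canonical vertex ordering for a four-vertex improper: hydrogen first,
    then remaining substituents by descending atomic number, then name."""
    nb = mol.neighbors(center)
    if len(nb) != 4:
        raise ChiralityError(
            f"atom {mol.atoms[center].name} has {len(nb)} neighbours, need 4")
    hydros = [i for i in nb if mol.atoms[i].element == "H"]
    if not hydros:
        raise ChiralityError(
            f"stereocenter {mol.atoms[center].name} has no bonded hydrogen")
    rest = sorted((i for i in nb if i != hydros[0]),
                  key=lambda i: (-atomic_number(mol.atoms[i].name), mol.atoms[i].name))
    return (hydros[0], *rest)


def measure_centers(mol: MoleculeGraph, coords: np.ndarray,
                    ring_only: bool = False) -> list[ChiralCenter]:
    """Chiral centers with four-vertex improper targets measured from
    ``coords`` (the reference geometry)."""
    out = []
    for c in find_stereocenters(mol, ring_only=ring_only):
        verts = vertex_order(mol, c)
        target = signed_dihedral(*(coords[v] for v in verts))
        out.append(ChiralCenter(c, verts, target))
    return out


# ---------------------------------------------------------------------------
# topology rewriting
# ---------------------------------------------------------------------------

def retarget_impropers(tset: TopologySet,
                       reference: dict[str, dict[str, np.ndarray]],
                       ring_only: bool = False) -> TopologySet:
    """Rewrite per-residue chirality impropers into the four-vertex form.

    ``reference`` maps residue name -> {atom name -> xyz} ideal coordinates.
    For every stereocenter of each residue, any improper quadruple that
    names the center among its four atoms and contains no hydrogen (the
    heavy-atom style) is removed and replaced by one improper over the four
    substituent vertices, hydrogen first, with its target measured on the
    reference coordinates.  Residues without reference coordinates are left
    untouched.
    """
    from .molecule import build_molecule

    out = TopologySet(residues={}, patches=dict(tset.patches),
                      masses=dict(tset.masses),
                      autogenerate_angles=tset.autogenerate_angles,
                      autogenerate_dihedrals=tset.autogenerate_dihedrals,
                      preamble=list(tset.preamble))
    for rname, res in tset.residues.items():
        if rname not in reference:
            out.residues[rname] = res
            continue
        ref = reference[rname]
        sub = TopologySet(residues={rname: res})
        mol = build_molecule([rname], sub)
        missing = [a.name for a in mol.atoms if a.name not in ref]
        if missing:
            raise ChiralityError(
                f"residue {rname}: reference coordinates missing for {missing}")
        coords = np.array([ref[a.name] for a in mol.atoms], float)
        centers = []
        for c in find_stereocenters(mol, ring_only=ring_only):
            if not any(mol.atoms[v].element == "H" for v in mol.neighbors(c)):
                raise ChiralityError(
                    f"residue {rname}: stereocenter {mol.atoms[c].name} "
                    f"has no hydrogen in the reference")
            centers.append(c)

        new_impropers = []
        new_targets = dict(res.improper_targets)
        center_names = {mol.atoms[c].name for c in centers}
        for quad in res.impropers:
            heavy_only = all(element_of(n) != "H" for n in quad)
            if heavy_only and any(n in center_names for n in quad):
                new_targets.pop(quad, None)
                continue        # replaced below
            new_impropers.append(quad)
        for c in centers:
            verts = vertex_order(mol, c)
            quad = tuple(mol.atoms[v].name for v in verts)
            if quad in new_impropers:
                continue
            target = signed_dihedral(*(coords[v] for v in verts))
            new_impropers.append(quad)
            new_targets[quad] = round(target, 6)
        out.residues[rname] = replace(res, impropers=new_impropers,
                                      improper_targets=new_targets)
    return out


# ---------------------------------------------------------------------------
# coordinate diagnosis
# ---------------------------------------------------------------------------

def check_chirality(coords: np.ndarray, centers: Sequence[ChiralCenter],
                    tolerance_deg: float = DEFAULT_TOLERANCE_DEG,
                    atom_names: Optional[Sequence[str]] = None) -> list[ChiralityViolation]:
    """Centers whose measured four-vertex improper disagrees with its target
    in sign, or deviates by more than ``tolerance_deg``."""
    coords = np.asarray(coords, float)
    out = []
    for c in centers:
        measured = signed_dihedral(*(coords[v] for v in c.vertices))
        sign_flip = np.sign(measured) != np.sign(c.target_improper)
        off = abs(float(wrap_deg(measured - c.target_improper)))
        if sign_flip or off > tolerance_deg:
            name = atom_names[c.center_atom] if atom_names is not None else str(c.center_atom)
            out.append(ChiralityViolation(c.center_atom, name, measured,
                                          c.target_improper, bool(sign_flip)))
    return out


def flip_hydrogen(coords: np.ndarray, center: int, hydrogen: int) -> np.ndarray:
    """Reflect one hydrogen through its carbon along the C-H line — the
    exact geometric move that heavy-atom impropers cannot see."""
    out = np.array(coords, float, copy=True)
    out[hydrogen] = 2.0 * coords[center] - coords[hydrogen]
    return out
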