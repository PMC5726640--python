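"""Molecule assembly: instantiate residues from a topology and apply
linkage/glycosylation patches to obtain a bonded graph with explicit
torsion-term lists, ready for parameter coverage checks and energy
evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .forcefield import PatchAtomRef, PatchDef, TopologySet

_ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}


def element_of(atom_name: str) -> str:
    """Element guessed from an atom name (first alphabetic character),
    e.g. C1 -> C, HO3 -> H, OG1 -> O, SG -> S."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def atomic_number(atom_name: str) -> int:
    return _ATOMIC_NUMBER.get(element_of(atom_name), 0)


class PatchError(ValueError):
    """Raised when a patch reference cannot be resolved."""


@dataclass(frozen=True)
class Atom:
    residue_index: int
    residue_name: str
    name: str
    type_code: str
    charge: float = 0.0

    @property
    def element(self) -> str:
        return element_of(self.name)


@dataclass
class MoleculeGraph:
    """Atoms plus an undirected bond graph and explicit torsion terms.

    ``explicit_impropers`` entries are ``(quadruple, target_or_None)``;
    a non-None target (degrees, signed) overrides parameter lookup — this is
    how mirror-distinguishing chirality impropers are carried, since one
    atom-type tuple cannot encode both hands.
    """

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    explicit_angles: list[tuple[int, int, int]] = field(default_factory=list)
    explicit_dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    explicit_impropers: list[tuple[tuple[int, int, int, int], Optional[float]]] = \
        field(default_factory=list)

    # -- queries -------------------------------------------------------

    def index_of(self, residue_index: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.name == name:
                return i
        raise KeyError((residue_index, name))

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def angle_triples(self) -> list[tuple[int, int, int]]:
        """All bonded triples i-j-k (i < k), the autogenerated angle list."""
        adj = self._adjacency()
        out = []
        for j in range(len(self.atoms)):
            nb = adj[j]
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    i, k = nb[x], nb[y]
                    out.append((i, j, k) if i < k else (k, j, i))
        return out

    def _adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        for nb in adj:
            nb.sort()
        return adj

    def n_components(self) -> int:
        n = len(self.atoms)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in self.bonds:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        return len({find(i) for i in range(n)})

    def validate(self) -> None:
        n = len(self.atoms)
        seen = set()
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"self-bond on atom index {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a},{b}) out of range")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate bond ({a},{b})")
            seen.add(key)
        for quad in self.explicit_dihedrals:
            if any(not 0 <= i < n for i in quad):
                raise ValueError(f"dihedral {quad} out of range")
        for quad, _ in self.explicit_impropers:
            if any(not 0 <= i < n for i in quad):
                raise ValueError(f"improper {quad} out of range")


def build_molecule(sequence: Sequence[str], tset: TopologySet) -> MoleculeGraph:
    """Instantiate residues in order; no inter-residue bonds are formed
    (linkages come from patches)."""
    mol = MoleculeGraph()
    for ridx, rname in enumerate(sequence):
        if rname not in tset.residues:
            raise KeyError(f"unknown residue {rname!r}")
        res = tset.residues[rname]
        offset = len(mol.atoms)
        local = {a.name: offset + i for i, a in enumerate(res.atoms)}
        for a in res.atoms:
            mol.atoms.append(Atom(ridx, rname, a.name, a.type_code, a.charge))
        for a, b in res.bonds:
            mol.bonds.append((local[a], local[b]))
        for t in res.angles:
            mol.explicit_angles.append(tuple(local[x] for x in t))
        for t in res.dihedrals:
            mol.explicit_dihedrals.append(tuple(local[x] for x in t))
        for t in res.impropers:
            mol.explicit_impropers.append(
                (tuple(local[x] for x in t), res.improper_targets.get(t)))
    mol.validate()
    return mol


def apply_patch(mol: MoleculeGraph, patch: PatchDef,
                mapping: dict[int, int]) -> MoleculeGraph:
    """Apply a patch, returning a new graph.

    ``mapping`` sends the patch's residue groups (the ``1-``/``2-``
    prefixes) to residue indices of ``mol``.  Deletions remove the atom and
    every bond/angle/dihedral/improper touching it; additions may reference
    both pre-existing and newly added atoms.
    """
    def resolve(ref: PatchAtomRef, atoms: list[Atom]) -> int:
        if ref.group not in mapping:
            raise PatchError(f"patch {patch.name}: no mapping for group {ref.group} ({ref})")
        ridx = mapping[ref.group]
        for i, a in enumerate(atoms):
            if a.residue_index == ridx and a.name == ref.name:
                return i
        raise PatchError(f"patch {patch.name}: cannot resolve atom reference {ref} "
                         f"(residue index {ridx})")

    atoms = list(mol.atoms)
    bonds = list(mol.bonds)
    angles = list(mol.explicit_angles)
    dihedrals = list(mol.explicit_dihedrals)
    impropers = list(mol.explicit_impropers)

    # modifications first (they never change indexing)
    for ref, type_code, charge in patch.modified_atoms:
        i = resolve(ref, atoms)
        a = atoms[i]
        atoms[i] = replace(a,
                           type_code=type_code if type_code is not None else a.type_code,
                           charge=charge if charge is not None else a.charge)

    # deletions: collect indices, then rebuild with an index remap
    doomed = sorted({resolve(ref, atoms) for ref in patch.deleted_atoms})
    if doomed:
        remap: dict[int, int] = {}
        kept: list[Atom] = []
        for i, a in enumerate(atoms):
            if i not in doomed:
                remap[i] = len(kept)
                kept.append(a)
        atoms = kept

        def alive(term: Iterable[int]) -> bool:
            return all(i in remap for i in term)

        bonds = [(remap[a], remap[b]) for a, b in bonds if alive((a, b))]
        angles = [tuple(remap[i] for i in t) for t in angles if alive(t)]
        dihedrals = [tuple(remap[i] for i in t) for t in dihedrals if alive(t)]
        impropers = [(tuple(remap[i] for i in q), tgt) for q, tgt in impropers if alive(q)]

    # additions
    for ref, adef in patch.added_atoms:
        if ref.group not in mapping:
            raise PatchError(f"patch {patch.name}: no mapping for group {ref.group}")
        ridx = mapping[ref.group]
        rname = next((a.residue_name for a in atoms if a.residue_index == ridx), "")
        atoms.append(Atom(ridx, rname, adef.name, adef.type_code, adef.charge))
    for r1, r2 in patch.added_bonds:
        bonds.append((resolve(r1, atoms), resolve(r2, atoms)))
    for refs in patch.added_angles:
        angles.append(tuple(resolve(r, atoms) for r in refs))
    for refs in patch.added_dihedrals:
        dihedrals.append(tuple(resolve(r, atoms) for r in refs))
    for refs, target in patch.added_impropers:
        impropers.append((tuple(resolve(r, atoms) for r in refs), target))

    out = MoleculeGraph(atoms, bonds, angles, dihedrals, impropers)
    out.validate()
    return out
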