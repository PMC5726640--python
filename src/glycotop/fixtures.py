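"""Synthetic inputs: a minimal pyranose residue with topology, parameters
and ideal chair coordinates; mirror/flipped/boat/noisy variants; randomized
topology and parameter sets for round-trip fuzzing; and two-residue
ensembles built at exact glycosidic torsions.

The pyranose is deliberately a *schematic* sugar — a six-membered O5,C1-C5
ring with one hydroxyl and one hydrogen per ring carbon and an exocyclic
CH2-OH arm — not a chemically faithful monosaccharide.  It exists to
exercise chirality, energy and annealing machinery with exactly known
geometry: bonds 1.526 A (C-C), 1.420 A (C-O), 1.090 A (C-H), 0.960 A (O-H)
and tetrahedral angles throughout, relaxed to the bottom of its own energy
surface so the reference energy is numerically zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .chirality import ChiralCenter, flip_hydrogen, measure_centers
from .energetics import TermList, energy, energy_and_gradient, enumerate_terms
from .ensemble import AtomMeta, Ensemble
from .forcefield import (AtomDef, BondParam, AngleParam, DihedralParam,
                         ImproperParam, NonbondedParam, ParameterSet,
                         PatchAtomRef, PatchDef, ResidueTopology, TopologySet,
                         NMR_ANGLE_K, NMR_BOND_K, NMR_DIHEDRAL_K, NMR_IMPROPER_K)
from .geometry import place_atom, reflect, signed_dihedral
from .molecule import MoleculeGraph, build_molecule, element_of

BOND_CC = 1.526
BOND_CO = 1.420
BOND_CH = 1.090
BOND_OH = 0.960
TET_ANGLE = math.degrees(math.acos(-1.0 / 3.0))   # 109.471...


_IDEAL_LENGTH = {
    frozenset(("C",)): BOND_CC,
    frozenset(("C", "O")): BOND_CO,
    frozenset(("C", "H")): BOND_CH,
    frozenset(("O", "H")): BOND_OH,
    frozenset(("C", "N")): 1.470,
    frozenset(("N", "H")): 1.010,
    frozenset(("C", "S")): 1.810,
    frozenset(("S", "H")): 1.340,
}


def _bond_length(e1: str, e2: str) -> float:
    try:
        return _IDEAL_LENGTH[frozenset((e1, e2))]
    except KeyError:
        raise ValueError(f"no ideal length for {e1}-{e2}") from None


@dataclass
class FixtureBundle:
    """Everything the test bench needs for one schematic pyranose."""

    topology: TopologySet                 # four-vertex chirality impropers
    topology_heavy: TopologySet           # heavy-atom-only impropers
    parameters: ParameterSet
    molecule: MoleculeGraph               # built from `topology`
    molecule_heavy: MoleculeGraph
    reference_conformation: np.ndarray    # (n, 3) A
    centers: list[ChiralCenter]           # four-vertex, targets from reference
    variants: dict[str, np.ndarray] = field(default_factory=dict)

    def terms(self, mode: str = "four_vertex", include_repel: bool = True) -> TermList:
        """Instantiated term list under either chirality-improper mode."""
        if mode == "four_vertex":
            mol = self.molecule
        elif mode == "heavy_only":
            mol = self.molecule_heavy
        else:
            raise ValueError(f"unknown improper mode {mode!r}")
        return enumerate_terms(mol, self.parameters, include_repel=include_repel)


# ---------------------------------------------------------------------------
# pyranose construction
# ---------------------------------------------------------------------------

_RING = ["O5", "C1", "C2", "C3", "C4", "C5"]

_ATOMS = [
    # name, type
    ("O5", "OE"),
    ("C1", "CC"), ("H1", "HA"), ("O1", "OH"), ("HO1", "HO"),
    ("C2", "CC"), ("H2", "HA"), ("O2", "OH"), ("HO2", "HO"),
    ("C3", "CC"), ("H3", "HA"), ("O3", "OH"), ("HO3", "HO"),
    ("C4", "CC"), ("H4", "HA"), ("O4", "OH"), ("HO4", "HO"),
    ("C5", "CC"), ("H5", "HA"),
    ("C6", "CC"), ("H61", "HA"), ("H62", "HA"), ("O6", "OH"), ("HO6", "HO"),
]

_BONDS = [
    ("O5", "C1"), ("C1", "C2"), ("C2", "C3"), ("C3", "C4"),
    ("C4", "C5"), ("C5", "O5"),
    ("C1", "H1"), ("C1", "O1"), ("O1", "HO1"),
    ("C2", "H2"), ("C2", "O2"), ("O2", "HO2"),
    ("C3", "H3"), ("C3", "O3"), ("O3", "HO3"),
    ("C4", "H4"), ("C4", "O4"), ("O4", "HO4"),
    ("C5", "H5"), ("C5", "C6"),
    ("C6", "H61"), ("C6", "H62"), ("C6", "O6"), ("O6", "HO6"),
]

#: heavy-atom-only chirality impropers (center listed last), the style that
#: leaves hydrogen positions energetically unconstrained
_HEAVY_IMPROPERS = [
    ("O5", "C2", "O1", "C1"),
    ("C1", "C3", "O2", "C2"),
    ("C2", "C4", "O3", "C3"),
    ("C3", "C5", "O4", "C4"),
    ("C4", "O5", "C6", "C5"),
]

_DIHEDRALS = [("C1", "C2", "C3", "C4"), ("O5", "C5", "C6", "O6")]


def _initial_coords(names: list[str]) -> np.ndarray:
    """Approximate ideal chair start, refined later by relaxation."""
    pos: dict[str, np.ndarray] = {}
    # ring by natural extension with alternating +-60 torsions
    pos["O5"] = np.array([0.0, 0.0, 0.0])
    pos["C1"] = np.array([BOND_CO, 0.0, 0.0])
    pos["C2"] = place_atom(pos["O5"] + np.array([0.0, 1.0, 0.0]),
                           pos["O5"], pos["C1"], BOND_CC, TET_ANGLE, 120.0)
    chain = [("C3", "O5", "C1", "C2", BOND_CC, 60.0),
             ("C4", "C1", "C2", "C3", BOND_CC, -60.0),
             ("C5", "C2", "C3", "C4", BOND_CC, 60.0)]
    for name, a, b, c, bond, tor in chain:
        pos[name] = place_atom(pos[a], pos[b], pos[c], bond, TET_ANGLE, tor)

    # substituents of ring carbons: two free tetrahedral directions
    ring_nb = {"C1": ("O5", "C2"), "C2": ("C1", "C3"), "C3": ("C2", "C4"),
               "C4": ("C3", "C5"), "C5": ("C4", "O5")}
    subs = {"C1": ("O1", "H1"), "C2": ("O2", "H2"), "C3": ("O3", "H3"),
            "C4": ("O4", "H4"), "C5": ("C6", "H5")}
    for c, (n1, n2) in ring_nb.items():
        u1 = pos[n1] - pos[c]
        u1 /= np.linalg.norm(u1)
        u2 = pos[n2] - pos[c]
        u2 /= np.linalg.norm(u2)
        e1 = -(u1 + u2)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u1, u2)
        e2 /= np.linalg.norm(e2)
        half = math.radians(TET_ANGLE) / 2.0
        d1 = e1 * math.cos(half) + e2 * math.sin(half)
        d2 = e1 * math.cos(half) - e2 * math.sin(half)
        # alternate which side carries the oxygen so adjacent substituents
        # stagger like an all-equatorial chair would
        flip = c in ("C2", "C4")
        first, second = subs[c]
        da, db = (d2, d1) if flip else (d1, d2)
        pos[first] = pos[c] + da * _bond_length("C", element_of(first))
        pos[second] = pos[c] + db * _bond_length("C", element_of(second))

    # hydroxyl hydrogens anti to the ring carbon's first ring neighbour
    for c, o in [("C1", "O1"), ("C2", "O2"), ("C3", "O3"), ("C4", "O4")]:
        ref = ring_nb[c][0]
        pos["H" + o] = place_atom(pos[ref], pos[c], pos[o], BOND_OH, TET_ANGLE, 180.0)
    # exocyclic arm
    pos["O6"] = place_atom(pos["C4"], pos["C5"], pos["C6"], BOND_CO, TET_ANGLE, 180.0)
    pos["H61"] = place_atom(pos["C4"], pos["C5"], pos["C6"], BOND_CH, TET_ANGLE, 60.0)
    pos["H62"] = place_atom(pos["C4"], pos["C5"], pos["C6"], BOND_CH, TET_ANGLE, -60.0)
    pos["HO6"] = place_atom(pos["C5"], pos["C6"], pos["O6"], BOND_OH, TET_ANGLE, 180.0)
    return np.array([pos[n] for n in names])


def _parameters_for(mol: MoleculeGraph) -> ParameterSet:
    """Complete-by-construction parameter set: one entry per type tuple
    actually occurring in the molecule, at the ideal-geometry targets."""
    pset = ParameterSet()
    types = [a.type_code for a in mol.atoms]
    elems = [a.element for a in mol.atoms]
    seen = set()
    for i, j in mol.bonds:
        key = frozenset((types[i], types[j]))
        if key not in seen:
            seen.add(key)
            pset.bonds.append(BondParam(types[i], types[j], NMR_BOND_K,
                                        _bond_length(elems[i], elems[j])))
    seen = set()
    for i, j, k in mol.angle_triples():
        key = min((types[i], types[j], types[k]), (types[k], types[j], types[i]))
        if key not in seen:
            seen.add(key)
            pset.angles.append(AngleParam(types[i], types[j], types[k],
                                          NMR_ANGLE_K, TET_ANGLE))
    for code in sorted(set(types)):
        pset.nonbonded.append(NonbondedParam(code, 0.1, 2.0))
    return pset


def _relax(coords: np.ndarray, terms: TermList) -> np.ndarray:
    """Drive bond+angle energy to numerical zero (construction-time only)."""
    n = coords.shape[0]

    def fun(x):
        e, g = energy_and_gradient(x.reshape(n, 3), terms)
        return e.total, g.ravel()

    res = _scipy_minimize(fun, coords.ravel(), jac=True, method="L-BFGS-B",
                          options={"maxiter": 20000, "ftol": 1e-18, "gtol": 1e-12})
    return res.x.reshape(n, 3)


def make_pyranose(seed: int = 0) -> FixtureBundle:
    """Build the schematic pyranose bundle.

    The reference conformation is an ideal chair relaxed under the bundle's
    own bond/angle parameters; dihedral and improper targets are then
    *measured* on that geometry, so the full energy at the reference is zero
    by construction.  Variants: ``flipped_H3`` (H3 reflected through C3),
    ``mirror`` (whole-molecule mirror image), ``boat`` (ring flipped to a
    boat), ``noisy`` (0.05 A Gaussian perturbation, seeded).
    """
    names = [n for n, _ in _ATOMS]
    # torsion terms are attached later, once their targets can be measured
    res = ResidueTopology(
        name="PYR",
        atoms=[AtomDef(n, t, 0.0) for n, t in _ATOMS],
        bonds=list(_BONDS),
    )
    tset = TopologySet(residues={"PYR": res})
    mol0 = build_molecule(["PYR"], tset)
    pset = _parameters_for(mol0)

    # relax bonds+angles+repel (no torsion terms exist yet on mol0), so the
    # reference is a minimum of the full energy once measured targets go in
    terms0 = enumerate_terms(mol0, pset, include_repel=True)
    ref = _relax(_initial_coords(names), terms0)

    # measure torsion targets on the relaxed reference
    idx = {n: i for i, n in enumerate(names)}
    dihedral_types = set()
    for quad in _DIHEDRALS:
        tt = tuple(mol0.atoms[idx[n]].type_code for n in quad)
        if tt not in dihedral_types:
            dihedral_types.add(tt)
            val = signed_dihedral(*(ref[idx[n]] for n in quad))
            pset.dihedrals.append(DihedralParam(tt, NMR_DIHEDRAL_K, 0, val))

    centers = measure_centers(mol0, ref)
    four_vertex = []
    fv_targets = {}
    for c in centers:
        quad = tuple(mol0.atoms[v].name for v in c.vertices)
        four_vertex.append(quad)
        fv_targets[quad] = c.target_improper
    heavy_targets = {}
    for quad in _HEAVY_IMPROPERS:
        heavy_targets[quad] = signed_dihedral(*(ref[idx[n]] for n in quad))

    res_fv = ResidueTopology(name="PYR", atoms=res.atoms, bonds=res.bonds,
                             dihedrals=list(_DIHEDRALS),
                             impropers=four_vertex, improper_targets=fv_targets)
    res_heavy = ResidueTopology(name="PYR", atoms=res.atoms, bonds=res.bonds,
                                dihedrals=list(_DIHEDRALS),
                                impropers=list(_HEAVY_IMPROPERS),
                                improper_targets=heavy_targets)
    top_fv = TopologySet(residues={"PYR": res_fv})
    top_heavy = TopologySet(residues={"PYR": res_heavy})
    mol_fv = build_molecule(["PYR"], top_fv)
    mol_heavy = build_molecule(["PYR"], top_heavy)

    # re-measure centers on the final molecule (same indices as mol0)
    centers = measure_centers(mol_fv, ref)

    rng = np.random.default_rng(seed)
    variants = {
        "flipped_H3": flip_hydrogen(ref, idx["C3"], idx["H3"]),
        "mirror": reflect(ref),
        "boat": _boat_variant(ref, idx),
        "noisy": ref + rng.normal(scale=0.05, size=ref.shape),
    }
    return FixtureBundle(top_fv, top_heavy, pset, mol_fv, mol_heavy, ref,
                         centers, variants)


def _boat_variant(ref: np.ndarray, idx: dict[str, int]) -> np.ndarray:
    """Push O5 and C3 to the same side of the C1-C2-C4-C5 plane (a crude
    boat; only the ring geometry is meaningful in this variant)."""
    out = np.array(ref, copy=True)
    plane = [idx[n] for n in ("C1", "C2", "C4", "C5")]
    centroid = out[plane].mean(axis=0)
    u, s, vt = np.linalg.svd(out[plane] - centroid)
    normal = vt[2]
    for name in ("O5", "C3"):
        i = idx[name]
        d = out[i] - centroid
        h = float(d @ normal)
        target = abs(h)
        out[i] = out[i] + (target - h) * normal
    return out


# ---------------------------------------------------------------------------
# companion residues for patching and coverage experiments
# ---------------------------------------------------------------------------

def make_serine_like() -> ResidueTopology:
    """Minimal Ser-like acceptor: CA-CB(-HB1,HB2)-OG-HG, enough to receive
    an O-glycosylation patch."""
    atoms = [AtomDef("CA", "CC"), AtomDef("HA", "HA"),
             AtomDef("CB", "CC"), AtomDef("HB1", "HA"), AtomDef("HB2", "HA"),
             AtomDef("OG", "OH"), AtomDef("HG", "HO")]
    bonds = [("CA", "HA"), ("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"),
             ("CB", "OG"), ("OG", "HG")]
    return ResidueTopology("SER", atoms, bonds)


def make_cysteine_like() -> ResidueTopology:
    atoms = [AtomDef("CA", "CC"), AtomDef("HA", "HA"),
             AtomDef("CB", "CC"), AtomDef("HB1", "HA"), AtomDef("HB2", "HA"),
             AtomDef("SG", "SH"), AtomDef("HG", "HO")]
    bonds = [("CA", "HA"), ("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"),
             ("CB", "SG"), ("SG", "HG")]
    return ResidueTopology("CYS", atoms, bonds)


def beta14_patch() -> PatchDef:
    """A beta(1,4)-style sugar-sugar condensation patch for two pyranoses:
    bond 1-C1 to 2-O4, eliminating the donor anomeric hydroxyl and the
    acceptor hydroxyl hydrogen."""
    r1 = lambda n: PatchAtomRef(1, n)
    r2 = lambda n: PatchAtomRef(2, n)
    return PatchDef(
        name="B14F",
        deleted_atoms=[r1("O1"), r1("HO1"), r2("HO4")],
        added_bonds=[(r1("C1"), r2("O4"))],
        added_impropers=[((r1("H1"), r1("O5"), r1("C2"), r2("O4")),
                          math.degrees(math.acos(1.0 / 3.0)))],
    )


def make_amide_fixture() -> tuple[MoleculeGraph, ParameterSet, ParameterSet]:
    """An N-acetyl-sugar-like residue bearing a peptide bond on its ring,
    with three planarity/chirality impropers across the amide.

    Returns ``(molecule, complete_params, stripped_params)`` where the
    stripped set lacks exactly the three amide improper entries — emulating
    the parameter gap that aborts a structure calculation the moment the
    amide improper terms are instantiated.
    """
    atoms = [AtomDef("C1", "CC"), AtomDef("C2", "CC"), AtomDef("H2", "HA"),
             AtomDef("N2", "NH"), AtomDef("HN2", "HN"),
             AtomDef("C7", "CO"), AtomDef("O7", "OC"), AtomDef("C8", "CC"),
             AtomDef("H81", "HA"), AtomDef("H82", "HA"), AtomDef("H83", "HA")]
    bonds = [("C1", "C2"), ("C2", "H2"), ("C2", "N2"), ("N2", "HN2"),
             ("N2", "C7"), ("C7", "O7"), ("C7", "C8"),
             ("C8", "H81"), ("C8", "H82"), ("C8", "H83")]
    impropers = [("C2", "C7", "HN2", "N2"),    # amide nitrogen planarity
                 ("N2", "O7", "C8", "C7"),     # carbonyl carbon planarity
                 ("HN2", "C2", "N2", "C7")]    # trans-amide torsion lock
    res = ResidueTopology("NAG", atoms, bonds, impropers=impropers)
    mol = build_molecule(["NAG"], TopologySet(residues={"NAG": res}))
    pset = _parameters_for(mol)
    complete = ParameterSet(bonds=list(pset.bonds), angles=list(pset.angles),
                            nonbonded=list(pset.nonbonded))
    types = [a.type_code for a in mol.atoms]
    names = [a.name for a in mol.atoms]
    for quad, _ in mol.explicit_impropers:
        complete.impropers.append(ImproperParam(
            tuple(types[i] for i in quad), NMR_IMPROPER_K, 0, 0.0))
    stripped = ParameterSet(bonds=list(complete.bonds), angles=list(complete.angles),
                            nonbonded=list(complete.nonbonded))
    return mol, complete, stripped


# ---------------------------------------------------------------------------
# ideal ring-only conformations for pucker tests
# ---------------------------------------------------------------------------

def ideal_ring(kind: str, radius: float = 1.45, amplitude: float = 0.25) -> np.ndarray:
    """Six ring-atom coordinates with an exactly known Cremer-Pople class:
    ``planar`` (amplitude 0), ``chair`` (alternating +-z) or ``boat``
    (cos(2*phase) z pattern)."""
    j = np.arange(6)
    x = radius * np.cos(2 * np.pi * j / 6)
    y = radius * np.sin(2 * np.pi * j / 6)
    if kind == "planar":
        z = np.zeros(6)
    elif kind == "chair":
        z = amplitude * (-1.0) ** j
    elif kind == "boat":
        z = amplitude * np.cos(4 * np.pi * j / 6)
    else:
        raise ValueError(f"unknown ideal ring kind {kind!r}")
    return np.column_stack([x, y, z])


# ---------------------------------------------------------------------------
# randomized topologies / parameters for round-trip fuzzing
# ---------------------------------------------------------------------------

_NAME_CHARS = "ABCDEFGHIKLMNOPQRSTUVWYZ"


def make_random_topology(seed: int, n_residues: int = 3, n_patches: int = 2) -> TopologySet:
    """Valid-by-construction random TopologySet, deterministic per seed."""
    rng = np.random.default_rng(seed)
    tset = TopologySet(autogenerate_angles=bool(rng.integers(2)),
                       autogenerate_dihedrals=bool(rng.integers(2)))
    used = set()
    for _ in range(n_residues):
        while True:
            rname = "".join(rng.choice(list(_NAME_CHARS), size=3))
            if rname not in used:
                used.add(rname)
                break
        n_atoms = int(rng.integers(2, 9))
        atoms = []
        for i in range(n_atoms):
            el = rng.choice(["C", "O", "H", "N"])
            atoms.append(AtomDef(f"{el}{i + 1}",
                                 f"{el}T{rng.integers(1, 4)}",
                                 round(float(rng.normal(scale=0.3)), 4)))
        names = [a.name for a in atoms]
        bonds = [(names[i], names[int(rng.integers(0, i))])
                 for i in range(1, n_atoms)]           # random spanning tree
        res = ResidueTopology(rname, atoms, bonds)
        if n_atoms >= 4 and rng.integers(2):
            quad = tuple(rng.choice(names, size=4, replace=False))
            res.impropers.append(quad)
            if rng.integers(2):
                res.improper_targets[quad] = round(float(rng.uniform(-170, 170)), 4)
        res.validate()
        tset.residues[rname] = res
    for _ in range(n_patches):
        while True:
            pname = "".join(rng.choice(list(_NAME_CHARS), size=3)) + "P"
            if pname not in tset.patches and pname not in used:
                break
        patch = PatchDef(pname)
        patch.deleted_atoms.append(PatchAtomRef(1, "O1"))
        patch.added_bonds.append((PatchAtomRef(1, "C1"), PatchAtomRef(2, "O2")))
        if rng.integers(2):
            patch.added_impropers.append(
                ((PatchAtomRef(1, "H1"), PatchAtomRef(1, "C2"),
                  PatchAtomRef(1, "O1"), PatchAtomRef(2, "O2")),
                 round(float(rng.uniform(-170, 170)), 4)))
        tset.patches[pname] = patch
    return tset


def make_random_parameters(seed: int) -> ParameterSet:
    rng = np.random.default_rng(seed)
    pset = ParameterSet()
    codes = [f"T{i}" for i in range(1, 1 + int(rng.integers(3, 7)))]
    for a, b in itertools.combinations_with_replacement(codes, 2):
        if rng.random() < 0.6:
            pset.bonds.append(BondParam(a, b, round(float(rng.uniform(100, 1200)), 3),
                                        round(float(rng.uniform(0.9, 1.8)), 4)))
    for _ in range(int(rng.integers(2, 8))):
        a, b, c = rng.choice(codes, size=3)
        pset.angles.append(AngleParam(a, b, c, round(float(rng.uniform(50, 600)), 3),
                                      round(float(rng.uniform(90, 125)), 3)))
    for _ in range(int(rng.integers(1, 5))):
        quad = tuple(rng.choice(codes + ["X"], size=4))
        n = int(rng.integers(0, 4))
        pset.dihedrals.append(DihedralParam(quad, round(float(rng.uniform(0.5, 4)), 3),
                                            n, round(float(rng.uniform(-180, 180)), 3)))
    for _ in range(int(rng.integers(1, 5))):
        quad = tuple(rng.choice(codes, size=4))
        pset.impropers.append(ImproperParam(quad, round(float(rng.uniform(100, 600)), 3),
                                            0, round(float(rng.uniform(-75, 75)), 3)))
    for code in codes:
        pset.nonbonded.append(NonbondedParam(code, round(float(rng.uniform(0.05, 0.3)), 4),
                                             round(float(rng.uniform(1.5, 3.5)), 4)))
    return pset


# ---------------------------------------------------------------------------
# torsion ensembles with exactly known phi/psi
# ---------------------------------------------------------------------------

def make_torsion_ensemble(phi_list, psi_list) -> Ensemble:
    """One model per (phi, psi): a schematic sugar (O5, C1, H1) O-linked to a
    threonine-like acceptor (OG1, CB, CA), built so that the heavy-atom
    glycosidic torsions are exactly the requested values."""
    if len(phi_list) != len(psi_list):
        raise ValueError("phi and psi lists must have equal length")
    atoms = [
        AtomMeta("A", 1, "SUG", "O5", "O", het=True),
        AtomMeta("A", 1, "SUG", "C1", "C", het=True),
        AtomMeta("A", 1, "SUG", "H1", "H", het=True),
        AtomMeta("A", 2, "THR", "OG1", "O"),
        AtomMeta("A", 2, "THR", "CB", "C"),
        AtomMeta("A", 2, "THR", "CA", "C"),
    ]
    models = []
    for phi, psi in zip(phi_list, psi_list):
        o5 = np.array([0.0, 0.0, 0.0])
        c1 = np.array([BOND_CO, 0.0, 0.0])
        og = place_atom(o5 + np.array([0.0, 1.0, 0.0]), o5, c1,
                        BOND_CO, TET_ANGLE, 137.0)
        cb = place_atom(o5, c1, og, BOND_CO, TET_ANGLE, float(phi))
        ca = place_atom(c1, og, cb, BOND_CC, TET_ANGLE, float(psi))
        h1 = place_atom(og, o5, c1, BOND_CH, TET_ANGLE, 121.0)
        models.append(np.stack([o5, c1, h1, og, cb, ca]))
    return Ensemble(atoms, np.stack(models))
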