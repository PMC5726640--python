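"""Term enumeration and the energy/gradient kernels, checked against
independent literal-transcription oracles and finite differences."""

import math

import numpy as np
import pytest

import glycotop as gt
from glycotop.energetics import EnergyError, TermList
from glycotop.forcefield import NMR_ANGLE_K


# ---------------------------------------------------------------------------
# term enumeration
# ---------------------------------------------------------------------------

def _tiny_molecule(n, bonds):
    from glycotop.molecule import Atom, MoleculeGraph
    atoms = [Atom(0, "TST", f"C{i+1}", "CT", 0.0) for i in range(n)]
    return MoleculeGraph(atoms, bonds)


def _tiny_params():
    return gt.ParameterSet(
        bonds=[gt.BondParam("CT", "CT", 1000.0, 1.5)],
        angles=[gt.AngleParam("CT", "CT", "CT", 500.0, 109.47)],
        nonbonded=[gt.NonbondedParam("CT", 0.1, 2.0)])


def test_two_bonds_make_one_autogenerated_angle():
    mol = _tiny_molecule(3, [(0, 1), (1, 2)])
    terms = gt.enumerate_terms(mol, _tiny_params())
    assert len(terms.bond_idx) == 2
    assert len(terms.angle_idx) == 1


@pytest.mark.parametrize("n", [2, 5, 9])
def test_linear_chain_counting(n):
    mol = _tiny_molecule(n, [(i, i + 1) for i in range(n - 1)])
    terms = gt.enumerate_terms(mol, _tiny_params())
    assert len(terms.bond_idx) == n - 1
    assert len(terms.angle_idx) == n - 2


def test_coverage_gap_raises_listing_tuples():
    mol = _tiny_molecule(2, [(0, 1)])
    with pytest.raises(EnergyError, match="bond"):
        gt.enumerate_terms(mol, gt.ParameterSet())


def test_pyranose_term_counts_match_brute_force(bundle):
    """Independent enumerator: angles as all j-centred neighbour pairs,
    repel pairs by explicit breadth-first bond distance."""
    mol = bundle.molecule
    terms = bundle.terms("four_vertex")
    adj = {i: set() for i in range(len(mol.atoms))}
    for a, b in mol.bonds:
        adj[a].add(b)
        adj[b].add(a)
    n_angles = sum(len(nb) * (len(nb) - 1) // 2 for nb in adj.values())
    assert len(terms.angle_idx) == n_angles

    def bfs_dist(src):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    n_repel = 0
    for i in range(len(mol.atoms)):
        d = bfs_dist(i)
        n_repel += sum(1 for j, dj in d.items() if j > i and dj >= 3)
    assert len(terms.repel_idx) == n_repel
    assert len(terms.bond_idx) == len(mol.bonds)
    assert len(terms.impr_idx) == len(mol.explicit_impropers)


def test_repel_list_never_contains_bonded_pairs(bundle):
    terms = bundle.terms("four_vertex")
    bonded = {frozenset(b) for b in map(tuple, terms.bond_idx)}
    onethree = {frozenset((i, k)) for i, _, k in map(tuple, terms.angle_idx)}
    for pair in map(tuple, terms.repel_idx):
        assert frozenset(pair) not in bonded
        assert frozenset(pair) not in onethree


# ---------------------------------------------------------------------------
# energy values
# ---------------------------------------------------------------------------

def test_equilibrium_geometry_has_zero_bonded_energy(bundle):
    e = gt.energy(bundle.reference_conformation, bundle.terms("four_vertex"))
    assert e.bond + e.angle + e.improper < 1e-9
    assert e.total == pytest.approx(e.bond + e.angle + e.dihedral + e.improper + e.repel,
                                    rel=1e-9)


def test_single_bond_arithmetic():
    """k=1000, |b-b0| = 0.1 A -> E = 10 kcal/mol."""
    terms = TermList(n_atoms=2, bond_idx=np.array([[0, 1]]),
                     bond_k=np.array([1000.0]), bond_b0=np.array([1.5]))
    coords = np.array([[0.0, 0.0, 0.0], [1.6, 0.0, 0.0]])
    assert gt.energy(coords, terms).bond == pytest.approx(10.0, rel=1e-12)


def _literal_oracle(coords, terms):
    """Scalar transcription of the functional forms, term by term."""
    def wrap(x):
        while x <= -math.pi:
            x += 2 * math.pi
        while x > math.pi:
            x -= 2 * math.pi
        return x

    e = 0.0
    for (i, j), k, b0 in zip(terms.bond_idx, terms.bond_k, terms.bond_b0):
        e += k * (np.linalg.norm(coords[i] - coords[j]) - b0) ** 2
    for (i, j, kk), k, t0 in zip(terms.angle_idx, terms.angle_k, terms.angle_theta0):
        u = coords[i] - coords[j]
        v = coords[kk] - coords[j]
        th = math.acos(np.clip(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1))
        e += k * (th - t0) ** 2
    for quad, k, n, d in zip(terms.dihe_idx, terms.dihe_k, terms.dihe_n, terms.dihe_delta):
        phi = math.radians(gt.signed_dihedral(*(coords[q] for q in quad)))
        if n > 0:
            e += k * (1 + math.cos(n * phi - d))
        else:
            e += k * wrap(phi - d) ** 2
    for quad, k, p0 in zip(terms.impr_idx, terms.impr_k, terms.impr_phi0):
        phi = math.radians(gt.signed_dihedral(*(coords[q] for q in quad)))
        e += k * wrap(phi - p0) ** 2
    for (i, j), s in zip(terms.repel_idx, terms.repel_sigma):
        r2 = float(np.sum((coords[i] - coords[j]) ** 2))
        viol = max(0.0, (terms.repel_scale * s) ** 2 - r2)
        e += terms.repel_k * viol ** 2
    return e


def test_energy_matches_literal_transcription_oracle(bundle):
    terms = bundle.terms("four_vertex")
    rng = np.random.default_rng(7)
    worst = 0.0
    for _ in range(200):
        coords = bundle.reference_conformation + rng.normal(scale=0.15,
                                                            size=bundle.reference_conformation.shape)
        mine = gt.energy(coords, terms).total
        ref = _literal_oracle(coords, terms)
        worst = max(worst, abs(mine - ref) / max(abs(ref), 1e-300))
    assert worst < 1e-12


def test_energy_invariant_under_rigid_motion(bundle, rng):
    from glycotop.geometry import random_rotation
    terms = bundle.terms("four_vertex")
    coords = bundle.variants["noisy"]
    e0 = gt.energy(coords, terms).total
    for _ in range(5):
        moved = coords @ random_rotation(rng).T + rng.normal(size=3) * 10
        assert gt.energy(moved, terms).total == pytest.approx(e0, rel=1e-9)


def test_improper_wrap_at_180():
    """Harmonic impropers measure the minimal-image difference: at -170 deg
    with target +170 deg the deviation is 20 deg, not 340."""
    terms = TermList(n_atoms=4, impr_idx=np.array([[0, 1, 2, 3]]),
                     impr_k=np.array([1.0]), impr_phi0=np.radians([170.0]))
    def conf(phi):
        from glycotop.geometry import place_atom
        a = np.array([0.0, 1.4, 0.0])
        b = np.array([0.0, 0.0, 0.0])
        c = np.array([1.5, 0.0, 0.0])
        d = place_atom(a, b, c, 1.4, 111.0, phi)
        return np.stack([a, b, c, d])
    e_minus170 = gt.energy(conf(-170.0), terms).total
    expected = math.radians(20.0) ** 2
    assert e_minus170 == pytest.approx(expected, rel=1e-6)
    # and the +190 representation is the same physical angle
    e_190 = gt.energy(conf(190.0), terms).total
    assert e_190 == pytest.approx(e_minus170, rel=1e-9)


def test_angle_constant_is_not_smaller_than_restraint_constants():
    """The harmonized angle energy must dominate typical experimental
    restraint force constants (~50 kcal/mol for NOE wells, ~200 for
    dihedral restraints), otherwise covalent geometry yields to restraints."""
    assert NMR_ANGLE_K >= 200.0


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def test_gradient_zero_at_minimum(bundle):
    g = gt.gradient(bundle.reference_conformation, bundle.terms("four_vertex"))
    assert np.linalg.norm(g) < 1e-6


def test_gradient_sums_to_zero(bundle):
    g = gt.gradient(bundle.variants["noisy"], bundle.terms("four_vertex"))
    assert np.abs(g.sum(axis=0)).max() < 1e-9


def test_gradient_matches_finite_differences(bundle):
    terms = bundle.terms("four_vertex")
    rng = np.random.default_rng(11)
    h = 1e-5
    for _ in range(50):
        coords = bundle.reference_conformation + rng.normal(
            scale=0.1, size=bundle.reference_conformation.shape)
        g = gt.gradient(coords, terms)
        # probe 6 random components per conformation
        for _ in range(6):
            i = int(rng.integers(coords.shape[0]))
            d = int(rng.integers(3))
            cp = coords.copy()
            cp[i, d] += h
            cm = coords.copy()
            cm[i, d] -= h
            num = (gt.energy(cp, terms).total - gt.energy(cm, terms).total) / (2 * h)
            scale = max(abs(num), np.abs(g).max(), 1.0)
            assert abs(g[i, d] - num) / scale < 1e-6
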