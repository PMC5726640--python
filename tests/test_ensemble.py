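"""Ensemble I/O, circular torsion statistics, superposed RMSD and
Cremer-Pople pucker classification."""

import numpy as np
import pytest

import glycotop as gt
from glycotop.ensemble import EnsembleError
from glycotop.fixtures import ideal_ring


@pytest.fixture(scope="module")
def pyr_ensemble(bundle):
    atoms = [gt.AtomMeta("A", 1, "PYR", a.name, a.element, het=True)
             for a in bundle.molecule.atoms]
    coords = np.stack([bundle.reference_conformation,
                       bundle.variants["noisy"],
                       bundle.variants["boat"]])
    return gt.Ensemble(atoms, coords)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_single_model_roundtrip(pyr_ensemble):
    one = gt.Ensemble(pyr_ensemble.atoms, pyr_ensemble.coords[:1])
    back = gt.read_ensemble(gt.write_ensemble(one))
    assert back.n_models == 1


def test_multi_model_roundtrip_to_three_decimals(pyr_ensemble):
    back = gt.read_ensemble(gt.write_ensemble(pyr_ensemble))
    assert back.n_models == pyr_ensemble.n_models
    assert [a.key() for a in back.atoms] == [a.key() for a in pyr_ensemble.atoms]
    assert np.abs(back.coords - pyr_ensemble.coords).max() < 5e-4 + 1e-9


def test_hetatm_flag_and_metadata_survive(pyr_ensemble):
    back = gt.read_ensemble(gt.write_ensemble(pyr_ensemble))
    assert all(a.het for a in back.atoms)
    assert back.atoms[0].resname == "PYR"
    assert back.atoms[0].chain == "A"


def test_roster_mismatch_between_models_is_an_error(pyr_ensemble):
    text = gt.write_ensemble(pyr_ensemble)
    # drop one atom line from the second model only
    lines = text.splitlines()
    second_model = [i for i, l in enumerate(lines) if l.startswith("MODEL")][1]
    del lines[second_model + 3]
    with pytest.raises(EnsembleError, match="model 2"):
        gt.read_ensemble("\n".join(lines))


# ---------------------------------------------------------------------------
# circular statistics and torsions
# ---------------------------------------------------------------------------

def test_circular_mean_wraps_correctly():
    assert gt.circular_mean_deg([179.0, -179.0]) == pytest.approx(180.0)
    assert gt.circular_mean_deg([10.0, 20.0]) == pytest.approx(15.0)
    assert gt.circular_std_deg([42.0]) == pytest.approx(0.0)


def test_single_model_ensemble_has_zero_sd():
    e = gt.make_torsion_ensemble([73.0], [-115.0])
    r = gt.glycosidic_torsions(e, gt.Linkage(("A", 1), ("A", 2),
                                             ("OG1", "CB", "CA"), "x"))
    assert (r.phi_sd, r.psi_sd) == (0.0, 0.0)
    assert r.phi_mean == pytest.approx(73.0)
    assert r.psi_mean == pytest.approx(-115.0)


@pytest.mark.parametrize("phi, psi", [(60.0, -30.0), (-46.5, 92.7), (53.4, 29.3),
                                      (179.5, -179.5)])
def test_constructed_torsions_recovered_exactly(phi, psi):
    e = gt.make_torsion_ensemble([phi], [psi])
    link = gt.Linkage.from_kind(("A", 1), ("A", 2), "thr")
    r = gt.glycosidic_torsions(e, link)
    assert abs(float(gt.wrap_deg(r.phi[0] - phi))) < 1e-6
    assert abs(float(gt.wrap_deg(r.psi[0] - psi))) < 1e-6


def test_h1_convention_differs_from_heavy():
    e = gt.make_torsion_ensemble([60.0], [-30.0])
    link = gt.Linkage.from_kind(("A", 1), ("A", 2), "thr")
    heavy = gt.glycosidic_torsions(e, link, convention="heavy")
    h1 = gt.glycosidic_torsions(e, link, convention="h1")
    assert heavy.phi[0] != pytest.approx(h1.phi[0])
    assert heavy.psi[0] == pytest.approx(h1.psi[0])     # psi shares no H1


def test_missing_atom_named_in_error():
    e = gt.make_torsion_ensemble([60.0], [-30.0])
    link = gt.Linkage(("A", 1), ("A", 2), ("OG9", "CB", "CA"), "bad")
    with pytest.raises(EnsembleError, match="OG9"):
        gt.glycosidic_torsions(e, link)


def test_wrap_mean_of_wide_ensemble():
    e = gt.make_torsion_ensemble([179.0, -179.0], [10.0, 10.0])
    link = gt.Linkage.from_kind(("A", 1), ("A", 2), "thr")
    r = gt.glycosidic_torsions(e, link)
    assert r.phi_mean == pytest.approx(180.0)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def test_identical_models_have_zero_rmsd(pyr_ensemble):
    e = gt.Ensemble(pyr_ensemble.atoms,
                    np.stack([pyr_ensemble.coords[0]] * 4))
    r = gt.ensemble_rmsd(e, lambda a: a.element != "H")
    assert r.mean_rmsd == 0.0


def test_rigid_transforms_do_not_change_rmsd(pyr_ensemble, rng):
    from glycotop.geometry import random_rotation
    base = pyr_ensemble.coords
    moved = np.stack([c @ random_rotation(rng).T + rng.normal(size=3) * 8
                      for c in base])
    sel = lambda a: a.element != "H"
    r0 = gt.ensemble_rmsd(pyr_ensemble, sel)
    r1 = gt.ensemble_rmsd(gt.Ensemble(pyr_ensemble.atoms, moved), sel)
    assert r1.mean_rmsd == pytest.approx(r0.mean_rmsd, abs=1e-6)
    assert r1.per_model == pytest.approx(r0.per_model, abs=1e-6)


def test_two_models_differing_by_rotation_superpose_to_zero(pyr_ensemble, rng):
    from glycotop.geometry import random_rotation
    c0 = pyr_ensemble.coords[0]
    e = gt.Ensemble(pyr_ensemble.atoms,
                    np.stack([c0, c0 @ random_rotation(rng).T + 3.0]))
    for mode in ("pairwise", "to_mean"):
        assert gt.ensemble_rmsd(e, lambda a: True, mode=mode).mean_rmsd == 0.0


def test_selection_smaller_than_three_atoms_rejected(pyr_ensemble):
    with pytest.raises(EnsembleError, match="need >= 3"):
        gt.ensemble_rmsd(pyr_ensemble, lambda a: a.name == "C1")


def _quaternion_rmsd(P, Q):
    """Horn's closed-form quaternion superposition as an independent oracle."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    Sxx = P.T @ Q
    K = np.empty((4, 4))
    K[0, 0] = Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2]
    K[0, 1] = K[1, 0] = Sxx[1, 2] - Sxx[2, 1]
    K[0, 2] = K[2, 0] = Sxx[2, 0] - Sxx[0, 2]
    K[0, 3] = K[3, 0] = Sxx[0, 1] - Sxx[1, 0]
    K[1, 1] = Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2]
    K[1, 2] = K[2, 1] = Sxx[0, 1] + Sxx[1, 0]
    K[1, 3] = K[3, 1] = Sxx[0, 2] + Sxx[2, 0]
    K[2, 2] = -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2]
    K[2, 3] = K[3, 2] = Sxx[1, 2] + Sxx[2, 1]
    K[3, 3] = -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P ** 2) + np.sum(Q ** 2) - 2.0 * lam) / P.shape[0]
    return np.sqrt(max(msd, 0.0))


def test_kabsch_agrees_with_quaternion_oracle():
    rng = np.random.default_rng(99)
    from glycotop.geometry import kabsch
    worst = 0.0
    for _ in range(100):
        n = int(rng.integers(4, 40))
        P = rng.normal(size=(n, 3)) * 5
        Q = rng.normal(size=(n, 3)) * 5
        worst = max(worst, abs(kabsch(P, Q)[2] - _quaternion_rmsd(P, Q)))
    assert worst < 1e-9


# ---------------------------------------------------------------------------
# ring pucker
# ---------------------------------------------------------------------------

def test_planar_hexagon_is_planar():
    r = gt.ring_pucker(ideal_ring("planar"), range(6))
    assert r.Q == pytest.approx(0.0, abs=1e-12)
    assert r.label == "planar"


def test_ideal_chair_classification():
    r = gt.ring_pucker(ideal_ring("chair"), range(6))
    assert r.theta <= 10.0 or r.theta >= 170.0
    assert r.label == "chair"


def test_ideal_boat_classification():
    r = gt.ring_pucker(ideal_ring("boat"), range(6))
    assert r.theta == pytest.approx(90.0, abs=1e-9)
    assert r.label == "boat"


def test_relaxed_pyranose_ring_is_a_chair(bundle, ring_indices):
    r = gt.ring_pucker(bundle.reference_conformation, ring_indices)
    assert r.label == "chair"
    assert r.Q > 0.4


def test_boat_variant_classifies_off_chair(bundle, ring_indices):
    r = gt.ring_pucker(bundle.variants["boat"], ring_indices)
    assert r.label in ("boat", "twist-boat", "envelope/half-chair")


def test_wrong_ring_size_rejected(bundle, ring_indices):
    with pytest.raises(EnsembleError):
        gt.ring_pucker(bundle.reference_conformation, ring_indices[:5])


# ---------------------------------------------------------------------------
# cross-module mirror consistency
# ---------------------------------------------------------------------------

def test_mirroring_flips_torsions_chair_hand_and_chirality(bundle, ring_indices):
    """One reflection, three synchronized consequences: phi/psi negate,
    Cremer-Pople theta flips to 180-theta, and every stereocenter reports a
    violation."""
    from glycotop.geometry import reflect
    e = gt.make_torsion_ensemble([60.0], [-30.0])
    mirrored = gt.Ensemble(e.atoms, np.stack([reflect(e.coords[0])]))
    link = gt.Linkage.from_kind(("A", 1), ("A", 2), "thr")
    r0 = gt.glycosidic_torsions(e, link)
    r1 = gt.glycosidic_torsions(mirrored, link)
    assert r1.phi[0] == pytest.approx(-r0.phi[0], abs=1e-9)
    assert r1.psi[0] == pytest.approx(-r0.psi[0], abs=1e-9)

    p0 = gt.ring_pucker(bundle.reference_conformation, ring_indices)
    p1 = gt.ring_pucker(reflect(bundle.reference_conformation), ring_indices)
    assert p1.theta == pytest.approx(180.0 - p0.theta, abs=1e-6)

    assert len(gt.check_chirality(bundle.variants["mirror"], bundle.centers)) == \
        len(bundle.centers)
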