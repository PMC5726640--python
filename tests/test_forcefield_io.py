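"""Topology/parameter dialect round-tripping, energy harmonization, lookup
semantics and parameter-coverage checking."""

import pytest

import glycotop as gt
from glycotop.forcefield import ForceFieldError


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def test_empty_topology_text_parses_to_empty_set():
    t = gt.parse_topology("")
    assert t.residues == {} and t.patches == {}


def test_minimal_residue_block():
    t = gt.parse_topology("""
        RESIdue TST
          ATOM C1 TYPE=CT CHARge=0.1 END
          ATOM O1 TYPE=OT CHARge=-0.4 END
          BOND C1 O1
        END
    """)
    res = t.residues["TST"]
    assert [a.name for a in res.atoms] == ["C1", "O1"]
    assert res.atoms[0].type_code == "CT"
    assert res.atoms[1].charge == -0.4
    assert res.bonds == [("C1", "O1")]


def test_keywords_matched_case_insensitively_on_four_chars():
    t = gt.parse_topology(
        "residue abc\n  atom C1 type=CT charGE=0.0 end\n  AtOm C2 TYPE=CT END\n"
        "  bonD C1 C2\nEnd\n")
    assert list(t.residues) == ["ABC"]
    assert t.residues["ABC"].bonds == [("C1", "C2")]


def test_comments_and_continuation_lines():
    t = gt.parse_topology(
        "! a file comment\nRESIdue XYZ ! trailing\n  ATOM C1 \\\n"
        "    TYPE=CT CHARge=0.5 END\nEND\n")
    assert t.residues["XYZ"].atoms[0].charge == 0.5


@pytest.mark.parametrize("text, fragment", [
    ("RESIdue AAA\n  ATOM C1 TYPE=CT END\n", "not terminated"),
    ("RESIdue AAA\nEND\nRESIdue AAA\nEND\n", "duplicate residue"),
    ("RESIdue AAA\n  ATOM C1 TYPE=CT END\n  BOND C1 C2\nEND\n", "undefined atom"),
])
def test_malformed_topology_raises_with_context(text, fragment):
    with pytest.raises(ForceFieldError, match=fragment):
        gt.parse_topology(text)


def test_parse_error_carries_line_number():
    with pytest.raises(ForceFieldError, match="line 1"):
        gt.parse_topology("RESIdue AAA\n  ATOM C1 TYPE=CT END\n")


@pytest.mark.parametrize("seed", range(50))
def test_topology_roundtrip_on_randomized_sets(seed):
    t = gt.make_random_topology(seed)
    assert gt.parse_topology(gt.write_topology(t)) == t


def test_topology_write_is_deterministic():
    a = gt.write_topology(gt.make_random_topology(7))
    b = gt.write_topology(gt.make_random_topology(7))
    assert a == b


def test_single_bond_param_statement():
    p = gt.parse_parameters("BOND CC OC 1000.0 1.43\n")
    assert len(p.bonds) == 1
    bp = p.bonds[0]
    assert (bp.k, bp.b0) == (1000.0, 1.43)


def test_empty_parameter_text():
    p = gt.parse_parameters("")
    assert p == gt.ParameterSet()


@pytest.mark.parametrize("seed", range(50))
def test_parameter_roundtrip_on_randomized_sets(seed):
    p = gt.make_random_parameters(seed)
    assert gt.parse_parameters(gt.write_parameters(p)) == p


def test_pyranose_files_roundtrip(bundle):
    assert gt.parse_topology(gt.write_topology(bundle.topology)) == bundle.topology
    assert gt.parse_parameters(gt.write_parameters(bundle.parameters)) == bundle.parameters


def test_malformed_parameter_statement_reports_line():
    with pytest.raises(ForceFieldError, match="line 2"):
        gt.parse_parameters("BOND CC OC 1000.0 1.43\nANGLe CC OC 12\n")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def test_harmonize_applies_the_protocol_constants():
    p = gt.harmonize_energies(gt.make_random_parameters(3))
    assert all(b.k == 1000.0 for b in p.bonds)
    assert all(a.k == 500.0 for a in p.angles)
    assert all(i.k == 500.0 for i in p.impropers)
    assert all(d.k == 2.0 for d in p.dihedrals)


def test_harmonize_preserves_geometry_targets_and_nonbonded():
    before = gt.make_random_parameters(11)
    after = gt.harmonize_energies(before)
    assert [b.b0 for b in after.bonds] == [b.b0 for b in before.bonds]
    assert [a.theta0 for a in after.angles] == [a.theta0 for a in before.angles]
    assert [(d.periodicity, d.delta) for d in after.dihedrals] == \
           [(d.periodicity, d.delta) for d in before.dihedrals]
    assert after.nonbonded == before.nonbonded


def test_harmonize_is_idempotent_and_empty_safe():
    p = gt.make_random_parameters(5)
    once = gt.harmonize_energies(p)
    assert gt.harmonize_energies(once) == once
    assert gt.harmonize_energies(gt.ParameterSet()) == gt.ParameterSet()


def test_harmonize_rejects_negative_constants():
    with pytest.raises(ForceFieldError):
        gt.harmonize_energies(gt.ParameterSet(), k_bond=-1.0)


# ---------------------------------------------------------------------------
# lookup semantics vs a brute-force matcher
# ---------------------------------------------------------------------------

def _brute_dihedral(entries, quad):
    """Independent matcher: enumerate all entries both ways, keep the last
    among those with the fewest wildcards."""
    hits = []
    for e in entries:
        for cand in (tuple(quad), tuple(reversed(quad))):
            if all(t == "X" or t == c for t, c in zip(e.types, cand)):
                hits.append(e)
                break
    if not hits:
        return None
    fewest = min(sum(t == "X" for t in e.types) for e in hits)
    return [e for e in hits if sum(t == "X" for t in e.types) == fewest][-1]


@pytest.mark.parametrize("seed", range(20))
def test_dihedral_lookup_matches_brute_force(seed, rng):
    import numpy as np
    local = np.random.default_rng(seed)
    p = gt.make_random_parameters(seed)
    codes = sorted({t for e in p.dihedrals for t in e.types if t != "X"}) or ["T1"]
    for _ in range(30):
        quad = tuple(local.choice(codes, size=4))
        assert p.find_dihedral(quad) is _brute_dihedral(p.dihedrals, quad)


def test_bond_and_angle_lookup_symmetry():
    p = gt.ParameterSet(
        bonds=[gt.BondParam("A", "B", 100.0, 1.5)],
        angles=[gt.AngleParam("A", "B", "C", 50.0, 110.0)])
    assert p.find_bond("B", "A") is p.bonds[0]
    assert p.find_angle("C", "B", "A") is p.angles[0]
    assert p.find_bond("A", "C") is None


def test_exact_match_outranks_wildcard():
    wild = gt.DihedralParam(("X", "A", "B", "X"), 1.0, 3, 0.0)
    exact = gt.DihedralParam(("C", "A", "B", "D"), 2.0, 3, 0.0)
    p = gt.ParameterSet(dihedrals=[exact, wild])
    assert p.find_dihedral(("C", "A", "B", "D")) is exact
    assert p.find_dihedral(("Z", "A", "B", "Z")) is wild


def test_duplicate_identical_tuples_last_wins():
    first = gt.BondParam("A", "B", 100.0, 1.5)
    second = gt.BondParam("A", "B", 300.0, 1.5)
    p = gt.ParameterSet(bonds=[first, second])
    assert p.find_bond("A", "B") is second


# ---------------------------------------------------------------------------
# coverage checking
# ---------------------------------------------------------------------------

def test_fixture_is_complete_by_construction(bundle):
    assert gt.check_coverage(bundle.molecule, bundle.parameters) == []


def test_deleting_one_angle_param_reports_exactly_its_instances(bundle):
    import dataclasses
    p = bundle.parameters
    victim = p.angles[0]
    reduced = dataclasses.replace(p, angles=[a for a in p.angles if a is not victim])
    missing = gt.check_coverage(bundle.molecule, reduced)
    assert missing and all(m.kind == "angle" for m in missing)
    # exactly the triples matched by the removed entry, no others
    types = [a.type_code for a in bundle.molecule.atoms]
    expected = {tuple(types[i] for i in t)
                for t in bundle.molecule.angle_triples()
                if victim.matches(types[t[0]], types[t[1]], types[t[2]])}
    assert {m.type_tuple for m in missing} <= expected | {tuple(reversed(t)) for t in expected}
    assert len(missing) == sum(
        1 for t in bundle.molecule.angle_triples()
        if victim.matches(types[t[0]], types[t[1]], types[t[2]]))


def test_amide_fixture_lacks_exactly_three_improper_params():
    mol, complete, stripped = gt.make_amide_fixture()
    assert gt.check_coverage(mol, complete) == []
    missing = gt.check_coverage(mol, stripped)
    assert len(missing) == 3
    assert all(m.kind == "improper" for m in missing)


def test_coverage_empty_iff_brute_force_finds_every_term(bundle):
    """check_coverage agrees with an independent exhaustive matcher."""
    mol, p = bundle.molecule, bundle.parameters
    types = [a.type_code for a in mol.atoms]

    def brute_has_bond(ta, tb):
        return any(set((e.type_a, e.type_b)) in ({ta, tb} | {"X"}, {ta, tb})
                   or (e.type_a in (ta, "X") and e.type_b in (tb, "X"))
                   or (e.type_a in (tb, "X") and e.type_b in (ta, "X"))
                   for e in p.bonds)

    assert all(brute_has_bond(types[i], types[j]) for i, j in mol.bonds)
    assert gt.check_coverage(mol, p) == []
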