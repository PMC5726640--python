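"""Reader/writer for the CNS/XPLOR-style topology (.top) and parameter
(.param) dialect used in NMR structure calculation, plus the parameter
transformations needed to make a carbohydrate force field compatible with
standard simulated-annealing protocols.

The dialect subset understood here covers RESIdue / PRESidue blocks with
ATOM / BOND / ANGLe / DIHEdral / IMPRoper / GROUp statements, patch edits
(ADD / DELEte / MODIfy), MASS and AUTOGENERATE headers, ``!`` comments and
free-form line continuation.  Keywords are matched case-insensitively on
their first four characters, as in the original programs.  Statements the
parser does not understand are preserved verbatim and re-emitted in place,
so files can round-trip without losing content.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

WILDCARD = "X"

#: Energy constants that make the carbohydrate terms as stiff as the
#: protein/nucleic-acid ones used by the standard annealing protocol:
#: BOND 1000.0 kcal/mol/A^2, ANGLE 500.0 kcal/mol/rad^2,
#: IMPROPER 500.0 kcal/mol/rad^2, DIHEDRAL 2.0 kcal/mol.
NMR_BOND_K = 1000.0
NMR_ANGLE_K = 500.0
NMR_IMPROPER_K = 500.0
NMR_DIHEDRAL_K = 2.0


class ForceFieldError(ValueError):
    """Raised for malformed topology/parameter input."""


# ---------------------------------------------------------------------------
# domain types — topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomDef:
    """One atom of a residue: name, parameter type code, partial charge."""

    name: str
    type_code: str
    charge: float = 0.0
    mass: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ForceFieldError("atom name must be nonempty")
        if not self.type_code:
            raise ForceFieldError(f"atom {self.name!r}: type code must be nonempty")


@dataclass
class ResidueTopology:
    """A residue: atoms plus the bonded-term template instantiated on build.

    ``improper_targets`` maps an improper name-quadruple to an explicit
    target angle in degrees (signed); chirality impropers carry their
    reference geometry this way because a single type tuple cannot
    distinguish the two mirror forms.
    """

    name: str
    atoms: list[AtomDef] = field(default_factory=list)
    bonds: list[tuple[str, str]] = field(default_factory=list)
    angles: list[tuple[str, str, str]] = field(default_factory=list)
    dihedrals: list[tuple[str, str, str, str]] = field(default_factory=list)
    impropers: list[tuple[str, str, str, str]] = field(default_factory=list)
    improper_targets: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    passthrough: list[str] = field(default_factory=list)

    def atom(self, name: str) -> AtomDef:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}

    def validate(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ForceFieldError(f"residue {self.name}: duplicate atom names {dup}")
        known = set(names)
        for kind, terms in (("BOND", self.bonds), ("ANGLE", self.angles),
                            ("DIHEDRAL", self.dihedrals), ("IMPROPER", self.impropers)):
            for term in terms:
                for n in term:
                    if n not in known:
                        raise ForceFieldError(
                            f"residue {self.name}: {kind} refers to undefined atom {n!r}")
        seen = set()
        for a, b in self.bonds:
            key = frozenset((a, b))
            if key in seen:
                raise ForceFieldError(f"residue {self.name}: duplicate bond {a}-{b}")
            seen.add(key)


@dataclass(frozen=True)
class PatchAtomRef:
    """Prefixed atom reference inside a patch, e.g. ``1-C1`` (first residue
    of the patch mapping) or ``2-OG`` (second)."""

    group: int
    name: str

    def __str__(self) -> str:  # emitted form
        return f"{self.group}-{self.name}"

    @classmethod
    def parse(cls, token: str) -> "PatchAtomRef":
        m = re.fullmatch(r"(\d+)-(\S+)", token)
        if not m:
            raise ForceFieldError(f"bad patch atom reference {token!r} (expected N-NAME)")
        return cls(int(m.group(1)), m.group(2))


@dataclass
class PatchDef:
    """A PRESidue: add/delete/modify edits applied to one or two residues."""

    name: str
    deleted_atoms: list[PatchAtomRef] = field(default_factory=list)
    added_atoms: list[tuple[PatchAtomRef, AtomDef]] = field(default_factory=list)
    added_bonds: list[tuple[PatchAtomRef, PatchAtomRef]] = field(default_factory=list)
    added_angles: list[tuple[PatchAtomRef, ...]] = field(default_factory=list)
    added_dihedrals: list[tuple[PatchAtomRef, ...]] = field(default_factory=list)
    added_impropers: list[tuple[tuple[PatchAtomRef, ...], Optional[float]]] = field(default_factory=list)
    modified_atoms: list[tuple[PatchAtomRef, Optional[str], Optional[float]]] = field(default_factory=list)
    passthrough: list[str] = field(default_factory=list)


@dataclass
class TopologySet:
    """Everything in one topology file: residues, patches, flags."""

    residues: dict[str, ResidueTopology] = field(default_factory=dict)
    patches: dict[str, PatchDef] = field(default_factory=dict)
    masses: dict[str, float] = field(default_factory=dict)
    autogenerate_angles: bool = True
    autogenerate_dihedrals: bool = False
    preamble: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for r in self.residues.values():
            r.validate()


# ---------------------------------------------------------------------------
# domain types — parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BondParam:
    type_a: str
    type_b: str
    k: float          # kcal/mol/A^2
    b0: float         # A

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ForceFieldError("bond force constant must be >= 0")
        if self.b0 <= 0:
            raise ForceFieldError("bond equilibrium length must be > 0")

    def matches(self, ta: str, tb: str) -> bool:
        return _tuple_match((self.type_a, self.type_b), (ta, tb)) or \
            _tuple_match((self.type_a, self.type_b), (tb, ta))


@dataclass(frozen=True)
class AngleParam:
    type_a: str
    type_b: str
    type_c: str
    k: float          # kcal/mol/rad^2
    theta0: float     # degrees

    def __post_init__(self) -> None:
        if not 0.0 < self.theta0 < 180.0:
            raise ForceFieldError("angle equilibrium must be in (0, 180) degrees")

    def matches(self, ta: str, tb: str, tc: str) -> bool:
        own = (self.type_a, self.type_b, self.type_c)
        return _tuple_match(own, (ta, tb, tc)) or _tuple_match(own, (tc, tb, ta))


@dataclass(frozen=True)
class DihedralParam:
    types: tuple[str, str, str, str]
    k: float          # kcal/mol
    periodicity: int  # 0 means harmonic about delta
    delta: float      # degrees

    def __post_init__(self) -> None:
        if self.periodicity < 0:
            raise ForceFieldError("periodicity must be >= 0")

    def matches(self, quad: Sequence[str]) -> bool:
        return _tuple_match(self.types, tuple(quad)) or \
            _tuple_match(self.types, tuple(reversed(tuple(quad))))

    def n_wildcards(self) -> int:
        return sum(1 for t in self.types if t == WILDCARD)


@dataclass(frozen=True)
class ImproperParam(DihedralParam):
    """Improper torsion parameter; ``delta`` is the target angle phi0."""


@dataclass(frozen=True)
class NonbondedParam:
    type_code: str
    epsilon: float    # kcal/mol
    sigma: float      # A
    extra: tuple[float, ...] = ()   # 1-4 pair values when present


@dataclass
class ParameterSet:
    bonds: list[BondParam] = field(default_factory=list)
    angles: list[AngleParam] = field(default_factory=list)
    dihedrals: list[DihedralParam] = field(default_factory=list)
    impropers: list[ImproperParam] = field(default_factory=list)
    nonbonded: list[NonbondedParam] = field(default_factory=list)
    verbatim_remainder: list[str] = field(default_factory=list)

    # -- lookups (symmetric, exact-before-wildcard) --------------------

    def find_bond(self, ta: str, tb: str) -> Optional[BondParam]:
        return _best([p for p in self.bonds if p.matches(ta, tb)],
                     lambda p: sum(t == WILDCARD for t in (p.type_a, p.type_b)))

    def find_angle(self, ta: str, tb: str, tc: str) -> Optional[AngleParam]:
        return _best([p for p in self.angles if p.matches(ta, tb, tc)],
                     lambda p: sum(t == WILDCARD for t in (p.type_a, p.type_b, p.type_c)))

    def find_dihedral(self, quad: Sequence[str]) -> Optional[DihedralParam]:
        return _best([p for p in self.dihedrals if p.matches(quad)],
                     DihedralParam.n_wildcards)

    def find_improper(self, quad: Sequence[str]) -> Optional[ImproperParam]:
        return _best([p for p in self.impropers if p.matches(quad)],
                     ImproperParam.n_wildcards)

    def find_nonbonded(self, type_code: str) -> Optional[NonbondedParam]:
        for p in self.nonbonded:
            if p.type_code == type_code:
                return p
        return None


def _tuple_match(pattern: Sequence[str], types: Sequence[str]) -> bool:
    return all(p == WILDCARD or p == t for p, t in zip(pattern, types))


def _best(candidates, wildcount):
    """Last entry among those with the fewest wildcards (last one wins on
    exact duplicates, mirroring common force-field file tolerance)."""
    if not candidates:
        return None
    lowest = min(wildcount(p) for p in candidates)
    exact = [p for p in candidates if wildcount(p) == lowest]
    return exact[-1]


# ---------------------------------------------------------------------------
# tokenizer shared by both file kinds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Tok:
    text: str
    line: int


def _strip_comment(line: str) -> str:
    i = line.find("!")
    return line if i < 0 else line[:i]


def _logical_lines(text: str) -> Iterable[tuple[str, int]]:
    """Comment-stripped logical lines; a trailing backslash continues."""
    pending = ""
    start = 0
    for ln, raw in enumerate(text.splitlines(), start=1):
        body = _strip_comment(raw).rstrip()
        if not pending:
            start = ln
        if body.endswith("\\"):
            pending += body[:-1] + " "
            continue
        whole = pending + body
        pending = ""
        if whole.strip():
            yield whole, start
    if pending.strip():
        yield pending, start


def _kw(token: str) -> str:
    """Normalized keyword: first four characters, upper-cased."""
    return token[:4].upper()


_KNOWN_TOP = {"REMA", "RESI", "PRES", "MASS", "AUTO", "SET", "END"}
_KNOWN_RES = {"ATOM", "BOND", "ANGL", "DIHE", "IMPR", "GROU", "END"}
_KNOWN_PATCH = {"ADD", "DELE", "MODI", "GROU", "END"}


# ---------------------------------------------------------------------------
# topology parsing
# ---------------------------------------------------------------------------

def parse_topology(text: str) -> TopologySet:
    """Parse ``.top``-dialect text into a :class:`TopologySet`.

    Raises :class:`ForceFieldError` with a line number for unterminated
    blocks, duplicate residue names, or references to undefined atoms.
    """
    tset = TopologySet()
    lines = list(_logical_lines(text))
    i = 0
    while i < len(lines):
        line, ln = lines[i]
        toks = line.split()
        kw = _kw(toks[0])
        if kw == "RESI" or kw == "PRES":
            if len(toks) < 2:
                raise ForceFieldError(f"line {ln}: {toks[0]} without a name")
            name = toks[1].upper()
            j = _find_block_end(lines, i, ln, name)
            block = lines[i + 1:j]
            if kw == "RESI":
                if name in tset.residues:
                    raise ForceFieldError(f"line {ln}: duplicate residue {name}")
                res = _parse_residue(name, block)
                res.validate()
                tset.residues[name] = res
            else:
                if name in tset.patches:
                    raise ForceFieldError(f"line {ln}: duplicate patch {name}")
                tset.patches[name] = _parse_patch(name, block)
            i = j + 1
        elif kw == "MASS":
            if len(toks) != 3:
                raise ForceFieldError(f"line {ln}: MASS expects type and value")
            tset.masses[toks[1].upper()] = float(toks[2])
            i += 1
        elif kw == "AUTO":
            for t in toks[1:]:
                u = t.upper().rstrip()
                if u.startswith("ANGL"):
                    tset.autogenerate_angles = u.endswith("TRUE")
                elif u.startswith("DIHE"):
                    tset.autogenerate_dihedrals = u.endswith("TRUE")
            i += 1
        else:
            tset.preamble.append(line.strip())
            i += 1
    return tset


def _find_block_end(lines, i, ln, name) -> int:
    depth = 0
    for j in range(i + 1, len(lines)):
        toks = lines[j][0].split()
        kw = _kw(toks[0])
        if kw in ("RESI", "PRES"):
            raise ForceFieldError(
                f"line {lines[j][1]}: block {name} (line {ln}) not terminated by END")
        # ATOM ... END statements close on the same logical line, so a bare
        # END token at statement position terminates the block.
        if kw == "END" and depth == 0:
            return j
    raise ForceFieldError(f"line {ln}: block {name} not terminated by END")


def _parse_atom_fields(toks: Sequence[str], ln: int) -> tuple[str, Optional[float], Optional[float]]:
    """TYPE= / CHARge= / MASS= fields of an ATOM statement (END consumed)."""
    type_code = ""
    charge = None
    mass = None
    for t in toks:
        u = t.upper()
        if u.startswith("TYPE="):
            type_code = t.split("=", 1)[1].upper()
        elif u.startswith("CHAR"):
            charge = float(t.split("=", 1)[1])
        elif u.startswith("MASS="):
            mass = float(t.split("=", 1)[1])
        elif u == "END":
            break
        else:
            raise ForceFieldError(f"line {ln}: unexpected ATOM field {t!r}")
    return type_code, charge, mass


def _parse_residue(name: str, block) -> ResidueTopology:
    res = ResidueTopology(name=name)
    for line, ln in block:
        toks = line.split()
        kw = _kw(toks[0])
        if kw == "ATOM":
            if len(toks) < 2:
                raise ForceFieldError(f"line {ln}: ATOM without a name")
            type_code, charge, mass = _parse_atom_fields(toks[2:], ln)
            res.atoms.append(AtomDef(toks[1].upper(), type_code, charge or 0.0, mass))
        elif kw == "BOND":
            res.bonds.append((toks[1].upper(), toks[2].upper()))
        elif kw == "ANGL":
            res.angles.append(tuple(t.upper() for t in toks[1:4]))
        elif kw == "DIHE":
            res.dihedrals.append(tuple(t.upper() for t in toks[1:5]))
        elif kw == "IMPR":
            quad = tuple(t.upper() for t in toks[1:5])
            res.impropers.append(quad)
            for t in toks[5:]:
                if t.upper().startswith("TARG"):
                    res.improper_targets[quad] = float(t.split("=", 1)[1])
        elif kw == "GROU":
            res.passthrough.append(line.strip())
        else:
            res.passthrough.append(line.strip())
    return res


def _parse_patch(name: str, block) -> PatchDef:
    patch = PatchDef(name=name)
    for line, ln in block:
        toks = line.split()
        kw = _kw(toks[0])
        if kw == "DELE":
            if len(toks) < 3 or _kw(toks[1]) != "ATOM":
                raise ForceFieldError(f"line {ln}: DELEte supports only 'DELEte ATOM ref'")
            patch.deleted_atoms.append(PatchAtomRef.parse(toks[2]))
        elif kw == "ADD":
            sub = _kw(toks[1])
            if sub == "ATOM":
                ref = PatchAtomRef.parse(toks[2])
                type_code, charge, mass = _parse_atom_fields(toks[3:], ln)
                patch.added_atoms.append((ref, AtomDef(ref.name, type_code, charge or 0.0, mass)))
            elif sub == "BOND":
                patch.added_bonds.append((PatchAtomRef.parse(toks[2]), PatchAtomRef.parse(toks[3])))
            elif sub == "ANGL":
                patch.added_angles.append(tuple(PatchAtomRef.parse(t) for t in toks[2:5]))
            elif sub == "DIHE":
                patch.added_dihedrals.append(tuple(PatchAtomRef.parse(t) for t in toks[2:6]))
            elif sub == "IMPR":
                quad = tuple(PatchAtomRef.parse(t) for t in toks[2:6])
                target = None
                for t in toks[6:]:
                    if t.upper().startswith("TARG"):
                        target = float(t.split("=", 1)[1])
                patch.added_impropers.append((quad, target))
            else:
                raise ForceFieldError(f"line {ln}: ADD {toks[1]} not supported")
        elif kw == "MODI":
            if _kw(toks[1]) != "ATOM":
                raise ForceFieldError(f"line {ln}: MODIfy supports only atoms")
            ref = PatchAtomRef.parse(toks[2])
            type_code, charge, _ = _parse_atom_fields(toks[3:], ln)
            patch.modified_atoms.append((ref, type_code or None, charge))
        else:
            patch.passthrough.append(line.strip())
    return patch


# ---------------------------------------------------------------------------
# topology writing
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    """Shortest decimal that parses back to the identical float."""
    return repr(float(x))


def write_topology(tset: TopologySet, header: str = "glycotop topology file") -> str:
    tset.validate()
    out = [f"! {header}"]
    out.append(
        "AUTOGENERATE ANGLES=%s DIHEDRALS=%s END"
        % ("TRUE" if tset.autogenerate_angles else "FALSE",
           "TRUE" if tset.autogenerate_dihedrals else "FALSE"))
    for line in tset.preamble:
        out.append(line)
    for code, mass in tset.masses.items():
        out.append(f"MASS {code} {_fmt(mass)}")
    for res in tset.residues.values():
        out.append("")
        out.append(f"RESIdue {res.name}")
        for line in res.passthrough:
            out.append(f"  {line}")
        for a in res.atoms:
            extra = f" MASS={_fmt(a.mass)}" if a.mass is not None else ""
            out.append(f"  ATOM {a.name} TYPE={a.type_code} CHARge={_fmt(a.charge)}{extra} END")
        for a, b in res.bonds:
            out.append(f"  BOND {a} {b}")
        for t in res.angles:
            out.append(f"  ANGLe {' '.join(t)}")
        for t in res.dihedrals:
            out.append(f"  DIHEdral {' '.join(t)}")
        for t in res.impropers:
            tail = ""
            if t in res.improper_targets:
                tail = f" TARGet={_fmt(res.improper_targets[t])}"
            out.append(f"  IMPRoper {' '.join(t)}{tail}")
        out.append("END")
    for patch in tset.patches.values():
        out.append("")
        out.append(f"PRESidue {patch.name}")
        for line in patch.passthrough:
            out.append(f"  {line}")
        for ref in patch.deleted_atoms:
            out.append(f"  DELEte ATOM {ref}")
        for ref, a in patch.added_atoms:
            out.append(f"  ADD ATOM {ref} TYPE={a.type_code} CHARge={_fmt(a.charge)} END")
        for r1, r2 in patch.added_bonds:
            out.append(f"  ADD BOND {r1} {r2}")
        for refs in patch.added_angles:
            out.append(f"  ADD ANGLe {' '.join(map(str, refs))}")
        for refs in patch.added_dihedrals:
            out.append(f"  ADD DIHEdral {' '.join(map(str, refs))}")
        for refs, target in patch.added_impropers:
            tail = f" TARGet={_fmt(target)}" if target is not None else ""
            out.append(f"  ADD IMPRoper {' '.join(map(str, refs))}{tail}")
        for ref, type_code, charge in patch.modified_atoms:
            fields = []
            if type_code is not None:
                fields.append(f"TYPE={type_code}")
            if charge is not None:
                fields.append(f"CHARge={_fmt(charge)}")
            out.append(f"  MODIfy ATOM {ref} {' '.join(fields)} END")
        out.append("END")
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# parameter parsing / writing
# ---------------------------------------------------------------------------

def parse_parameters(text: str) -> ParameterSet:
    """Parse ``.param``-dialect text (BOND/ANGLe/DIHEdral/IMPRoper/NONBonded
    statements) into a :class:`ParameterSet`."""
    pset = ParameterSet()
    for line, ln in _logical_lines(text):
        toks = line.split()
        kw = _kw(toks[0])
        try:
            if kw == "BOND":
                pset.bonds.append(BondParam(toks[1].upper(), toks[2].upper(),
                                            float(toks[3]), float(toks[4])))
            elif kw == "ANGL":
                pset.angles.append(AngleParam(toks[1].upper(), toks[2].upper(),
                                              toks[3].upper(), float(toks[4]), float(toks[5])))
            elif kw == "DIHE":
                pset.dihedrals.append(DihedralParam(
                    tuple(t.upper() for t in toks[1:5]),
                    float(toks[5]), int(toks[6]), float(toks[7])))
            elif kw == "IMPR":
                pset.impropers.append(ImproperParam(
                    tuple(t.upper() for t in toks[1:5]),
                    float(toks[5]), int(toks[6]), float(toks[7])))
            elif kw == "NONB":
                nums = tuple(float(t) for t in toks[2:])
                pset.nonbonded.append(NonbondedParam(toks[1].upper(), nums[0], nums[1],
                                                     tuple(nums[2:])))
            else:
                pset.verbatim_remainder.append(line.strip())
        except (IndexError, ValueError) as exc:
            raise ForceFieldError(f"line {ln}: malformed {kw} statement: {line.strip()!r}") from exc
    _warn_duplicates(pset)
    return pset


def _warn_duplicates(pset: ParameterSet) -> None:
    for kind, entries, key in (
            ("BOND", pset.bonds, lambda p: (frozenset((p.type_a, p.type_b)), p.b0)),
            ("ANGLE", pset.angles,
             lambda p: (min((p.type_a, p.type_b, p.type_c), (p.type_c, p.type_b, p.type_a)), p.theta0))):
        seen: dict = {}
        for p in entries:
            k = key(p)
            if k in seen and seen[k].k != p.k:
                logger.warning("%s parameter %s duplicated with different k; last wins", kind, k)
            seen[k] = p


def write_parameters(pset: ParameterSet, header: str = "glycotop parameter file") -> str:
    out = [f"! {header}"]
    for p in pset.bonds:
        out.append(f"BOND {p.type_a} {p.type_b} {_fmt(p.k)} {_fmt(p.b0)}")
    for p in pset.angles:
        out.append(f"ANGLe {p.type_a} {p.type_b} {p.type_c} {_fmt(p.k)} {_fmt(p.theta0)}")
    for p in pset.dihedrals:
        out.append(f"DIHEdral {' '.join(p.types)} {_fmt(p.k)} {p.periodicity} {_fmt(p.delta)}")
    for p in pset.impropers:
        out.append(f"IMPRoper {' '.join(p.types)} {_fmt(p.k)} {p.periodicity} {_fmt(p.delta)}")
    for p in pset.nonbonded:
        nums = " ".join(_fmt(x) for x in (p.epsilon, p.sigma) + p.extra)
        out.append(f"NONBonded {p.type_code} {nums}")
    for line in pset.verbatim_remainder:
        out.append(line)
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def harmonize_energies(pset: ParameterSet,
                       k_bond: float = NMR_BOND_K,
                       k_angle: float = NMR_ANGLE_K,
                       k_improper: float = NMR_IMPROPER_K,
                       k_dihedral: float = NMR_DIHEDRAL_K) -> ParameterSet:
    """Return a copy with every force constant set to the uniform values the
    standard protein/nucleic-acid annealing protocol expects.  Equilibrium
    geometry (b0, theta0, phi0, periodicity) and nonbonded entries are
    untouched.  Idempotent."""
    for name, k in (("k_bond", k_bond), ("k_angle", k_angle),
                    ("k_improper", k_improper), ("k_dihedral", k_dihedral)):
        if k < 0:
            raise ForceFieldError(f"{name} must be >= 0, got {k}")
    return ParameterSet(
        bonds=[replace(p, k=k_bond) for p in pset.bonds],
        angles=[replace(p, k=k_angle) for p in pset.angles],
        dihedrals=[replace(p, k=k_dihedral) for p in pset.dihedrals],
        impropers=[replace(p, k=k_improper) for p in pset.impropers],
        nonbonded=list(pset.nonbonded),
        verbatim_remainder=list(pset.verbatim_remainder),
    )


@dataclass(frozen=True)
class MissingTerm:
    """A bonded term instance with no matching parameter entry."""

    kind: str                       # "bond" | "angle" | "dihedral" | "improper"
    type_tuple: tuple[str, ...]
    atom_names: tuple[str, ...]


def check_coverage(mol, pset: ParameterSet) -> list[MissingTerm]:
    """Every term instance of ``mol`` lacking a parameter (exact or wildcard).

    An empty return means an energy evaluation over the molecule cannot hit
    a parameter-lookup failure — the error class that aborted annealing runs
    when amide impropers were missing for N-acetyl sugars.
    """
    missing: list[MissingTerm] = []
    types = [a.type_code for a in mol.atoms]
    names = [a.name for a in mol.atoms]
    for i, j in mol.bonds:
        if pset.find_bond(types[i], types[j]) is None:
            missing.append(MissingTerm("bond", (types[i], types[j]), (names[i], names[j])))
    for i, j, k in mol.angle_triples():
        if pset.find_angle(types[i], types[j], types[k]) is None:
            missing.append(MissingTerm("angle", (types[i], types[j], types[k]),
                                       (names[i], names[j], names[k])))
    for quad in mol.explicit_dihedrals:
        tt = tuple(types[i] for i in quad)
        if pset.find_dihedral(tt) is None:
            missing.append(MissingTerm("dihedral", tt, tuple(names[i] for i in quad)))
    for quad, target in mol.explicit_impropers:
        if target is not None:
            continue    # carries its own geometry; no lookup needed
        tt = tuple(types[i] for i in quad)
        if pset.find_improper(tt) is None:
            missing.append(MissingTerm("improper", tt, tuple(names[i] for i in quad)))
    return missing
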