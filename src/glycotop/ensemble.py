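"""NMR-ensemble analysis: glycosidic torsion statistics (the carbohydrate
Ramachandran axes), sugar heavy-atom ensemble RMSD, and Cremer-Pople ring
pucker classification on multi-model PDB files."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .geometry import kabsch, signed_dihedral, wrap_deg
from .molecule import element_of


class EnsembleError(ValueError):
    pass


@dataclass(frozen=True)
class AtomMeta:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    icode: str = ""
    het: bool = False

    def key(self):
        return (self.chain, self.resnum, self.icode, self.name)


Selection = Union[Callable[[AtomMeta], bool], Sequence[int]]


@dataclass
class Ensemble:
    """One or more models sharing a single atom roster."""

    atoms: list[AtomMeta]
    coords: np.ndarray            # (n_models, n_atoms, 3), Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleError("coords must be (n_models, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise EnsembleError("an ensemble needs at least one model")
        if self.coords.shape[1] != len(self.atoms):
            raise EnsembleError("coords and atom roster disagree in length")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def indices(self, selection: Selection) -> list[int]:
        if callable(selection):
            return [i for i, a in enumerate(self.atoms) if selection(a)]
        return list(selection)

    def atom_index(self, chain: str, resnum: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.resnum == resnum and a.name == name:
                return i
        raise EnsembleError(f"atom {name} of residue {chain}:{resnum} not found")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_ensemble(source: str) -> Ensemble:
    """Read a (multi-model) PDB file or PDB-format string.

    Altloc 'A'/'' preferred; HETATM records (sugars!) retained; all models
    must share one atom roster.
    """
    import gemmi

    if "\n" in source or source.strip().startswith(("ATOM", "HETATM", "MODEL", "HEADER", "REMARK")):
        st = gemmi.read_pdb_string(source)
    else:
        st = gemmi.read_structure(source, format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    rosters = []
    coords = []
    for model in st:
        atoms = []
        xyz = []
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("", "\x00", "A"):
                        continue
                    atoms.append(AtomMeta(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        name=atom.name,
                        element=atom.element.name or element_of(atom.name),
                        icode=(res.seqid.icode or "").strip(),
                        het=res.het_flag == "H"))
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        rosters.append(atoms)
        coords.append(xyz)
    if not rosters:
        raise EnsembleError("no models in input")
    first = [a.key() for a in rosters[0]]
    for m, roster in enumerate(rosters[1:], start=2):
        keys = [a.key() for a in roster]
        if keys != first:
            bad = next((k for k, f in zip(keys, first) if k != f),
                       keys[len(first):][:1] or first[len(keys):][:1])
            raise EnsembleError(f"model {m} roster differs from model 1 "
                                f"(first offending atom: {bad})")
    return Ensemble(rosters[0], np.array(coords, float))


def write_ensemble(e: Ensemble) -> str:
    """Multi-model PDB text (fixed-column, 3-decimal coordinates)."""
    lines = []
    multi = e.n_models > 1
    for m in range(e.n_models):
        if multi:
            lines.append(f"MODEL     {m + 1:4d}")
        for i, a in enumerate(e.atoms):
            x, y, z = e.coords[m, i]
            record = "HETATM" if a.het else "ATOM  "
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"{record}{i + 1:5d} {name:<4s}{'':1s}{a.resname:<4s}"
                f"{a.chain[:1]:1s}{a.resnum:4d}{a.icode:<1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def circular_mean_deg(angles: Sequence[float]) -> float:
    """Mean direction in degrees, in (-180, 180]; mean of {179, -179} is 180."""
    a = np.radians(np.asarray(angles, float))
    s, c = np.sin(a).sum(), np.cos(a).sum()
    if abs(s) < 1e-15 and abs(c) < 1e-15:
        raise EnsembleError("circular mean undefined (resultant is zero)")
    return float(wrap_deg(math.degrees(math.atan2(s, c))))


def circular_std_deg(angles: Sequence[float]) -> float:
    """Circular standard deviation sqrt(-2 ln R) in degrees."""
    a = np.radians(np.asarray(angles, float))
    R = float(np.hypot(np.sin(a).mean(), np.cos(a).mean()))
    R = min(R, 1.0)
    if R <= 0.0:
        return float("inf")
    return math.degrees(math.sqrt(-2.0 * math.log(R)))


# ---------------------------------------------------------------------------
# glycosidic torsions
# ---------------------------------------------------------------------------

#: acceptor-side atom paths (Ox, Cx, C_previous) per linkage chemistry
ACCEPTOR_PATHS = {
    "ser": ("OG", "CB", "CA"),
    "thr": ("OG1", "CB", "CA"),
    "cys": ("SG", "CB", "CA"),
    "1-3": ("O3", "C3", "C2"),
    "1-4": ("O4", "C4", "C3"),
    "1-6": ("O6", "C6", "C5"),
}


@dataclass(frozen=True)
class Linkage:
    """A glycosidic or glycosylation linkage: the sugar donating C1, the
    acceptor residue and the acceptor-side atom path (Ox, Cx, C_prev)."""

    donor: tuple[str, int]        # (chain, resnum) of the sugar
    acceptor: tuple[str, int]
    acceptor_path: tuple[str, str, str]
    label: str = ""

    @classmethod
    def from_kind(cls, donor, acceptor, kind: str, label: str = "") -> "Linkage":
        return cls(donor, acceptor, ACCEPTOR_PATHS[kind], label or kind)


@dataclass
class TorsionResult:
    label: str
    phi: np.ndarray               # degrees per model
    psi: np.ndarray
    phi_mean: float = field(init=False)
    phi_sd: float = field(init=False)
    psi_mean: float = field(init=False)
    psi_sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, float)
        self.psi = np.asarray(self.psi, float)
        self.phi_mean = round(circular_mean_deg(self.phi), 1)
        self.phi_sd = round(circular_std_deg(self.phi), 1)
        self.psi_mean = round(circular_mean_deg(self.psi), 1)
        self.psi_sd = round(circular_std_deg(self.psi), 1)


def glycosidic_torsions(e: Ensemble, linkage: Linkage,
                        convention: str = "heavy") -> TorsionResult:
    """Per-model phi/psi of one linkage with circular mean +/- SD.

    phi = O5-C1-Ox'-Cx' under the heavy-atom convention (default), or
    H1-C1-Ox'-Cx' under the ``h1`` convention; psi = C1-Ox'-Cx'-C(x-1)'.
    """
    if convention not in ("heavy", "h1"):
        raise ValueError(f"unknown torsion convention {convention!r}")
    dc, dn = linkage.donor
    ac, an = linkage.acceptor
    first = "O5" if convention == "heavy" else "H1"
    ox, cx, cprev = linkage.acceptor_path
    idx = [e.atom_index(dc, dn, first), e.atom_index(dc, dn, "C1"),
           e.atom_index(ac, an, ox), e.atom_index(ac, an, cx),
           e.atom_index(ac, an, cprev)]
    phi = np.array([signed_dihedral(*(e.coords[m, i] for i in idx[:4]))
                    for m in range(e.n_models)])
    psi = np.array([signed_dihedral(*(e.coords[m, i] for i in idx[1:]))
                    for m in range(e.n_models)])
    return TorsionResult(linkage.label or f"{dc}:{dn}->{ac}:{an}", phi, psi)


# ---------------------------------------------------------------------------
# ensemble RMSD
# ---------------------------------------------------------------------------

@dataclass
class RmsdReport:
    selection: str
    mode: str
    mean_rmsd: float              # A, rounded to 0.01
    per_model: np.ndarray         # pairwise means or distances to the mean


def ensemble_rmsd(e: Ensemble, selection: Selection,
                  mode: str = "pairwise", label: str = "") -> RmsdReport:
    """Ensemble spread over an atom selection after optimal superposition.

    ``pairwise``: mean RMSD over all model pairs, each pair superposed on
    the selection.  ``to_mean``: RMSD of each model to the iterated mean
    structure after superposition.
    """
    idx = e.indices(selection)
    if len(idx) < 3:
        raise EnsembleError(f"selection matches {len(idx)} atoms; need >= 3")
    pts = e.coords[:, idx, :]
    m = e.n_models
    if mode == "pairwise":
        vals = []
        per_model = np.zeros(m)
        for i in range(m):
            for j in range(i + 1, m):
                r = kabsch(pts[i], pts[j])[2]
                vals.append(r)
                per_model[i] += r
                per_model[j] += r
        mean = float(np.mean(vals)) if vals else 0.0
        if m > 1:
            per_model /= (m - 1)
    elif mode == "to_mean":
        ref = pts[0]
        for _ in range(10):
            fitted = np.array([p @ kabsch(p, ref)[0].T + kabsch(p, ref)[1] for p in pts])
            new_ref = fitted.mean(axis=0)
            if np.max(np.abs(new_ref - ref)) < 1e-10:
                ref = new_ref
                break
            ref = new_ref
        per_model = np.array([kabsch(p, ref)[2] for p in pts])
        mean = float(per_model.mean())
    else:
        raise ValueError(f"unknown rmsd mode {mode!r}")
    return RmsdReport(label or f"{len(idx)} atoms", mode, round(mean, 2 if mean >= 0.005 else 4),
                      per_model)


# ---------------------------------------------------------------------------
# Cremer-Pople ring pucker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PuckerResult:
    ring_atoms: tuple[str, ...]
    Q: float                      # puckering amplitude, A
    theta: float                  # degrees, [0, 180]
    phi2: float                   # degrees, [0, 360)
    label: str                    # chair | boat | twist-boat | envelope/half-chair | planar


def ring_pucker(coords: np.ndarray, ring_indices: Sequence[int],
                ring_names: Optional[Sequence[str]] = None) -> PuckerResult:
    """Cremer-Pople puckering sphere (Q, theta, phi2) of one six-membered
    ring, atoms cyclically ordered (O5, C1..C5 for a pyranose).

    Classification by theta band: chair below 45 deg or above 135 deg;
    boat/twist-boat within 10 deg of the equator (boat when phi2 falls on a
    multiple of 60 deg +/- 15, twist-boat otherwise); everything between is
    the envelope/half-chair band.  Q below 0.05 A is planar.
    """
    coords = np.asarray(coords, float)
    if len(ring_indices) != 6:
        raise EnsembleError("ring_pucker needs exactly 6 atoms")
    r = coords[list(ring_indices)]
    center = r.mean(axis=0)
    rc = r - center
    j = np.arange(6)
    Rp = (rc * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    Rpp = (rc * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(Rp, Rpp)
    n /= np.linalg.norm(n)
    z = rc @ n
    q2c = math.sqrt(2.0 / 6.0) * float((z * np.cos(4 * np.pi * j / 6)).sum())
    q2s = -math.sqrt(2.0 / 6.0) * float((z * np.sin(4 * np.pi * j / 6)).sum())
    q3 = math.sqrt(1.0 / 6.0) * float((z * (-1.0) ** j).sum())
    q2 = math.hypot(q2c, q2s)
    Q = math.hypot(q2, q3)
    names = tuple(ring_names) if ring_names is not None else tuple(map(str, ring_indices))
    if Q < 0.05:
        return PuckerResult(names, Q, 90.0, 0.0, "planar")
    theta = math.degrees(math.acos(max(-1.0, min(1.0, q3 / Q))))
    phi2 = math.degrees(math.atan2(q2s, q2c)) % 360.0
    if theta < 45.0 or theta > 135.0:
        label = "chair"
    elif 80.0 <= theta <= 100.0:
        on_boat_phase = min(phi2 % 60.0, 60.0 - phi2 % 60.0) <= 15.0
        label = "boat" if on_boat_phase else "twist-boat"
    else:
        label = "envelope/half-chair"
    return PuckerResult(names, Q, theta, phi2, label)
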