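"""Bonded-term energies and analytic gradients.

Functional forms (the dialect convention, k * delta^2 with no 1/2 factor):

* bond        E = k (b - b0)^2                        k in kcal/mol/A^2
* angle       E = k (theta - theta0)^2                k in kcal/mol/rad^2
* dihedral    E = k (1 + cos(n*phi - delta))  (n>0)   k in kcal/mol
              E = k (dphi)^2                  (n=0, harmonic)
* improper    E = k (dphi)^2 with dphi the minimal-image difference to phi0
* repel       E = k_rep (max(0, (s*sigma_ij)^2 - r^2))^2

Angles are held in radians internally; file formats use degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .forcefield import NMR_IMPROPER_K, ParameterSet
from .molecule import MoleculeGraph


class EnergyError(ValueError):
    pass


@dataclass
class TermList:
    """Fully instantiated term arrays for one molecule."""

    n_atoms: int
    bond_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_b0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))   # rad
    dihe_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), int))
    dihe_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihe_n: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    dihe_delta: np.ndarray = field(default_factory=lambda: np.zeros(0))     # rad
    impr_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), int))
    impr_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    impr_phi0: np.ndarray = field(default_factory=lambda: np.zeros(0))      # rad
    repel_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    repel_sigma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    repel_k: float = 4.0
    repel_scale: float = 0.8

    def validate(self) -> None:
        bonded = {frozenset(b) for b in map(tuple, self.bond_idx)}
        onethree = {frozenset((i, k)) for i, _, k in map(tuple, self.angle_idx)}
        for pair in map(tuple, self.repel_idx):
            if frozenset(pair) in bonded or frozenset(pair) in onethree:
                raise EnergyError(f"repel pair {pair} is 1-2/1-3 bonded")

    def without_impropers(self) -> "TermList":
        out = TermList(**{k: v for k, v in self.__dict__.items()})
        out.impr_idx = np.zeros((0, 4), int)
        out.impr_k = np.zeros(0)
        out.impr_phi0 = np.zeros(0)
        return out


@dataclass(frozen=True)
class EnergyBreakdown:
    bond: float
    angle: float
    dihedral: float
    improper: float
    repel: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.dihedral + self.improper + self.repel


def enumerate_terms(mol: MoleculeGraph, pset: ParameterSet, *,
                    autogenerate_angles: bool = True,
                    include_repel: bool = True,
                    repel_k: float = 4.0, repel_scale: float = 0.8,
                    default_sigma: float = 2.0,
                    improper_k_default: float = NMR_IMPROPER_K) -> TermList:
    """Instantiate every term of ``mol`` against ``pset``.

    Raises :class:`EnergyError` listing the missing type tuples when the
    parameter set does not cover the molecule (the failure mode that aborts
    an annealing run mid-protocol).
    """
    from .forcefield import check_coverage

    missing = check_coverage(mol, pset)
    if missing:
        gaps = ", ".join(f"{m.kind}{m.type_tuple}" for m in missing[:10])
        raise EnergyError(f"parameter coverage gaps: {gaps}")

    types = [a.type_code for a in mol.atoms]
    terms = TermList(n_atoms=len(mol.atoms))

    if mol.bonds:
        params = [pset.find_bond(types[i], types[j]) for i, j in mol.bonds]
        terms.bond_idx = np.array(mol.bonds, int)
        terms.bond_k = np.array([p.k for p in params])
        terms.bond_b0 = np.array([p.b0 for p in params])

    triples = mol.angle_triples() if autogenerate_angles else list(mol.explicit_angles)
    if triples:
        params = [pset.find_angle(types[i], types[j], types[k]) for i, j, k in triples]
        terms.angle_idx = np.array(triples, int)
        terms.angle_k = np.array([p.k for p in params])
        terms.angle_theta0 = np.radians([p.theta0 for p in params])

    if mol.explicit_dihedrals:
        params = [pset.find_dihedral(tuple(types[i] for i in q))
                  for q in mol.explicit_dihedrals]
        terms.dihe_idx = np.array(mol.explicit_dihedrals, int)
        terms.dihe_k = np.array([p.k for p in params])
        terms.dihe_n = np.array([p.periodicity for p in params], int)
        terms.dihe_delta = np.radians([p.delta for p in params])

    if mol.explicit_impropers:
        idx, ks, phi0s = [], [], []
        for quad, target in mol.explicit_impropers:
            idx.append(quad)
            if target is not None:
                p = pset.find_improper(tuple(types[i] for i in quad))
                ks.append(p.k if p is not None else improper_k_default)
                phi0s.append(np.radians(target))
            else:
                p = pset.find_improper(tuple(types[i] for i in quad))
                ks.append(p.k)
                phi0s.append(np.radians(p.delta))
        terms.impr_idx = np.array(idx, int)
        terms.impr_k = np.array(ks)
        terms.impr_phi0 = np.array(phi0s)

    if include_repel:
        pairs, sigmas = _repel_pairs(mol, pset, types, default_sigma)
        terms.repel_idx = pairs
        terms.repel_sigma = sigmas
        terms.repel_k = repel_k
        terms.repel_scale = repel_scale

    terms.validate()
    return terms


def _repel_pairs(mol, pset, types, default_sigma):
    """All pairs at bond-graph distance >= 3 (1-2 and 1-3 excluded; 1-4 and
    beyond at full weight), with sigma_ij the arithmetic mean of per-type
    sigmas."""
    n = len(mol.atoms)
    dist = np.full((n, n), 99, int)
    np.fill_diagonal(dist, 0)
    for a, b in mol.bonds:
        dist[a, b] = dist[b, a] = 1
    # two BFS relaxation sweeps are enough to mark distances 1 and 2
    for a, b in mol.bonds:
        for c in range(n):
            if dist[a, c] == 1 and c != b:
                dist[b, c] = dist[c, b] = min(dist[b, c], 2)
            if dist[b, c] == 1 and c != a:
                dist[a, c] = dist[c, a] = min(dist[a, c], 2)

    def sigma(t: str) -> float:
        p = pset.find_nonbonded(t)
        return p.sigma if p is not None else default_sigma

    pairs, sigs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] >= 3:
                pairs.append((i, j))
                sigs.append(0.5 * (sigma(types[i]) + sigma(types[j])))
    if not pairs:
        return np.zeros((0, 2), int), np.zeros(0)
    return np.array(pairs, int), np.array(sigs)


# ---------------------------------------------------------------------------
# geometry kernels (vectorized over term arrays)
# ---------------------------------------------------------------------------

def _wrap(x):
    """Minimal-image angular difference, radians in (-pi, pi]."""
    return -((-x + np.pi) % (2 * np.pi) - np.pi)


def _cross(a, b):
    return np.cross(a, b)


def _dihedrals(coords, idx, grad=False):
    """Signed dihedral (radians) for each index quadruple; optionally the
    analytic derivative d phi / d x for the four participating atoms,
    shaped (m, 4, 3)."""
    x1, x2, x3, x4 = (coords[idx[:, i]] for i in range(4))
    b1 = x2 - x1
    b2 = x3 - x2
    b3 = x4 - x3
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    if np.any(nb2 < 1e-10) or np.any(n1sq < 1e-20) or np.any(n2sq < 1e-20):
        raise EnergyError("degenerate (collinear/overlapping) dihedral frame")
    y = nb2 * np.einsum("ij,ij->i", b1, n2)
    x = np.einsum("ij,ij->i", n1, n2)
    phi = np.arctan2(y, x)
    if not grad:
        return phi, None
    dphi = np.empty(idx.shape + (3,))
    A = -(nb2 / n1sq)[:, None] * n1         # d phi / d x1
    B = (nb2 / n2sq)[:, None] * n2          # d phi / d x4
    c1 = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
    c3 = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
    dphi[:, 0] = A
    dphi[:, 3] = B
    dphi[:, 1] = -(c1 + 1.0) * A + c3 * B
    dphi[:, 2] = c1 * A - (c3 + 1.0) * B
    return phi, dphi


def _angles(coords, idx, grad=False):
    xi, xj, xk = (coords[idx[:, i]] for i in range(3))
    u = xi - xj
    v = xk - xj
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(c)
    if not grad:
        return theta, None
    s = np.sqrt(np.clip(1.0 - c ** 2, 1e-16, None))
    dti = (c[:, None] * uh - vh) / (nu * s)[:, None]
    dtk = (c[:, None] * vh - uh) / (nv * s)[:, None]
    dtheta = np.empty(idx.shape + (3,))
    dtheta[:, 0] = dti
    dtheta[:, 2] = dtk
    dtheta[:, 1] = -(dti + dtk)
    return theta, dtheta


# ---------------------------------------------------------------------------
# energy and gradient
# ---------------------------------------------------------------------------

def energy(coords: np.ndarray, terms: TermList) -> EnergyBreakdown:
    coords = np.asarray(coords, float)
    if not np.all(np.isfinite(coords)):
        raise EnergyError("non-finite coordinates")
    e = _eval(coords, terms, grad=False)[0]
    return e


def gradient(coords: np.ndarray, terms: TermList) -> np.ndarray:
    """Analytic gradient, kcal/mol/A, shaped like ``coords``."""
    coords = np.asarray(coords, float)
    return _eval(coords, terms, grad=True)[1]


def energy_and_gradient(coords: np.ndarray, terms: TermList):
    coords = np.asarray(coords, float)
    return _eval(coords, terms, grad=True)


def _eval(coords, terms, grad):
    g = np.zeros_like(coords) if grad else None
    e_bond = e_angle = e_dihe = e_impr = e_rep = 0.0

    if len(terms.bond_idx):
        i, j = terms.bond_idx[:, 0], terms.bond_idx[:, 1]
        d = coords[i] - coords[j]
        r = np.linalg.norm(d, axis=1)
        db = r - terms.bond_b0
        e_bond = float(np.sum(terms.bond_k * db ** 2))
        if grad:
            f = (2.0 * terms.bond_k * db / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(g, i, f)
            np.add.at(g, j, -f)

    if len(terms.angle_idx):
        theta, dtheta = _angles(coords, terms.angle_idx, grad)
        dt = theta - terms.angle_theta0
        e_angle = float(np.sum(terms.angle_k * dt ** 2))
        if grad:
            coef = (2.0 * terms.angle_k * dt)[:, None, None]
            np.add.at(g, terms.angle_idx.ravel(), (coef * dtheta).reshape(-1, 3))

    if len(terms.dihe_idx):
        phi, dphi = _dihedrals(coords, terms.dihe_idx, grad)
        periodic = terms.dihe_n > 0
        e_arr = np.where(
            periodic,
            terms.dihe_k * (1.0 + np.cos(terms.dihe_n * phi - terms.dihe_delta)),
            terms.dihe_k * _wrap(phi - terms.dihe_delta) ** 2)
        e_dihe = float(np.sum(e_arr))
        if grad:
            dEdphi = np.where(
                periodic,
                -terms.dihe_k * terms.dihe_n * np.sin(terms.dihe_n * phi - terms.dihe_delta),
                2.0 * terms.dihe_k * _wrap(phi - terms.dihe_delta))
            np.add.at(g, terms.dihe_idx.ravel(),
                      (dEdphi[:, None, None] * dphi).reshape(-1, 3))

    if len(terms.impr_idx):
        phi, dphi = _dihedrals(coords, terms.impr_idx, grad)
        dp = _wrap(phi - terms.impr_phi0)
        e_impr = float(np.sum(terms.impr_k * dp ** 2))
        if grad:
            dEdphi = 2.0 * terms.impr_k * dp
            np.add.at(g, terms.impr_idx.ravel(),
                      (dEdphi[:, None, None] * dphi).reshape(-1, 3))

    if len(terms.repel_idx):
        i, j = terms.repel_idx[:, 0], terms.repel_idx[:, 1]
        d = coords[i] - coords[j]
        r2 = np.einsum("ij,ij->i", d, d)
        cut = (terms.repel_scale * terms.repel_sigma) ** 2
        f = np.maximum(0.0, cut - r2)
        e_rep = float(terms.repel_k * np.sum(f ** 2))
        if grad:
            coef = (-4.0 * terms.repel_k * f)[:, None] * d
            np.add.at(g, i, coef)
            np.add.at(g, j, -coef)

    return EnergyBreakdown(e_bond, e_angle, e_dihe, e_impr, e_rep), g
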