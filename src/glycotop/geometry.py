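"""Low-level Cartesian geometry: signed torsions, internal-coordinate atom
placement, and optimal rigid superposition."""

from __future__ import annotations

import numpy as np


class GeometryError(ValueError):
    pass


def signed_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking down p2->p3, a clockwise rotation of the
    far bond relative to the near bond is positive.  Invariant under
    reversal of the point order (the torsion looks the same from either
    end); mirror reflection negates it.  Raises :class:`GeometryError` when
    three consecutive points are (near-)collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb2 < 1e-10:
        raise GeometryError("collinear points: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(nb2 * np.dot(b1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else float(ang)


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees."""
    u = np.asarray(p1, float) - np.asarray(p2, float)
    v = np.asarray(p3, float) - np.asarray(p2, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom d such that |cd| = bond, angle(b,c,d) = angle_deg and
    torsion(a,b,c,d) = torsion_deg (natural-extension reference frame)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               np.sin(ang) * np.sin(tor)])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear frame atoms for placement")
    n /= nn
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def wrap_deg(x):
    """Wrap angle(s) to (-180, 180]."""
    w = (np.asarray(x, float) + 180.0) % 360.0 - 180.0
    return np.where(np.isclose(w, -180.0), 180.0, w)


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation/translation superposing P onto Q (both (n,3)).

    Returns ``(R, t, rmsd)`` with ``P @ R.T + t`` the superposed copy.
    SVD-based with the usual determinant correction against improper
    rotations.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("point sets must both be (n, 3)")
    if P.shape[0] < 3:
        raise GeometryError("need at least 3 points for superposition")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def superposed_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    return kabsch(P, Q)[2]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Qm, R = np.linalg.qr(A)
    Qm = Qm @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] = -Qm[:, 0]
    return Qm


def reflect(coords: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mirror image through the plane normal to one coordinate axis."""
    out = np.array(coords, float, copy=True)
    out[..., axis] = -out[..., axis]
    return out
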