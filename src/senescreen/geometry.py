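"""Rigid-body superposition, dihedral angles, and an ideal-geometry
peptide builder.

The superposition is the classic least-squares (Kabsch) fit: singular
value decomposition of the coordinate cross-covariance, with the sign of
the smallest singular vector flipped when needed so the returned matrix
is always a proper rotation (det = +1).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import GeometryError
from .structure import Structure, AtomPredicate, sel_all

# Ideal peptide internal coordinates (Engh-Huber-style averages), Å / degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
OMEGA_TRANS = 180.0


class SuperpositionResult(NamedTuple):
    rotation: np.ndarray     # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float              # Å, over the fitted atoms


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid transform taking ``mobile`` onto ``reference``.

    Both arrays are (n, 3) with matched rows.  Returns rotation R and
    translation t such that ``mobile @ R.T + t`` minimizes the RMSD to
    ``reference``, plus that minimized RMSD.

    Raises
    ------
    GeometryError
        For fewer than 3 atom pairs or a collinear point set, where the
        rotation is not uniquely determined.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("superposition needs matched (n, 3) coordinate sets")
    n = len(P)
    if n < 3:
        raise GeometryError(f"superposition needs >= 3 atom pairs, got {n}")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    # collinearity: rank of the centered cloud < 2
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise GeometryError("selected atoms are collinear; rotation is degenerate")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    rmsd = float(np.sqrt(max(np.mean(
        np.sum((P0 @ R.T - Q0) ** 2, axis=1)), 0.0)))
    t = qc - R @ pc
    return SuperpositionResult(R, t, rmsd)


def kabsch_superpose(mobile: Structure, reference: Structure,
                     selection: AtomPredicate = sel_all) -> SuperpositionResult:
    """Superpose ``mobile`` onto ``reference`` over the atoms picked by
    ``selection`` that exist (by chain/residue/name identity) in both."""
    mob_sel = mobile.subset(selection)
    ref_sel = reference.subset(selection)
    ref_index = {k: i for i, k in enumerate(ref_sel.atom_keys())}
    pairs = [(i, ref_index[k]) for i, k in enumerate(mob_sel.atom_keys())
             if k in ref_index]
    if len(pairs) < 3:
        raise GeometryError(
            f"selection yields only {len(pairs)} shared atom pairs (need >= 3)")
    mi, ri = zip(*pairs)
    return kabsch(mob_sel.coords[list(mi)], ref_sel.coords[list(ri)])


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d given the
    three previous atoms, the c-d bond length, the b-c-d angle and the
    a-b-c-d torsion."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(n_residues: int, phi: float = -57.0, psi: float = -47.0,
                  chain: str = "A", resname: str = "ALA",
                  origin: np.ndarray | None = None,
                  start_resnum: int = 1) -> Structure:
    """Build an ideal-geometry poly-residue chain with N, CA, C, O, CB
    atoms and uniform backbone torsions (defaults: an α-helix).

    Used as the common topology for synthetic pose ensembles and
    trajectories; the uniform (phi, psi) makes dihedral recovery an exact
    round trip.
    """
    if n_residues < 1:
        raise GeometryError("need at least one residue")
    N = np.array([0.0, 0.0, 0.0])
    CA = N + np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone = [(N, CA, C)]
    for _ in range(1, n_residues):
        pN, pCA, pC = backbone[-1]
        nN = place_atom(pN, pCA, pC, BOND_C_N, ANGLE_CA_C_N, psi)
        nCA = place_atom(pCA, pC, nN, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        nC = place_atom(pC, nN, nCA, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.append((nN, nCA, nC))

    chains, resnums, resnames, names, elements, xyz = [], [], [], [], [], []
    for i, (rN, rCA, rC) in enumerate(backbone):
        resnum = start_resnum + i
        # carbonyl O sits trans to the next amide N in the peptide plane
        O = place_atom(rN, rCA, rC, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        CB = place_atom(rC, rN, rCA, BOND_CA_CB, ANGLE_N_CA_CB, 122.6)
        for nm, el, pos in (("N", "N", rN), ("CA", "C", rCA), ("C", "C", rC),
                            ("O", "O", O), ("CB", "C", CB)):
            chains.append(chain)
            resnums.append(resnum)
            resnames.append(resname)
            names.append(nm)
            elements.append(el)
            xyz.append(pos)
    coords = np.array(xyz, dtype=float)
    if origin is not None:
        coords = coords + np.asarray(origin, dtype=float)
    return Structure(np.array(chains), np.array(resnums, dtype=int),
                     np.array(resnames), np.array(names), np.array(elements),
                     coords)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix with
    sign fix)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
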