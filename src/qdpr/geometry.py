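"""Rigid-body superposition and idealized backbone construction.

Superposition uses the Kabsch algorithm, batched over frames with a single
stacked SVD. The backbone builder places N/CA/C atoms by internal coordinates
(NeRF chain extension) from phi/psi dihedrals, then adds carbonyl O and amide
H by planar geometry — enough structural realism for hydrogen-bond and
surface-area featurization of toy systems and test fixtures.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_rotations", "superpose", "build_backbone", "BackboneAtoms"]

# ideal backbone internal coordinates (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 117.2, 121.7
_OMEGA = 180.0


def kabsch_rotations(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotations aligning each frame of centred ``mobile`` (F, A, 3)
    onto centred ``reference`` (A, 3). Returns (F, 3, 3) proper rotations."""
    h = np.einsum("fai,aj->fij", mobile, reference)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", u, vt))
    flip = np.ones((mobile.shape[0], 3))
    flip[:, 2] = det
    return np.einsum("fij,fj,fjk->fik", u, flip, vt)


def superpose(
    coords: np.ndarray, reference: np.ndarray, fit_atoms: np.ndarray | None = None
) -> np.ndarray:
    """Least-squares superpose every frame onto ``reference``.

    The fit is computed on ``fit_atoms`` (default: all atoms) and the
    resulting rigid transform is applied to all atoms of the frame.
    """
    coords = np.asarray(coords, float)
    if fit_atoms is None:
        fit_atoms = np.arange(coords.shape[1])
    sub = coords[:, fit_atoms]
    ref_sub = reference[fit_atoms]
    ref_centroid = ref_sub.mean(axis=0)
    centroids = sub.mean(axis=1, keepdims=True)
    rot = kabsch_rotations(sub - centroids, ref_sub - ref_centroid)
    return np.einsum("fai,fij->faj", coords - centroids, rot) + ref_centroid


def _place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement of atom d with given internal coordinates to c-b-a."""
    ang, dih = np.deg2rad(angle), np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


class BackboneAtoms(dict):
    """Mapping atom-name -> (n_residues, 3) array; H rows may contain NaN
    where no amide hydrogen exists (the N-terminal residue)."""


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> BackboneAtoms:
    """Build an ideal peptide backbone from per-residue phi/psi (degrees).

    ``phi[0]`` and ``psi[-1]`` are undefined for a real chain and ignored.
    Returns N, CA, C, O, H coordinate arrays (Angstrom).
    """
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    n_res = len(phi)
    if len(psi) != n_res or n_res < 2:
        raise ValueError("need matching phi/psi for at least two residues")

    n = np.zeros((n_res, 3))
    ca = np.zeros((n_res, 3))
    c = np.zeros((n_res, 3))
    # seed the first residue in a canonical pose
    n[0] = (0.0, 0.0, 0.0)
    ca[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    c[0] = ca[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        n[i] = _place_atom(n[i - 1], ca[i - 1], c[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        ca[i] = _place_atom(ca[i - 1], c[i - 1], n[i], _B_N_CA, _A_C_N_CA, _OMEGA)
        c[i] = _place_atom(c[i - 1], n[i], ca[i], _B_CA_C, _A_N_CA_C, phi[i])

    # carbonyl O: in the CA(i)-C(i)-N(i+1) plane, trans to N(i+1)
    o = np.zeros((n_res, 3))
    for i in range(n_res - 1):
        o[i] = _place_atom(n[i + 1], ca[i], c[i], 1.231, 120.5, 180.0)
    # terminal carboxyl O placed trans to N(last) about CA-C
    o[-1] = _place_atom(n[-1], ca[-1], c[-1], 1.231, 120.5, 180.0)

    # amide H: bisector convention, 1.01 A from N opposite CA and C(i-1)
    h = np.full((n_res, 3), np.nan)
    for i in range(1, n_res):
        u1 = n[i] - ca[i]
        u1 /= np.linalg.norm(u1)
        u2 = n[i] - c[i - 1]
        u2 /= np.linalg.norm(u2)
        bis = u1 + u2
        bis /= np.linalg.norm(bis)
        h[i] = n[i] + 1.01 * bis

    out = BackboneAtoms()
    out.update({"N": n, "CA": ca, "C": c, "O": o, "H": h})
    return out
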