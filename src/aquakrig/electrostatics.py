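"""Intermolecular multipolar electrostatics truncated by interaction rank.

A pair of atoms carrying spherical multipoles of ranks l_A and l_B interacts
at overall rank L = l_A + l_B + 1; an electrostatic model "at rank L"
includes every pair interaction with l_A + l_B + 1 <= L.  With atomic
moments limited to rank 2 (quadrupole) and L <= 3 the required couplings are
charge-charge (1/R), charge-dipole (1/R^2), dipole-dipole and
charge-quadrupole (1/R^3).

Internally the spherical components are converted to Cartesian tensors
(charge q, dipole vector mu, traceless quadrupole Theta) and the classical
closed forms are used, with R the vector from atom A to atom B and u = R/|R|:

    E_qq = qA qB / R
    E_qd = [qB (muA . u) - qA (muB . u)] / R^2
    E_dd = [muA . muB - 3 (muA . u)(muB . u)] / R^3
    E_qQ = [qA (u' ThetaB u) + qB (u' ThetaA u)] / R^3

Energies are converted to kJ/mol with the Coulomb factor e^2/(4 pi eps0);
analytic derivatives with respect to R and to the moment components are
provided for force evaluation.  Intramolecular pairs are excluded from
cluster sums (intramolecular physics lives in the learned atomic energies).
"""

from __future__ import annotations

import numpy as np

from .constants import COULOMB
from .multipoles import (
    MultipoleSet,
    _UNIT_THETA,
    dipole_to_cartesian,
    quadrupole_to_cartesian,
)

__all__ = [
    "admitted_pairs",
    "interaction_tensor",
    "pair_electrostatic_energy",
    "total_electrostatic_energy",
    "electrostatic_energy_forces",
]

_MAX_ATOM_RANK = 2


def admitted_pairs(L: int) -> set[tuple[int, int]]:
    """Rank pairs (l_A, l_B) admitted at overall interaction rank L.

    L = 1 gives charge-charge only; L = 3 gives the six couplings up to
    dipole-dipole and charge-quadrupole.
    """
    if L < 1:
        raise ValueError("interaction rank L must be >= 1")
    return {
        (la, lb)
        for la in range(_MAX_ATOM_RANK + 1)
        for lb in range(_MAX_ATOM_RANK + 1)
        if la + lb + 1 <= L
    }


def _pair_cartesian_energy(qa, mua, tha, qb, mub, thb, R, L):
    """Vectorised pair energies (no Coulomb factor); R is (..., 3) from A to B."""
    r2 = np.sum(R * R, axis=-1)
    r = np.sqrt(r2)
    u = R / r[..., None]
    pairs = admitted_pairs(L)
    if any(la + lb > 2 for la, lb in pairs):
        raise NotImplementedError("interactions beyond l_A + l_B = 2 are not supported")

    e = np.zeros(np.shape(r))
    if (0, 0) in pairs:
        e = e + qa * qb / r
    if (0, 1) in pairs:  # includes (1, 0) by construction of admitted_pairs
        mua_u = np.sum(mua * u, axis=-1)
        mub_u = np.sum(mub * u, axis=-1)
        e = e + (qb * mua_u - qa * mub_u) / r2
    if (1, 1) in pairs:
        mua_u = np.sum(mua * u, axis=-1)
        mub_u = np.sum(mub * u, axis=-1)
        e = e + (np.sum(mua * mub, axis=-1) - 3.0 * mua_u * mub_u) / (r2 * r)
    if (0, 2) in pairs:
        ua_th_a = np.einsum("...a,...ab,...b->...", u, tha, u)
        ua_th_b = np.einsum("...a,...ab,...b->...", u, thb, u)
        e = e + (qa * ua_th_b + qb * ua_th_a) / (r2 * r)
    return e


def _pair_cartesian_derivatives(qa, mua, tha, qb, mub, thb, R, L):
    """Energy, dE/dR and moment partials for every pair; all vectorised.

    Returns (e, dR, dqa, dmua, dtha, dqb, dmub, dthb) without the Coulomb
    factor; dtha/dthb are full (..., 3, 3) matrices to be contracted with the
    traceless unit tensors.
    """
    r2 = np.sum(R * R, axis=-1)
    r = np.sqrt(r2)
    u = R / r[..., None]
    r3 = r2 * r
    r5 = r3 * r2
    pairs = admitted_pairs(L)

    shape = np.shape(r)
    e = np.zeros(shape)
    dR = np.zeros(shape + (3,))
    dqa = np.zeros(shape)
    dqb = np.zeros(shape)
    dmua = np.zeros(shape + (3,))
    dmub = np.zeros(shape + (3,))
    dtha = np.zeros(shape + (3, 3))
    dthb = np.zeros(shape + (3, 3))

    if (0, 0) in pairs:
        e += qa * qb / r
        dR += -(qa * qb / r3)[..., None] * R
        dqa += qb / r
        dqb += qa / r

    if (0, 1) in pairs:
        mua_R = np.sum(mua * R, axis=-1)
        mub_R = np.sum(mub * R, axis=-1)
        e += (qb * mua_R - qa * mub_R) / r3
        dR += (qb[..., None] * mua - qa[..., None] * mub) / r3[..., None] - (
            3.0 * (qb * mua_R - qa * mub_R) / r5
        )[..., None] * R
        dqa += -mub_R / r3
        dqb += mua_R / r3
        dmua += (qb / r3)[..., None] * R
        dmub += -(qa / r3)[..., None] * R

    if (1, 1) in pairs:
        mua_R = np.sum(mua * R, axis=-1)
        mub_R = np.sum(mub * R, axis=-1)
        dot = np.sum(mua * mub, axis=-1)
        e += dot / r3 - 3.0 * mua_R * mub_R / r5
        dR += (
            -(3.0 * dot / r5)[..., None] * R
            - (3.0 / r5)[..., None] * (mua * mub_R[..., None] + mub * mua_R[..., None])
            + (15.0 * mua_R * mub_R / (r5 * r2))[..., None] * R
        )
        dmua += mub / r3[..., None] - (3.0 * mub_R / r5)[..., None] * R
        dmub += mua / r3[..., None] - (3.0 * mua_R / r5)[..., None] * R

    if (0, 2) in pairs:
        thaR = np.einsum("...ab,...b->...a", tha, R)
        thbR = np.einsum("...ab,...b->...a", thb, R)
        RthaR = np.sum(R * thaR, axis=-1)
        RthbR = np.sum(R * thbR, axis=-1)
        e += (qa * RthbR + qb * RthaR) / r5
        dR += (
            2.0 * (qa[..., None] * thbR + qb[..., None] * thaR) / r5[..., None]
            - (5.0 * (qa * RthbR + qb * RthaR) / (r5 * r2))[..., None] * R
        )
        dqa += RthbR / r5
        dqb += RthaR / r5
        RR = R[..., :, None] * R[..., None, :]
        dtha += (qb / r5)[..., None, None] * RR
        dthb += (qa / r5)[..., None, None] * RR

    return e, dR, dqa, dmua, dtha, dqb, dmub, dthb


def _split_cartesian(moments: np.ndarray):
    """(..., 9) spherical components -> (q, mu, Theta) Cartesian views."""
    Q = np.asarray(moments, dtype=float)
    return Q[..., 0], dipole_to_cartesian(Q[..., 1:4]), quadrupole_to_cartesian(Q[..., 4:9])


def _unit_component(l: int, m: int) -> np.ndarray:
    if not 0 <= l <= _MAX_ATOM_RANK:
        raise ValueError("rank must be 0, 1 or 2")
    sizes = {0: 1, 1: 3, 2: 5}
    if not 0 <= m < sizes[l]:
        raise ValueError(f"component index {m} invalid for rank {l}")
    Q = np.zeros(9)
    Q[{0: 0, 1: 1, 2: 4}[l] + m] = 1.0
    return Q


def interaction_tensor(l_A: int, m_A: int, l_B: int, m_B: int, R_vec: np.ndarray) -> float:
    """Coupling between unit spherical components across a separation R_vec.

    Component indices follow the storage order within each rank:
    (0), (10, 11c, 11s), (20, 21c, 21s, 22c, 22s).  The value scales as
    |R|^-(l_A + l_B + 1) and carries no Coulomb factor (units A^-(lA+lB+1)).
    """
    if l_A + l_B > 2:
        raise ValueError("interaction tensors implemented for l_A + l_B <= 2")
    R = np.asarray(R_vec, dtype=float)
    if np.linalg.norm(R) == 0:
        raise ValueError("zero separation")
    qa, mua, tha = _split_cartesian(_unit_component(l_A, m_A))
    qb, mub, thb = _split_cartesian(_unit_component(l_B, m_B))
    return float(_pair_cartesian_energy(qa, mua, tha, qb, mub, thb, R, L=l_A + l_B + 1))


def pair_electrostatic_energy(
    Q_A: MultipoleSet, Q_B: MultipoleSet, R_vec: np.ndarray, L: int
) -> float:
    """Electrostatic energy (kJ/mol) of one atom pair at truncation rank L.

    Both moment sets must be tagged global-frame; R_vec points from A to B in
    angstrom.
    """
    if Q_A.frame != "global" or Q_B.frame != "global":
        raise ValueError("pair energies require global-frame moments")
    R = np.asarray(R_vec, dtype=float)
    if np.linalg.norm(R) == 0:
        raise ValueError("zero separation")
    qa, mua, tha = _split_cartesian(Q_A.components)
    qb, mub, thb = _split_cartesian(Q_B.components)
    return COULOMB * float(_pair_cartesian_energy(qa, mua, tha, qb, mub, thb, R, L))


def _intermolecular_pairs(
    positions: np.ndarray, molecule_index: np.ndarray, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    n = len(positions)
    ii, jj = np.triu_indices(n, k=1)
    keep = molecule_index[ii] != molecule_index[jj]
    ii, jj = ii[keep], jj[keep]
    d = positions[jj] - positions[ii]
    keep = np.sum(d * d, axis=-1) <= cutoff**2
    return ii[keep], jj[keep]


def total_electrostatic_energy(
    positions: np.ndarray,
    molecule_index: np.ndarray,
    moments: np.ndarray,
    L: int,
    cutoff: float = 30.0,
) -> float:
    """Direct-space sum over intermolecular atom pairs within the cutoff.

    positions (N, 3) A; molecule_index (N,); moments (N, 9) global-frame
    spherical components.  Nonperiodic: no images, no switching function.
    """
    positions = np.asarray(positions, dtype=float)
    molecule_index = np.asarray(molecule_index)
    ii, jj = _intermolecular_pairs(positions, molecule_index, cutoff)
    if len(ii) == 0:
        return 0.0
    q, mu, th = _split_cartesian(moments)
    e = _pair_cartesian_energy(
        q[ii], mu[ii], th[ii], q[jj], mu[jj], th[jj], positions[jj] - positions[ii], L
    )
    return COULOMB * float(np.sum(e))


def electrostatic_energy_forces(
    positions: np.ndarray,
    molecule_index: np.ndarray,
    moments: np.ndarray,
    L: int,
    cutoff: float = 30.0,
    moment_jacobians: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Energy (kJ/mol) and per-atom forces (kJ/mol/A) of the truncated sum.

    ``moment_jacobians``, when given, holds d(moments)/d(positions) per
    molecule with shape (N_mol, 3, 9, 9): for molecule M, atom a within M and
    spherical component c, the derivative with respect to the molecule's nine
    Cartesian coordinates (atom-major).  These polarization terms make the
    forces the exact gradient of the energy as the predicted moments respond
    to geometry; omit them for geometry-frozen (rigid) moments.
    """
    positions = np.asarray(positions, dtype=float)
    molecule_index = np.asarray(molecule_index)
    n = len(positions)
    ii, jj = _intermolecular_pairs(positions, molecule_index, cutoff)
    forces = np.zeros((n, 3))
    if len(ii) == 0:
        return 0.0, forces

    q, mu, th = _split_cartesian(moments)
    R = positions[jj] - positions[ii]
    e, dR, dqa, dmua, dtha, dqb, dmub, dthb = _pair_cartesian_derivatives(
        q[ii], mu[ii], th[ii], q[jj], mu[jj], th[jj], R, L
    )
    energy = COULOMB * float(np.sum(e))

    # positional (interaction-tensor) part: E depends on R = r_j - r_i
    np.add.at(forces, jj, -COULOMB * dR)
    np.add.at(forces, ii, +COULOMB * dR)

    if moment_jacobians is not None:
        # accumulate dE/dQ per atom in the spherical representation
        dE_dQ = np.zeros((n, 9))
        np.add.at(dE_dQ, ii, _cartesian_to_spherical_partials(dqa, dmua, dtha))
        np.add.at(dE_dQ, jj, _cartesian_to_spherical_partials(dqb, dmub, dthb))
        dE_dQ *= COULOMB
        jac = np.asarray(moment_jacobians)
        n_mol = jac.shape[0]
        dE_dQ_mol = dE_dQ.reshape(n_mol, 3, 9)
        # (mol, atom, comp) x (mol, atom, comp, coord) -> (mol, 9 coords)
        grad = np.einsum("mac,macx->mx", dE_dQ_mol, jac)
        forces -= grad.reshape(n, 3)

    return energy, forces


def _cartesian_to_spherical_partials(dq, dmu, dth):
    """Convert (dE/dq, dE/dmu, dE/dTheta) into dE/d(9 spherical components)."""
    out = np.zeros(np.shape(dq) + (9,))
    out[..., 0] = dq
    out[..., 1] = dmu[..., 2]  # Q10 -> mu_z
    out[..., 2] = dmu[..., 0]  # Q11c -> mu_x
    out[..., 3] = dmu[..., 1]  # Q11s -> mu_y
    out[..., 4:9] = np.einsum("mab,...ab->...m", _UNIT_THETA, dth)
    return out
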