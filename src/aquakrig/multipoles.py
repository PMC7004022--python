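"""Real spherical atomic multipole moments, ranks 0-2, and their rotation.

Moments are stored as 9-component vectors in the order

    (Q00, Q10, Q11c, Q11s, Q20, Q21c, Q21s, Q22c, Q22s)

using real tesseral harmonics with Racah normalization, so the components
relate to Cartesian tensors by

    dipole:     mu = (Q11c, Q11s, Q10)                      [e A]
    quadrupole: Theta_zz = Q20, Theta_xz = (sqrt3/2) Q21c, ...  [e A^2]

with the traceless Cartesian quadrupole Theta_ab = sum_i q_i (3 a_i b_i -
r_i^2 delta_ab) / 2.  Rank-2 rotations are carried out by the Cartesian
round trip spherical -> Theta -> R Theta R^T -> spherical, which is exact and
avoids hand-coded Wigner matrices.  All routines broadcast over leading axes
and preserve complex dtypes (complex-step differentiable).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import LocalFrame

__all__ = [
    "MultipoleSet",
    "COMPONENT_NAMES",
    "dipole_to_cartesian",
    "cartesian_to_dipole",
    "quadrupole_to_cartesian",
    "cartesian_to_quadrupole",
    "rotate_moment_array",
    "rotate_multipoles",
]

COMPONENT_NAMES = ("q00", "q10", "q11c", "q11s", "q20", "q21c", "q21s", "q22c", "q22s")

_S3H = np.sqrt(3.0) / 2.0

# dTheta / dQ2m, shape (5, 3, 3); also the inverse-conversion basis
_UNIT_THETA = np.zeros((5, 3, 3))
_UNIT_THETA[0] = np.diag([-0.5, -0.5, 1.0])             # Q20
_UNIT_THETA[1][0, 2] = _UNIT_THETA[1][2, 0] = _S3H      # Q21c
_UNIT_THETA[2][1, 2] = _UNIT_THETA[2][2, 1] = _S3H      # Q21s
_UNIT_THETA[3] = np.diag([_S3H, -_S3H, 0.0])            # Q22c
_UNIT_THETA[4][0, 1] = _UNIT_THETA[4][1, 0] = _S3H      # Q22s


def dipole_to_cartesian(q1: np.ndarray) -> np.ndarray:
    """(Q10, Q11c, Q11s) -> (mu_x, mu_y, mu_z); broadcasts over leading axes."""
    q1 = np.asarray(q1)
    return np.stack([q1[..., 1], q1[..., 2], q1[..., 0]], axis=-1)


def cartesian_to_dipole(mu: np.ndarray) -> np.ndarray:
    mu = np.asarray(mu)
    return np.stack([mu[..., 2], mu[..., 0], mu[..., 1]], axis=-1)


def quadrupole_to_cartesian(q2: np.ndarray) -> np.ndarray:
    """(Q20..Q22s) -> traceless Cartesian Theta, shape (..., 3, 3)."""
    return np.einsum("...m,mab->...ab", np.asarray(q2), _UNIT_THETA)


def cartesian_to_quadrupole(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta)
    inv_s3h = 1.0 / _S3H
    return np.stack(
        [
            theta[..., 2, 2],
            inv_s3h * theta[..., 0, 2],
            inv_s3h * theta[..., 1, 2],
            (theta[..., 0, 0] - theta[..., 1, 1]) / np.sqrt(3.0),
            inv_s3h * theta[..., 0, 1],
        ],
        axis=-1,
    )


def rotate_moment_array(moments: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Rotate 9-component moment vectors by (...,3,3) rotation matrices.

    Rank 0 is invariant; rank 1 rotates as a Cartesian vector; rank 2 via the
    traceless-Cartesian round trip.  Broadcasts over leading axes.
    """
    Q = np.asarray(moments)
    R = np.asarray(rotation)
    mu = np.einsum("...ab,...b->...a", R, dipole_to_cartesian(Q[..., 1:4]))
    theta = quadrupole_to_cartesian(Q[..., 4:9])
    theta_rot = np.einsum("...ac,...cd,...bd->...ab", R, theta, R)
    q0 = np.broadcast_to(Q[..., :1], mu.shape[:-1] + (1,))
    return np.concatenate(
        [q0, cartesian_to_dipole(mu), cartesian_to_quadrupole(theta_rot)], axis=-1
    )


@dataclasses.dataclass
class MultipoleSet:
    """Real spherical moments of one atom, ranks 0-2, with a frame tag.

    ``frame`` is "local" (body-fixed axes of the atom) or "global" (laboratory
    axes); electrostatics refuses local-frame moments.
    """

    components: np.ndarray  # (9,)
    frame: str = "local"

    def __post_init__(self) -> None:
        comp = np.asarray(self.components, dtype=float)
        if comp.shape != (9,):
            raise ValueError(f"expected 9 components (ranks 0-2), got {comp.shape}")
        if self.frame not in ("local", "global"):
            raise ValueError(f"frame must be 'local' or 'global', got {self.frame!r}")
        self.components = comp

    @property
    def charge(self) -> float:
        return float(self.components[0])

    @property
    def dipole(self) -> np.ndarray:
        return self.components[1:4]

    @property
    def quadrupole(self) -> np.ndarray:
        return self.components[4:9]

    @property
    def dipole_cartesian(self) -> np.ndarray:
        return dipole_to_cartesian(self.dipole)

    @property
    def quadrupole_cartesian(self) -> np.ndarray:
        return quadrupole_to_cartesian(self.quadrupole)

    def rank_norms(self) -> np.ndarray:
        """Euclidean norm of each rank's components (rotation invariants)."""
        return np.array(
            [
                abs(self.charge),
                float(np.linalg.norm(self.dipole)),
                float(np.linalg.norm(self.quadrupole)),
            ]
        )

    @classmethod
    def from_charge(cls, q: float, frame: str = "global") -> "MultipoleSet":
        comp = np.zeros(9)
        comp[0] = q
        return cls(comp, frame)


def rotate_multipoles(moments: MultipoleSet, frame: LocalFrame) -> MultipoleSet:
    """Express local-frame moments in the global frame via the atom's axes."""
    if moments.frame != "local":
        raise ValueError("rotate_multipoles expects local-frame moments")
    rotated = rotate_moment_array(moments.components, frame.rotation)
    return MultipoleSet(rotated, frame="global")
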