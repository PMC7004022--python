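"""Geometric primitives for the water monomer.

A water configuration is an ordered (O, H1, H2) triple of Cartesian positions
in angstrom.  Three internal coordinates -- the two O-H bond lengths and the
H-O-H angle -- form a complete, rotation- and translation-invariant feature
set for a three-atom molecule; every machine-learned atomic property in this
package is a function of these three features alone.

Vector and tensor properties (dipoles, quadrupoles) additionally need a
body-fixed axis system per atom so that they can be learned in a frame that
co-rotates with the molecule.  The convention used here:

* O atom: x along the H-O-H bisector, z along (O->H1) x (O->H2) (the
  molecular-plane normal), y completing a right-handed set.
* H atoms: x along H->O, z along the same molecular-plane normal, y = z cross x.

All frame math is written dtype-generically (no branching, unconjugated
norms) so that complex-step differentiation through it is exact.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .constants import SEED_ANGLE_DEG, SEED_R_OH

__all__ = [
    "WaterConfiguration",
    "FeatureVector",
    "LocalFrame",
    "seed_configuration",
    "compute_features",
    "features_from_positions",
    "feature_jacobian",
    "build_local_frame",
    "frame_rotations",
]

#: atom ordering of every water configuration in this package
ATOM_ORDER = ("O", "H", "H")

_MIN_BOND = 0.3  # A; below this the geometry is considered unphysical


def _vnorm(v: np.ndarray) -> np.ndarray:
    # unconjugated norm: exact under complex-step differentiation
    return np.sqrt(np.sum(v * v, axis=-1))


@dataclasses.dataclass
class WaterConfiguration:
    """One water molecule: positions (3, 3) in angstrom, rows (O, H1, H2)."""

    positions: np.ndarray
    molecule_id: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (3, 3):
            raise ValueError(f"positions must be (3, 3), got {pos.shape}")
        self.positions = pos
        r1, r2, theta = features_from_positions(pos)
        if r1 <= _MIN_BOND or r2 <= _MIN_BOND:
            raise ValueError(
                f"O-H bond lengths must exceed {_MIN_BOND} A (got {r1:.3f}, {r2:.3f})"
            )
        if not (0.0 < theta < np.pi):
            raise ValueError(f"H-O-H angle must lie in (0, pi), got {theta:.6f} rad")

    @property
    def oxygen(self) -> np.ndarray:
        return self.positions[0]

    @property
    def hydrogens(self) -> np.ndarray:
        return self.positions[1:]

    def translated(self, shift: np.ndarray) -> "WaterConfiguration":
        return WaterConfiguration(self.positions + np.asarray(shift), self.molecule_id)

    def rotated(self, rotation: np.ndarray) -> "WaterConfiguration":
        """Apply a proper rotation matrix about the origin."""
        return WaterConfiguration(
            self.positions @ np.asarray(rotation).T, self.molecule_id
        )

    def swapped_hydrogens(self) -> "WaterConfiguration":
        return WaterConfiguration(self.positions[[0, 2, 1]], self.molecule_id)


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """Internal coordinates (r_OH1, r_OH2, theta_HOH); lengths in A, angle in rad."""

    r1: float
    r2: float
    theta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.theta])

    @property
    def theta_degrees(self) -> float:
        return float(np.degrees(self.theta))


N_FEAT = 3


@dataclasses.dataclass(frozen=True)
class LocalFrame:
    """Body-fixed axis system: origin at the nucleus, rotation maps local->global."""

    origin: np.ndarray
    rotation: np.ndarray  # (3, 3), columns are the local x, y, z axes in global coords

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-12):
            raise ValueError("frame rotation must be orthonormal to 1e-12")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-12):
            raise ValueError("frame rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))


def seed_configuration(
    r_oh: float = SEED_R_OH, angle_deg: float = SEED_ANGLE_DEG
) -> WaterConfiguration:
    """Equilibrium monomer in the molecular (xy) plane, bisector along +x.

    O sits at the origin; the two hydrogens are placed symmetrically about the
    x axis at the given bond length and opening angle.
    """
    half = 0.5 * np.radians(angle_deg)
    h1 = r_oh * np.array([np.cos(half), np.sin(half), 0.0])
    h2 = r_oh * np.array([np.cos(half), -np.sin(half), 0.0])
    return WaterConfiguration(np.array([[0.0, 0.0, 0.0], h1, h2]))


def features_from_positions(positions: np.ndarray) -> np.ndarray:
    """Internal coordinates (r1, r2, theta) from a (..., 3, 3) position array."""
    pos = np.asarray(positions)
    b1 = pos[..., 1, :] - pos[..., 0, :]
    b2 = pos[..., 2, :] - pos[..., 0, :]
    r1 = _vnorm(b1)
    r2 = _vnorm(b2)
    c = np.sum(b1 * b2, axis=-1) / (r1 * r2)
    if not np.iscomplexobj(c):
        c = np.clip(c, -1.0, 1.0)
    theta = np.arccos(c)
    return np.stack([r1, r2, theta], axis=-1)


def compute_features(config: WaterConfiguration) -> FeatureVector:
    """Rotation/translation-invariant features of one configuration."""
    r1, r2, theta = features_from_positions(config.positions)
    if np.sin(theta) < 1e-10:
        raise ValueError("degenerate (collinear) geometry: H-O-H angle is 0 or pi")
    return FeatureVector(float(r1), float(r2), float(theta))


def feature_jacobian(positions: np.ndarray) -> np.ndarray:
    """Wilson B-matrix d(features)/d(positions), shape (3, 3, 3).

    Axis 0 indexes the feature (r1, r2, theta), axis 1 the atom (O, H1, H2),
    axis 2 the Cartesian component.
    """
    pos = np.asarray(positions, dtype=float)
    b1 = pos[1] - pos[0]
    b2 = pos[2] - pos[0]
    r1 = np.linalg.norm(b1)
    r2 = np.linalg.norm(b2)
    u1 = b1 / r1
    u2 = b2 / r2
    cos_t = float(np.clip(u1 @ u2, -1.0, 1.0))
    sin_t = np.sqrt(max(1.0 - cos_t**2, 0.0))
    if sin_t < 1e-10:
        raise ValueError("angle gradient undefined for collinear geometry")

    B = np.zeros((3, 3, 3))
    B[0, 1] = u1
    B[0, 0] = -u1
    B[1, 2] = u2
    B[1, 0] = -u2
    dt_h1 = (cos_t * u1 - u2) / (r1 * sin_t)
    dt_h2 = (cos_t * u2 - u1) / (r2 * sin_t)
    B[2, 1] = dt_h1
    B[2, 2] = dt_h2
    B[2, 0] = -(dt_h1 + dt_h2)
    return B


def frame_rotations(positions: np.ndarray) -> np.ndarray:
    """Local->global rotation matrices for the O, H1, H2 frames.

    Accepts a (..., 3, 3) position array (real or complex) and returns
    (..., 3, 3, 3): for each configuration, three rotation matrices whose
    columns are the local x, y, z axes expressed in the global frame.
    """
    pos = np.asarray(positions)
    b1 = pos[..., 1, :] - pos[..., 0, :]
    b2 = pos[..., 2, :] - pos[..., 0, :]
    u1 = b1 / _vnorm(b1)[..., None]
    u2 = b2 / _vnorm(b2)[..., None]

    n = np.cross(u1, u2)
    z = n / _vnorm(n)[..., None]

    bis = u1 + u2
    x_o = bis / _vnorm(bis)[..., None]
    y_o = np.cross(z, x_o)

    x_h1 = -u1
    y_h1 = np.cross(z, x_h1)
    x_h2 = -u2
    y_h2 = np.cross(z, x_h2)

    def _assemble(x, y):
        return np.stack([x, y, z], axis=-1)  # columns

    return np.stack([_assemble(x_o, y_o), _assemble(x_h1, y_h1), _assemble(x_h2, y_h2)], axis=-3)


def build_local_frame(config: WaterConfiguration, atom_index: int) -> LocalFrame:
    """Body-fixed frame of one atom (0 = O, 1 = H1, 2 = H2)."""
    if atom_index not in (0, 1, 2):
        raise ValueError("atom_index must be 0, 1 or 2")
    theta = compute_features(config).theta  # raises on collinearity
    del theta
    R = frame_rotations(config.positions)[atom_index]
    return LocalFrame(origin=config.positions[atom_index], rotation=R)
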