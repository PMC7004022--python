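"""NVT/NVE molecular dynamics of water clusters with learned monomer models.

The total potential of a cluster of flexible monomers is

    E = sum_mol sum_A E_A(f_mol)            (kriged atomic energies)
      + sum_{intermolecular pairs} E_elec   (multipolar, truncated at rank L)
      + sum_{intermolecular pairs} E_LJ     (shifted 12-6, Lorentz-Berthelot)

with the atomic multipole moments re-predicted from the current monomer
geometry every step -- this geometric response of the moments is the
polarization mechanism, and its gradient contribution is included in the
forces, which are the exact gradient of E (net force is zero to rounding).

Equations of motion are integrated with velocity Verlet (1 fs default
timestep); temperature is maintained by the Andersen thermostat (independent
per-atom Maxwell-Boltzmann velocity redraws at a fixed collision rate).
Clusters are non-periodic (a droplet in vacuum); the Lennard-Jones cutoff is
10 A with the potential shifted to zero at the cutoff, and electrostatics
use a direct-space 30 A cutoff that exceeds any cluster diameter here.

Rigid-monomer control simulations reset each molecule to its reference
internal geometry after every position update (mass-weighted best-fit
superposition) and project velocities onto rigid-body motion; local-frame
moments are then frozen at their reference values, though they still
co-rotate with each molecule.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .constants import EUNIT, KB, MASS_H, MASS_O
from .electrostatics import electrostatic_energy_forces
from .geometry import frame_rotations, seed_configuration
from .models import (
    KrigingStack,
    WaterModelSet,
    molecule_global_moments,
    molecule_moment_jacobians,
)
from .multipoles import rotate_moment_array

__all__ = [
    "LJParameters",
    "SimulationState",
    "WaterForceField",
    "lj_energy_force",
    "intramolecular_energy_forces",
    "andersen_thermostat",
    "velocity_verlet_step",
    "initialize_cluster",
    "run_simulation",
    "SimulationBlowupError",
]

_MASSES = np.array([MASS_O, MASS_H, MASS_H])  # per molecule, atom-ordered


@dataclasses.dataclass(frozen=True)
class LJParameters:
    """12-6 parameters for O and H with Lorentz-Berthelot combination."""

    epsilon_oo: float = 0.753   # kJ/mol
    epsilon_hh: float = 0.015   # kJ/mol
    sigma_oo: float = 3.23      # A
    sigma_hh: float = 1.10      # A

    def __post_init__(self) -> None:
        if self.epsilon_oo < 0 or self.epsilon_hh < 0:
            raise ValueError("epsilon must be non-negative")
        if self.sigma_oo <= 0 or self.sigma_hh <= 0:
            raise ValueError("sigma must be positive")

    @property
    def epsilon_oh(self) -> float:
        return float(np.sqrt(self.epsilon_oo * self.epsilon_hh))

    @property
    def sigma_oh(self) -> float:
        return 0.5 * (self.sigma_oo + self.sigma_hh)

    def tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(epsilon, sigma) lookup tables indexed by species (0 = O, 1 = H)."""
        eps = np.array([[self.epsilon_oo, self.epsilon_oh],
                        [self.epsilon_oh, self.epsilon_hh]])
        sig = np.array([[self.sigma_oo, self.sigma_oh],
                        [self.sigma_oh, self.sigma_hh]])
        return eps, sig


def lj_energy_force(
    r: np.ndarray, epsilon: float, sigma: float, cutoff: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Shifted 12-6 energy and radial derivative dE/dr at separation r.

    The energy is shifted so it is exactly zero at the cutoff; the force uses
    the unshifted derivative and both vanish beyond the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separations must be positive")
    sr6 = (sigma / r) ** 6
    src6 = (sigma / cutoff) ** 6
    shift = 4.0 * epsilon * (src6 * src6 - src6)
    inside = r <= cutoff
    e = np.where(inside, 4.0 * epsilon * (sr6 * sr6 - sr6) - shift, 0.0)
    dedr = np.where(inside, -24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r, 0.0)
    return e, dedr


@dataclasses.dataclass
class SimulationState:
    """Positions/velocities/forces of N_mol molecules (A, A/fs, kJ/mol/A)."""

    positions: np.ndarray    # (M, 3, 3)
    velocities: np.ndarray   # (M, 3, 3)
    forces: np.ndarray       # (M, 3, 3)
    time: float = 0.0        # fs

    def __post_init__(self) -> None:
        shape = np.shape(self.positions)
        if len(shape) != 3 or shape[1:] != (3, 3):
            raise ValueError("positions must be (N_mol, 3, 3)")
        if np.shape(self.velocities) != shape or np.shape(self.forces) != shape:
            raise ValueError("velocities/forces must match positions")

    @property
    def n_mol(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return 3 * self.n_mol

    def kinetic_energy(self) -> float:
        v2 = np.sum(self.velocities**2, axis=-1)
        return float(0.5 * EUNIT * np.sum(_MASSES[None, :] * v2))

    def temperature(self, dof: int | None = None) -> float:
        if dof is None:
            dof = 3 * self.n_atoms
        return 2.0 * self.kinetic_energy() / (dof * KB)


def intramolecular_energy_forces(
    positions: np.ndarray, energy_stack: KrigingStack
) -> tuple[float, np.ndarray]:
    """Summed kriged atomic energies and their exact force contribution."""
    from .geometry import feature_jacobian, features_from_positions

    pos = np.asarray(positions, dtype=float)
    feats = features_from_positions(pos)
    pred, grad = energy_stack.predict_with_gradients(np.atleast_2d(feats))
    energy = float(np.sum(pred))
    dEdf = grad.sum(axis=1)                                   # (M, 3)
    B = np.stack([feature_jacobian(p).reshape(3, 9) for p in pos])
    forces = -np.einsum("mh,mhx->mx", dEdf, B).reshape(pos.shape)
    return energy, forces


class WaterForceField:
    """Total energy/force evaluator for a cluster of water monomers.

    Parameters
    ----------
    models : trained :class:`WaterModelSet` (energies required; moments
        required unless frozen moments are supplied).
    L : electrostatic truncation rank (1, 2 or 3).
    flexible : re-predict local moments from geometry each evaluation
        (polarizable); if False, local moments are frozen at the reference
        geometry's values and only co-rotate with each molecule.
    """

    def __init__(
        self,
        models: WaterModelSet,
        L: int = 3,
        lj: LJParameters = LJParameters(),
        lj_cutoff: float = 10.0,
        elec_cutoff: float = 30.0,
        flexible: bool = True,
        reference_positions: np.ndarray | None = None,
    ) -> None:
        if L not in (1, 2, 3):
            raise ValueError("electrostatic rank L must be 1, 2 or 3")
        self.L = L
        self.lj = lj
        self.lj_cutoff = lj_cutoff
        self.elec_cutoff = elec_cutoff
        self.flexible = flexible
        self.energy_stack = models.energy_stack()
        self.moment_stack = models.moment_stack()
        self._frozen_q_loc: np.ndarray | None = None
        if not flexible:
            ref = (
                np.asarray(reference_positions, dtype=float)
                if reference_positions is not None
                else seed_configuration().positions
            )
            _, q_loc = molecule_global_moments(ref[None], self.moment_stack)
            self._frozen_q_loc = q_loc[0]  # (3, 9)
        eps, sig = lj.tables()
        self._lj_eps = eps
        self._lj_sig = sig
        self._species = np.array([0, 1, 1])

    def _moments_and_jacobians(self, pos: np.ndarray, with_jac: bool):
        m = pos.shape[0]
        if self.flexible:
            q_glob, q_loc = molecule_global_moments(pos, self.moment_stack)
            jac = (
                molecule_moment_jacobians(pos, self.moment_stack, q_loc)
                if with_jac
                else None
            )
        else:
            q_loc = np.broadcast_to(self._frozen_q_loc, (m, 3, 9))
            rots = frame_rotations(pos)
            q_glob = rotate_moment_array(q_loc, rots)
            jac = molecule_moment_jacobians(pos, None, q_loc) if with_jac else None
        return q_glob, jac

    def _lj_energy_forces(self, pos_flat: np.ndarray, mol_index: np.ndarray):
        n = len(pos_flat)
        ii, jj = np.triu_indices(n, k=1)
        keep = mol_index[ii] != mol_index[jj]
        ii, jj = ii[keep], jj[keep]
        d = pos_flat[jj] - pos_flat[ii]
        r2 = np.sum(d * d, axis=-1)
        keep = r2 <= self.lj_cutoff**2
        ii, jj, d, r2 = ii[keep], jj[keep], d[keep], r2[keep]
        forces = np.zeros((n, 3))
        if len(ii) == 0:
            return 0.0, forces
        r = np.sqrt(r2)
        sp = np.tile(self._species, n // 3)
        eps = self._lj_eps[sp[ii], sp[jj]]
        sig = self._lj_sig[sp[ii], sp[jj]]
        sr6 = (sig / r) ** 6
        src6 = (sig / self.lj_cutoff) ** 6
        e = 4.0 * eps * (sr6 * sr6 - sr6) - 4.0 * eps * (src6 * src6 - src6)
        dedr = -24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
        u = d / r[:, None]
        np.add.at(forces, jj, -dedr[:, None] * u)
        np.add.at(forces, ii, +dedr[:, None] * u)
        return float(np.sum(e)), forces

    def evaluate(self, positions: np.ndarray, with_forces: bool = True):
        """Energies (dict, kJ/mol) and forces (N_mol, 3, 3) for a cluster."""
        pos = np.asarray(positions, dtype=float)
        m = pos.shape[0]
        pos_flat = pos.reshape(-1, 3)
        mol_index = np.repeat(np.arange(m), 3)

        if self.flexible:
            e_intra, f_intra = intramolecular_energy_forces(pos, self.energy_stack)
        else:
            e_intra, f_intra = 0.0, np.zeros_like(pos)

        q_glob, jac = self._moments_and_jacobians(pos, with_jac=with_forces)
        e_elec, f_elec = electrostatic_energy_forces(
            pos_flat,
            mol_index,
            q_glob.reshape(-1, 9),
            L=self.L,
            cutoff=self.elec_cutoff,
            moment_jacobians=jac,
        )
        e_lj, f_lj = self._lj_energy_forces(pos_flat, mol_index)

        energies = {
            "intramolecular": e_intra,
            "electrostatic": e_elec,
            "lennard_jones": e_lj,
            "potential": e_intra + e_elec + e_lj,
        }
        forces = f_intra + (f_elec + f_lj).reshape(pos.shape)
        return energies, forces


class SimulationBlowupError(RuntimeError):
    """Raised when the integration diverges; carries the last good state."""

    def __init__(self, message: str, state: SimulationState, log: pd.DataFrame):
        super().__init__(message)
        self.state = state
        self.log = log


def andersen_thermostat(
    state: SimulationState,
    temperature: float,
    collision_rate: float,
    dt: float,
    rng: np.random.Generator,
) -> None:
    """Redraw each atom's velocity with probability collision_rate * dt.

    collision_rate is per atom in 1/fs (10 ps^-1 = 0.01 fs^-1 is the
    default elsewhere); redraws are Maxwell-Boltzmann at the target
    temperature for the atom's mass.  In-place; no-op at zero rate.
    """
    if collision_rate < 0:
        raise ValueError("collision_rate must be non-negative")
    if collision_rate == 0:
        return
    m = state.n_mol
    hit = rng.random((m, 3)) < collision_rate * dt
    if not np.any(hit):
        return
    sigma = np.sqrt(KB * temperature / (_MASSES * EUNIT))  # (3,) A/fs per species
    draws = rng.normal(size=(m, 3, 3)) * sigma[None, :, None]
    state.velocities[hit] = draws[hit]


def velocity_verlet_step(
    state: SimulationState, dt: float, forcefield: WaterForceField
) -> dict:
    """One velocity-Verlet step; returns the energy decomposition after it."""
    inv_m = 1.0 / (_MASSES[None, :, None] * EUNIT)
    state.velocities += 0.5 * dt * state.forces * inv_m
    state.positions += dt * state.velocities
    energies, forces = forcefield.evaluate(state.positions)
    if not np.all(np.isfinite(forces)):
        raise RuntimeError("non-finite forces encountered in velocity Verlet step")
    state.forces = forces
    state.velocities += 0.5 * dt * state.forces * inv_m
    state.time += dt
    return energies


def _rigid_reset(state: SimulationState, reference: np.ndarray) -> None:
    """Best-fit rigid-body constraint: restore each monomer's internal geometry.

    Positions are replaced by the mass-weighted optimal superposition of the
    reference geometry onto the current one; velocities are projected onto
    centre-of-mass translation plus rigid rotation.
    """
    w = _MASSES / _MASSES.sum()
    ref_c = reference - np.einsum("a,ac->c", w, reference)
    for k in range(state.n_mol):
        cur = state.positions[k]
        com = np.einsum("a,ac->c", w, cur)
        cur_c = cur - com
        H = np.einsum("a,ac,ad->cd", _MASSES, ref_c, cur_c)
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        new = com + ref_c @ R.T
        state.positions[k] = new
        v = state.velocities[k]
        v_com = np.einsum("a,ac->c", w, v)
        rel = new - com
        ang_mom = np.einsum("a,ac->c", _MASSES, np.cross(rel, v - v_com))
        inertia = np.einsum(
            "a,acd->cd",
            _MASSES,
            np.einsum("a,cd->acd", np.sum(rel * rel, axis=1), np.eye(3))
            - np.einsum("ac,ad->acd", rel, rel),
        )
        omega = np.linalg.solve(inertia, ang_mom)
        state.velocities[k] = v_com + np.cross(omega, rel)


def initialize_cluster(
    n_mol: int,
    rng_seed: int = 0,
    temperature: float = 300.0,
    spacing: float = 3.4,
    jitter: float = 0.2,
    min_oo: float = 2.6,
    min_any: float = 1.5,
    max_attempts: int = 200,
) -> SimulationState:
    """Seed-geometry monomers on a jittered cubic lattice, random orientations.

    Guarantees every O-O separation >= ``min_oo`` and every intermolecular
    atom-atom separation >= ``min_any``; velocities are Maxwell-Boltzmann at
    the requested temperature with the net linear momentum removed.
    """
    if n_mol < 1:
        raise ValueError("n_mol must be >= 1")
    rng = np.random.default_rng(rng_seed)
    ref = seed_configuration().positions
    ref_c = ref - ref.mean(axis=0)

    side = int(np.ceil(n_mol ** (1.0 / 3.0)))
    grid = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
        dtype=float,
    )
    grid = (grid - grid.mean(axis=0)) * spacing
    grid = grid[np.argsort(np.linalg.norm(grid, axis=1))][:n_mol]

    for _ in range(max_attempts):
        sites = grid + rng.normal(scale=jitter, size=grid.shape)
        if n_mol == 1:
            sites = np.zeros((1, 3))
        pos = np.empty((n_mol, 3, 3))
        for k in range(n_mol):
            R = _random_rotation(rng)
            pos[k] = sites[k] + ref_c @ R.T
        if n_mol == 1:
            break
        oo = pos[:, 0, :]
        d_oo = np.linalg.norm(oo[:, None] - oo[None, :], axis=-1)
        np.fill_diagonal(d_oo, np.inf)
        flat = pos.reshape(-1, 3)
        d_all = np.linalg.norm(flat[:, None] - flat[None, :], axis=-1)
        mol = np.repeat(np.arange(n_mol), 3)
        d_all[mol[:, None] == mol[None, :]] = np.inf
        if d_oo.min() >= min_oo and d_all.min() >= min_any:
            break
    else:
        raise RuntimeError(
            f"could not pack {n_mol} molecules with O-O >= {min_oo} A; "
            "increase spacing or reduce jitter"
        )

    sigma = np.sqrt(KB * temperature / (_MASSES * EUNIT))
    vel = rng.normal(size=(n_mol, 3, 3)) * sigma[None, :, None]
    total_m = n_mol * _MASSES.sum()
    p_net = np.einsum("a,mac->c", _MASSES, vel)
    vel -= p_net[None, None, :] / total_m
    return SimulationState(pos, vel, np.zeros_like(pos))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def run_simulation(
    forcefield: WaterForceField,
    state: SimulationState,
    n_steps: int,
    dt: float = 1.0,
    temperature: float = 300.0,
    collision_rate: float = 0.01,
    rng_seed: int = 0,
    rigid: bool = False,
    reference: np.ndarray | None = None,
    traj_every: int = 10,
    blowup_energy: float = 1e8,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Integrate and log; returns (trajectory (F, n_atoms, 3), energy log).

    The energy log has one row per step: time, the potential-energy
    decomposition, kinetic energy, total energy and kinetic temperature.
    Rigid mode applies the monomer constraint after every position update and
    freezes local-frame moments (the force field should be constructed with
    ``flexible=False``).  Raises :class:`SimulationBlowupError` (carrying the
    last good state and the log so far) if the energy diverges.
    """
    rng = np.random.default_rng(rng_seed)
    ref = reference if reference is not None else seed_configuration().positions
    energies, forces = forcefield.evaluate(state.positions)
    state.forces = forces
    dof = 6 * state.n_mol if rigid else 3 * state.n_atoms

    frames = [state.positions.reshape(-1, 3).copy()]
    records = []
    for step in range(n_steps):
        try:
            energies = velocity_verlet_step(state, dt, forcefield)
        except RuntimeError as err:
            raise SimulationBlowupError(
                f"integration failed at step {step}: {err}",
                state,
                pd.DataFrame(records),
            ) from err
        if rigid:
            _rigid_reset(state, ref)
        andersen_thermostat(state, temperature, collision_rate, dt, rng)
        e_kin = state.kinetic_energy()
        e_tot = energies["potential"] + e_kin
        records.append(
            {
                "time_fs": state.time,
                "e_intra": energies["intramolecular"],
                "e_elec": energies["electrostatic"],
                "e_lj": energies["lennard_jones"],
                "e_kinetic": e_kin,
                "e_total": e_tot,
                "temperature_K": state.temperature(dof),
                "net_force": float(np.abs(state.forces.sum(axis=(0, 1))).max()),
            }
        )
        if abs(e_tot) > blowup_energy or not np.isfinite(e_tot):
            raise SimulationBlowupError(
                f"energy blow-up at step {step}: E_total = {e_tot:.3e} kJ/mol",
                state,
                pd.DataFrame(records),
            )
        if (step + 1) % traj_every == 0:
            frames.append(state.positions.reshape(-1, 3).copy())
    return np.array(frames), pd.DataFrame(records)
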