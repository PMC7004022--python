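"""Training-ensemble generation: normal-mode sampling, filtering, splitting.

Monomer training configurations are produced by stochastically displacing a
seed (minimum-energy) geometry along its three internal vibrational normal
modes, with the hard constraint that neither O-H bond length nor the H-O-H
angle departs from its seed value by more than a given fraction (20% by
default).  Mode coordinates are drawn uniformly over the largest per-mode
interval that respects the constraint, with joint draws rejection-sampled
against the full constraint, so the allowed box is covered out to its edges.

Before training, labelled configurations are discarded when the net
molecular charge exceeds a tolerance (default 0.001 e) or when any atom's
integration-error figure L(Omega) exceeds a threshold (0.0001 or 0.00005 Ha
are the standard choices); the remaining ensemble is split at random into
disjoint training and validation sets.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import MASS_H, MASS_O
from .geometry import (
    WaterConfiguration,
    feature_jacobian,
    features_from_positions,
)
from .surrogate import (
    DEFAULT_PARAMETERS,
    SurrogateParameters,
    molecular_energy_feature_gradient,
    molecular_energy_from_features,
)

__all__ = [
    "NormalModeBasis",
    "EnsembleFilterPolicy",
    "compute_normal_modes",
    "sample_configurations",
    "filter_ensemble",
    "split_train_validation",
]

_MASSES = np.array([MASS_O, MASS_H, MASS_H])
_HESS_STEP = 1e-4  # A, central-difference step for the Cartesian Hessian


@dataclasses.dataclass
class NormalModeBasis:
    """Internal vibrational modes of the monomer at its minimum.

    displacements: (3, 3, 3) Cartesian displacement patterns (mode, atom,
    xyz), normalised in mass-weighted coordinates.  eigenvalues are in
    kJ/mol/(u A^2); wavenumbers_cm are the corresponding harmonic
    frequencies.  amplitudes[(k, 0|1)] give how far mode k can be followed in
    the -/+ direction before the distortion constraint bites.
    """

    displacements: np.ndarray
    eigenvalues: np.ndarray
    wavenumbers_cm: np.ndarray
    labels: tuple
    amplitudes: np.ndarray  # (3, 2): (negative reach, positive reach), both > 0

    def __post_init__(self) -> None:
        flat = self.displacements.reshape(3, 9)
        if np.linalg.matrix_rank(flat) != 3:
            raise ValueError("mode displacements must be linearly independent")


@dataclasses.dataclass(frozen=True)
class EnsembleFilterPolicy:
    """Thresholds for discarding poorly integrated labelled configurations."""

    charge_tolerance: float = 0.001           # e
    integration_error_threshold: float = 5e-5  # Ha

    def __post_init__(self) -> None:
        if self.charge_tolerance <= 0 or self.integration_error_threshold <= 0:
            raise ValueError("filter thresholds must be strictly positive")


def _cartesian_hessian(pes: Callable[[np.ndarray], float], pos0: np.ndarray) -> np.ndarray:
    """9x9 central-difference Hessian of a position-space energy function."""
    n = 9
    H = np.zeros((n, n))
    h = _HESS_STEP

    def e_at(delta):
        return pes(pos0 + delta.reshape(3, 3))

    for i in range(n):
        for j in range(i, n):
            di = np.zeros(n)
            dj = np.zeros(n)
            di[i] = h
            dj[j] = h
            if i == j:
                val = (e_at(di) - 2.0 * e_at(di * 0) + e_at(-di)) / h**2
            else:
                val = (
                    e_at(di + dj) - e_at(di - dj) - e_at(-di + dj) + e_at(-di - dj)
                ) / (4.0 * h**2)
            H[i, j] = H[j, i] = val
    return H


def _rigid_body_space(pos0: np.ndarray, sqrt_m: np.ndarray) -> np.ndarray:
    """Orthonormal basis (9, 6) of mass-weighted translations and rotations."""
    vecs = []
    for ax in range(3):
        t = np.zeros((3, 3))
        t[:, ax] = 1.0
        vecs.append((t * sqrt_m[:, None]).ravel())
    com = (pos0 * _MASSES[:, None]).sum(axis=0) / _MASSES.sum()
    rel = pos0 - com
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        r = np.cross(e, rel) * sqrt_m[:, None]
        vecs.append(r.ravel())
    basis, _ = np.linalg.qr(np.column_stack(vecs))
    return basis


def _classify_modes(internal: np.ndarray, r0: float) -> list:
    """Label modes (bend / symmetric stretch / asymmetric stretch).

    internal: (3 modes, 3) rows of (dr1, dr2, dtheta) per unit mode
    coordinate.  The bend is the mode with the largest angle content (scaled
    by r0 to make it commensurate with the stretches); of the remaining two,
    in-phase bond displacement is symmetric.
    """
    scaled = np.abs(internal[:, 2]) * r0 / np.linalg.norm(
        np.column_stack([internal[:, 0], internal[:, 1], internal[:, 2] * r0]), axis=1
    )
    labels = [None, None, None]
    bend = int(np.argmax(scaled))
    labels[bend] = "bend"
    rest = [k for k in range(3) if k != bend]
    for k in rest:
        labels[k] = (
            "symmetric stretch" if internal[k, 0] * internal[k, 1] > 0 else "asymmetric stretch"
        )
    return labels


def _max_fractional_distortion(pos: np.ndarray, seed_feats: np.ndarray) -> float:
    feats = features_from_positions(pos)
    return float(np.max(np.abs(feats - seed_feats) / seed_feats))


def compute_normal_modes(
    seed: WaterConfiguration,
    pes: Callable[[np.ndarray], float] | None = None,
    params: SurrogateParameters = DEFAULT_PARAMETERS,
    max_distortion: float = 0.20,
    grad_tol: float = 1e-6,
) -> NormalModeBasis:
    """Vibrational modes from the mass-weighted finite-difference Hessian.

    ``pes`` maps a (3, 3) position array to an energy in kJ/mol; when omitted
    the analytic surrogate PES is used (and the minimum check uses its exact
    gradient).  Raises if the seed is not a minimum (significant gradient or
    a non-positive vibrational eigenvalue).
    """
    pos0 = seed.positions
    seed_feats = features_from_positions(pos0)

    if pes is None:
        def pes_fn(p):
            return float(molecular_energy_from_features(features_from_positions(p), params))
        gf = molecular_energy_feature_gradient(seed_feats, params)
        grad = np.einsum("f,fac->ac", gf, feature_jacobian(pos0))
    else:
        pes_fn = pes
        grad = np.zeros((3, 3))
        h = 1e-5
        for a in range(3):
            for c in range(3):
                d = np.zeros((3, 3))
                d[a, c] = h
                grad[a, c] = (pes_fn(pos0 + d) - pes_fn(pos0 - d)) / (2 * h)
        grad_tol = max(grad_tol, 1e-3)  # finite-difference noise floor

    if np.linalg.norm(grad) > grad_tol:
        raise ValueError(
            f"seed is not a PES minimum: |gradient| = {np.linalg.norm(grad):.3e} kJ/mol/A"
        )

    sqrt_m = np.sqrt(_MASSES)
    H = _cartesian_hessian(pes_fn, pos0)
    inv_sqrt = np.repeat(1.0 / sqrt_m, 3)
    H_mw = H * inv_sqrt[:, None] * inv_sqrt[None, :]

    rigid = _rigid_body_space(pos0, sqrt_m)
    P = np.eye(9) - rigid @ rigid.T
    H_int = P @ H_mw @ P
    evals, evecs = np.linalg.eigh(H_int)
    vib = np.argsort(np.abs(evals))[-3:]
    vib = vib[np.argsort(evals[vib])]
    lam = evals[vib]
    if np.any(lam <= 0):
        raise ValueError(f"non-minimum seed: vibrational eigenvalues {lam}")

    # eigenvalue [kJ/mol/(u A^2)] -> omega [1/fs] -> wavenumber [1/cm]
    omega = np.sqrt(lam / 1.0e4)
    wavenumbers = omega / (2.0 * np.pi * 2.99792458e-5)

    disp = (evecs[:, vib].T * inv_sqrt[None, :]).reshape(3, 3, 3)
    internal = np.array(
        [np.einsum("fac,ac->f", feature_jacobian(pos0), d) for d in disp]
    )
    labels = tuple(_classify_modes(internal, float(seed_feats[0])))

    amplitudes = np.zeros((3, 2))
    for k in range(3):
        for s, sign in enumerate((-1.0, 1.0)):
            def excess(a):
                return _max_fractional_distortion(pos0 + sign * a * disp[k], seed_feats) - max_distortion
            hi = 0.01
            while excess(hi) < 0 and hi < 1e3:
                hi *= 2.0
            amplitudes[k, s] = brentq(excess, 0.0, hi, xtol=1e-10)

    return NormalModeBasis(disp, lam, wavenumbers, labels, amplitudes)


def sample_configurations(
    seed: WaterConfiguration,
    n: int,
    max_distortion: float = 0.20,
    rng_seed: int = 0,
    basis: NormalModeBasis | None = None,
    params: SurrogateParameters = DEFAULT_PARAMETERS,
) -> list[WaterConfiguration]:
    """Draw ``n`` constrained normal-mode-displaced monomer configurations.

    Deterministic for a given ``rng_seed``.  ``max_distortion`` = 0 returns
    ``n`` copies of the seed; negative values are rejected.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if max_distortion < 0:
        raise ValueError("max_distortion must be non-negative")
    if max_distortion == 0:
        return [WaterConfiguration(seed.positions.copy(), i) for i in range(n)]
    if basis is None:
        basis = compute_normal_modes(seed, params=params, max_distortion=max_distortion)

    rng = np.random.default_rng(rng_seed)
    seed_feats = features_from_positions(seed.positions)
    out: list[WaterConfiguration] = []
    lo = -basis.amplitudes[:, 0]
    hi = basis.amplitudes[:, 1]
    while len(out) < n:
        a = rng.uniform(lo, hi)
        pos = seed.positions + np.einsum("k,kac->ac", a, basis.displacements)
        if _max_fractional_distortion(pos, seed_feats) <= max_distortion:
            out.append(WaterConfiguration(pos, len(out)))
    return out


def filter_ensemble(labelled: Sequence, policy: EnsembleFilterPolicy) -> list:
    """Keep configurations passing both the net-charge and L(Omega) screens.

    A configuration is removed iff |sum of atomic charges| exceeds the charge
    tolerance OR any atom's L(Omega) exceeds the integration-error threshold.
    Order is preserved; the input is not mutated.
    """
    kept = []
    for lc in labelled:
        if lc.atomic_moments is None or len(lc.atomic_moments) != 3:
            raise ValueError("labelled configuration is missing multipole labels")
        errs = np.asarray(lc.integration_errors, dtype=float)
        if errs.shape != (3,):
            raise ValueError("labelled configuration is missing integration errors")
        if abs(lc.net_charge) > policy.charge_tolerance:
            continue
        if np.any(errs > policy.integration_error_threshold):
            continue
        kept.append(lc)
    return kept


def split_train_validation(
    configs: Sequence, n_trn: int, rng_seed: int = 0
) -> tuple[list, list]:
    """Random disjoint (training, validation) split with |training| = n_trn."""
    n = len(configs)
    if not 0 < n_trn < n:
        raise ValueError(f"n_trn must be in (0, {n}), got {n_trn}")
    perm = np.random.default_rng(rng_seed).permutation(n)
    train = [configs[i] for i in perm[:n_trn]]
    valid = [configs[i] for i in perm[n_trn:]]
    return train, valid
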