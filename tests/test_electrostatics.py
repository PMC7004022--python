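"""Rank-truncated multipolar electrostatics: tensors, energies, forces."""

import numpy as np
import pytest

from aquakrig.constants import COULOMB
from aquakrig.electrostatics import (
    admitted_pairs,
    electrostatic_energy_forces,
    interaction_tensor,
    pair_electrostatic_energy,
    total_electrostatic_energy,
)
from aquakrig.multipoles import MultipoleSet, rotate_moment_array
from tests.test_geometry import random_rotation


class TestRankRule:
    def test_admitted_sets(self):
        assert admitted_pairs(1) == {(0, 0)}
        assert admitted_pairs(2) == {(0, 0), (0, 1), (1, 0)}
        assert admitted_pairs(3) == {(0, 0), (0, 1), (1, 0), (0, 2), (2, 0), (1, 1)}

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            admitted_pairs(0)

    def test_truncation_nesting(self, rng):
        # E(L=3) - E(L=2) equals exactly the sum of the three added couplings
        QA = MultipoleSet(rng.normal(size=9), "global")
        QB = MultipoleSet(rng.normal(size=9), "global")
        R = np.array([2.5, 1.0, -0.7])
        e2 = pair_electrostatic_energy(QA, QB, R, 2)
        e3 = pair_electrostatic_energy(QA, QB, R, 3)
        added = 0.0
        for (la, lb) in admitted_pairs(3) - admitted_pairs(2):
            offs = {0: 0, 1: 1, 2: 4}
            sizes = {0: 1, 1: 3, 2: 5}
            for ma in range(sizes[la]):
                for mb in range(sizes[lb]):
                    added += (
                        QA.components[offs[la] + ma]
                        * interaction_tensor(la, ma, lb, mb, R)
                        * QB.components[offs[lb] + mb]
                    )
        assert e3 - e2 == pytest.approx(COULOMB * added, rel=1e-12)


class TestInteractionTensor:
    def test_charge_charge_is_inverse_distance(self):
        assert interaction_tensor(0, 0, 0, 0, [2.0, 0, 0]) == pytest.approx(0.5)

    def test_homogeneity_in_distance(self, rng):
        R = rng.normal(size=3)
        for (la, ma, lb, mb) in [(0, 0, 0, 0), (0, 0, 1, 1), (1, 2, 1, 0), (2, 3, 0, 0)]:
            t1 = interaction_tensor(la, ma, lb, mb, R)
            t2 = interaction_tensor(la, ma, lb, mb, 2.0 * R)
            assert t2 == pytest.approx(t1 * 2.0 ** -(la + lb + 1), rel=1e-12)

    def test_exchange_identity(self, rng):
        # swapping the roles of A and B while reversing the separation vector
        R = rng.normal(size=3)
        for (la, ma, lb, mb) in [(0, 0, 1, 0), (1, 1, 1, 2), (0, 0, 2, 4), (2, 1, 0, 0)]:
            assert interaction_tensor(la, ma, lb, mb, R) == pytest.approx(
                interaction_tensor(lb, mb, la, ma, -R), rel=1e-12, abs=1e-15
            )

    def test_parity_in_separation(self, rng):
        R = rng.normal(size=3)
        for (la, ma, lb, mb) in [(0, 0, 1, 1), (1, 0, 1, 1), (0, 0, 2, 2)]:
            t = interaction_tensor(la, ma, lb, mb, R)
            t_neg = interaction_tensor(la, ma, lb, mb, -R)
            assert t_neg == pytest.approx((-1.0) ** (la + lb) * t, rel=1e-12, abs=1e-15)

    def test_unsupported_rank_combination(self):
        with pytest.raises(ValueError):
            interaction_tensor(1, 0, 2, 0, [1.0, 0, 0])

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError):
            interaction_tensor(0, 0, 0, 0, [0.0, 0.0, 0.0])


class TestPairEnergy:
    def test_unit_charges_at_three_angstrom(self):
        qa = MultipoleSet.from_charge(1.0)
        qb = MultipoleSet.from_charge(-1.0)
        e = pair_electrostatic_energy(qa, qb, [3.0, 0, 0], 1)
        assert e == pytest.approx(-COULOMB / 3.0, rel=1e-12)
        assert e == pytest.approx(-463.12, abs=0.01)

    def test_collinear_dipoles_head_to_tail(self):
        mu, R = 0.4, 4.0
        comp = np.zeros(9)
        comp[2] = mu  # mu_x
        a = MultipoleSet(comp, "global")
        e = pair_electrostatic_energy(a, a, [R, 0, 0], 3)
        assert e == pytest.approx(-2.0 * mu**2 * COULOMB / R**3, rel=1e-12)

    def test_dipole_point_charge_limit_quadratic(self):
        # two parallel dipoles as +/- charge pairs, L = 1 code as the oracle
        mu, R = 0.3, 3.5
        comp = np.zeros(9)
        comp[2] = mu
        a = MultipoleSet(comp, "global")
        exact = pair_electrostatic_energy(a, a, [R, 0, 0], 3)
        errs = []
        ds = np.array([0.2, 0.1, 0.05, 0.025])
        for d in ds:
            q = mu / d
            pos = np.array(
                [[-d / 2, 0, 0], [d / 2, 0, 0], [R - d / 2, 0, 0], [R + d / 2, 0, 0]]
            )
            charges = [-q, q, -q, q]
            e = 0.0
            for i in range(2):
                for j in range(2, 4):
                    e += pair_electrostatic_energy(
                        MultipoleSet.from_charge(charges[i]),
                        MultipoleSet.from_charge(charges[j]),
                        pos[j] - pos[i],
                        1,
                    )
            errs.append(abs(e - exact))
        slope = np.polyfit(np.log(ds), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_charge_quadrupole_point_charge_limit_quadratic(self):
        # linear quadrupole (+q, -2q, +q along z) against a probe charge
        theta_zz, R = 0.25, 3.0
        comp = np.zeros(9)
        comp[4] = theta_zz  # Q20
        quad = MultipoleSet(comp, "global")
        probe = MultipoleSet.from_charge(1.0)
        Rv = np.array([1.2, -0.5, R])
        exact = pair_electrostatic_energy(quad, probe, Rv, 3)
        errs, ds = [], np.array([0.2, 0.1, 0.05])
        for d in ds:
            q = theta_zz / (2.0 * d**2)
            arr = [(q, [0, 0, d]), (-2 * q, [0, 0, 0.0]), (q, [0, 0, -d])]
            e = sum(
                pair_electrostatic_energy(
                    MultipoleSet.from_charge(qi), probe, Rv - np.array(ri), 1
                )
                for qi, ri in arr
            )
            errs.append(abs(e - exact))
        slope = np.polyfit(np.log(ds), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_local_frame_moments_rejected(self, rng):
        a = MultipoleSet(rng.normal(size=9), "local")
        b = MultipoleSet.from_charge(1.0)
        with pytest.raises(ValueError, match="global"):
            pair_electrostatic_energy(a, b, [3.0, 0, 0], 3)


def _random_cluster(rng, n_mol=3, spread=5.0):
    pos = rng.normal(scale=1.2, size=(3 * n_mol, 3))
    pos += np.repeat(rng.normal(scale=spread, size=(n_mol, 3)), 3, axis=0)
    mol = np.repeat(np.arange(n_mol), 3)
    Q = rng.normal(scale=0.3, size=(3 * n_mol, 9))
    return pos, mol, Q


class TestClusterSums:
    def test_single_molecule_has_no_energy(self, rng):
        pos = rng.normal(size=(3, 3))
        Q = rng.normal(size=(3, 9))
        assert total_electrostatic_energy(pos, np.zeros(3, dtype=int), Q, 3) == 0.0

    def test_two_molecules_decompose_into_nine_pairs(self, rng):
        pos, mol, Q = _random_cluster(rng, n_mol=2)
        total = total_electrostatic_energy(pos, mol, Q, 3)
        acc = 0.0
        for i in range(3):
            for j in range(3, 6):
                acc += pair_electrostatic_energy(
                    MultipoleSet(Q[i], "global"),
                    MultipoleSet(Q[j], "global"),
                    pos[j] - pos[i],
                    3,
                )
        assert total == pytest.approx(acc, rel=1e-12)

    def test_cutoff_excludes_distant_pairs(self, rng):
        pos, mol, Q = _random_cluster(rng, n_mol=2, spread=0.0)
        pos[3:] += np.array([50.0, 0.0, 0.0])
        assert total_electrostatic_energy(pos, mol, Q, 3, cutoff=30.0) == 0.0

    def test_rigid_rotation_invariance(self, rng):
        pos, mol, Q = _random_cluster(rng)
        e0 = total_electrostatic_energy(pos, mol, Q, 3)
        for _ in range(5):
            R = random_rotation(rng)
            e1 = total_electrostatic_energy(pos @ R.T, mol, rotate_moment_array(Q, R), 3)
            assert abs(e1 - e0) < 1e-10 * max(1.0, abs(e0))

    @pytest.mark.parametrize("L", [1, 2, 3])
    def test_forces_match_finite_differences(self, rng, L):
        pos, mol, Q = _random_cluster(rng)
        e0, F = electrostatic_energy_forces(pos, mol, Q, L)
        h = 1e-6
        fd = np.zeros_like(F)
        for i in range(len(pos)):
            for c in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[i, c] += h
                pm[i, c] -= h
                fd[i, c] = -(
                    total_electrostatic_energy(pp, mol, Q, L)
                    - total_electrostatic_energy(pm, mol, Q, L)
                ) / (2 * h)
        assert np.max(np.abs(F - fd)) / np.max(np.abs(fd)) < 1e-6

    def test_net_force_and_torque_vanish(self, rng):
        pos, mol, Q = _random_cluster(rng, n_mol=2)
        _, F = electrostatic_energy_forces(pos, mol, Q, 3)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-9)
        # torque balance requires the moment-rotation terms; with fixed global
        # moments only the interatomic forces act, and they are central only
        # for the charge-charge rank
        Qc = np.zeros_like(Q)
        Qc[:, 0] = Q[:, 0]
        _, F1 = electrostatic_energy_forces(pos, mol, Qc, 1)
        torque = np.sum(np.cross(pos, F1), axis=0)
        assert np.allclose(torque, 0.0, atol=1e-9)
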