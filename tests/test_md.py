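"""Integrator, thermostat, Lennard-Jones terms and cluster dynamics."""

import numpy as np
import pandas as pd
import pytest

from aquakrig.constants import EUNIT, KB
from aquakrig.geometry import features_from_positions, seed_configuration
from aquakrig.md import (
    LJParameters,
    SimulationBlowupError,
    SimulationState,
    WaterForceField,
    andersen_thermostat,
    initialize_cluster,
    lj_energy_force,
    run_simulation,
    velocity_verlet_step,
)


class _StubField:
    """Harmonic tether to a reference structure (or free flight at k = 0)."""

    def __init__(self, k, x0):
        self.k = k
        self.x0 = np.asarray(x0, dtype=float)

    def evaluate(self, positions, with_forces=True):
        d = positions - self.x0
        e = 0.5 * self.k * float(np.sum(d * d))
        return {
            "intramolecular": e,
            "electrostatic": 0.0,
            "lennard_jones": 0.0,
            "potential": e,
        }, -self.k * d


class TestLennardJones:
    def test_energy_exactly_zero_at_cutoff(self):
        e, _ = lj_energy_force(10.0, 0.753, 3.23, cutoff=10.0)
        assert e == 0.0

    def test_zero_beyond_cutoff(self):
        e, f = lj_energy_force(10.5, 0.753, 3.23, cutoff=10.0)
        assert e == 0.0 and f == 0.0

    def test_at_sigma_only_the_shift_remains(self):
        eps, sig, rc = 0.753, 3.23, 10.0
        e, _ = lj_energy_force(sig, eps, sig, cutoff=rc)
        shift = 4 * eps * ((sig / rc) ** 12 - (sig / rc) ** 6)
        assert e == pytest.approx(-shift, rel=1e-12)

    def test_minimum_location_and_depth(self):
        eps, sig, rc = 0.753, 3.23, 10.0
        rmin = 2 ** (1 / 6) * sig
        e, dedr = lj_energy_force(rmin, eps, sig, cutoff=rc)
        shift = 4 * eps * ((sig / rc) ** 12 - (sig / rc) ** 6)
        assert dedr == pytest.approx(0.0, abs=1e-12)
        assert e == pytest.approx(-eps - shift, rel=1e-12)

    def test_lorentz_berthelot_rules(self):
        lj = LJParameters()
        assert lj.epsilon_oh == pytest.approx(np.sqrt(0.753 * 0.015))
        assert lj.sigma_oh == pytest.approx((3.23 + 1.10) / 2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LJParameters(sigma_oo=-1.0)


class TestVelocityVerlet:
    def _oscillator_error(self, dt, k=300.0, n_periods=3):
        x0 = seed_configuration().positions[None].copy()
        state = SimulationState(x0.copy(), np.zeros_like(x0), np.zeros_like(x0))
        state.positions[0, 0, 0] += 0.05  # displace the O atom
        ff = _StubField(k, x0)
        _, state.forces = ff.evaluate(state.positions)
        period = 2 * np.pi / np.sqrt(k / (16.0 * EUNIT))
        n = int(n_periods * period / dt)
        e0 = ff.evaluate(state.positions)[0]["potential"] + state.kinetic_energy()
        worst = 0.0
        for _ in range(n):
            en = velocity_verlet_step(state, dt, ff)
            worst = max(worst, abs(en["potential"] + state.kinetic_energy() - e0))
        return worst

    def test_energy_error_is_second_order_in_timestep(self):
        e1 = self._oscillator_error(dt=2.0)
        e2 = self._oscillator_error(dt=1.0)
        order = np.log2(e1 / e2)
        assert order == pytest.approx(2.0, abs=0.1)

    def test_zero_forces_give_straight_line_motion(self):
        x0 = seed_configuration().positions[None].copy()
        v0 = np.full_like(x0, 0.01)
        state = SimulationState(x0.copy(), v0.copy(), np.zeros_like(x0))
        ff = _StubField(0.0, x0)
        for _ in range(100):
            velocity_verlet_step(state, 1.0, ff)
        assert np.allclose(state.positions, x0 + v0 * 100.0, atol=1e-12)
        assert np.allclose(state.velocities, v0, atol=1e-15)

    def test_nonfinite_forces_abort(self):
        x0 = seed_configuration().positions[None].copy()
        state = SimulationState(x0.copy(), np.zeros_like(x0), np.zeros_like(x0))

        class Bad(_StubField):
            def evaluate(self, positions, with_forces=True):
                e, f = super().evaluate(positions)
                return e, f * np.nan

        with pytest.raises(RuntimeError, match="non-finite"):
            velocity_verlet_step(state, 1.0, Bad(1.0, x0))


class TestAndersenThermostat:
    def test_zero_rate_is_noop(self):
        state = initialize_cluster(5, rng_seed=1)
        v0 = state.velocities.copy()
        andersen_thermostat(state, 300.0, 0.0, 1.0, np.random.default_rng(0))
        assert np.array_equal(state.velocities, v0)

    def test_deterministic_collision_sequence(self):
        a = initialize_cluster(5, rng_seed=1)
        b = initialize_cluster(5, rng_seed=1)
        for seed_state in (a, b):
            rng = np.random.default_rng(77)
            for _ in range(10):
                andersen_thermostat(seed_state, 300.0, 0.05, 1.0, rng)
        assert np.array_equal(a.velocities, b.velocities)

    def test_equipartition_on_free_system(self):
        # ideal-gas control: the long-run kinetic temperature must equal the
        # thermostat target by equipartition
        state = initialize_cluster(10, rng_seed=3, temperature=100.0)
        ff = _StubField(0.0, state.positions.copy())
        _, state.forces = ff.evaluate(state.positions)
        rng = np.random.default_rng(5)
        temps = []
        for step in range(3000):
            velocity_verlet_step(state, 1.0, ff)
            state.positions[:] = ff.x0  # keep the gas in place
            andersen_thermostat(state, 300.0, 0.05, 1.0, rng)
            if step >= 500:
                temps.append(state.temperature())
        assert np.mean(temps) == pytest.approx(300.0, abs=10.0)


class TestInitializeCluster:
    def test_single_molecule_is_seed_geometry_at_origin(self):
        state = initialize_cluster(1, rng_seed=0)
        feats = features_from_positions(state.positions[0])
        ref = features_from_positions(seed_configuration().positions)
        assert np.allclose(feats, ref, atol=1e-12)
        com = state.positions[0].mean(axis=0)
        assert np.linalg.norm(com) < 1.0

    @pytest.mark.parametrize("n_mol", [8, 25])
    def test_packing_constraints(self, n_mol):
        state = initialize_cluster(n_mol, rng_seed=4)
        oo = state.positions[:, 0, :]
        d = np.linalg.norm(oo[:, None] - oo[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2.6

    def test_net_momentum_removed(self):
        state = initialize_cluster(12, rng_seed=9, temperature=300.0)
        masses = np.array([15.999, 1.008, 1.008])
        p = np.einsum("a,mac->c", masses, state.velocities)
        assert np.linalg.norm(p) < 1e-12

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            initialize_cluster(0)


class TestClusterDynamics:
    def test_identical_seed_identical_trajectory(self, standard_models):
        ff = WaterForceField(standard_models, L=1)
        runs = []
        for _ in range(2):
            state = initialize_cluster(3, rng_seed=6)
            frames, log = run_simulation(
                ff, state, 30, dt=1.0, rng_seed=8, traj_every=5
            )
            runs.append((frames, log))
        assert np.array_equal(runs[0][0], runs[1][0])
        pd.testing.assert_frame_equal(runs[0][1], runs[1][1])

    def test_newtons_third_law_along_trajectory(self, standard_models):
        ff = WaterForceField(standard_models, L=3)
        state = initialize_cluster(3, rng_seed=2)
        frames, _ = run_simulation(ff, state, 20, dt=1.0, rng_seed=3, traj_every=4)
        for frame in frames:
            _, F = ff.evaluate(frame.reshape(-1, 3, 3))
            assert np.abs(F.sum(axis=(0, 1))).max() < 1e-9

    def test_rigid_mode_freezes_internal_coordinates(self, standard_models):
        ff = WaterForceField(standard_models, L=1, flexible=False)
        state = initialize_cluster(3, rng_seed=5)
        frames, _ = run_simulation(
            ff, state, 60, dt=1.0, rng_seed=5, rigid=True, traj_every=5
        )
        mols = frames.reshape(len(frames), 3, 3, 3)
        feats = features_from_positions(mols)
        assert feats[..., 0].std() < 1e-10
        assert feats[..., 1].std() < 1e-10
        assert feats[..., 2].std() < 1e-10

    def test_blowup_aborts_with_state(self, standard_models):
        ff = WaterForceField(standard_models, L=1)
        state = initialize_cluster(2, rng_seed=7)
        with pytest.raises(SimulationBlowupError) as exc:
            run_simulation(ff, state, 50, dt=1.0, rng_seed=1, blowup_energy=1e-6)
        assert isinstance(exc.value.state, SimulationState)
        assert isinstance(exc.value.log, pd.DataFrame)

    def test_energy_log_schema(self, standard_models):
        ff = WaterForceField(standard_models, L=2)
        state = initialize_cluster(2, rng_seed=11)
        _, log = run_simulation(ff, state, 10, dt=1.0, rng_seed=2)
        assert list(log.columns) == [
            "time_fs", "e_intra", "e_elec", "e_lj", "e_kinetic", "e_total",
            "temperature_K", "net_force",
        ]
        assert np.all(np.isfinite(log.to_numpy()))
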