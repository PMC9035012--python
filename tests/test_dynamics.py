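"""Stochastic-dynamics integrator, friction model, SHAKE and thermostat."""

import math

import numpy as np
import pytest

from conftest import finite_difference_forces
from implisolv.core import Atom, Conformation, Topology
from implisolv.dynamics import (
    DEFAULT_HEATUP_SCHEDULE,
    HeatupStage,
    ParticleState,
    SDParameters,
    SDSystem,
    friction_coefficients,
    heatup_protocol,
    kinetic_temperature,
    maxwell_velocities,
    neighbour_counts,
    run_sd,
    sd_step,
    shake,
    weak_coupling_scale,
)
from implisolv.forcefield import ToyForceField, toy_forcefield_eval
from implisolv.units import KB


def _atoms(n, element="C", code="C"):
    return [Atom(f"X{k}", element, 12.0, code, 1, "X") for k in range(n)]


class TestNeighbourCounts:
    def test_isolated_atom(self):
        topo = Topology(_atoms(1))
        c = neighbour_counts(Conformation([[0, 0, 0]]), topo)
        assert c[0] == 0

    def test_linear_triatom(self):
        topo = Topology(_atoms(3))
        x = [[0, 0, 0], [0.15, 0, 0], [0.30, 0, 0]]
        c = neighbour_counts(Conformation(x), topo)
        assert list(c) == [1, 2, 1]

    def test_seven_contacts(self):
        topo = Topology(_atoms(8))
        x = [[0, 0, 0]] + [
            [0.2 * math.cos(k), 0.2 * math.sin(k), 0.0] for k in range(7)
        ]
        c = neighbour_counts(Conformation(x), topo)
        assert c[0] == 7

    def test_hydrogens_do_not_count(self):
        atoms = _atoms(1) + [Atom("H1", "H", 1.0, "HC", 1, "X")]
        topo = Topology(atoms)
        c = neighbour_counts(Conformation([[0, 0, 0], [0.1, 0, 0]]), topo)
        assert c[0] == 0  # H neighbour ignored
        assert c[1] == 1  # but the H atom sees the heavy atom


class TestFriction:
    def test_full_exposure(self):
        p = SDParameters()
        g = friction_coefficients(np.array([0]), p)
        assert g[0] == pytest.approx(91.0)

    def test_buried_clamps_to_zero(self):
        p = SDParameters()
        assert friction_coefficients(np.array([6]), p)[0] == 0.0
        assert friction_coefficients(np.array([9]), p)[0] == 0.0

    def test_half_buried(self):
        p = SDParameters()
        assert friction_coefficients(np.array([3]), p)[0] == pytest.approx(45.5)

    def test_omega_bounded(self):
        p = SDParameters()
        g = friction_coefficients(np.arange(0, 20), p)
        assert np.all(g >= 0.0) and np.all(g <= p.gamma_solv)


class TestSDStep:
    def test_gamma_zero_reduces_to_leapfrog(self):
        p = SDParameters(t_ref=300.0, dt=0.002)
        m = np.array([12.0])
        state = ParticleState(
            np.zeros((1, 3)), np.full((1, 3), 0.5), m, np.zeros(1)
        )
        f = np.array([[6.0, 0.0, -12.0]])
        rng = np.random.default_rng(0)
        sd_step(state, f, p, rng, noise=False)
        assert np.allclose(state.velocities[0], [0.5 + 1.0e-3, 0.5, 0.5 - 2.0e-3])
        assert np.allclose(state.positions[0], state.velocities[0] * p.dt)

    def test_free_particle_equipartition(self):
        p = SDParameters(t_ref=308.0)
        rng = np.random.default_rng(11)
        n = 20
        m = np.full(n, 12.0)
        state = ParticleState(
            np.zeros((n, 3)),
            maxwell_velocities(m, 308.0, rng),
            m,
            np.full(n, 91.0),
        )
        f = np.zeros((n, 3))
        temps = []
        for step in range(12000):
            sd_step(state, f, p, rng)
            if step >= 2000:
                temps.append(kinetic_temperature(state.velocities, m))
        assert np.mean(temps) == pytest.approx(308.0, rel=0.02)

    def test_harmonic_oscillator_boltzmann_variance(self):
        k = 1000.0
        p = SDParameters(t_ref=300.0, gamma_solv=10.0)
        rng = np.random.default_rng(5)
        n = 64
        m = np.full(n, 12.0)
        state = ParticleState(
            np.zeros((n, 3)),
            maxwell_velocities(m, 300.0, rng),
            m,
            np.full(n, 10.0),
        )
        samples = []
        for step in range(30000):
            sd_step(state, -k * state.positions, p, rng)
            if step >= 5000:
                samples.append(state.positions.copy())
        var = np.concatenate(samples).var()
        assert var == pytest.approx(KB * 300.0 / k, rel=0.03)

    def test_energy_conservation_at_zero_friction(self):
        """gamma=0 with noise off is plain leap-frog: a harmonic oscillator
        conserves total energy to high relative precision."""
        k = 1000.0
        m = np.array([12.0])
        p = SDParameters(t_ref=300.0, dt=0.002)
        x = np.array([[0.05, 0.0, 0.0]])
        v = np.zeros((1, 3))
        state = ParticleState(x, v, m, np.zeros(1))
        energies = []
        for _ in range(100000):
            x_n = state.positions.copy()
            sd_step(state, -k * x_n, p, None, noise=False)
            # the discrete invariant of leap-frog: 1/2 m v_half^2 + 1/2 k x_n x_{n+1}
            e = 0.5 * m[0] * np.sum(state.velocities**2) + 0.5 * k * np.sum(
                x_n * state.positions
            )
            energies.append(e)
        drift = abs(energies[-1] - energies[0]) / abs(energies[0])
        assert drift < 1e-4
        assert np.ptp(energies) / abs(energies[0]) < 1e-4

    def test_nonfinite_force_aborts_with_diagnostics(self):
        p = SDParameters()
        m = np.array([12.0])
        state = ParticleState(np.zeros((1, 3)), np.zeros((1, 3)), m, np.zeros(1))
        with pytest.raises(FloatingPointError):
            sd_step(state, np.array([[np.nan, 0, 0]]), p, np.random.default_rng(0))

    def test_velocity_autocorrelation_decays_at_gamma(self):
        """Free-particle velocity autocorrelation is exp(-gamma t)."""
        gamma = 20.0
        p = SDParameters(t_ref=300.0, gamma_solv=gamma, dt=0.002)
        rng = np.random.default_rng(3)
        n = 200
        m = np.full(n, 12.0)
        state = ParticleState(
            np.zeros((n, 3)),
            maxwell_velocities(m, 300.0, rng),
            m,
            np.full(n, gamma),
        )
        f = np.zeros((n, 3))
        vs = []
        for step in range(4000):
            sd_step(state, f, p, rng)
            if step >= 500:
                vs.append(state.velocities[:, 0].copy())
        vs = np.array(vs)
        lag = 25  # 0.05 ps
        c = np.mean(vs[:-lag] * vs[lag:]) / np.mean(vs * vs)
        assert c == pytest.approx(math.exp(-gamma * lag * p.dt), abs=0.05)


class TestShake:
    def test_satisfied_constraints_unchanged(self):
        x = np.array([[0, 0, 0], [0.15, 0, 0]], float)
        out = shake(x, x.copy(), [(0, 1, 0.15)], [12.0, 12.0])
        assert np.allclose(out, x)

    def test_single_stretched_bond_symmetric_for_equal_masses(self):
        before = np.array([[0, 0, 0], [0.15, 0, 0]], float)
        after = np.array([[-0.01, 0, 0], [0.16, 0, 0]], float)
        out = shake(before, after, [(0, 1, 0.15)], [12.0, 12.0])
        d = np.linalg.norm(out[0] - out[1])
        assert abs(d - 0.15) / 0.15 <= 1e-4
        # equal masses: both ends move toward each other by the same amount
        assert out[0, 0] - after[0, 0] == pytest.approx(
            -(out[1, 0] - after[1, 0]), rel=1e-6
        )

    def test_chain_of_three_constraints(self):
        before = np.array(
            [[0, 0, 0], [0.15, 0, 0], [0.30, 0, 0], [0.45, 0, 0]], float
        )
        rng = np.random.default_rng(0)
        after = before + rng.normal(scale=0.01, size=before.shape)
        cons = [(0, 1, 0.15), (1, 2, 0.15), (2, 3, 0.15)]
        out = shake(before, after, cons, [12.0] * 4)
        for i, j, d in cons:
            assert abs(np.linalg.norm(out[i] - out[j]) - d) / d <= 1e-4

    def test_unequal_masses_weighting(self):
        before = np.array([[0, 0, 0], [0.15, 0, 0]], float)
        after = np.array([[0, 0, 0], [0.17, 0, 0]], float)
        out = shake(before, after, [(0, 1, 0.15)], [1.0, 100.0])
        # the light atom absorbs most of the correction
        assert abs(out[1, 0] - after[1, 0]) < abs(out[0, 0] - after[0, 0])


class TestWeakCoupling:
    def test_at_reference_no_scaling(self):
        assert weak_coupling_scale(308.0, SDParameters(t_ref=308.0)) == 1.0

    def test_formula_at_double_temperature(self):
        p = SDParameters(t_ref=150.0, dt=0.002, tau_t=0.1)
        lam = weak_coupling_scale(300.0, p)
        assert lam == pytest.approx(math.sqrt(0.99))

    def test_monotone_decreasing_in_temperature(self):
        p = SDParameters(t_ref=308.0)
        ts = np.linspace(50, 600, 12)
        lams = [weak_coupling_scale(t, p) for t in ts]
        assert all(a > b for a, b in zip(lams, lams[1:]))


class TestToyForceField:
    def test_bond_at_rest_length_zero(self):
        ff = ToyForceField(bonds=[(0, 1, 0.15, 1000.0)])
        e, f = toy_forcefield_eval(
            Conformation([[0, 0, 0], [0.15, 0, 0]]), ff
        )
        assert e["bond"] == pytest.approx(0.0)
        assert np.allclose(f, 0.0)

    def test_stretched_bond_harmonic_energy(self):
        ff = ToyForceField(bonds=[(0, 1, 0.15, 1000.0)])
        delta = 0.02
        e, _ = toy_forcefield_eval(
            Conformation([[0, 0, 0], [0.15 + delta, 0, 0]]), ff
        )
        assert e["bond"] == pytest.approx(0.5 * 1000.0 * delta**2)

    def test_forces_match_finite_differences(self, rng):
        n = 6
        ff = ToyForceField(
            bonds=[(k, k + 1, 0.15, 2000.0) for k in range(n - 1)],
            angles=[(k, k + 1, k + 2, 109.5, 300.0) for k in range(n - 2)],
            torsions=[(k, k + 1, k + 2, k + 3, 3, 0.0, 5.0) for k in range(n - 3)],
            c6=np.full(n, 1e-3),
            c12=np.full(n, 1e-6),
            charges=rng.uniform(-0.5, 0.5, n),
            exclusions={(k, k + 1) for k in range(n - 1)}
            | {(k, k + 2) for k in range(n - 2)},
        )
        x = np.cumsum(rng.uniform(0.08, 0.16, size=(n, 3)), axis=0)
        _, f = toy_forcefield_eval(Conformation(x), ff)

        def energy(y):
            terms, _ = toy_forcefield_eval(Conformation(y), ff)
            return sum(terms.values())

        fd = finite_difference_forces(energy, x)
        assert np.allclose(f, fd, rtol=1e-4, atol=1e-5 * max(np.abs(fd).max(), 1))


def _chain_system(n_res, seed):
    from implisolv import fixtures

    topo, conf = fixtures.make_toy_chain(n_res, seed=seed)
    ff = ToyForceField.from_topology(topo)

    def fn(x):
        return toy_forcefield_eval(Conformation(x), ff)

    return SDSystem(topo, conf, fn, topo.constraints), topo


class TestRunSD:
    def test_zero_steps_initial_frame_only(self):
        system, _ = _chain_system(3, 0)
        traj = run_sd(system, SDParameters(rng_seed=1), 0)
        assert len(traj) == 1

    def test_same_seed_identical_trajectories(self):
        p = SDParameters(rng_seed=42, store_interval=0.02)
        t1 = run_sd(_chain_system(3, 0)[0], p, 50)
        t2 = run_sd(_chain_system(3, 0)[0], p, 50)
        assert np.array_equal(t1.coordinates, t2.coordinates)

    def test_shake_precision_in_stored_frames(self):
        system, topo = _chain_system(4, 1)
        p = SDParameters(rng_seed=3, store_interval=0.05)
        traj = run_sd(system, p, 300)
        for f in traj.frames:
            for i, j, d in topo.constraints:
                err = abs(np.linalg.norm(f.coordinates[i] - f.coordinates[j]) - d)
                assert err / d <= 1e-4

    def test_energy_bookkeeping_with_sasa_term(self):
        from implisolv import fixtures, sasa

        topo, conf = fixtures.make_toy_chain(3, seed=0)
        ff = ToyForceField.from_topology(topo)
        params_set = sasa.load_parameter_set("per-type")

        def fn(x):
            terms, f = toy_forcefield_eval(Conformation(x), ff)
            res = sasa.sasa_energy_forces(Conformation(x), topo, params_set)
            terms["sasa"] = res.energy
            return terms, f + res.forces

        system = SDSystem(topo, conf, fn, topo.constraints)
        log = []
        run_sd(system, SDParameters(rng_seed=0, store_interval=0.05), 100,
               energy_log=log)
        assert log and all("sasa" in row and "bond" in row for row in log)
        for row in log:
            assert np.isfinite(row["sasa"]) and np.isfinite(row["temperature"])


class TestHeatup:
    def test_default_schedule_matches_protocol(self):
        temps = [s.t_ref for s in DEFAULT_HEATUP_SCHEDULE]
        ks = [s.restraint_k for s in DEFAULT_HEATUP_SCHEDULE]
        assert temps == [60.0, 120.0, 180.0, 240.0, 308.0]
        assert ks == [25000.0, 2500.0, 250.0, 25.0, None]
        assert all(s.duration == 20.0 for s in DEFAULT_HEATUP_SCHEDULE)

    def test_empty_schedule_is_noop(self):
        system, _ = _chain_system(2, 0)
        traj = heatup_protocol(system, SDParameters(), [])
        assert len(traj) == 0

    def test_scaled_schedule_reaches_target_temperature(self):
        system, topo = _chain_system(4, 2)
        schedule = [
            HeatupStage(60.0, 1.0, 25000.0),
            HeatupStage(120.0, 1.0, 2500.0),
            HeatupStage(180.0, 1.0, 250.0),
            HeatupStage(240.0, 1.0, 25.0),
            HeatupStage(308.0, 1.0, None),
        ]
        p = SDParameters(rng_seed=4, store_interval=0.02)
        log: list = []
        heatup_protocol(system, p, schedule, energy_log=log)
        final_temps = [r["temperature"] for r in log if r["stage_t_ref"] == 308.0]
        assert len(final_temps) > 10
        assert np.mean(final_temps) == pytest.approx(308.0, rel=0.10)


class TestParameterValidation:
    def test_dt_must_be_below_tau(self):
        with pytest.raises(ValueError):
            SDParameters(dt=0.2, tau_t=0.1)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            SDParameters(neighbour_radius=-1.0)
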