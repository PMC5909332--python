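"""Integrators, thermostats, barostat, mass repartitioning, the minimizer,
and trajectory determinism."""

import math

import numpy as np
import pytest
from _helpers import run_thermostat_only

from polarmd.dynamics import (MDRunner, MDState, beeman_step,
                              berendsen_barostat,
                              h_mass_repartition, initialize_velocities,
                              kinetic_energy, respa_step, thermostat_step,
                              velocity_verlet_step)
from polarmd.minimize import lbfgs_minimize, minimize_system
from polarmd.system import (ConfigurationError, MDConfig, SimulationBox,
                            TopologyError)
from polarmd.units import BOLTZMANN, MD_ACCEL


def harmonic_force(k):
    def f(x):
        return -k * x, 0.5 * k * float(np.sum(x * x)), {}
    return f


def free_force(x):
    return np.zeros_like(x), 0.0, {}


class TestVerlet:
    def test_free_particle_uniform_motion(self):
        m = np.array([2.0])
        st = MDState(np.zeros((1, 3)), np.array([[0.01, 0.0, 0.0]]))
        for _ in range(100):
            velocity_verlet_step(st, free_force, 1.0, m)
        assert np.allclose(st.positions, [[1.0, 0, 0]], atol=1e-12)

    def test_fixed_point(self):
        m = np.array([1.0])
        st = MDState(np.ones((1, 3)), np.zeros((1, 3)))
        velocity_verlet_step(st, free_force, 1.0, m)
        assert np.allclose(st.positions, 1.0)

    def test_harmonic_oscillator_period_and_energy(self):
        # U = ½kx² with k chosen so ω = sqrt(k·MD_ACCEL/m)
        k, m = 10.0, np.array([3.0])
        omega = math.sqrt(k * MD_ACCEL / m[0])
        period = 2 * math.pi / omega
        dt = period / 1000.0
        st = MDState(np.array([[1.0, 0, 0]]), np.zeros((1, 3)))
        e0 = 0.5 * k
        prev_x = 1.0
        crossings = []
        energies = []
        for step in range(2100):
            velocity_verlet_step(st, harmonic_force(k), dt, m)
            x = st.positions[0, 0]
            energies.append(st.potential
                            + kinetic_energy(m, st.velocities))
            if prev_x < 0 <= x:
                crossings.append(step * dt)
            prev_x = x
        assert max(abs(np.array(energies) - e0)) / e0 < 1e-4   # O(dt²)
        measured = crossings[1] - crossings[0]   # successive upward crossings
        assert abs(measured - period) / period < 1e-3

    def test_nonfinite_force_aborts(self):
        def bad(x):
            return np.full_like(x, np.nan), 0.0, {}
        st = MDState(np.zeros((1, 3)), np.zeros((1, 3)))
        with pytest.raises(FloatingPointError):
            velocity_verlet_step(st, bad, 1.0, np.array([1.0]))


class TestBeeman:
    def test_free_particle(self):
        m = np.array([1.0])
        st = MDState(np.zeros((1, 3)), np.array([[0.02, 0, 0]]))
        for _ in range(50):
            beeman_step(st, free_force, 1.0, m)
        assert np.allclose(st.positions[0, 0], 1.0, atol=1e-12)

    def test_oscillator_energy_error_order_dt2(self):
        k, m = 10.0, np.array([3.0])
        omega = math.sqrt(k * MD_ACCEL / m[0])
        period = 2 * math.pi / omega
        errs = []
        for nsub in (500, 1000):
            dt = period / nsub
            st = MDState(np.array([[1.0, 0, 0]]), np.zeros((1, 3)))
            emax = 0.0
            for _ in range(nsub):
                beeman_step(st, harmonic_force(k), dt, m)
                emax = max(emax, abs(st.potential
                                     + kinetic_energy(m, st.velocities)
                                     - 0.5 * k))
            errs.append(emax)
        assert errs[1] < errs[0] / 2.5         # ~ dt² scaling


class TestRespa:
    def test_single_substep_equals_verlet(self):
        k = 5.0
        m = np.array([2.0, 1.0])

        def full(x):
            return -k * x, 0.5 * k * float(np.sum(x * x)), {}

        def zero(x):
            return np.zeros_like(x), 0.0, {}

        rng = np.random.default_rng(0)
        x0 = rng.normal(size=(2, 3))
        v0 = rng.normal(size=(2, 3)) * 0.01
        s1 = MDState(x0.copy(), v0.copy())
        s2 = MDState(x0.copy(), v0.copy())
        for _ in range(20):
            velocity_verlet_step(s1, full, 0.5, m)
            respa_step(s2, full, zero, 0.5, 1, m)
        assert np.allclose(s1.positions, s2.positions, atol=1e-12)
        assert np.allclose(s1.velocities, s2.velocities, atol=1e-12)

    def test_invalid_substeps(self):
        with pytest.raises(ConfigurationError):
            respa_step(MDState(np.zeros((1, 3)), np.zeros((1, 3))),
                       free_force, free_force, 1.0, 0, np.array([1.0]))

    def test_respa_stable_on_small_water_box(self):
        """2 fs outer / 1 fs inner NVE stays bounded on a 32-water box."""
        from polarmd.engine import Engine
        from polarmd.fixtures import gen_water_box

        system, params = gen_water_box(n_waters=32, seed=11)
        cfg = MDConfig(polar_solver="pcg", polar_eps=1e-6,
                       ewald_cutoff=4.5, vdw_cutoff=4.5, bspline_order=5,
                       pme_grid=(24, 24, 24))
        eng = Engine(system, params, cfg)
        runner = MDRunner(eng, dt=2.0, integrator="respa", n_inner=2,
                          thermostat="bussi", temperature=298.0, tau_t=50.0,
                          seed=1)
        v = initialize_velocities(system.masses, 298.0, seed=1)
        st = runner.run(system.positions, v, 100)
        eng.aspc.clear()
        nve = MDRunner(eng, dt=2.0, integrator="respa", n_inner=2)
        totals = []
        nve.run(st.positions, st.velocities, 150,
                callback=lambda s: totals.append(
                    s.potential + kinetic_energy(system.masses,
                                                 s.velocities)))
        spread = max(totals[20:]) - min(totals[20:])
        assert spread / system.n_sites < 0.05   # bounded, no blow-up


class TestMassRepartition:
    def test_water_bookkeeping(self):
        masses = np.array([15.999, 1.008, 1.008])
        bonds = np.array([(0, 1), (0, 2)])
        m = h_mass_repartition(masses, bonds, 3.0)
        assert m[1] == m[2] == 3.0
        assert m[0] == pytest.approx(15.999 - 2 * (3.0 - 1.008), abs=1e-12)
        assert m.sum() == pytest.approx(masses.sum(), abs=1e-12)

    def test_isolated_hydrogen_rejected(self):
        with pytest.raises(TopologyError):
            h_mass_repartition(np.array([1.008]), np.zeros((0, 2)))


class TestThermostats:
    def test_decoupled_limit_is_noop(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(10, 3)) * 0.01
        m = np.full(10, 12.0)
        v2 = thermostat_step(v, m, "berendsen", 300.0, 1e12, 1.0, 27)
        assert np.allclose(v2, v, rtol=1e-12)
        v3 = thermostat_step(v, m, "bussi", 300.0, 1e12, 1.0, 27,
                             np.random.default_rng(1))
        assert np.allclose(v3, v, rtol=1e-6)

    def test_berendsen_moves_toward_target(self):
        rng = np.random.default_rng(0)
        m = np.full(50, 12.0)
        v = initialize_velocities(m, 100.0, seed=2)
        for _ in range(200):
            v = thermostat_step(v, m, "berendsen", 300.0, 20.0, 1.0,
                                3 * 50 - 3)
        T = 2 * kinetic_energy(m, v) / ((3 * 50 - 3) * BOLTZMANN)
        assert abs(T - 300.0) / 300.0 < 0.05

    def test_bussi_mean_temperature(self):
        kes, ndof = run_thermostat_only(200, 300.0, 100.0, 1.0, 5000, seed=4)
        Tmean = 2 * np.mean(kes[1000:]) / (ndof * BOLTZMANN)
        assert abs(Tmean - 300.0) / 300.0 < 0.02

    def test_invalid_target(self):
        with pytest.raises(ConfigurationError):
            thermostat_step(np.zeros((2, 3)), np.ones(2), "bussi", -5.0,
                            10.0, 1.0, 3, np.random.default_rng(0))


class TestBarostat:
    def test_no_scaling_at_target(self):
        box = SimulationBox.cubic(10.0)
        pos = np.ones((2, 3))
        p2, box2 = berendsen_barostat(pos, box, 1.0, 1.0, 1000.0, 1.0)
        assert box2.a == pytest.approx(10.0, abs=1e-12)
        assert np.allclose(p2, pos)

    def test_overpressure_expands(self):
        box = SimulationBox.cubic(10.0)
        edges = [box.a]
        pos = np.ones((2, 3))
        for _ in range(10):
            pos, box = berendsen_barostat(pos, box, 500.0, 1.0, 100.0, 1.0)
            edges.append(box.a)
        assert all(b > a for a, b in zip(edges, edges[1:]))

    def test_infinite_tau_recovers_nvt(self):
        box = SimulationBox.cubic(10.0)
        _, box2 = berendsen_barostat(np.ones((1, 3)), box, 500.0, 1.0,
                                     1e15, 1.0)
        assert box2.a == pytest.approx(10.0, rel=1e-12)

    def test_open_box_rejected(self):
        with pytest.raises(ConfigurationError):
            berendsen_barostat(np.zeros((1, 3)),
                               SimulationBox.open_boundary(), 2.0, 1.0,
                               100.0, 1.0)


class TestMinimizer:
    def test_convex_quadratic_exact(self):
        A = np.diag(np.arange(1.0, 11.0))
        b = np.arange(10.0)
        x_star = np.linalg.solve(A, b)

        calls = {"n": 0}

        def eg(x):
            calls["n"] += 1
            return 0.5 * x @ A @ x - b @ x, A @ x - b

        x, e, info = lbfgs_minimize(np.zeros(10), eg, grms_tol=1e-10)
        assert np.allclose(x, x_star, atol=1e-7)
        assert info["iterations"] <= 20

    def test_start_at_minimum(self):
        def eg(x):
            return float(np.sum(x**2)), 2 * x
        x, e, info = lbfgs_minimize(np.zeros(5), eg, grms_tol=1e-8)
        assert info["iterations"] <= 1 and e == 0.0

    def test_water_dimer_minimization(self, water_dimer_engine):
        eng, system = water_dimer_engine
        rng = np.random.default_rng(0)
        start = system.positions + rng.normal(scale=0.05,
                                              size=system.positions.shape)
        e_start = eng.energy(start)
        x, e, info = minimize_system(eng, start, grms_tol=0.5,
                                     max_iterations=200)
        assert e < e_start
        assert info["grms"] <= 0.5


def test_trajectory_determinism_bitwise():
    from polarmd.engine import Engine
    from polarmd.fixtures import gen_water_box

    system, params = gen_water_box(n_waters=8, seed=2)
    cfg = MDConfig(polar_solver="pcg", polar_eps=1e-6, ewald_cutoff=3.0,
                   vdw_cutoff=3.0, bspline_order=5, pme_grid=(16, 16, 16))
    outs = []
    for _ in range(2):
        eng = Engine(system.copy(), params, cfg)
        runner = MDRunner(eng, dt=1.0, thermostat="bussi",
                          temperature=250.0, tau_t=50.0, seed=42)
        v = initialize_velocities(system.masses, 250.0, seed=42)
        st = runner.run(system.positions.copy(), v, 25)
        outs.append((st.positions.copy(), st.velocities.copy()))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert np.array_equal(outs[0][1], outs[1][1])


def test_momentum_conservation_nve():
    from polarmd.engine import Engine
    from polarmd.fixtures import gen_water_box

    system, params = gen_water_box(n_waters=8, seed=2)
    cfg = MDConfig(polar_solver="pcg", polar_eps=1e-7, ewald_cutoff=3.0,
                   vdw_cutoff=3.0, bspline_order=5, pme_grid=(16, 16, 16))
    eng = Engine(system, params, cfg)
    runner = MDRunner(eng, dt=1.0)
    v = initialize_velocities(system.masses, 200.0, seed=5)
    p0 = np.sum(system.masses[:, None] * v, axis=0)
    st = runner.run(system.positions, v, 200)
    p1 = np.sum(system.masses[:, None] * st.velocities, axis=0)
    assert np.abs(p1 - p0).max() < 1e-10
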