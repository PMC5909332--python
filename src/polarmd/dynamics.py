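"""Integrators (velocity Verlet, Beeman, RESPA), Bussi/Berendsen
thermostats, the Berendsen barostat, H-mass repartitioning and the MD runner.

Units: positions Å, velocities Å/fs, forces kcal·mol⁻¹·Å⁻¹; accelerations
use a = MD_ACCEL·F/m so that timesteps are in fs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .system import ConfigurationError, TopologyError
from .units import BOLTZMANN, MD_ACCEL


@dataclass
class MDState:
    positions: np.ndarray
    velocities: np.ndarray
    forces: Optional[np.ndarray] = None
    prev_accel: Optional[np.ndarray] = None     # Beeman history
    step: int = 0
    potential: float = 0.0
    info: dict = field(default_factory=dict)


def kinetic_energy(masses, velocities):
    return 0.5 * float(np.sum(masses[:, None] * velocities**2)) / MD_ACCEL


def initialize_velocities(masses, temperature, seed=0, remove_momentum=True):
    """Maxwell-Boltzmann velocities at the target temperature (seeded)."""
    rng = np.random.default_rng(seed)
    n = len(masses)
    sigma = np.sqrt(MD_ACCEL * BOLTZMANN * temperature / masses)
    v = rng.normal(size=(n, 3)) * sigma[:, None]
    if remove_momentum and n > 1:
        p = np.sum(masses[:, None] * v, axis=0)
        v -= p / masses.sum()
    return v


def _accel(forces, masses):
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite force encountered; aborting step")
    return MD_ACCEL * forces / masses[:, None]


def velocity_verlet_step(state: MDState, force_fn: Callable, dt: float,
                         masses, reassign_hook: Callable | None = None):
    """One symplectic velocity Verlet step; ``force_fn(x) -> (F, U, info)``."""
    if state.forces is None:
        state.forces, state.potential, state.info = force_fn(state.positions)
    a = _accel(state.forces, masses)
    v_half = state.velocities + 0.5 * dt * a
    state.positions = state.positions + dt * v_half
    if reassign_hook is not None:
        reassign_hook(state)
    state.forces, state.potential, state.info = force_fn(state.positions)
    state.velocities = v_half + 0.5 * dt * _accel(state.forces, masses)
    state.step += 1
    return state


def beeman_step(state: MDState, force_fn, dt, masses):
    """Beeman's algorithm; the first step bootstraps the previous
    acceleration from the current one (documented rule)."""
    if state.forces is None:
        state.forces, state.potential, state.info = force_fn(state.positions)
    a = _accel(state.forces, masses)
    if state.prev_accel is None:
        state.prev_accel = a.copy()
    a_prev = state.prev_accel
    state.positions = (state.positions + dt * state.velocities
                       + dt * dt * (4.0 * a - a_prev) / 6.0)
    state.forces, state.potential, state.info = force_fn(state.positions)
    a_new = _accel(state.forces, masses)
    state.velocities = state.velocities + dt * (2.0 * a_new + 5.0 * a
                                                - a_prev) / 6.0
    state.prev_accel = a
    state.step += 1
    return state


def respa_step(state: MDState, fast_fn, slow_fn, dt, n_inner, masses):
    """Impulse (r-RESPA) step: slow (non-bonded) forces kick at dt/2, fast
    (bonded) forces integrate with velocity Verlet at dt/n_inner."""
    if n_inner < 1:
        raise ConfigurationError("RESPA substeps must be >= 1")
    if "slow_forces" not in state.info:
        Fs, Us, info_s = slow_fn(state.positions)
        state.info["slow_forces"] = Fs
        state.info["slow_potential"] = Us
    if state.forces is None:
        Ff, Uf, _ = fast_fn(state.positions)
        state.forces = Ff
        state.potential = Uf
    state.velocities = state.velocities + 0.5 * dt * _accel(
        state.info["slow_forces"], masses)
    h = dt / n_inner
    Ff = state.forces
    for _ in range(n_inner):
        a = _accel(Ff, masses)
        v_half = state.velocities + 0.5 * h * a
        state.positions = state.positions + h * v_half
        Ff, Uf, _ = fast_fn(state.positions)
        state.velocities = v_half + 0.5 * h * _accel(Ff, masses)
    state.forces = Ff
    Fs, Us, info_s = slow_fn(state.positions)
    state.info["slow_forces"] = Fs
    state.info["slow_potential"] = Us
    state.info.update(info_s)
    state.velocities = state.velocities + 0.5 * dt * _accel(Fs, masses)
    state.potential = Uf + Us
    state.step += 1
    return state


def h_mass_repartition(masses, bonds, target_h_mass=3.024, h_threshold=1.5):
    """Shift mass from each hydrogen's bonded heavy atom onto the hydrogen.

    The default target 3.024 amu triples the hydrogen mass; total and
    per-molecule mass are conserved exactly.
    """
    m = np.array(masses, dtype=float)
    adj = {}
    for i, j in bonds:
        adj.setdefault(int(i), []).append(int(j))
        adj.setdefault(int(j), []).append(int(i))
    for h in range(len(m)):
        if m[h] >= h_threshold:
            continue
        heavies = [k for k in adj.get(h, []) if m[k] >= h_threshold]
        if len(heavies) != 1:
            raise TopologyError(
                f"hydrogen {h} bonded to {len(heavies)} heavy atoms")
        dm = target_h_mass - m[h]
        m[h] += dm
        m[heavies[0]] -= dm
        if m[heavies[0]] <= 0:
            raise TopologyError("heavy atom mass exhausted by repartitioning")
    return m


# ---------------------------------------------------------------------------
# thermostats / barostat
# ---------------------------------------------------------------------------


def berendsen_thermostat(velocities, masses, T0, tau, dt, ndof):
    ke = kinetic_energy(masses, velocities)
    T = 2.0 * ke / (ndof * BOLTZMANN) if ndof else T0
    if T <= 0:
        return velocities
    lam = math.sqrt(max(1.0 + (dt / tau) * (T0 / T - 1.0), 0.0))
    return velocities * lam


def bussi_thermostat(velocities, masses, T0, tau, dt, ndof, rng):
    """Stochastic velocity rescaling (canonical sampling); seeded stream."""
    ke = kinetic_energy(masses, velocities)
    if ke <= 0:
        return velocities
    ke_target = 0.5 * ndof * BOLTZMANN * T0
    c = math.exp(-dt / tau)
    r1 = rng.standard_normal()
    # sum of squares of ndof-1 further Gaussians
    r2 = 2.0 * rng.standard_gamma(0.5 * (ndof - 1)) if ndof > 1 else 0.0
    alpha2 = (c + (1.0 - c) * (r1 * r1 + r2) * ke_target / (ndof * ke)
              + 2.0 * r1 * math.sqrt(c * (1.0 - c) * ke_target / (ndof * ke)))
    return velocities * math.sqrt(max(alpha2, 0.0))


def thermostat_step(velocities, masses, kind, T0, tau, dt, ndof, rng=None):
    if T0 <= 0:
        raise ConfigurationError("target temperature must be positive")
    if kind == "berendsen":
        return berendsen_thermostat(velocities, masses, T0, tau, dt, ndof)
    if kind == "bussi":
        if rng is None:
            raise ConfigurationError("Bussi thermostat needs a random stream")
        return bussi_thermostat(velocities, masses, T0, tau, dt, ndof, rng)
    raise ConfigurationError(f"unknown thermostat '{kind}'")


def berendsen_barostat(positions, box, pressure, P0, tau_p, dt,
                       compressibility=4.5e-5):
    """Isotropic Berendsen box scaling toward the target pressure (atm)."""
    if not box.periodic:
        raise ConfigurationError("barostat requires a periodic box")
    mu = (1.0 - compressibility * (dt / tau_p) * (P0 - pressure)) ** (1.0 / 3.0)
    box.a *= mu
    box.b *= mu
    box.c *= mu
    return positions * mu, box


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------


class MDRunner:
    """Couples an Engine to the integrators and (optionally) thermostat and
    barostat; logs per-interval energies and solver diagnostics."""

    def __init__(self, engine, dt=1.0, integrator="verlet", n_inner=2,
                 thermostat=None, temperature=298.0, tau_t=100.0,
                 barostat=None, pressure=1.0, tau_p=1000.0,
                 use_aspc=True, solver=None, seed=0):
        self.engine = engine
        self.dt = dt
        self.integrator = integrator
        self.n_inner = n_inner
        self.thermostat = thermostat
        self.temperature = temperature
        self.tau_t = tau_t
        self.barostat = barostat
        self.pressure = pressure
        self.tau_p = tau_p
        self.use_aspc = use_aspc
        self.solver = solver
        self.rng = np.random.default_rng(seed)
        self.masses = engine.system.masses
        self.ndof = max(3 * engine.system.n_sites - 3, 1)
        self.log = []

    def _force_full(self, x):
        out = self.engine.evaluate(x, solver=self.solver,
                                   use_aspc=self.use_aspc)
        info = {"components": out["components"]}
        if out["dipoles"] is not None:
            info["polar_iterations"] = out["dipoles"].iterations
        F = out["forces"]
        # strip the tiny spurious net mesh force so momentum is conserved
        F = F - F.mean(axis=0)
        return F, out["potential"], info

    def _force_fast(self, x):
        bt = self.engine.bonded.energy_forces(x, self.engine.system.box)
        e = bt["bond"] + bt["angle"] + bt["torsion"]
        F = bt["forces"]
        if self.engine.restraints is not None:
            er, fr = self.engine.restraints.energy_forces(
                x, self.engine.system.box, self.masses)
            e += er
            F = F + fr
        return F, e, {}

    def _force_slow(self, x):
        out = self.engine.evaluate(x, solver=self.solver,
                                   use_aspc=self.use_aspc)
        bt_keys = ("bond", "angle", "torsion", "restraint")
        e = sum(v for k, v in out["components"].items()
                if k not in bt_keys and k != "dvdw_dlambda")
        F = out["forces"] - self._force_fast(x)[0]
        F = F - F.mean(axis=0)
        info = {"components": out["components"]}
        if out["dipoles"] is not None:
            info["polar_iterations"] = out["dipoles"].iterations
        return F, e, info

    def run(self, positions, velocities, n_steps, log_interval=0,
            callback=None):
        state = MDState(positions.copy(), velocities.copy())
        for _ in range(n_steps):
            if self.integrator == "verlet":
                velocity_verlet_step(state, self._force_full, self.dt,
                                     self.masses)
            elif self.integrator == "beeman":
                beeman_step(state, self._force_full, self.dt, self.masses)
            elif self.integrator == "respa":
                respa_step(state, self._force_fast, self._force_slow,
                           self.dt, self.n_inner, self.masses)
            else:
                raise ConfigurationError(
                    f"unknown integrator '{self.integrator}'")
            if self.thermostat:
                state.velocities = thermostat_step(
                    state.velocities, self.masses, self.thermostat,
                    self.temperature, self.tau_t, self.dt, self.ndof,
                    self.rng)
            if self.barostat:
                ke = kinetic_energy(self.masses, state.velocities)
                P = self.engine.instantaneous_pressure(state.positions, ke)
                state.positions, _ = berendsen_barostat(
                    state.positions, self.engine.system.box, P,
                    self.pressure, self.tau_p, self.dt)
                self.engine.nlist.rebuild(state.positions)
            if log_interval and state.step % log_interval == 0:
                ke = kinetic_energy(self.masses, state.velocities)
                self.log.append({
                    "step": state.step,
                    "potential": state.potential,
                    "kinetic": ke,
                    "total": state.potential + ke,
                    "temperature": 2 * ke / (self.ndof * BOLTZMANN),
                    "polar_iterations": state.info.get("polar_iterations"),
                })
            if callback is not None:
                callback(state)
        return state


def energy_drift_rate(times_ps, totals, n_atoms):
    """|slope| of a linear fit to the total energy, kcal/mol/atom/ps."""
    t = np.asarray(times_ps, dtype=float)
    e = np.asarray(totals, dtype=float)
    slope = np.polyfit(t, e, 1)[0]
    return abs(slope) / n_atoms
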