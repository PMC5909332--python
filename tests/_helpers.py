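"""Shared test utilities: finite-difference force checks and small builders."""

import numpy as np


def fd_force_error(engine, positions, atoms=None, h=1e-5, solver=None):
    """Max |F_analytic - F_central_difference| relative to the force scale."""
    out = engine.evaluate(positions, solver=solver)
    F = out["forces"]
    scale = max(1.0, float(np.abs(F).max()))
    if atoms is None:
        atoms = range(positions.shape[0])
    worst = 0.0
    for i in atoms:
        for c in range(3):
            pp = positions.copy()
            pp[i, c] += h
            pm = positions.copy()
            pm[i, c] -= h
            fd = -(engine.energy(pp, solver=solver)
                   - engine.energy(pm, solver=solver)) / (2 * h)
            worst = max(worst, abs(fd - F[i, c]) / scale)
    return worst


def random_traceless(rng, scale=0.1):
    A = rng.normal(size=(3, 3)) * scale
    A = 0.5 * (A + A.T)
    return A - np.trace(A) / 3.0 * np.eye(3)


def brute_force_pairs(positions, box, cutoff):
    """O(N²) minimum-image pair oracle, returned as a sorted set of tuples."""
    n = positions.shape[0]
    out = set()
    for i in range(n):
        dr = box.minimum_image(positions[i + 1:] - positions[i])
        d2 = np.einsum("ka,ka->k", dr, dr)
        for j in np.nonzero(d2 <= cutoff * cutoff)[0]:
            out.add((i, i + 1 + int(j)))
    return out


def run_thermostat_only(n_particles, temperature, tau, dt, n_steps, seed,
                        kind="bussi", mass=12.0):
    """Free-particle gas evolved by the thermostat alone; returns the kinetic
    energy time series (kcal/mol) and the number of degrees of freedom."""
    from polarmd.dynamics import kinetic_energy, thermostat_step

    rng = np.random.default_rng(seed)
    masses = np.full(n_particles, mass)
    from polarmd.dynamics import initialize_velocities
    v = initialize_velocities(masses, temperature * 0.5, seed=seed)
    ndof = 3 * n_particles - 3
    kes = []
    for _ in range(n_steps):
        v = thermostat_step(v, masses, kind, temperature, tau, dt, ndof, rng)
        kes.append(kinetic_energy(masses, v))
    return np.array(kes), ndof
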