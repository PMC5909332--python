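"""Self-contained validation benchmarks: lattice constants through the mesh
pipeline, splitting-parameter invariance, mesh-vs-explicit-k agreement,
finite-difference force audits, solver cross-checks, conservation runs, and
estimator recoveries.

These routines regenerate their inputs from seeds and recompute every
quantity from scratch; they power both the test suite and the standalone
acceptance script.
"""

from __future__ import annotations

import math

import numpy as np

from . import reference as ref
from .engine import Engine
from .fixtures import (gen_ion_in_water, gen_random_multipole_gas,
                       gen_rocksalt, gen_water_box, gen_water_dimer)
from .system import MDConfig
from .units import BOLTZMANN, COULOMB

#: shared settings of the 64-water conservation protocol
WATER64_CONFIG = dict(ewald_cutoff=6.0, vdw_cutoff=6.0, bspline_order=6,
                      pme_grid=(30, 30, 30))


def madelung_constant(cells=2):
    """Rock-salt Madelung constant from the full mesh-Ewald energy."""
    system, params = gen_rocksalt(cells=cells)
    a = 5.6402
    rc = min(4.9, system.box.min_edge / 2.0 - 0.3)
    cfg = MDConfig(ewald_cutoff=rc, vdw_cutoff=rc, bspline_order=8,
                   pme_grid=(48, 48, 48) if cells == 2 else (32, 32, 32))
    eng = Engine(system, params, cfg)
    out = eng.evaluate(system.positions, compute_forces=False)
    total = out["potential"]
    n_pairs = system.n_sites / 2
    d = a / 2.0
    return -total * d / (COULOMB * n_pairs)


def wigner_constant(edge=10.0, beta=0.8):
    """Self-energy constant of one unit charge in a cubic cell, from the
    mesh path: E_total = C·k_C/(2·edge) with C ≈ -2.837297."""
    from .electrostatics import background_correction, self_energy
    from .spme import spme_total

    from .system import SimulationBox
    box = SimulationBox.cubic(edge)
    pos = np.array([[0.31 * edge, 0.47 * edge, 0.11 * edge]])
    q = np.array([1.0])
    rec = spme_total(pos, box, q, None, None, beta, dims=(36, 36, 36),
                     order=8, compute_forces=False)["energy"]
    total = (rec + self_energy(q, np.zeros((1, 3)), np.zeros((1, 3, 3)), beta)
             + background_correction(q, beta, box.volume))
    return total * 2.0 * edge / COULOMB


def beta_sweep_spread(n=50, seed=0, betas=(0.35, 0.40, 0.45, 0.50)):
    """Max-min spread (kcal/mol) of the total electrostatic energy of a
    random multipole gas as the Ewald splitting parameter sweeps."""
    system, params = gen_random_multipole_gas(n, edge=22.0, seed=seed,
                                              polarizable=False)
    vals = []
    for beta in betas:
        cfg = MDConfig(ewald_cutoff=10.5, ewald_beta=beta, bspline_order=8,
                       pme_grid=(48, 48, 48), vdw_cutoff=10.5)
        eng = Engine(system, params, cfg)
        vals.append(eng.energy(system.positions))
    return max(vals) - min(vals), vals


def spme_oracle_errors(n=50, seed=1, beta=0.5):
    """Relative energy and field error of the mesh (order 8) against the
    explicit k-space sum on one random multipole system."""
    system, params = gen_random_multipole_gas(n, edge=18.0, seed=seed,
                                              polarizable=False)
    eng = Engine(system, params, MDConfig(ewald_cutoff=8.0, ewald_beta=beta,
                                          bspline_order=8, vdw_cutoff=8.0,
                                          pme_grid=(48, 48, 48)))
    q, mu, Q, _, _, _ = eng._lab_multipoles(system.positions)
    from .spme import spme_total
    out = spme_total(system.positions, system.box, q, mu, Q, beta,
                     dims=(48, 48, 48), order=8, compute_forces=False)
    ex = ref.ewald_recip_explicit(system.positions, system.box, q, mu, Q,
                                  beta)
    e_err = abs(out["energy"] - ex["energy"]) / abs(ex["energy"])
    f_err = (np.abs(out["field"] - ex["field"]).max()
             / np.abs(ex["field"]).max())
    return e_err, f_err


# ---------------------------------------------------------------------------
# force audits
# ---------------------------------------------------------------------------


def _fd_error(engine, positions, atoms, h=1e-5, solver=None):
    out = engine.evaluate(positions, solver=solver)
    F = out["forces"]
    scale = max(1.0, float(np.abs(F).max()))
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


def gradient_audit(seed=0):
    """Finite-difference force errors (relative to the force scale) for every
    analytic-gradient route; returns a dict of named errors."""
    errs = {}
    # permanent multipoles + polarization on a random gas
    system, params = gen_random_multipole_gas(10, edge=10.0, seed=seed + 12)
    cfg = MDConfig(polar_solver="pcg", polar_eps=1e-10, polar_maxiter=400,
                   ewald_cutoff=4.5, bspline_order=6, pme_grid=(24, 24, 24))
    eng = Engine(system, params, cfg)
    errs["permanent_pcg"] = _fd_error(eng, system.positions, (0, 4, 9))
    errs["tcg1"] = _fd_error(eng, system.positions, (0, 9), solver="tcg1")
    errs["tcg2"] = _fd_error(eng, system.positions, (0, 9), solver="tcg2")
    # water dimer: frames, vdW, bonded through one surface
    dsys, dpar = gen_water_dimer(seed=seed)
    deng = Engine(dsys, dpar, MDConfig(polar_solver="pcg", polar_eps=1e-10,
                                       polar_maxiter=400))
    errs["water_dimer_full"] = _fd_error(deng, dsys.positions,
                                         range(dsys.n_sites))
    # restraints
    from .restraints import (CentroidRestraint, DistanceRestraint,
                             PositionRestraint, RestraintSet)
    rs = RestraintSet()
    rs.add(PositionRestraint(0, dsys.positions[0] + 0.4, 3.0))
    rs.add(DistanceRestraint(0, 3, 2.5, 4.0))
    rs.add(CentroidRestraint([3, 4, 5], dsys.positions[3] + 1.0, 2.0))
    reng = Engine(dsys, dpar, MDConfig(polar_solver="pcg", polar_eps=1e-10,
                                       polar_maxiter=400), restraint_set=rs)
    errs["restraints"] = _fd_error(reng, dsys.positions, (0, 3, 4))
    # softcore dE/dλ
    from .engine import AlchemicalState
    isys, ipar = gen_ion_in_water(n_waters=8, charge=0.0, seed=seed + 3)
    icfg = MDConfig(polar_solver="pcg", polar_eps=1e-8, ewald_cutoff=3.0,
                    vdw_cutoff=3.0, bspline_order=5, pme_grid=(16, 16, 16))
    h = 1e-6
    worst = 0.0
    for lam in (0.3, 0.7):
        engs = {}
        for l2 in (lam - h, lam, lam + h):
            engs[l2] = Engine(isys, ipar, icfg, alchemy=AlchemicalState(
                lambda_vdw=l2, solute=frozenset([0])))
        dl = engs[lam].evaluate(isys.positions,
                                compute_forces=False)["components"][
                                    "dvdw_dlambda"]
        up = engs[lam + h].evaluate(isys.positions, compute_forces=False)
        dn = engs[lam - h].evaluate(isys.positions, compute_forces=False)
        fd = (up["components"]["vdw"] - dn["components"]["vdw"]) / (2 * h)
        worst = max(worst, abs(fd - dl) / max(1.0, abs(fd)))
    errs["softcore_dlambda"] = worst
    return errs


# ---------------------------------------------------------------------------
# solver cross-checks
# ---------------------------------------------------------------------------


def solver_oracle(seed=3):
    """PCG/JI-DIIS against a dense LU solve, the TCG/k-step-CG identity, and
    the TCG2-vs-TCG1 accuracy ordering across a fixture suite."""
    import scipy.linalg

    from .polarization import (PolarizationModel, SolverSettings,
                               polarization_energy, solve_induced, solve_tcg)
    from .units import DEBYE_PER_EA

    system, params = gen_random_multipole_gas(30, edge=12.0, seed=seed)
    cfg = MDConfig(ewald_cutoff=5.5, bspline_order=6, pme_grid=(24, 24, 24))
    eng = Engine(system, params, cfg)
    _, _, _, _, _, alphas = eng._lab_multipoles(system.positions)
    model = PolarizationModel(system.positions, system.box, alphas,
                              eng.tholes, eng._pairs(system.positions),
                              eng.beta, recip=eng.grid)
    rng = np.random.default_rng(seed)
    E = rng.normal(size=(30, 3)) * 0.05
    T, idx = model.to_dense()
    mu_ref = np.zeros_like(E)
    mu_ref[idx] = scipy.linalg.lu_solve(scipy.linalg.lu_factor(T),
                                        E[idx].ravel()).reshape(-1, 3)
    out = {}
    for method in ("pcg", "jidiis"):
        st = solve_induced(model, E, SolverSettings(method=method,
                                                    tolerance=1e-10,
                                                    max_iterations=500))
        out[f"{method}_rms_debye"] = DEBYE_PER_EA * math.sqrt(
            float(np.mean((st.mu - mu_ref)[model.active] ** 2)))
    # TCG equals the k-step CG iterate
    diffs = []
    for order in (1, 2):
        st = solve_tcg(model, E, order=order)
        mu = np.zeros_like(E)
        r = E.copy()
        z = model.alphas[:, None] * r
        p = z.copy()
        rz = float(np.sum(r * z))
        for _ in range(order):
            qv = model.matvec(p)
            t = rz / float(np.sum(p * qv))
            mu = mu + t * p
            r = r - t * qv
            z = model.alphas[:, None] * r
            rz_new = float(np.sum(r * z))
            p = z + (rz_new / rz) * p
            rz = rz_new
        diffs.append(float(np.abs(st.mu - mu).max()))
    out["tcg_vs_kstep_cg_max"] = max(diffs)
    # ordering across 20 systems
    ok = 0
    for s in range(20):
        sys2, par2 = gen_random_multipole_gas(12, edge=10.0, seed=500 + s)
        e2 = Engine(sys2, par2, MDConfig(ewald_cutoff=4.5, bspline_order=5,
                                         pme_grid=(16, 16, 16)))
        _, _, _, _, _, al2 = e2._lab_multipoles(sys2.positions)
        m2 = PolarizationModel(sys2.positions, sys2.box, al2, e2.tholes,
                               e2._pairs(sys2.positions), e2.beta,
                               recip=e2.grid)
        rng2 = np.random.default_rng(s)
        E2 = rng2.normal(size=(12, 3)) * 0.03
        T2, idx2 = m2.to_dense()
        mu2 = np.zeros_like(E2)
        mu2[idx2] = np.linalg.solve(T2, E2[idx2].ravel()).reshape(-1, 3)
        ee = polarization_energy(m2, mu2, E2)
        e1 = polarization_energy(m2, solve_tcg(m2, E2, 1).mu, E2)
        e2v = polarization_energy(m2, solve_tcg(m2, E2, 2).mu, E2)
        if abs(e2v - ee) <= abs(e1 - ee) + 1e-12:
            ok += 1
    out["tcg2_better_fraction"] = ok / 20.0
    return out


def decomposition_audit(n_configs=100, seed=0):
    """Midpoint ownership covers every within-cutoff pair exactly once over
    random configurations and block grids 1³..4³; cell lists equal the O(N²)
    oracle.  Returns the violation count (0 = pass)."""
    from .decomposition import BlockGrid, midpoint_owners
    from .neighbors import NeighborList
    from .system import SimulationBox

    rng = np.random.default_rng(seed)
    violations = 0
    for cfg_i in range(n_configs):
        box = SimulationBox.cubic(12.0)
        pos = rng.uniform(0, 12, size=(64, 3))
        nl = NeighborList(pos, box, 4.0, skin=0.0)
        # oracle
        n = 64
        oracle = set()
        for i in range(n):
            dr = box.minimum_image(pos[i + 1:] - pos[i])
            d2 = np.einsum("ka,ka->k", dr, dr)
            for j in np.nonzero(d2 <= 16.0)[0]:
                oracle.add((i, i + 1 + int(j)))
        got = set(zip(nl.pairs[0].tolist(), nl.pairs[1].tolist()))
        if got != oracle:
            violations += 1
        nb = cfg_i % 4 + 1
        grid = BlockGrid(box, (nb, nb, nb))
        pi = np.array([p[0] for p in sorted(oracle)], dtype=np.int64)
        pj = np.array([p[1] for p in sorted(oracle)], dtype=np.int64)
        owners = midpoint_owners(grid, pos, (pi, pj))
        if len(owners) != len(oracle) or \
                np.any(owners < 0) or np.any(owners >= grid.n_blocks):
            violations += 1
    return violations


# ---------------------------------------------------------------------------
# conservation / dynamics benchmarks
# ---------------------------------------------------------------------------


def _equilibrated_water64(seed):
    from .dynamics import MDRunner, initialize_velocities

    system, params = gen_water_box(n_waters=64, seed=seed)
    cfg = MDConfig(polar_solver="pcg", polar_eps=1e-5, **WATER64_CONFIG)
    eng = Engine(system, params, cfg)
    runner = MDRunner(eng, dt=1.0, thermostat="bussi", temperature=298.0,
                      tau_t=50.0, use_aspc=True, seed=seed)
    v = initialize_velocities(system.masses, 298.0, seed=seed)
    st = runner.run(system.positions.copy(), v, 300)
    return system, params, st.positions, st.velocities


def nve_protocol(seed=7, n_steps=5000):
    """The 64-water conservation protocol: 5 ps NVE at 1 fs with TCG2 and
    with tightly converged PCG, plus the forward/backward reversibility run.

    Returns drifts in kcal/mol/atom/ps and the maximum position mismatch of
    the reversed trajectory in Å.
    """
    from .dynamics import MDRunner, energy_drift_rate, kinetic_energy

    system, params, pos0, vel0, = _equilibrated_water64(seed)
    out = {}
    for label, solver, eps, aspc in (("tcg2", "tcg2", 1e-5, False),
                                     ("pcg", "pcg", 1e-8, True)):
        cfg = MDConfig(polar_solver=solver, polar_eps=eps, polar_maxiter=300,
                       **WATER64_CONFIG)
        eng = Engine(system, params, cfg)
        runner = MDRunner(eng, dt=1.0, use_aspc=aspc)
        totals = []

        def grab(s):
            totals.append(s.potential
                          + kinetic_energy(system.masses, s.velocities))

        runner.run(pos0.copy(), vel0.copy(), n_steps, callback=grab)
        out[f"drift_{label}"] = energy_drift_rate(
            np.arange(len(totals)) / 1000.0, totals, system.n_sites)
    out["reversibility_max_A"] = reversibility_check(system, params, pos0,
                                                     vel0)
    return out


def reversibility_check(system, params, pos0, vel0, n_steps=100):
    """Integrate forward with TCG2, negate the velocities, integrate back;
    returns the maximum position deviation from the start (Å)."""
    from .dynamics import MDRunner

    cfg = MDConfig(polar_solver="tcg2", **WATER64_CONFIG)
    eng = Engine(system, params, cfg)
    # make the neighbour list a pure function of positions
    eng.nlist.skin = 0.0
    eng.nlist.rebuild(pos0)
    runner = MDRunner(eng, dt=1.0, use_aspc=False)
    st = runner.run(pos0.copy(), vel0.copy(), n_steps)
    st2 = runner.run(st.positions, -st.velocities, n_steps)
    return float(np.abs(st2.positions - pos0).max())


def aspc_benchmark(seed=11, n_waters=32, n_steps=1000):
    """Mean PCG iteration count (1e-5 D) along an NVE trajectory with the
    ASPC predictor guess versus a zero guess."""
    from .dynamics import MDRunner, initialize_velocities

    system, params = gen_water_box(n_waters=n_waters, seed=seed)
    means = {}
    for label in ("aspc", "zero"):
        cfg = MDConfig(polar_solver="pcg", polar_eps=1e-5,
                       polar_guess="zero", ewald_cutoff=4.5, vdw_cutoff=4.5,
                       bspline_order=5, pme_grid=(24, 24, 24))
        eng = Engine(system, params, cfg)
        runner = MDRunner(eng, dt=1.0, use_aspc=label == "aspc",
                          thermostat="bussi", temperature=298.0, tau_t=100.0,
                          seed=seed)
        v = initialize_velocities(system.masses, 298.0, seed=seed)
        iters = []
        runner.run(system.positions.copy(), v, n_steps,
                   callback=lambda s: iters.append(
                       s.info.get("polar_iterations", 0)))
        means[label] = float(np.mean(iters))
    return means


def thermostat_benchmark(seed=5, n_particles=200, temperature=300.0,
                         n_steps=10000, tau=10.0):
    """Bussi thermostat on a free-particle gas over 10 ps: time-mean
    temperature and a χ² goodness-of-fit p-value of the kinetic-energy
    distribution (samples decorrelated by several coupling times)."""
    from scipy import stats

    from .dynamics import initialize_velocities, kinetic_energy, \
        thermostat_step

    rng = np.random.default_rng(seed)
    masses = np.full(n_particles, 18.0)
    v = initialize_velocities(masses, temperature * 0.7, seed=seed)
    ndof = 3 * n_particles - 3
    kes = []
    for _ in range(n_steps):
        v = thermostat_step(v, masses, "bussi", temperature, tau, 1.0, ndof,
                            rng)
        kes.append(kinetic_energy(masses, v))
    kes = np.array(kes)
    t_mean = 2 * float(np.mean(kes[1000:])) / (ndof * BOLTZMANN)
    samples = kes[1000::50]               # ≥ 5 coupling times apart
    # canonical KE distribution: Gamma(ndof/2, kT)
    kT = BOLTZMANN * temperature
    nbins = 10
    edges = stats.gamma.ppf(np.linspace(0, 1, nbins + 1), a=ndof / 2,
                            scale=kT)
    edges[0], edges[-1] = 0.0, np.inf
    counts, _ = np.histogram(samples, bins=edges)
    expected = np.full(nbins, len(samples) / nbins)
    chi2, p = stats.chisquare(counts, expected)
    return {"mean_temperature": t_mean, "chi2_pvalue": float(p)}


def bar_benchmarks(seed=2, n=100_000):
    """Synthetic BAR recoveries: Crooks-consistent Gaussians (ΔG=1 kT, σ=2)
    and the harmonic-oscillator k:1→4 path (ΔG = ½ ln 4 kT)."""
    from .alchemy import bar_estimate_reduced

    rng = np.random.default_rng(seed)
    dg_true, sigma = 1.0, 2.0
    wf = rng.normal(dg_true + sigma**2 / 2, sigma, n)
    wr = rng.normal(-dg_true + sigma**2 / 2, sigma, n)
    dg_c, se_c = bar_estimate_reduced(wf, wr)
    xa = rng.normal(0, 1.0, n // 2)
    xb = rng.normal(0, 0.5, n // 2)
    wf2 = 0.5 * 4 * xa**2 - 0.5 * xa**2
    wr2 = 0.5 * xb**2 - 0.5 * 4 * xb**2
    dg_o, se_o = bar_estimate_reduced(wf2, wr2)
    return {"crooks_dg_kT": dg_c, "crooks_se_kT": se_c,
            "oscillator_dg_kT": dg_o, "oscillator_se_kT": se_o,
            "oscillator_exact_kT": 0.5 * math.log(4.0)}


def fixture_sizes():
    """Benchmark-box bookkeeping: atom count at the 98.5 Å preset and box
    edge for 6000 molecules."""
    big, _ = gen_water_box(edge=98.5, seed=0, jitter=0.0)
    small, _ = gen_water_box(n_waters=6000, seed=0, jitter=0.0)
    return {"atoms_at_98p5": big.n_sites, "edge_6000": float(small.box.a)}
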