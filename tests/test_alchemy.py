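"""BAR estimator recovery, standard-state correction, λ scaling and the
hydration-cycle bookkeeping."""

import math

import numpy as np
import pytest

from polarmd.alchemy import (LambdaSchedule, WorkSamples, bar_estimate,
                             bar_estimate_reduced, combine_cycle_legs,
                             standard_state_correction, zwanzig_reduced)
from polarmd.units import BOLTZMANN


class TestBAR:
    def test_symmetric_distributions_give_zero(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0.0, 1.0, 5000)
        dg, se = bar_estimate_reduced(w, w.copy())
        assert abs(dg) <= 3 * se
        assert se < 0.1

    def test_crooks_gaussian_recovery(self):
        # forward N(ΔG+σ²/2, σ²), reverse N(-ΔG+σ²/2, σ²) with ΔG=1, σ=2
        rng = np.random.default_rng(1)
        dg_true, sigma, n = 1.0, 2.0, 100_000
        wf = rng.normal(dg_true + sigma**2 / 2, sigma, n)
        wr = rng.normal(-dg_true + sigma**2 / 2, sigma, n)
        dg, se = bar_estimate_reduced(wf, wr)
        assert abs(dg - dg_true) <= 3 * se
        assert se < 0.02

    def test_crooks_unbiased_over_replicates(self):
        dg_true, sigma, n = 1.0, 2.0, 4000
        ests, ses = [], []
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            wf = rng.normal(dg_true + sigma**2 / 2, sigma, n)
            wr = rng.normal(-dg_true + sigma**2 / 2, sigma, n)
            dg, se = bar_estimate_reduced(wf, wr)
            ests.append(dg)
            ses.append(se)
        mean = np.mean(ests)
        sem = np.mean(ses) / math.sqrt(len(ests))
        assert abs(mean - dg_true) <= 3 * sem

    def test_harmonic_oscillator_lambda_path(self):
        # k: 1 → 4 at kT=1; ΔG = ½ ln 4
        rng = np.random.default_rng(2)
        n = 50_000
        xa = rng.normal(0, 1.0, n)                  # samples from k=1
        xb = rng.normal(0, 0.5, n)                  # samples from k=4
        u = lambda k, x: 0.5 * k * x * x
        wf = u(4, xa) - u(1, xa)
        wr = u(1, xb) - u(4, xb)
        dg, se = bar_estimate_reduced(wf, wr)
        assert abs(dg - 0.5 * math.log(4)) <= 3 * se
        assert se < 0.02

    def test_zwanzig_fallback_no_reverse(self):
        rng = np.random.default_rng(3)
        wf = rng.normal(0.5, 0.3, 20000)
        dg_bar, _ = bar_estimate_reduced(wf, np.array([]))
        dg_zw, _ = zwanzig_reduced(wf)
        assert dg_bar == dg_zw
        # closed form for Gaussian work: ΔG = μ - σ²/2
        assert dg_zw == pytest.approx(0.5 - 0.09 / 2, abs=0.02)

    def test_kcal_interface(self):
        rng = np.random.default_rng(4)
        T = 298.0
        kT = BOLTZMANN * T
        wf = rng.normal(1.2, 0.8, 20000)
        wr = rng.normal(-1.2 + 0.0, 0.8, 20000)
        samples = WorkSamples(wf, wr, T)
        dg, se = bar_estimate(samples)
        dg_red, se_red = bar_estimate_reduced(wf, wr)
        assert dg == pytest.approx(kT * dg_red, rel=1e-12)


class TestStandardState:
    def test_closed_form(self):
        val = standard_state_correction(298.15)
        rt = BOLTZMANN * 298.15
        assert val == pytest.approx(rt * math.log(24.465), abs=1e-3)
        # close to (but not exactly) the conventional printed 1.87 value
        assert 1.8 < val < 1.95

    def test_cancels_in_relative_free_energies(self):
        a = 5.0 + standard_state_correction(298.15)
        b = 3.0 + standard_state_correction(298.15)
        assert a - b == pytest.approx(2.0, abs=1e-12)

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            standard_state_correction(298.15, convention="weird")


class TestSchedules:
    def test_default_21_states(self):
        s = LambdaSchedule()
        assert len(s.ele) == 21 and len(s.vdw) == 21
        assert s.ele[0] == 0.0 and s.ele[-1] == 1.0

    def test_monotone_required(self):
        with pytest.raises(ValueError):
            LambdaSchedule(ele=np.array([0.0, 0.7, 0.5, 1.0]))

    def test_leg_combination_bookkeeping(self):
        assert combine_cycle_legs(1.5, -2.0, 0.25) == pytest.approx(-0.25)
        # permuting legs leaves the sum unchanged
        assert combine_cycle_legs(0.25, 1.5, -2.0) == pytest.approx(-0.25)


class TestScaledElectrostatics:
    def test_endpoint_identity_and_zero(self):
        from polarmd.alchemy import scaled_electrostatics
        q = np.array([0.3, -0.3])
        mu = np.random.default_rng(0).normal(size=(2, 3))
        Q = np.zeros((2, 3, 3))
        al = np.array([0.5, 0.9])
        q1, m1, Q1, a1 = scaled_electrostatics(q, mu, Q, al, 1.0)
        assert np.array_equal(q1, q) and np.array_equal(a1, al)
        q0, m0, Q0, a0 = scaled_electrostatics(q, mu, Q, al, 0.0)
        assert not np.any(q0) and not np.any(m0) and not np.any(a0)

    def test_solute_decoupled_at_lambda_zero(self):
        """λ_ele=0 removes the solute-water electrostatic + polarization
        cross energy entirely."""
        from polarmd.engine import AlchemicalState, Engine
        from polarmd.fixtures import gen_ion_in_water
        from polarmd.system import MDConfig

        system, params = gen_ion_in_water(n_waters=8, charge=1.0, seed=3)
        cfg = MDConfig(polar_solver="pcg", polar_eps=1e-7,
                       ewald_cutoff=3.0, vdw_cutoff=3.0, bspline_order=5,
                       pme_grid=(16, 16, 16))
        sol = frozenset([0])
        e_off = Engine(system, params, cfg,
                       alchemy=AlchemicalState(lambda_ele=0.0, solute=sol))
        out_off = e_off.evaluate(system.positions, compute_forces=False)
        # the same system with the ion's multipole record removed
        params2 = params
        import copy
        params2 = copy.deepcopy(params)
        params2.multipoles[9].charge = 0.0
        e_none = Engine(system, params2, cfg)
        out_none = e_none.evaluate(system.positions, compute_forces=False)
        for k in ("real", "recip", "self", "polarization"):
            assert out_off["components"][k] == pytest.approx(
                out_none["components"][k], abs=1e-8)

    def test_energy_quadratic_or_lower_in_lambda(self):
        """On a frozen configuration the permanent electrostatic energy is
        at most quadratic in λ_ele (3-point parabola reproduces a 4th)."""
        from polarmd.engine import AlchemicalState, Engine
        from polarmd.fixtures import gen_ion_in_water
        from polarmd.system import MDConfig

        system, params = gen_ion_in_water(n_waters=8, charge=1.0, seed=3)
        params.polarize = {}              # permanent terms only
        cfg = MDConfig(ewald_cutoff=3.0, vdw_cutoff=3.0, bspline_order=5,
                       pme_grid=(16, 16, 16))
        sol = frozenset([0])

        def elec(lam):
            eng = Engine(system, params, cfg,
                         alchemy=AlchemicalState(lambda_ele=lam, solute=sol))
            c = eng.evaluate(system.positions,
                             compute_forces=False)["components"]
            return c["real"] + c["recip"] + c["self"] + c.get("background", 0)

        e = {lam: elec(lam) for lam in (0.0, 0.5, 1.0, 0.25)}
        # fit parabola through 0, 0.5, 1 and check 0.25
        a = 2 * e[1.0] - 4 * e[0.5] + 2 * e[0.0]
        b = -e[1.0] + 4 * e[0.5] - 3 * e[0.0]
        c = e[0.0]
        pred = a * 0.25**2 + b * 0.25 + c
        assert pred == pytest.approx(e[0.25], abs=1e-6)


def test_hydration_cycle_driver_runs_and_reports():
    """Three-leg driver on a tiny box with a neutral LJ particle: finite
    per-leg table, signed total, and the ion correction reported separately
    when requested."""
    import numpy as np

    from polarmd.alchemy import LambdaSchedule, hydration_cycle
    from polarmd.fixtures import gen_ion_in_water
    from polarmd.system import (MDConfig, ParticleSystem, SimulationBox)

    system, params = gen_ion_in_water(n_waters=8, charge=0.0, epsilon=0.05,
                                      seed=4)
    vac = ParticleSystem(np.zeros((1, 3)), [22.99], [9], [9],
                         np.zeros((0, 2)), SimulationBox.open_boundary())
    cfg = MDConfig(polar_solver="pcg", polar_eps=1e-4, ewald_cutoff=3.0,
                   vdw_cutoff=3.0, bspline_order=5, pme_grid=(16, 16, 16),
                   dt=1.0, polar_maxiter=200)
    sched = LambdaSchedule(ele=np.array([0.0, 0.5, 1.0]),
                           vdw=np.array([0.0, 0.5, 1.0]))
    out = hydration_cycle(system, params, cfg, [0], vacuum_system=vac,
                          schedule=sched, n_equil=3, n_sample=9,
                          sample_stride=3, seed=2, ion_charge=1.0)
    assert set(out["legs"]) == {"discharge_vacuum", "couple_vdw",
                                "recharge_solvent"}
    total, se = out["total"]
    assert np.isfinite(total) and np.isfinite(se)
    # uncharged solute: both electrostatic legs are exactly zero
    assert abs(out["legs"]["discharge_vacuum"][0]) < 1e-8
    assert abs(out["legs"]["recharge_solvent"][0]) < 1e-8
    assert out["total_corrected"][0] == total + out[
        "standard_state_correction"]


def test_trivial_solute_cycle_is_zero():
    """A solute with no charge and no vdW couples to nothing: every sampled
    work value is identically zero and all legs give ΔG = 0."""
    from polarmd.alchemy import sample_and_cross_evaluate, leg_free_energy
    from polarmd.fixtures import gen_ion_in_water
    from polarmd.system import MDConfig

    system, params = gen_ion_in_water(n_waters=8, charge=0.0, epsilon=0.0,
                                      seed=6)
    cfg = MDConfig(polar_solver="pcg", polar_eps=1e-5, ewald_cutoff=3.0,
                   vdw_cutoff=3.0, bspline_order=5, pme_grid=(16, 16, 16),
                   dt=1.0)
    samples = sample_and_cross_evaluate(
        system, params, cfg, [0], "vdw", [0.0, 0.5, 1.0],
        n_equil=5, n_sample=10, sample_stride=5, temperature=298.0, seed=1)
    dg, se = leg_free_energy(samples, 298.0)
    assert abs(dg) < 1e-8
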