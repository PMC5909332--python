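"""Alchemical free energies: λ schedules, the Bennett acceptance ratio
estimator, the 1 M ↔ 1 atm standard-state correction, and the three-leg
hydration-cycle driver (solute discharging in vacuum, vdW coupling in
solvent, recharging in solvent).

Internally all work values are reduced (u = E/kT); conversions happen at the
interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .engine import AlchemicalState, Engine
from .units import BOLTZMANN, GAS_CONSTANT


class BAREstimationError(RuntimeError):
    pass


@dataclass
class WorkSamples:
    """Bidirectional reduced energy differences for one state pair.

    forward: u_j(x) - u_i(x) over samples from state i;
    reverse: u_i(x) - u_j(x) over samples from state j.
    """
    forward: np.ndarray
    reverse: np.ndarray
    temperature: float = 298.0

    def __post_init__(self):
        self.forward = np.asarray(self.forward, dtype=float)
        self.reverse = np.asarray(self.reverse, dtype=float)
        if not (np.all(np.isfinite(self.forward))
                and np.all(np.isfinite(self.reverse))):
            raise BAREstimationError("non-finite work samples")


@dataclass
class LambdaSchedule:
    """Ordered λ values per coupling channel; default 21 evenly spaced."""
    ele: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 21))
    vdw: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 21))

    def __post_init__(self):
        for lam in (self.ele, self.vdw):
            lam = np.asarray(lam)
            if lam[0] != 0.0 or lam[-1] != 1.0 or np.any(np.diff(lam) <= 0):
                raise ValueError("schedule must run strictly from 0 to 1")


def _fermi(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def bar_estimate_reduced(w_forward, w_reverse, tol=1e-10):
    """Self-consistent BAR solution in reduced units.

    Returns (ΔG/kT, SE/kT).  With no reverse samples, falls back to the
    exponential-averaging (Zwanzig) estimate.
    """
    wF = np.asarray(w_forward, dtype=float)
    wR = np.asarray(w_reverse, dtype=float)
    nF, nR = len(wF), len(wR)
    if nF == 0 and nR == 0:
        raise BAREstimationError("no work samples")
    if nR == 0:
        return zwanzig_reduced(wF)
    if nF == 0:
        dg, se = zwanzig_reduced(wR)
        return -dg, se
    M = math.log(nF / nR)

    def g(dg):
        return (float(np.sum(_fermi(M + wF - dg)))
                - float(np.sum(_fermi(-M + wR + dg))))

    lo = min(wF.min(), -wR.max()) - 50.0
    hi = max(wF.max(), -wR.min()) + 50.0
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise BAREstimationError("BAR equation not bracketable")
    dg = brentq(g, lo, hi, xtol=tol)
    # Newton polish
    for _ in range(3):
        fF = _fermi(M + wF - dg)
        fR = _fermi(-M + wR + dg)
        num = float(np.sum(fF) - np.sum(fR))
        den = float(np.sum(fF * (1 - fF)) + np.sum(fR * (1 - fR)))
        if den <= 0:
            break
        dg -= num / den

    # Bennett asymptotic variance
    fF = _fermi(M + wF - dg)
    fR = _fermi(-M + wR + dg)
    mF, mR = np.mean(fF), np.mean(fR)
    if mF <= 0 or mR <= 0:
        return dg, math.inf
    var = ((np.mean(fF**2) / mF**2 - 1.0) / nF
           + (np.mean(fR**2) / mR**2 - 1.0) / nR)
    overlap_warn = var > 4.0
    se = math.sqrt(max(var, 0.0))
    if overlap_warn:
        import warnings
        warnings.warn("poor forward/reverse overlap; BAR error bar is wide")
    return dg, se


def zwanzig_reduced(w):
    """Exponential averaging ΔG/kT = -ln⟨exp(-w)⟩ with jackknife-free SE."""
    w = np.asarray(w, dtype=float)
    wmin = w.min()
    ex = np.exp(-(w - wmin))
    dg = wmin - math.log(float(np.mean(ex)))
    se = float(np.std(ex) / (math.sqrt(len(w)) * np.mean(ex)))
    return dg, se


def bar_estimate(samples: WorkSamples):
    """BAR in kcal/mol: (ΔG, statistical error)."""
    kT = BOLTZMANN * samples.temperature
    dg, se = bar_estimate_reduced(samples.forward, samples.reverse)
    return kT * dg, kT * se


def standard_state_correction(temperature=298.15, convention="1M-1atm"):
    """RT·ln(V_molar/1 L·mol⁻¹) for moving between the 1 mol/L simulation
    standard state and the 1 atm gas standard state."""
    if convention != "1M-1atm":
        raise ValueError(f"unknown standard-state convention '{convention}'")
    # ideal-gas molar volume in litres at (T, 1 atm)
    v_molar = 0.0820573660809596 * temperature
    return GAS_CONSTANT * temperature * math.log(v_molar)


def scaled_electrostatics(q, mu, Q, alphas, lam):
    """Linear λ scaling of permanent multipoles and polarizabilities."""
    return lam * np.asarray(q), lam * np.asarray(mu), lam * np.asarray(Q), \
        lam * np.asarray(alphas)


# ---------------------------------------------------------------------------
# cycle driver
# ---------------------------------------------------------------------------


def sample_and_cross_evaluate(system, params, config, solute, channel,
                              lambdas, n_equil, n_sample, sample_stride,
                              temperature, seed, base_state=None):
    """MD sampling at every λ state of one leg plus cross-state energies.

    Returns a list of WorkSamples for the adjacent state pairs.  ``channel``
    is 'ele' or 'vdw'; ``base_state`` fixes the other channel's λ.
    """
    from .dynamics import MDRunner, initialize_velocities

    base = base_state or AlchemicalState(solute=frozenset(solute))
    kT = BOLTZMANN * temperature

    def make_state(lam):
        if channel == "ele":
            return AlchemicalState(lambda_vdw=base.lambda_vdw,
                                   lambda_ele=lam, solute=frozenset(solute))
        return AlchemicalState(lambda_vdw=lam, lambda_ele=base.lambda_ele,
                               solute=frozenset(solute))

    engines = {}

    def engine_at(lam):
        if lam not in engines:
            engines[lam] = Engine(system.copy(), params, config,
                                  alchemy=make_state(lam))
        return engines[lam]

    frames = {lam: [] for lam in lambdas}
    for si, lam in enumerate(lambdas):
        eng = engine_at(lam)
        runner = MDRunner(eng, dt=config.dt, thermostat="bussi",
                          temperature=temperature, tau_t=50.0,
                          use_aspc=True, seed=seed + 101 * si)
        v = initialize_velocities(system.masses, temperature,
                                  seed=seed + 7 * si)
        st = runner.run(system.positions.copy(), v, n_equil)
        collected = 0

        def grab(state, lam=lam):
            nonlocal collected
            if state.step % sample_stride == 0:
                frames[lam].append(state.positions.copy())
                collected += 1

        runner.run(st.positions, st.velocities, n_sample, callback=grab)

    out = []
    for a, b in zip(lambdas[:-1], lambdas[1:]):
        eng_a, eng_b = engine_at(a), engine_at(b)
        wf = [(eng_b.energy(x) - eng_a.energy(x)) / kT for x in frames[a]]
        wr = [(eng_a.energy(x) - eng_b.energy(x)) / kT for x in frames[b]]
        out.append(WorkSamples(np.array(wf), np.array(wr), temperature))
    return out


def leg_free_energy(samples_list, temperature):
    """Chain BAR over adjacent pairs; returns (ΔG, SE) in kcal/mol."""
    total, var = 0.0, 0.0
    for s in samples_list:
        dg, se = bar_estimate(s)
        total += dg
        var += se * se
    return total, math.sqrt(var)


def combine_cycle_legs(dg_discharge, dg_couple, dg_recharge):
    """Hydration total as the signed sum of the three legs (the leg values
    are already directed: vacuum discharging, solvent vdW coupling, solvent
    recharging)."""
    return dg_discharge + dg_couple + dg_recharge


def hydration_cycle(solvated_system, params, config, solute,
                    vacuum_system=None, schedule: LambdaSchedule | None = None,
                    temperature=298.0, n_equil=50, n_sample=200,
                    sample_stride=10, seed=0, ion_charge=0.0):
    """Three-step hydration cycle at desk scale.

    Returns a dict with the per-leg ΔG table, the signed total, and (for
    ions) the standard-state correction reported separately.
    """
    schedule = schedule or LambdaSchedule()
    legs = {}

    if vacuum_system is not None:
        # leg 1: discharge the solute in vacuum (λ_ele 1 -> 0); sampled as
        # the 0 -> 1 charging leg and negated
        samples = sample_and_cross_evaluate(
            vacuum_system, params, config_vacuum(config), range(
                vacuum_system.n_sites), "ele", list(schedule.ele),
            n_equil, n_sample, sample_stride, temperature, seed)
        dg_chg, se1 = leg_free_energy(samples, temperature)
        legs["discharge_vacuum"] = (-dg_chg, se1)
    else:
        legs["discharge_vacuum"] = (0.0, 0.0)

    samples = sample_and_cross_evaluate(
        solvated_system, params, config, solute, "vdw", list(schedule.vdw),
        n_equil, n_sample, sample_stride, temperature, seed + 1,
        base_state=AlchemicalState(lambda_ele=0.0, solute=frozenset(solute)))
    legs["couple_vdw"] = leg_free_energy(samples, temperature)

    samples = sample_and_cross_evaluate(
        solvated_system, params, config, solute, "ele", list(schedule.ele),
        n_equil, n_sample, sample_stride, temperature, seed + 2)
    legs["recharge_solvent"] = leg_free_energy(samples, temperature)

    total = combine_cycle_legs(legs["discharge_vacuum"][0],
                               legs["couple_vdw"][0],
                               legs["recharge_solvent"][0])
    se = math.sqrt(sum(v[1] ** 2 for v in legs.values()))
    out = {"legs": legs, "total": (total, se)}
    if abs(ion_charge) > 0:
        corr = standard_state_correction(temperature)
        out["standard_state_correction"] = corr
        out["total_corrected"] = (total + corr, se)
    return out


def config_vacuum(config):
    from dataclasses import replace
    return replace(config, pme_grid=None)
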