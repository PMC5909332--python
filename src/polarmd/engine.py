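"""Force-field engine: orchestrates every energy term for one system.

Evaluation order per configuration (mirroring a single force computation of
the decomposed MD step): neighbour list update, local→lab multipole rotation,
real-space permanent electrostatics, reciprocal SPME, Ewald self/background
terms, permanent-field assembly and induced-dipole solution, polarization
forces (variational or TCG-adjoint), van der Waals, bonded terms, restraints,
and finally the frame-anchor forces that account for the orientation
dependence of the permanent multipoles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import electrostatics as el
from .bonded import BondedTerms
from .frames import build_frames, frame_forces, rotate_multipoles
from .masking import MaskingTable
from .neighbors import NeighborList
from .polarization import (ASPCHistory, PolarizationModel, SolverSettings,
                           converged_gradient_terms, polarization_energy,
                           solve_induced, solve_tcg, tcg_gradient_terms)
from .spme import PMEGrid
from .system import ConfigurationError, MDConfig
from .units import COULOMB
from .vdw import combine_buffered, combine_lj, vdw_energy_forces

#: kcal·mol⁻¹·Å⁻³ → atm
PRESSURE_ATM = 68568.4


@dataclass
class AlchemicalState:
    """Coupling of a solute subset: linear electrostatic scaling and
    softcore vdW; λ=1 endpoints reproduce the unmodified potentials."""
    lambda_vdw: float = 1.0
    lambda_ele: float = 1.0
    solute: frozenset = field(default_factory=frozenset)

    def validate(self):
        for lam in (self.lambda_vdw, self.lambda_ele):
            if not 0.0 <= lam <= 1.0:
                raise ConfigurationError("lambda outside [0, 1]")


class Engine:
    def __init__(self, system, params, config: MDConfig | None = None,
                 alchemy: AlchemicalState | None = None, restraint_set=None):
        system.validate()
        params.validate()
        self.system = system
        self.params = params
        self.config = config or MDConfig()
        self.alchemy = alchemy
        self.restraints = restraint_set
        box = system.box
        n = system.n_sites

        # per-site parameter arrays
        self.q_loc = np.zeros(n)
        self.mu_loc = np.zeros((n, 3))
        self.Q_loc = np.zeros((n, 3, 3))
        self.alphas = np.zeros(n)
        self.tholes = np.zeros(n)
        for i, t in enumerate(system.atom_types):
            rec = params.multipoles.get(int(t))
            if rec is not None:
                self.q_loc[i] = rec.charge
                self.mu_loc[i] = rec.dipole
                self.Q_loc[i] = rec.quadrupole
            pol = params.polarize.get(int(t))
            if pol is not None:
                self.alphas[i] = pol.alpha
                self.tholes[i] = pol.thole
        self.has_mpoles = bool(np.any(self.q_loc) or np.any(self.mu_loc)
                               or np.any(self.Q_loc))
        self.has_polarization = bool(np.any(self.alphas))
        self.frames = build_frames(system, params)

        self.vdw_rmin = np.zeros(n)
        self.vdw_eps = np.zeros(n)
        self.vdw_lj = np.zeros(n, dtype=bool)
        for i, c in enumerate(system.atom_classes):
            rec = params.vdw.get(int(c))
            if rec is not None:
                self.vdw_rmin[i] = rec.r_min
                self.vdw_eps[i] = rec.epsilon
                self.vdw_lj[i] = rec.form == "lj"
        self.has_vdw = bool(np.any(self.vdw_eps))

        self.mask_mpole = MaskingTable(n, system.bonds, params.mpole_scales)
        self.mask_vdw = MaskingTable(n, system.bonds, params.vdw_scales)
        self.bonded = BondedTerms(system, params)

        if box.periodic:
            self.beta = self.config.resolved_beta()
            rc = self.config.ewald_cutoff
            rv = self.config.vdw_cutoff if self.has_vdw else 0.0
            box.check_cutoff(rc)
            if self.has_vdw:
                box.check_cutoff(rv)
            rmax = max(rc, rv)
            skin = min(self.config.neighbor_skin,
                       box.min_edge / 2.0 - rmax)
            if skin <= 0:
                raise ConfigurationError(
                    "no room for a neighbour-list skin; reduce the cutoffs")
            self.nlist = NeighborList(system.positions, box, rmax, skin)
            self.grid = PMEGrid(
                box, self.beta, dims=self.config.pme_grid,
                order=self.config.bspline_order,
                has_quadrupoles=bool(np.any(self.Q_loc))) \
                if self.has_mpoles or self.has_polarization else None
        else:
            self.beta = 0.0
            self.nlist = None
            self.grid = None

        self._scale_cache = None
        self.aspc = ASPCHistory(self.config.aspc_order)

    # ------------------------------------------------------------------
    def _pairs(self, positions):
        if self.nlist is not None:
            self.nlist.update(positions)
            return self.nlist.pairs
        n = self.system.n_sites
        ii, jj = np.triu_indices(n, k=1)
        return ii.astype(np.int64), jj.astype(np.int64)

    def _pair_scales(self, pairs):
        key = (id(pairs[0]), len(pairs[0]))
        if self._scale_cache is None or self._scale_cache[0] != key:
            s_el = self.mask_mpole.scale_array(pairs[0], pairs[1])
            s_vdw = self.mask_vdw.scale_array(pairs[0], pairs[1])
            self._scale_cache = (key, s_el, s_vdw)
        return self._scale_cache[1], self._scale_cache[2]

    def _lab_multipoles(self, positions):
        q_loc = self.q_loc
        mu_loc = self.mu_loc
        Q_loc = self.Q_loc
        alphas = self.alphas
        if self.alchemy is not None and self.alchemy.lambda_ele != 1.0:
            lam = self.alchemy.lambda_ele
            sol = np.array([i in self.alchemy.solute
                            for i in range(self.system.n_sites)])
            fac = np.where(sol, lam, 1.0)
            q_loc = q_loc * fac
            mu_loc = mu_loc * fac[:, None]
            Q_loc = Q_loc * fac[:, None, None]
            alphas = alphas * fac
        q, mu, Q, _ = rotate_multipoles(positions, self.system.box,
                                        self.frames, q_loc, mu_loc, Q_loc)
        return q, mu, Q, mu_loc, Q_loc, alphas

    # ------------------------------------------------------------------
    def evaluate(self, positions, compute_forces=True, solver=None,
                 guess=None, use_aspc=False):
        """Full energy/force evaluation; returns a component dict."""
        box = self.system.box
        n = self.system.n_sites
        comp = {}
        forces = np.zeros((n, 3))
        dUdmu = np.zeros((n, 3))
        dUdQ = np.zeros((n, 3, 3))
        pairs = self._pairs(positions)
        s_el, s_vdw = self._pair_scales(pairs)
        q, mu, Q, mu_loc_eff, Q_loc_eff, alphas = self._lab_multipoles(positions)
        state = None

        if self.has_mpoles:
            real = el.real_space_permanent(positions, box, pairs, q, mu, Q,
                                           self.beta, s_el, compute_forces)
            comp["real"] = real["energy"]
            if compute_forces:
                forces += real["forces"]
            dUdmu += real["dUdmu"]
            dUdQ += real["dUdQ"]

            if box.periodic:
                phig, _ = self.grid.potential_grid(positions, q, mu, Q)
                rec = self.grid.site_energy_forces(
                    phig, positions, q, mu, Q, compute_forces=compute_forces)
                comp["recip"] = rec["energy"]
                if compute_forces:
                    forces += rec["forces"]
                dUdmu += rec["dUdmu"]
                dUdQ += rec["dUdQ"]
                comp["self"] = el.self_energy(q, mu, Q, self.beta)
                dm, dQ = el.self_moment_derivatives(mu, Q, self.beta)
                dUdmu += dm
                dUdQ += dQ
                comp["background"] = el.background_correction(
                    q, self.beta, box.volume)
                recip_field = rec["field"]
            else:
                recip_field = None

        if self.has_polarization:
            model = PolarizationModel(
                positions, box, alphas, self.tholes, pairs, self.beta,
                recip=self.grid, mask_scales=s_el)
            E_raw = np.zeros((n, 3))
            if self.has_mpoles:
                fr = np.zeros((n, 3))
                if len(pairs[0]):
                    el.perm_field_kernel(model.pi, model.pj, model.dr,
                                         model.cl_perm, q, mu, Q, fr)
                E_raw += fr
                if recip_field is not None:
                    E_raw += recip_field / COULOMB
                if model.c_self:
                    E_raw += model.c_self * mu
            settings = self._solver_settings(solver)
            mu_guess = guess
            if mu_guess is None:
                if use_aspc and len(self.aspc):
                    mu_guess = self.aspc.predict()
                elif self.config.polar_guess == "direct":
                    mu_guess = model.direct_guess(E_raw)
            is_tcg = settings.method.startswith("tcg")
            if is_tcg:
                state = solve_tcg(model, E_raw, order=int(settings.method[-1]),
                                  peek=settings.tcg_peek,
                                  omega=settings.tcg_omega,
                                  precond=settings.preconditioner == "diagonal")
            else:
                state = solve_induced(model, E_raw, settings, mu_guess)
            if use_aspc:
                self.aspc.push(state.mu, mu_guess)
            comp["polarization"] = polarization_energy(
                model, state.mu, E_raw, state.aux.get("Tmu"))
            if compute_forces:
                if is_tcg:
                    pairs_T, gE = tcg_gradient_terms(model, state)
                else:
                    pairs_T, gE = converged_gradient_terms(state)
                grad_pol = np.zeros((n, 3))
                model.contraction_gradient(pairs_T, grad_pol)
                model.recip_pair_gradient(pairs_T, grad_pol)
                if self.has_mpoles:
                    cross = el.dipole_permanent_cross_real(
                        model.dr, model.cl_perm, model.pi, model.pj,
                        gE, q, mu, Q, n)
                    # k_C gE·E_real = -U_cross  →  ∇E_pol term = -∇U_cross,
                    # which is exactly the cross "force" array
                    grad_pol += cross["forces"]
                    dUdmu -= cross["dUdmu"]
                    dUdQ -= cross["dUdQ"]
                    if box.periodic and self.grid is not None:
                        xr = model.dipole_recip_cross(gE, q, mu, Q)
                        grad_pol += xr["forces"]
                        dUdmu -= xr["dUdmu_probe"]
                        dUdQ -= xr["dUdQ_probe"]
                    if model.c_self:
                        dUdmu += COULOMB * model.c_self * gE
                forces -= grad_pol

        if self.has_vdw:
            e, f, dl = self._vdw(positions, pairs, s_vdw)
            comp["vdw"] = e
            comp["dvdw_dlambda"] = dl
            if compute_forces:
                forces += f

        bt = self.bonded.energy_forces(positions, box)
        for kk in ("bond", "angle", "torsion"):
            if bt[kk]:
                comp[kk] = bt[kk]
        if compute_forces:
            forces += bt["forces"]

        if self.restraints is not None:
            e, f = self.restraints.energy_forces(positions, box,
                                                 self.system.masses)
            comp["restraint"] = e
            if compute_forces:
                forces += f

        if compute_forces and (self.has_mpoles or self.has_polarization):
            forces += frame_forces(positions, box, self.frames,
                                   mu_loc_eff, Q_loc_eff, dUdmu, dUdQ)

        total = sum(v for k, v in comp.items() if k != "dvdw_dlambda")
        out = {"components": comp, "potential": total,
               "forces": forces if compute_forces else None,
               "dipoles": state}
        return out

    def _solver_settings(self, solver=None):
        cfg = self.config
        s = SolverSettings(
            method=solver or cfg.polar_solver,
            tolerance=cfg.polar_eps,
            max_iterations=cfg.polar_maxiter,
            preconditioner=cfg.preconditioner,
            tcg_peek=cfg.tcg_peek)
        return s

    def _vdw(self, positions, pairs, s_vdw):
        pi, pj = pairs
        box = self.system.box
        dr = box.minimum_image(positions[pi] - positions[pj])
        r2 = np.einsum("ka,ka->k", dr, dr)
        cut = self.config.vdw_cutoff if box.periodic else math.inf
        keep = (r2 <= cut * cut) & ((self.vdw_eps[pi] * self.vdw_eps[pj]) > 0)
        pi, pj, sc = pi[keep], pj[keep], s_vdw[keep]
        lj = self.vdw_lj[pi] | self.vdw_lj[pj]
        rmin = np.empty(len(pi))
        eps = np.empty(len(pi))
        if np.any(~lj):
            rmin[~lj], eps[~lj] = combine_buffered(
                self.vdw_rmin[pi[~lj]], self.vdw_eps[pi[~lj]],
                self.vdw_rmin[pj[~lj]], self.vdw_eps[pj[~lj]])
        if np.any(lj):
            rmin[lj], eps[lj] = combine_lj(
                self.vdw_rmin[pi[lj]], self.vdw_eps[pi[lj]],
                self.vdw_rmin[pj[lj]], self.vdw_eps[pj[lj]])
        softcore_mask = None
        lam = 1.0
        if self.alchemy is not None:
            sol = self.alchemy.solute
            in_i = np.array([a in sol for a in pi], dtype=bool)
            in_j = np.array([a in sol for a in pj], dtype=bool)
            softcore_mask = in_i ^ in_j
            lam = self.alchemy.lambda_vdw
        return vdw_energy_forces(positions, box, (pi, pj), rmin, eps, lj,
                                 sc, softcore_mask, lam,
                                 cutoff=cut if box.periodic else None)

    # ------------------------------------------------------------------
    def energy(self, positions, solver=None):
        return self.evaluate(positions, compute_forces=False,
                             solver=solver)["potential"]

    def instantaneous_pressure(self, positions, kinetic_energy,
                               d_eps=5e-4):
        """Pressure (atm) from kinetic term plus a central-difference volume
        derivative of the potential under isotropic strain."""
        box = self.system.box
        if not box.periodic:
            raise ConfigurationError("pressure needs a periodic box")
        V = box.volume
        es = []
        for s in (1.0 + d_eps, 1.0 - d_eps):
            sys2 = self.system.copy()
            sys2.box.a *= s
            sys2.box.b *= s
            sys2.box.c *= s
            sys2.positions = positions * s
            eng = Engine(sys2, self.params, self.config, self.alchemy,
                         self.restraints)
            es.append(eng.energy(sys2.positions))
        dV = V * ((1 + d_eps) ** 3 - (1 - d_eps) ** 3)
        dUdV = (es[0] - es[1]) / dV
        return PRESSURE_ATM * (2.0 * kinetic_energy / (3.0 * V) - dUdV)
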