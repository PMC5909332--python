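"""Induced-dipole polarization: the T-operator, iterative solvers (JOR, PCG,
JI/DIIS), the truncated conjugate gradient (TCG1/TCG2) with exact adjoint
gradient information, and the ASPC predictor.

The linear system T μ = E is solved in raw electrostatic units (fields in
e/Å², dipoles in e·Å); T v = v/α − F(v) where F(v) is the Thole-damped Ewald
field of the dipole set v (real pairs + reciprocal mesh + self term).  The
polarization energy is the quadratic functional
E_pol = k_C (½ μ·Tμ − μ·E), valid for truncated dipoles as well; at exact
convergence it reduces to -½ k_C μ·E.

Convergence metric: RMS over the active 3N dipole components of the change
in μ per iteration, expressed in debye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .electrostatics import (damped_multipliers, dipole_contraction_kernel,
                             dipole_field_kernel, effective_coefficients,
                             self_field_coefficient)
from .units import COULOMB, DEBYE_PER_EA


class ConvergenceError(RuntimeError):
    """Iterative dipole solver failed to reach the requested tolerance."""


@dataclass
class SolverSettings:
    method: str = "pcg"             # jor | pcg | jidiis | tcg1 | tcg2
    tolerance: float = 1e-5         # debye (RMS change per iteration)
    max_iterations: int = 100
    preconditioner: str = "diagonal"
    jor_omega: float = 0.7
    diis_window: int = 6
    tcg_peek: bool = False
    tcg_omega: float = 1.0


@dataclass
class DipoleState:
    mu: np.ndarray
    iterations: int
    residual_D: float
    converged: bool
    method: str
    aux: dict = field(default_factory=dict)


class PolarizationModel:
    """Geometry-bound polarization operator for one configuration."""

    def __init__(self, positions, box, alphas, tholes, pairs, beta,
                 recip=None, mask_scales=None):
        self.positions = positions
        self.box = box
        self.alphas = np.asarray(alphas, dtype=float)
        self.tholes = np.asarray(tholes, dtype=float)
        self.beta = float(beta)
        self.recip = recip
        self.active = self.alphas > 0
        self.n = positions.shape[0]
        pi, pj = pairs
        self.pi = np.ascontiguousarray(pi, dtype=np.int64)
        self.pj = np.ascontiguousarray(pj, dtype=np.int64)
        dr = box.minimum_image(positions[self.pi] - positions[self.pj])
        self.dr = np.ascontiguousarray(dr)
        r = np.sqrt(np.sum(dr * dr, axis=1))
        self.r = r
        a_pair = np.minimum(self.tholes[self.pi], self.tholes[self.pj])
        # induced-induced interactions: Thole-damped, unmasked
        m_dd = damped_multipliers(r, self.alphas[self.pi],
                                  self.alphas[self.pj], a_pair)
        cl = effective_coefficients(r, beta, m_dd)
        self.c1 = np.ascontiguousarray(cl[:, 1])
        self.c2 = np.ascontiguousarray(cl[:, 2])
        self.c3 = np.ascontiguousarray(cl[:, 3])
        # permanent-field kernels: Thole-damped and masked
        if mask_scales is None:
            mask_scales = np.ones(len(r))
        m_pf = damped_multipliers(r, self.alphas[self.pi],
                                  self.alphas[self.pj], a_pair,
                                  scale=mask_scales)
        self.cl_perm = np.ascontiguousarray(
            effective_coefficients(r, beta, m_pf))
        self.c_self = (self_field_coefficient(beta) / COULOMB
                       if (box.periodic and beta > 0) else 0.0)
        inv = np.zeros(self.n)
        inv[self.active] = 1.0 / self.alphas[self.active]
        self._alpha_inv = inv

    # ------------------------------------------------------------------
    def field_from_dipoles(self, mu):
        """Raw (e/Å²) field of a dipole set at every site."""
        f = np.zeros((self.n, 3))
        if len(self.pi):
            dipole_field_kernel(self.pi, self.pj, self.dr,
                                self.c1, self.c2,
                                np.ascontiguousarray(mu), f)
        if self.recip is not None:
            grid = self.recip.spread(self.positions, np.zeros(self.n), mu, None)
            phig, _ = self.recip.convolve(grid)
            _, gphi, _, _ = self.recip.interpolate(phig, self.positions, 1)
            f -= gphi / COULOMB
        if self.c_self:
            f += self.c_self * mu
        return f

    def matvec(self, mu):
        """T μ (raw units); zero rows on non-polarizable sites."""
        out = self._alpha_inv[:, None] * mu - self.field_from_dipoles(mu)
        out[~self.active] = 0.0
        return out

    def precondition(self, v, kind="diagonal"):
        if kind == "diagonal":
            return self.alphas[:, None] * v
        return v.copy()

    def to_dense(self):
        """Dense T over active degrees of freedom (small systems only)."""
        idx = np.nonzero(self.active)[0]
        na = len(idx)
        T = np.zeros((3 * na, 3 * na))
        for k in range(3 * na):
            v = np.zeros((self.n, 3))
            v[idx[k // 3], k % 3] = 1.0
            T[:, k] = self.matvec(v)[idx].ravel()
        return T, idx

    def direct_guess(self, E):
        mu = self.alphas[:, None] * E
        mu[~self.active] = 0.0
        return mu

    # ------------------------------------------------------------------
    def contraction_gradient(self, pairs_T, positions_grad, engine_cross=None):
        """Accumulate k_C · Σ_w w·∇(u·T·v) into ``positions_grad``.

        Only the geometric (𝒯) part depends on positions: ∇(u·T·v) =
        -∇(u·𝒯·v).  The real-space part is handled here; the caller adds the
        reciprocal mesh part through ``recip_pair_gradient``.
        """
        if not len(self.pi) or not pairs_T:
            return
        nsets = len(pairs_T)
        U = np.ascontiguousarray(
            np.stack([w * u for (u, v, w) in pairs_T]))
        V = np.ascontiguousarray(np.stack([v for (u, v, w) in pairs_T]))
        grad = np.zeros_like(positions_grad)
        val = np.zeros(1)
        dipole_contraction_kernel(self.pi, self.pj, self.dr,
                                  self.c1, self.c2, self.c3, U, V, grad, val)
        # u·T·v geometric part is -u·𝒯·v
        positions_grad -= COULOMB * grad

    def recip_pair_gradient(self, pairs_T, positions_grad):
        """Reciprocal-mesh part of Σ w·∇(u·T·v) (same sign convention)."""
        if self.recip is None or not pairs_T:
            return
        zeros_q = np.zeros(self.n)
        for (u, v, w) in pairs_T:
            gu = self.recip.spread(self.positions, zeros_q, u, None)
            phiu, _ = self.recip.convolve(gu)
            fv = self.recip.site_energy_forces(
                phiu, self.positions, zeros_q, v, None,
                compute_forces=True, self_energy_factor=1.0)
            gv = self.recip.spread(self.positions, zeros_q, v, None)
            phiv, _ = self.recip.convolve(gv)
            fu = self.recip.site_energy_forces(
                phiv, self.positions, zeros_q, u, None,
                compute_forces=True, self_energy_factor=1.0)
            # u·𝒯_recip·v = -U_cross(u, v);  forces = -∂U_cross/∂x
            # ∇(u·T·v) ⊃ -∇(u·𝒯v) = ∇U_cross = -(F_u + F_v)
            positions_grad += w * (fv["forces"] + fu["forces"]) * (-1.0)

    def dipole_recip_cross(self, dip, probe_q, probe_mu, probe_Q,
                           compute_forces=True):
        """Reciprocal cross interaction of a lab-frame dipole set with an
        arbitrary probe multipole set sharing the same sites.

        Returns the cross energy Σ_i probe·∇φ_dip etc. (kcal/mol), forces on
        both roles combined, and moment derivatives for the probe set.
        """
        zeros_q = np.zeros(self.n)
        gd = self.recip.spread(self.positions, zeros_q, dip, None)
        phid, _ = self.recip.convolve(gd)
        probe = self.recip.site_energy_forces(
            phid, self.positions, probe_q, probe_mu, probe_Q,
            compute_forces=compute_forces, self_energy_factor=1.0)
        gp = self.recip.spread(self.positions, probe_q, probe_mu, probe_Q)
        phip, _ = self.recip.convolve(gp)
        dipside = self.recip.site_energy_forces(
            phip, self.positions, zeros_q, dip, None,
            compute_forces=compute_forces, self_energy_factor=1.0)
        out = {
            "energy": probe["energy"],
            "dUdmu_probe": probe["dUdmu"],
            "dUdQ_probe": probe["dUdQ"],
            "dUdmu_dip": dipside["dUdmu"],
        }
        if compute_forces:
            out["forces"] = probe["forces"] + dipside["forces"]
        return out


# ---------------------------------------------------------------------------
# solver helpers
# ---------------------------------------------------------------------------


def _vdot(a, b):
    return float(np.sum(a * b))


def _rms_debye(delta, active):
    n_active = int(np.count_nonzero(active))
    if n_active == 0:
        return 0.0
    return DEBYE_PER_EA * math.sqrt(
        float(np.sum(delta[active] ** 2)) / (3 * n_active))


def solve_induced(model: PolarizationModel, E, settings: SolverSettings,
                  guess=None) -> DipoleState:
    """Dispatch to the configured dipole solver."""
    method = settings.method.lower()
    if method == "jor":
        return solve_jor(model, E, settings, guess)
    if method == "pcg":
        return solve_pcg(model, E, settings, guess)
    if method == "jidiis":
        return solve_jidiis(model, E, settings, guess)
    if method in ("tcg1", "tcg2"):
        return solve_tcg(model, E, order=int(method[-1]),
                         peek=settings.tcg_peek, omega=settings.tcg_omega,
                         precond=settings.preconditioner == "diagonal")
    raise ValueError(f"unknown polarization solver '{settings.method}'")


def solve_jor(model, E, settings, guess=None):
    """Jacobi over-relaxation: μ ← (1-ω)μ + ω·α(E + F(μ))."""
    mu = model.direct_guess(E) if guess is None else guess.copy()
    omega = settings.jor_omega
    for it in range(1, settings.max_iterations + 1):
        target = model.alphas[:, None] * (E + model.field_from_dipoles(mu))
        target[~model.active] = 0.0
        new = (1.0 - omega) * mu + omega * target
        res = _rms_debye(new - mu, model.active)
        mu = new
        if not np.isfinite(res):
            raise ConvergenceError(f"JOR diverged at iteration {it}")
        if res <= settings.tolerance:
            return DipoleState(mu, it, res, True, "jor")
    raise ConvergenceError(
        f"JOR: RMS change {res:.3e} D after {settings.max_iterations} iterations")


def solve_pcg(model, E, settings, guess=None):
    """Preconditioned conjugate gradient (diagonal preconditioner = α)."""
    kind = settings.preconditioner
    mu = np.zeros_like(E) if guess is None else guess.copy()
    mu[~model.active] = 0.0
    r = E - model.matvec(mu)
    r[~model.active] = 0.0
    z = model.precondition(r, kind)
    z[~model.active] = 0.0
    p = z.copy()
    rz = _vdot(r, z)
    res = _rms_debye(model.precondition(r, kind), model.active)
    if res <= settings.tolerance:
        return DipoleState(mu, 0, res, True, "pcg")
    for it in range(1, settings.max_iterations + 1):
        q = model.matvec(p)
        denom = _vdot(p, q)
        if denom <= 0 or not np.isfinite(denom):
            raise ConvergenceError("PCG: operator lost positive definiteness")
        t = rz / denom
        step = t * p
        mu = mu + step
        r = r - t * q
        z = model.precondition(r, kind)
        z[~model.active] = 0.0
        rz_new = _vdot(r, z)
        # preconditioned residual = the next Jacobi-step change in μ
        res = _rms_debye(z, model.active)
        if res <= settings.tolerance:
            return DipoleState(mu, it, res, True, "pcg")
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise ConvergenceError(
        f"PCG: RMS change {res:.3e} D after {settings.max_iterations} iterations")


def solve_jidiis(model, E, settings, guess=None):
    """Jacobi iterations accelerated by direct inversion of the iterative
    subspace (DIIS) over the stored residual history."""
    mu = model.direct_guess(E) if guess is None else guess.copy()
    mus, errs = [], []
    for it in range(1, settings.max_iterations + 1):
        jac = model.alphas[:, None] * (E + model.field_from_dipoles(mu))
        jac[~model.active] = 0.0
        err = jac - mu
        mus.append(jac)
        errs.append(err)
        if len(mus) > settings.diis_window:
            mus.pop(0)
            errs.pop(0)
        m = len(mus)
        B = np.empty((m + 1, m + 1))
        B[-1, :] = 1.0
        B[:, -1] = 1.0
        B[-1, -1] = 0.0
        for i in range(m):
            for j in range(m):
                B[i, j] = _vdot(errs[i], errs[j])
        rhs = np.zeros(m + 1)
        rhs[-1] = 1.0
        try:
            coef = np.linalg.solve(B, rhs)[:m]
        except np.linalg.LinAlgError:
            coef = np.zeros(m)
            coef[-1] = 1.0
        new = sum(c * x for c, x in zip(coef, mus))
        res = _rms_debye(new - mu, model.active)
        mu = new
        if not np.isfinite(res):
            raise ConvergenceError(f"JI/DIIS diverged at iteration {it}")
        if res <= settings.tolerance:
            return DipoleState(mu, it, res, True, "jidiis")
    raise ConvergenceError(
        f"JI/DIIS: RMS change {res:.3e} D after {settings.max_iterations} iterations")


# ---------------------------------------------------------------------------
# truncated conjugate gradient
# ---------------------------------------------------------------------------


def solve_tcg(model, E, order=2, peek=False, omega=1.0, precond=True):
    """Fixed-cost TCG: exactly the ``order``-step preconditioned CG iterate
    from a zero start, with the Krylov intermediates needed by the analytic
    gradient stored in ``aux``.  Optional Jacobi "peek" refinement step."""
    kind = "diagonal" if precond else "none"
    P = lambda v: model.precondition(v, kind)

    def T(v):
        return model.matvec(v)

    E = np.where(model.active[:, None], E, 0.0)
    z0 = P(E)
    z0[~model.active] = 0.0
    n0 = _vdot(E, z0)
    aux = {"order": order, "peek": peek, "omega": omega, "kind": kind, "E": E}
    if n0 < 1e-28:
        mu = np.zeros_like(E)
        aux.update(mu=mu, Tmu=np.zeros_like(E), degenerate=True)
        return DipoleState(mu, order, 0.0, True, f"tcg{order}", aux)
    q0 = T(z0)
    d0 = _vdot(z0, q0)
    t1 = n0 / d0
    mu1 = t1 * z0
    aux.update(z0=z0, n0=n0, q0=q0, d0=d0, t1=t1)
    if order == 1:
        mu_pre = mu1
        Tmu_pre = t1 * q0
    else:
        r1 = E - t1 * q0
        z1 = P(r1)
        z1[~model.active] = 0.0
        n1 = _vdot(r1, z1)
        b1 = n1 / n0
        p1 = z1 + b1 * z0
        q1 = T(p1)
        d1 = _vdot(p1, q1)
        t2 = n1 / d1
        mu_pre = mu1 + t2 * p1
        Tmu_pre = t1 * q0 + t2 * q1
        aux.update(r1=r1, z1=z1, n1=n1, b1=b1, p1=p1, q1=q1, d1=d1, t2=t2)
    if peek:
        rk = E - Tmu_pre
        mu = mu_pre + omega * P(rk)
        mu[~model.active] = 0.0
        Tmu = T(mu)
        aux.update(mu_pre=mu_pre, rk=rk)
    else:
        mu = mu_pre
        Tmu = Tmu_pre
    aux.update(mu=mu, Tmu=Tmu)
    res = _rms_debye(E - Tmu, model.active)
    return DipoleState(mu, order, res, True, f"tcg{order}", aux)


def tcg_gradient_terms(model, state: DipoleState):
    """Exact reverse-mode differentiation of the TCG recursion.

    Returns (pairs_T, gE) with dE_pol/k_C = Σ w·u·δT·v + gE·δE; combined with
    the geometric gradients of T and E this yields the analytic TCG forces.
    """
    aux = state.aux
    if aux.get("degenerate"):
        return [], np.zeros_like(state.mu)
    P = lambda v: model.precondition(v, aux["kind"])
    T = model.matvec
    E = aux["E"]
    mu = aux["mu"]
    pairs = [(mu, mu, 0.5)]
    gE = -mu.copy()
    bar_mu = aux["Tmu"] - E
    if aux["peek"]:
        # mu = mu_pre + ω P r_k,  r_k = E − T mu_pre
        mu_pre = aux["mu_pre"]
        bar_rk = aux["omega"] * P(bar_mu)
        gE += bar_rk
        pairs.append((bar_rk, mu_pre, -1.0))
        bar_mu = bar_mu - T(bar_rk)
    z0, n0, q0, d0, t1 = (aux["z0"], aux["n0"], aux["q0"], aux["d0"],
                          aux["t1"])
    if aux["order"] == 2:
        r1, z1, n1, b1, p1, q1, d1, t2 = (
            aux["r1"], aux["z1"], aux["n1"], aux["b1"], aux["p1"],
            aux["q1"], aux["d1"], aux["t2"])
        bar_mu1 = bar_mu.copy()
        bar_t2 = _vdot(p1, bar_mu)
        bar_p1 = t2 * bar_mu
        bar_n1 = bar_t2 / d1
        bar_d1 = -t2 * bar_t2 / d1
        bar_p1 = bar_p1 + bar_d1 * q1
        bar_q1 = bar_d1 * p1
        bar_p1 = bar_p1 + T(bar_q1)
        pairs.append((bar_q1, p1, 1.0))
        bar_z1 = bar_p1.copy()
        bar_b1 = _vdot(z0, bar_p1)
        bar_z0 = b1 * bar_p1
        bar_n1 += bar_b1 / n0
        bar_n0 = -b1 * bar_b1 / n0
        bar_r1 = bar_n1 * z1
        bar_z1 = bar_z1 + bar_n1 * r1
        bar_r1 = bar_r1 + P(bar_z1)
        gE += bar_r1
        bar_t1 = -_vdot(q0, bar_r1)
        bar_q0 = -t1 * bar_r1
    else:
        bar_mu1 = bar_mu
        bar_n0 = 0.0
        bar_t1 = 0.0
        bar_q0 = np.zeros_like(E)
    # mu1 = t1 z0
    bar_t1 += _vdot(z0, bar_mu1)
    bar_z0 = (bar_z0 if aux["order"] == 2 else np.zeros_like(E)) \
        + t1 * bar_mu1
    # t1 = n0/d0
    bar_n0 += bar_t1 / d0
    bar_d0 = -t1 * bar_t1 / d0
    # d0 = z0·q0
    bar_z0 = bar_z0 + bar_d0 * q0
    bar_q0 = bar_q0 + bar_d0 * z0
    # q0 = T z0
    bar_z0 = bar_z0 + T(bar_q0)
    pairs.append((bar_q0, z0, 1.0))
    # n0 = E·z0
    gE += bar_n0 * z0
    bar_z0 = bar_z0 + bar_n0 * E
    # z0 = P E
    gE += P(bar_z0)
    gE[~model.active] = 0.0
    return pairs, gE


def converged_gradient_terms(state: DipoleState):
    """Gradient contraction terms for a converged (variational) solution:
    dE_pol/k_C = ½ μ·δT·μ − μ·δE."""
    return [(state.mu, state.mu, 0.5)], -state.mu.copy()


def polarization_energy(model, mu, E, Tmu=None):
    """E_pol = k_C (½ μ·Tμ − μ·E); valid for truncated dipoles."""
    if Tmu is None:
        Tmu = model.matvec(mu)
    return COULOMB * (0.5 * _vdot(mu, Tmu) - _vdot(mu, E))


# ---------------------------------------------------------------------------
# ASPC predictor
# ---------------------------------------------------------------------------


def aspc_coefficients(k: int) -> np.ndarray:
    """Always-stable predictor coefficients for a history of length k:
    A_j = (-1)^(j+1) · j · C(2k, k-j)/C(2k-2, k-1); they sum to one and
    reproduce linear drifts exactly."""
    denom = math.comb(2 * k - 2, k - 1)
    return np.array([(-1) ** (j + 1) * j * math.comb(2 * k, k - j) / denom
                     for j in range(1, k + 1)])


class ASPCHistory:
    """Ring buffer of previous dipole solutions with Kolafa extrapolation."""

    def __init__(self, order: int = 6, corrector: bool = True):
        self.order = int(order)
        self.corrector = corrector
        self.omega = (self.order + 2) / (2 * self.order + 3)
        self._hist = []

    def __len__(self):
        return len(self._hist)

    def clear(self):
        self._hist = []

    def predict(self) -> Optional[np.ndarray]:
        k = len(self._hist)
        if k == 0:
            return None
        if k == 1:
            return self._hist[0].copy()
        coef = aspc_coefficients(k)
        out = np.zeros_like(self._hist[0])
        for c, mu in zip(coef, self._hist):
            out += c * mu
        return out

    def push(self, mu_solved: np.ndarray, mu_predicted=None):
        if self.corrector and mu_predicted is not None:
            stored = self.omega * mu_solved + (1 - self.omega) * mu_predicted
        else:
            stored = mu_solved.copy()
        self._hist.insert(0, stored)
        if len(self._hist) > self.order:
            self._hist.pop()


def aspc_predict(history: ASPCHistory):
    """Spec surface: predictor from the stored history (None if empty)."""
    return history.predict()
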