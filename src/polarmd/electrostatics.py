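"""Real-space multipolar electrostatics.

Interactions between sites carrying charge q, dipole μ and traceless
quadrupole Q are generated from radial kernel coefficients B_l with the
recursion B_{l+1} = -(1/r) dB_l/dr:

* bare Coulomb:       B_l = (2l-1)!! / r^(2l+1)
* erfc (Ewald real):  B_0 = erfc(βr)/r plus the standard Gaussian recursion

Masking and Thole damping enter as per-l multipliers m_l on the *direct*
(bare) part of a pair:  C_l = B_l^erfc + (m_l - 1) B_l^bare, so the
reciprocal-space sum may always include every pair at full strength.

Energy convention for the quadrupole: U = (1/3) Q : ∇∇φ with Q traceless
(the 1/3 is kept explicit; parameter files store plain traceless Cartesian
quadrupoles in e·Å²).  All public functions return energies scaled by the
Coulomb constant; the raw kernels work in e²/Å units.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.special import erfcinv

from .units import COULOMB

SQRT_PI = math.sqrt(math.pi)


class SingularityError(ZeroDivisionError):
    """Two interacting sites coincide."""


def beta_from_cutoff(cutoff: float, tail: float = 1e-8) -> float:
    """Ewald splitting parameter from the real-space tail criterion
    erfc(β·r_c) <= tail (discarded tail relative to a unit-charge pair)."""
    return float(erfcinv(tail)) / cutoff


# ---------------------------------------------------------------------------
# Radial kernel coefficients
# ---------------------------------------------------------------------------


def bl_bare(r: np.ndarray, lmax: int = 5) -> np.ndarray:
    """(n, lmax+1) bare coefficients B_l = (2l-1)!!/r^(2l+1)."""
    r = np.asarray(r, dtype=float)
    out = np.empty(r.shape + (lmax + 1,))
    inv_r2 = 1.0 / (r * r)
    out[..., 0] = 1.0 / r
    for l in range(lmax):
        out[..., l + 1] = (2 * l + 1) * out[..., l] * inv_r2
    return out


def bl_erfc(r: np.ndarray, beta: float, lmax: int = 5) -> np.ndarray:
    """(n, lmax+1) erfc-screened coefficients; reduces to bare at beta=0."""
    from scipy.special import erfc

    r = np.asarray(r, dtype=float)
    out = np.empty(r.shape + (lmax + 1,))
    inv_r2 = 1.0 / (r * r)
    out[..., 0] = erfc(beta * r) / r
    g = (2.0 * beta / SQRT_PI) * np.exp(-(beta * r) ** 2)
    two_b2 = 2.0 * beta * beta
    coef = 1.0
    for l in range(lmax):
        out[..., l + 1] = ((2 * l + 1) * out[..., l] + coef * g) * inv_r2
        coef *= two_b2
    return out


def bl_erf_origin(beta: float, lmax: int = 5) -> np.ndarray:
    """r→0 limits of the complementary (erf) kernel coefficients,
    B_l(0) = (2β/√π)(2β²)^l/(2l+1); the Ewald self terms follow from these."""
    out = np.empty(lmax + 1)
    base = 2.0 * beta / SQRT_PI
    for l in range(lmax + 1):
        out[l] = base * (2.0 * beta * beta) ** l / (2 * l + 1)
    return out


def thole_factors(r: np.ndarray, alpha_i: np.ndarray, alpha_j: np.ndarray,
                  a: np.ndarray) -> np.ndarray:
    """Thole exponential damping multipliers (λ3, λ5, λ7, λ9) for B_1..B_4.

    ``a`` is the pairwise damping factor (conventionally min of the two
    per-type factors); sites with zero polarizability are undamped.
    """
    r = np.asarray(r, dtype=float)
    lam = np.ones(r.shape + (4,))
    aa = np.asarray(alpha_i, dtype=float) * np.asarray(alpha_j, dtype=float)
    ok = aa > 0
    if not np.any(ok):
        return lam
    u3 = np.where(ok, r**3 / np.sqrt(np.where(ok, aa, 1.0)), 0.0)
    au3 = np.minimum(np.asarray(a) * u3, 50.0)
    e = np.where(ok, np.exp(-au3), 0.0)
    lam[..., 0] = 1.0 - e
    lam[..., 1] = 1.0 - (1.0 + au3) * e
    lam[..., 2] = 1.0 - (1.0 + au3 + 0.6 * au3**2) * e
    lam[..., 3] = 1.0 - (1.0 + au3 + (18.0 * au3**2 + 9.0 * au3**3) / 35.0) * e
    return lam


def effective_coefficients(r: np.ndarray, beta: float,
                           multipliers: np.ndarray, lmax: int = 5) -> np.ndarray:
    """C_l = B_l^erfc + (m_l - 1) B_l^bare for per-pair, per-l multipliers.

    ``multipliers`` has shape (n, lmax+1); with beta=0 this is m_l·B_l^bare.
    """
    bare = bl_bare(r, lmax)
    if beta > 0:
        cl = bl_erfc(r, beta, lmax)
    else:
        cl = bare.copy()
    cl += (multipliers - 1.0) * bare
    return cl


def permanent_multipliers(scale: np.ndarray, lmax: int = 5) -> np.ndarray:
    """Masking-only multipliers (same scale for every l)."""
    scale = np.asarray(scale, dtype=float)
    return np.repeat(scale[:, None], lmax + 1, axis=1)


def damped_multipliers(r, alpha_i, alpha_j, thole_a, scale=None, lmax: int = 5):
    """Multipliers combining masking and Thole damping for dipole-involving
    kernels: m_0 = scale, m_l = scale·λ_(2l+1) for l=1..4 (λ9 reused at l=5,
    where no damped term ever contributes)."""
    lam = thole_factors(r, alpha_i, alpha_j, thole_a)
    n = len(np.atleast_1d(r))
    m = np.ones((n, lmax + 1))
    s = np.ones(n) if scale is None else np.asarray(scale, dtype=float)
    m[:, 0] = s
    for l in range(1, 5):
        m[:, l] = s * lam[:, l - 1]
    if lmax >= 5:
        m[:, 5] = s * lam[:, 3]
    return m


# ---------------------------------------------------------------------------
# numba pair kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _phi_source(sx, sy, sz, c, q, mu, Q, phi, gphi, ggphi):
    """Potential, gradient and second gradient at s (target minus source)
    generated by moments (q, mu, Q); results written into the out slices."""
    ds = mu[0] * sx + mu[1] * sy + mu[2] * sz
    Qs0 = Q[0, 0] * sx + Q[0, 1] * sy + Q[0, 2] * sz
    Qs1 = Q[1, 0] * sx + Q[1, 1] * sy + Q[1, 2] * sz
    Qs2 = Q[2, 0] * sx + Q[2, 1] * sy + Q[2, 2] * sz
    sQs = sx * Qs0 + sy * Qs1 + sz * Qs2
    c0, c1, c2, c3, c4 = c[0], c[1], c[2], c[3], c[4]

    phi[0] = q * c0 + ds * c1 + sQs * c2 / 3.0

    s = (sx, sy, sz)
    Qs = (Qs0, Qs1, Qs2)
    for a in range(3):
        gphi[a] = (-q * s[a] * c1 + mu[a] * c1 - ds * s[a] * c2
                   + (2.0 / 3.0) * Qs[a] * c2 - (sQs / 3.0) * s[a] * c3)
    for a in range(3):
        for b in range(3):
            d_ab = 1.0 if a == b else 0.0
            val = q * (s[a] * s[b] * c2 - d_ab * c1)
            val -= ((d_ab * ds + mu[a] * s[b] + mu[b] * s[a]) * c2
                    - s[a] * s[b] * ds * c3)
            val += (1.0 / 3.0) * (2.0 * Q[a, b] * c2
                                  - (d_ab * sQs + 2.0 * s[a] * Qs[b]
                                     + 2.0 * s[b] * Qs[a]) * c3
                                  + s[a] * s[b] * sQs * c4)
            ggphi[a, b] = val


@njit(cache=True)
def mpole_pair_kernel(rij, cl, qi, mui, Qi, qj, muj, Qj, do_force,
                      energy, force, phi_i, gphi_i, ggphi_i,
                      phi_j, gphi_j, ggphi_j):
    """Vectorised multipole-multipole interactions for a batch of pairs.

    rij = x_i - x_j (minimum image applied by the caller); cl are effective
    per-pair radial coefficients C_0..C_5.  Outputs are per-pair and in
    e²/Å units (Coulomb constant applied by the caller).  force is the force
    on site i; the force on j is its negative.
    """
    n = rij.shape[0]
    Qir = np.empty(3)
    Qjr = np.empty(3)
    for k in range(n):
        rx, ry, rz = rij[k, 0], rij[k, 1], rij[k, 2]
        c0, c1, c2, c3, c4, c5 = (cl[k, 0], cl[k, 1], cl[k, 2],
                                  cl[k, 3], cl[k, 4], cl[k, 5])
        qa, qb = qi[k], qj[k]
        ma, mb = mui[k], muj[k]
        Qa, Qb = Qi[k], Qj[k]

        dri = ma[0] * rx + ma[1] * ry + ma[2] * rz
        drj = mb[0] * rx + mb[1] * ry + mb[2] * rz
        for a in range(3):
            Qir[a] = Qa[a, 0] * rx + Qa[a, 1] * ry + Qa[a, 2] * rz
            Qjr[a] = Qb[a, 0] * rx + Qb[a, 1] * ry + Qb[a, 2] * rz
        qiRR = rx * Qir[0] + ry * Qir[1] + rz * Qir[2]
        qjRR = rx * Qjr[0] + ry * Qjr[1] + rz * Qjr[2]
        mumu = ma[0] * mb[0] + ma[1] * mb[1] + ma[2] * mb[2]
        muiQjr = ma[0] * Qjr[0] + ma[1] * Qjr[1] + ma[2] * Qjr[2]
        mujQir = mb[0] * Qir[0] + mb[1] * Qir[1] + mb[2] * Qir[2]
        QiQj = 0.0
        for a in range(3):
            for b in range(3):
                QiQj += Qa[a, b] * Qb[a, b]
        QirQjr = Qir[0] * Qjr[0] + Qir[1] * Qjr[1] + Qir[2] * Qjr[2]

        S0 = qa * qb
        S1 = qa * drj - qb * dri + mumu
        S2 = ((qa * qjRR + qb * qiRR) / 3.0 - dri * drj
              + (2.0 / 3.0) * (muiQjr - mujQir) + (2.0 / 9.0) * QiQj)
        S3 = (qiRR * drj - qjRR * dri) / 3.0 - (4.0 / 9.0) * QirQjr
        S4 = qiRR * qjRR / 9.0

        energy[k] = S0 * c0 + S1 * c1 + S2 * c2 + S3 * c3 + S4 * c4

        if do_force:
            rad = S0 * c1 + S1 * c2 + S2 * c3 + S3 * c4 + S4 * c5
            r3 = (rx, ry, rz)
            for a in range(3):
                QjmuI = Qb[a, 0] * ma[0] + Qb[a, 1] * ma[1] + Qb[a, 2] * ma[2]
                QimuJ = Qa[a, 0] * mb[0] + Qa[a, 1] * mb[1] + Qa[a, 2] * mb[2]
                QiQjr = Qa[a, 0] * Qjr[0] + Qa[a, 1] * Qjr[1] + Qa[a, 2] * Qjr[2]
                QjQir = Qb[a, 0] * Qir[0] + Qb[a, 1] * Qir[1] + Qb[a, 2] * Qir[2]
                dS1 = qa * mb[a] - qb * ma[a]
                dS2 = ((2.0 / 3.0) * (qa * Qjr[a] + qb * Qir[a])
                       - (ma[a] * drj + mb[a] * dri)
                       + (2.0 / 3.0) * (QjmuI - QimuJ))
                dS3 = ((2.0 * Qir[a] * drj + qiRR * mb[a]
                        - 2.0 * Qjr[a] * dri - qjRR * ma[a]) / 3.0
                       - (4.0 / 9.0) * (QiQjr + QjQir))
                dS4 = (2.0 / 9.0) * (Qir[a] * qjRR + Qjr[a] * qiRR)
                force[k, a] = (-(dS1 * c1 + dS2 * c2 + dS3 * c3 + dS4 * c4)
                               + r3[a] * rad)

        _phi_source(rx, ry, rz, cl[k], qb, mb, Qb,
                    phi_i[k:k + 1], gphi_i[k], ggphi_i[k])
        _phi_source(-rx, -ry, -rz, cl[k], qa, ma, Qa,
                    phi_j[k:k + 1], gphi_j[k], ggphi_j[k])


@njit(cache=True)
def perm_field_kernel(pi, pj, rij, cl, q, mu, Q, field):
    """Accumulate the (damped) field of permanent multipoles at every site;
    field is (N,3), E = -∇φ, in e/Å² units."""
    n = pi.shape[0]
    phi = np.empty(1)
    gphi = np.empty(3)
    ggphi = np.empty((3, 3))
    for k in range(n):
        i = pi[k]
        j = pj[k]
        rx, ry, rz = rij[k, 0], rij[k, 1], rij[k, 2]
        _phi_source(rx, ry, rz, cl[k], q[j], mu[j], Q[j], phi, gphi, ggphi)
        for a in range(3):
            field[i, a] -= gphi[a]
        _phi_source(-rx, -ry, -rz, cl[k], q[i], mu[i], Q[i], phi, gphi, ggphi)
        for a in range(3):
            field[j, a] -= gphi[a]


@njit(cache=True)
def dipole_field_kernel(pi, pj, rij, c1, c2, mu, field):
    """Field at each site from a set of point dipoles over the pair list
    (the real-space part of the polarization matrix-vector product)."""
    n = pi.shape[0]
    for k in range(n):
        i = pi[k]
        j = pj[k]
        rx, ry, rz = rij[k, 0], rij[k, 1], rij[k, 2]
        a1 = c1[k]
        a2 = c2[k]
        drj = mu[j, 0] * rx + mu[j, 1] * ry + mu[j, 2] * rz
        dri = mu[i, 0] * rx + mu[i, 1] * ry + mu[i, 2] * rz
        field[i, 0] += -mu[j, 0] * a1 + rx * drj * a2
        field[i, 1] += -mu[j, 1] * a1 + ry * drj * a2
        field[i, 2] += -mu[j, 2] * a1 + rz * drj * a2
        field[j, 0] += -mu[i, 0] * a1 + rx * dri * a2
        field[j, 1] += -mu[i, 1] * a1 + ry * dri * a2
        field[j, 2] += -mu[i, 2] * a1 + rz * dri * a2


@njit(cache=True)
def dipole_contraction_kernel(pi, pj, rij, c1, c2, c3, U, V, grad, value):
    """Gradient (wrt positions) and value of Σ_k u_k·𝒯·v_k for stacked
    dipole-set pairs U, V of shape (nsets, N, 3); 𝒯 is the real-space damped
    dipole field operator.  grad accumulates d(value)/dx."""
    n = pi.shape[0]
    nsets = U.shape[0]
    for k in range(n):
        i = pi[k]
        j = pj[k]
        rx, ry, rz = rij[k, 0], rij[k, 1], rij[k, 2]
        a1, a2, a3 = c1[k], c2[k], c3[k]
        gx = 0.0
        gy = 0.0
        gz = 0.0
        for s in range(nsets):
            # unordered pair sum: u_i·T·v_j + v_i·T·u_j
            for ordering in range(2):
                if ordering == 0:
                    ua = U[s]
                    va = V[s]
                else:
                    ua = V[s]
                    va = U[s]
                uv = (ua[i, 0] * va[j, 0] + ua[i, 1] * va[j, 1]
                      + ua[i, 2] * va[j, 2])
                ur = ua[i, 0] * rx + ua[i, 1] * ry + ua[i, 2] * rz
                vr = va[j, 0] * rx + va[j, 1] * ry + va[j, 2] * rz
                value[0] += -uv * a1 + ur * vr * a2
                gx += (uv * rx + ua[i, 0] * vr + va[j, 0] * ur) * a2 \
                    - ur * vr * rx * a3
                gy += (uv * ry + ua[i, 1] * vr + va[j, 1] * ur) * a2 \
                    - ur * vr * ry * a3
                gz += (uv * rz + ua[i, 2] * vr + va[j, 2] * ur) * a2 \
                    - ur * vr * rz * a3
        grad[i, 0] += gx
        grad[i, 1] += gy
        grad[i, 2] += gz
        grad[j, 0] -= gx
        grad[j, 1] -= gy
        grad[j, 2] -= gz


# ---------------------------------------------------------------------------
# public wrappers
# ---------------------------------------------------------------------------


@njit(cache=True)
def _scatter_pair(target, pi, pj, vals, sign_j):
    n = pi.shape[0]
    if vals.ndim == 2:
        for k in range(n):
            for a in range(3):
                target[pi[k], a] += vals[k, a]
                target[pj[k], a] += sign_j * vals[k, a]
    else:
        for k in range(n):
            target[pi[k]] += vals[k]
            target[pj[k]] += sign_j * vals[k]


@njit(cache=True)
def _scatter_phi(phi, pi, pj, phi_i, phi_j, scale):
    for k in range(pi.shape[0]):
        phi[pi[k]] += scale * phi_i[k]
        phi[pj[k]] += scale * phi_j[k]


@njit(cache=True)
def _scatter_two(tmu, tQ, pi, pj, gi, gj, ggi, ggj, scale):
    n = pi.shape[0]
    for k in range(n):
        for a in range(3):
            tmu[pi[k], a] += scale * gi[k, a]
            tmu[pj[k], a] += scale * gj[k, a]
            for b in range(3):
                tQ[pi[k], a, b] += scale * ggi[k, a, b] / 3.0
                tQ[pj[k], a, b] += scale * ggj[k, a, b] / 3.0


@njit(cache=True)
def _scatter_moments_one(tmu, tQ, idx, g, gg, scale):
    for k in range(idx.shape[0]):
        for a in range(3):
            tmu[idx[k], a] += scale * g[k, a]
            for b in range(3):
                tQ[idx[k], a, b] += scale * gg[k, a, b] / 3.0


@njit(cache=True)
def _scatter_forces(F, pi, pj, f, scale):
    n = pi.shape[0]
    for k in range(n):
        for a in range(3):
            F[pi[k], a] += scale * f[k, a]
            F[pj[k], a] -= scale * f[k, a]


def _pair_geometry(positions, box, pi, pj):
    dr = positions[pi] - positions[pj]
    dr = box.minimum_image(dr)
    r = np.sqrt(np.sum(dr * dr, axis=1))
    if np.any(r < 1e-10):
        k = int(np.argmin(r))
        raise SingularityError(
            f"sites {int(pi[k])} and {int(pj[k])} coincide")
    return np.ascontiguousarray(dr), r


def real_space_permanent(positions, box, pairs, q, mu, Q, beta, scales,
                         compute_forces=True):
    """Erfc-screened permanent multipole energy/forces over a half pair list.

    ``pairs`` is (pi, pj); ``scales`` the per-pair masking factors.  Returns a
    dict with energy (kcal/mol), forces, and the per-site derivatives of the
    energy with respect to lab-frame dipoles and quadrupoles (for torques).
    """
    pi, pj = pairs
    N = positions.shape[0]
    res = {
        "energy": 0.0,
        "forces": np.zeros((N, 3)),
        "dUdmu": np.zeros((N, 3)),
        "dUdQ": np.zeros((N, 3, 3)),
        "phi": np.zeros(N),
    }
    if len(pi) == 0:
        return res
    dr, r = _pair_geometry(positions, box, pi, pj)
    cl = effective_coefficients(r, beta, permanent_multipliers(scales))
    n = len(pi)
    e = np.empty(n)
    f = np.empty((n, 3))
    phi_i = np.empty(n)
    phi_j = np.empty(n)
    gphi_i = np.empty((n, 3))
    gphi_j = np.empty((n, 3))
    ggphi_i = np.empty((n, 3, 3))
    ggphi_j = np.empty((n, 3, 3))
    mpole_pair_kernel(dr, cl, q[pi], mu[pi], Q[pi], q[pj], mu[pj], Q[pj],
                      compute_forces, e, f, phi_i, gphi_i, ggphi_i,
                      phi_j, gphi_j, ggphi_j)
    res["energy"] = COULOMB * float(e.sum())
    if compute_forces:
        _scatter_forces(res["forces"], pi, pj, f, COULOMB)
    _scatter_two(res["dUdmu"], res["dUdQ"], pi, pj, gphi_i, gphi_j,
                 ggphi_i, ggphi_j, COULOMB)
    _scatter_phi(res["phi"], pi, pj, phi_i, phi_j, COULOMB)
    return res


def dipole_permanent_cross_real(dr, cl, pi, pj, dip, q, mu, Q, n_sites,
                                compute_forces=True):
    """Real-space cross interaction of a lab-frame dipole set with the
    permanent multipoles over a half pair list (damped coefficients ``cl``).

    Returns energy (kcal/mol), forces, and ∂U/∂μ_perm, ∂U/∂Q_perm needed by
    the frame-force pass.  U follows the qφ + μ·∇φ + Q:∇∇φ/3 convention, so
    U = -k_C · dip·E_perm for the damped permanent field E_perm.
    """
    npair = len(pi)
    out = {"energy": 0.0, "forces": np.zeros((n_sites, 3)),
           "dUdmu": np.zeros((n_sites, 3)), "dUdQ": np.zeros((n_sites, 3, 3))}
    if npair == 0:
        return out
    zeros_q = np.zeros(npair)
    zeros_Q = np.zeros((npair, 3, 3))
    e = np.empty(npair)
    f = np.empty((npair, 3))
    buf = [np.empty(npair), np.empty((npair, 3)), np.empty((npair, 3, 3))]
    buf2 = [np.empty(npair), np.empty((npair, 3)), np.empty((npair, 3, 3))]
    # dipoles at i against permanents at j
    mpole_pair_kernel(dr, cl, zeros_q, dip[pi], zeros_Q,
                      q[pj], mu[pj], Q[pj], compute_forces,
                      e, f, buf[0], buf[1], buf[2], buf2[0], buf2[1], buf2[2])
    out["energy"] += COULOMB * float(e.sum())
    if compute_forces:
        _scatter_forces(out["forces"], pi, pj, f, COULOMB)
    _scatter_moments_one(out["dUdmu"], out["dUdQ"], pj, buf2[1], buf2[2],
                         COULOMB)
    # permanents at i against dipoles at j
    mpole_pair_kernel(dr, cl, q[pi], mu[pi], Q[pi],
                      zeros_q, dip[pj], zeros_Q, compute_forces,
                      e, f, buf[0], buf[1], buf[2], buf2[0], buf2[1], buf2[2])
    out["energy"] += COULOMB * float(e.sum())
    if compute_forces:
        _scatter_forces(out["forces"], pi, pj, f, COULOMB)
    _scatter_moments_one(out["dUdmu"], out["dUdQ"], pi, buf[1], buf[2],
                         COULOMB)
    return out


def pair_multipole_interaction(xi, xj, box, q_i, mu_i, Q_i, q_j, mu_j, Q_j,
                               beta=0.0, scale=1.0):
    """Single-pair interaction: energy, forces, torques and potential/field/
    field-gradient at both sites (kcal/mol units)."""
    pos = np.array([xi, xj], dtype=float)
    pairs = (np.array([0]), np.array([1]))
    out = real_space_permanent(
        pos, box, pairs,
        np.array([q_i, q_j], dtype=float),
        np.array([mu_i, mu_j], dtype=float),
        np.array([Q_i, Q_j], dtype=float),
        beta, np.array([scale]))
    mu = np.array([mu_i, mu_j], dtype=float)
    Q = np.array([Q_i, Q_j], dtype=float)
    torques = np.array([
        torque_from_moment_derivatives(mu[k], Q[k],
                                       out["dUdmu"][k], out["dUdQ"][k])
        for k in range(2)])
    field = -out["dUdmu"]                # ∂U/∂μ = ∇φ, E = -∇φ
    fieldgrad = -3.0 * out["dUdQ"]       # ∂U/∂Q = ∇∇φ/3
    return {
        "energy": out["energy"],
        "forces": out["forces"],
        "torques": torques,
        "potential": out["phi"],
        "field": field,
        "field_gradient": fieldgrad,
    }


_EPS_LC = np.zeros((3, 3, 3))
for _a, _b, _c in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
    _EPS_LC[_a, _b, _c] = 1.0
    _EPS_LC[_c, _b, _a] = -1.0


def torque_from_moment_derivatives(mu, Q, dUdmu, dUdQ):
    """Torque on a site given ∂U/∂μ and ∂U/∂Q (lab frame):
    τ = ∂U/∂μ × μ  - 2 ε : (∂U/∂Q · Q)."""
    tau = np.cross(dUdmu, mu)
    P = dUdQ @ Q
    tau = tau - 2.0 * np.einsum("adc,ac->d", _EPS_LC, P)
    return tau


def self_energy(q, mu, Q, beta):
    """Ewald self energy of a multipole set (removes the reciprocal-space
    interaction of each Gaussian-screened multipole with itself)."""
    b = bl_erf_origin(beta)
    q2 = float(np.sum(q * q))
    m2 = float(np.sum(mu * mu))
    qq = float(np.sum(Q * Q))
    return -0.5 * COULOMB * (q2 * b[0] + m2 * b[1] + (2.0 / 9.0) * qq * b[2])


def self_moment_derivatives(mu, Q, beta):
    """(dUdmu, dUdQ) of the self energy — needed so frame torques balance."""
    b = bl_erf_origin(beta)
    return -COULOMB * b[1] * mu, -COULOMB * (2.0 / 9.0) * b[2] * Q


def self_field_coefficient(beta):
    """Self-field coefficient: E_self = c·μ with c = (4β³/3√π)·k_C."""
    return COULOMB * bl_erf_origin(beta)[1]


def background_correction(q, beta, volume):
    """Uniform neutralizing background term for non-neutral cells."""
    Qtot = float(np.sum(q))
    if abs(Qtot) < 1e-12:
        return 0.0
    return -COULOMB * math.pi * Qtot * Qtot / (2.0 * beta * beta * volume)


def thole_damped_tensors(alpha_i, alpha_j, thole_a, dr, beta=0.0):
    """Damped (and optionally erfc-screened) dipole field tensor T (3×3) and
    its gradient (3×3×3, d T_ab / d r_c) for one displacement vector.

    The field at i from a dipole at j is E = T μ_j (e/Å² per unit dipole,
    multiply by the Coulomb constant for kcal units).  Finite as r → 0 for
    damped pairs; tends to the erfc-screened point-dipole tensor at large r.
    """
    dr = np.asarray(dr, dtype=float)
    r = np.linalg.norm(dr)
    m = damped_multipliers(np.array([r]), np.array([alpha_i]),
                           np.array([alpha_j]), np.array([thole_a]))
    cl = effective_coefficients(np.array([r]), beta, m)[0]
    c1, c2, c3 = cl[1], cl[2], cl[3]
    eye = np.eye(3)
    T = -eye * c1 + np.outer(dr, dr) * c2
    grad = np.empty((3, 3, 3))
    for c in range(3):
        grad[:, :, c] = (eye * dr[c] * c2
                         + np.outer(np.eye(3)[c], dr) * c2
                         + np.outer(dr, np.eye(3)[c]) * c2
                         - np.outer(dr, dr) * dr[c] * c3)
    return T, grad
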