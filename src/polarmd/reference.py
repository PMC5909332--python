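"""Slow, mesh-free reference implementations used to validate the fast path.

These brute-force routines share no code with the SPME/neighbour-list
machinery: the reciprocal sum is an explicit loop over k-vectors, the
real-space sum loops over explicit periodic images, and the Madelung
constant is evaluated by Evjen's charge-weighted direct lattice summation.
They are intended for small systems (tens of sites) in tests and in the
acceptance script.
"""

from __future__ import annotations

import math

import numpy as np

from .electrostatics import (background_correction, bl_erfc,
                             mpole_pair_kernel, permanent_multipliers,
                             self_energy)
from .units import COULOMB


def ewald_recip_explicit(positions, box, q, mu=None, Q=None, beta=0.5,
                         tol=1e-12, kmax=None):
    """Explicit k-space reciprocal sum for multipoles.

    Returns dict with the reciprocal energy and per-site potential, field and
    field gradient (self-interaction included, matching the SPME convention).
    """
    n = positions.shape[0]
    mu = np.zeros((n, 3)) if mu is None else np.asarray(mu, dtype=float)
    Q = np.zeros((n, 3, 3)) if Q is None else np.asarray(Q, dtype=float)
    q = np.asarray(q, dtype=float)
    L = box.lengths
    V = box.volume
    if kmax is None:
        kcut = 2.0 * beta * math.sqrt(-math.log(tol))
        mmax = np.ceil(kcut * L / (2 * math.pi)).astype(int)
    else:
        mmax = np.array([kmax, kmax, kmax])
    ms = [np.arange(-m, m + 1) for m in mmax]
    M1, M2, M3 = np.meshgrid(*ms, indexing="ij")
    kvecs = np.stack([2 * math.pi * M1.ravel() / L[0],
                      2 * math.pi * M2.ravel() / L[1],
                      2 * math.pi * M3.ravel() / L[2]], axis=1)
    k2 = np.einsum("ka,ka->k", kvecs, kvecs)
    keep = k2 > 1e-12
    kcut2 = (2.0 * beta * math.sqrt(-math.log(tol))) ** 2
    keep &= k2 <= kcut2
    kvecs = kvecs[keep]
    k2 = k2[keep]
    wgt = np.exp(-k2 / (4.0 * beta * beta)) / k2          # (nk,)

    phase = np.exp(1j * positions @ kvecs.T)              # (n, nk)
    kmu = mu @ kvecs.T                                    # (n, nk)
    kQk = np.einsum("ka,iab,kb->ik", kvecs, Q, kvecs)     # (n, nk)
    lam = q[:, None] + 1j * kmu - kQk / 3.0
    S = np.sum(lam * phase, axis=0)                       # (nk,)

    pref = 2.0 * math.pi * COULOMB / V
    energy = pref * float(np.sum(wgt * np.abs(S) ** 2))

    # site potential and derivatives: φ(x_i) = (4π/V) Σ w ρ̂(k) e^{ik·x}
    # with ρ̂ = conj over our S convention
    coeff = 2.0 * pref * wgt * np.conj(S)                 # (nk,)
    e_ikx = phase                                         # e^{+ik·x_i}
    phi = np.real(e_ikx @ coeff)
    gradphi = np.real(np.einsum("ik,ka,k->ia", 1j * e_ikx, kvecs, coeff))
    ggphi = np.real(np.einsum("ik,ka,kb,k->iab", -e_ikx, kvecs, kvecs, coeff))
    return {"energy": energy, "phi": phi, "field": -gradphi,
            "field_gradient": -ggphi, "gradphi": gradphi, "ggphi": ggphi}


def ewald_real_images(positions, box, q, mu=None, Q=None, beta=0.5, tol=1e-14):
    """Real-space erfc sum over explicit periodic images (no cutoff list)."""
    n = positions.shape[0]
    mu = np.zeros((n, 3)) if mu is None else np.asarray(mu, dtype=float)
    Q = np.zeros((n, 3, 3)) if Q is None else np.asarray(Q, dtype=float)
    q = np.asarray(q, dtype=float)
    L = box.lengths
    rmax = math.sqrt(-math.log(tol)) / beta
    shells = np.ceil(rmax / L).astype(int)
    total = 0.0
    imgs = [np.arange(-s, s + 1) for s in shells]
    I1, I2, I3 = np.meshgrid(*imgs, indexing="ij")
    shifts = np.stack([I1.ravel() * L[0], I2.ravel() * L[1],
                       I3.ravel() * L[2]], axis=1)
    for shift in shifts:
        central = np.allclose(shift, 0.0)
        # pair (i, j+shift); for the central cell use i<j, otherwise all i,j
        # with a 1/2 factor (every image pair counted twice over ±shift)
        if central:
            ii, jj = np.triu_indices(n, k=1)
        else:
            ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
            ii, jj = ii.ravel(), jj.ravel()
        if len(ii) == 0:
            continue
        dr = positions[ii] - (positions[jj] + shift)
        r = np.linalg.norm(dr, axis=1)
        keep = r <= rmax
        if central:
            keep &= r > 1e-12
        ii, jj, dr, r = ii[keep], jj[keep], dr[keep], r[keep]
        if len(ii) == 0:
            continue
        cl = bl_erfc(r, beta, 5)
        ne = len(ii)
        e = np.empty(ne)
        f = np.empty((ne, 3))
        tmp = [np.empty(ne), np.empty((ne, 3)), np.empty((ne, 3, 3))]
        tmp2 = [np.empty(ne), np.empty((ne, 3)), np.empty((ne, 3, 3))]
        mpole_pair_kernel(np.ascontiguousarray(dr), cl,
                          q[ii], mu[ii], Q[ii], q[jj], mu[jj], Q[jj],
                          False, e, f, tmp[0], tmp[1], tmp[2],
                          tmp2[0], tmp2[1], tmp2[2])
        total += float(e.sum()) * (1.0 if central else 0.5)
    return COULOMB * total


def total_ewald_energy(positions, box, q, mu=None, Q=None, beta=0.5):
    """β-independent total electrostatic energy of the periodic system:
    explicit real images + explicit k sum + self + background."""
    n = positions.shape[0]
    mu0 = np.zeros((n, 3)) if mu is None else np.asarray(mu, dtype=float)
    Q0 = np.zeros((n, 3, 3)) if Q is None else np.asarray(Q, dtype=float)
    q = np.asarray(q, dtype=float)
    e_real = ewald_real_images(positions, box, q, mu0, Q0, beta)
    e_rec = ewald_recip_explicit(positions, box, q, mu0, Q0, beta)["energy"]
    e_self = self_energy(q, mu0, Q0, beta)
    e_bg = background_correction(q, beta, box.volume)
    return e_real + e_rec + e_self + e_bg


def coulomb_direct(positions, q, mu=None, Q=None):
    """Bare (non-periodic) all-pairs multipole energy."""
    n = positions.shape[0]
    mu = np.zeros((n, 3)) if mu is None else np.asarray(mu, dtype=float)
    Q = np.zeros((n, 3, 3)) if Q is None else np.asarray(Q, dtype=float)
    q = np.asarray(q, dtype=float)
    ii, jj = np.triu_indices(n, k=1)
    dr = positions[ii] - positions[jj]
    r = np.linalg.norm(dr, axis=1)
    cl = (permanent_multipliers(np.ones(len(ii))) *
          np.stack([r**-(2 * l + 1) * math.prod(range(1, 2 * l, 2))
                    for l in range(6)], axis=1))
    ne = len(ii)
    e = np.empty(ne)
    f = np.empty((ne, 3))
    tmp = [np.empty(ne), np.empty((ne, 3)), np.empty((ne, 3, 3))]
    tmp2 = [np.empty(ne), np.empty((ne, 3)), np.empty((ne, 3, 3))]
    mpole_pair_kernel(np.ascontiguousarray(dr), np.ascontiguousarray(cl),
                      q[ii], mu[ii], Q[ii], q[jj], mu[jj], Q[jj],
                      False, e, f, tmp[0], tmp[1], tmp[2],
                      tmp2[0], tmp2[1], tmp2[2])
    return COULOMB * float(e.sum())


def madelung_evjen(n_shells: int = 12) -> float:
    """Madelung constant of rock salt by Evjen's method: direct lattice sum
    over an expanding cube with fractional weights on faces/edges/corners."""
    n = n_shells
    idx = np.arange(-n, n + 1)
    I, J, K = np.meshgrid(idx, idx, idx, indexing="ij")
    r = np.sqrt(I**2 + J**2 + K**2)
    sign = np.where((I + J + K) % 2 == 0, 1.0, -1.0)
    w = np.ones_like(r)
    for A in (I, J, K):
        w *= np.where(np.abs(A) == n, 0.5, 1.0)
    mask = r > 0
    return -float(np.sum(sign[mask] * w[mask] / r[mask]))


def wigner_self_energy(edge: float, beta: float = 0.8) -> float:
    """Total Ewald energy of one unit charge in a cubic box (its interaction
    with its own periodic images and neutralising background); equals
    -2.837297/(2·edge) Coulomb units for the simple-cubic Wigner lattice."""
    from .system import SimulationBox

    box = SimulationBox.cubic(edge)
    pos = np.array([[0.0, 0.0, 0.0]])
    return total_ewald_energy(pos, box, np.array([1.0]), beta=beta)
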