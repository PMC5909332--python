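"""van der Waals interactions: Halgren buffered 14-7, Lennard-Jones, and the
softcore alchemical variants.

Buffered 14-7 with δ=0.07, γ=0.12 (Halgren's published buffering constants):
    U(ρ) = ε ((1+δ)/(ρ+δ))⁷ ((1+γ)/(ρ⁷+γ) − 2),  ρ = r/r_min
with minimum -ε at ρ=1.  The softcore form inserts s = α_sc(1-λ)² into both
buffered denominators and scales by λ⁵, so λ=1 reproduces the unmodified
potential bitwise and the λ=0 end vanishes identically while staying finite
at r=0.  No long-range tail correction is applied.

Combining rules: cubic-mean for r_min and HHG for ε (buffered form),
Lorentz-Berthelot for LJ.
"""

from __future__ import annotations

import numpy as np

DELTA = 0.07
GAMMA = 0.12
SOFTCORE_ALPHA = 0.7
SOFTCORE_POWER = 5


def combine_buffered(r1, e1, r2, e2):
    """Cubic-mean r_min, HHG epsilon."""
    r = (r1**3 + r2**3) / (r1**2 + r2**2)
    se = np.sqrt(e1) + np.sqrt(e2)
    eps = np.where(se > 0, 4.0 * e1 * e2 / np.maximum(se, 1e-30) ** 2, 0.0)
    return r, eps


def combine_lj(s1, e1, s2, e2):
    """Lorentz-Berthelot."""
    return 0.5 * (s1 + s2), np.sqrt(e1 * e2)


def _buffered(rho, eps, shift):
    """Buffered 14-7 with an additive softcore shift in both denominators.

    Returns (energy, dU/dρ, dU/dshift)."""
    d7 = (rho + DELTA) ** 7 + shift
    g7 = rho**7 + GAMMA + shift
    A = (1.0 + DELTA) ** 7
    B = 1.0 + GAMMA
    t1 = A / d7
    t2 = B / g7 - 2.0
    e = eps * t1 * t2
    dd7 = 7.0 * (rho + DELTA) ** 6
    dg7 = 7.0 * rho**6
    de_drho = eps * (-t1 / d7 * dd7 * t2 + t1 * (-B / g7**2) * dg7)
    de_ds = eps * (-t1 / d7 * t2 + t1 * (-B / g7**2))
    return e, de_drho, de_ds


def _lj(x6, eps, shift):
    """LJ via x6=(r/σ)⁶ with softcore shift: 4ε[1/(s+x6)² − 1/(s+x6)].

    Returns (energy, dU/dx6, dU/dshift)."""
    den = x6 + shift
    e = 4.0 * eps * (1.0 / den**2 - 1.0 / den)
    de_dden = 4.0 * eps * (-2.0 / den**3 + 1.0 / den**2)
    return e, de_dden, de_dden


def vdw_pair(r, r_min, eps, form="buffered-14-7", lam=1.0, softcore=False,
             alpha_sc=SOFTCORE_ALPHA, power=SOFTCORE_POWER):
    """Energy, radial force dU/dr, and dU/dλ for one pair.

    With ``softcore`` the λ-coupled potential is evaluated; λ=1 reduces to
    the plain potential exactly and λ=0 gives zero.
    """
    r = np.asarray(r, dtype=float)
    if softcore:
        shift = alpha_sc * (1.0 - lam) ** 2
        pref = lam**power
        dpref = power * lam ** (power - 1)
        dshift = -2.0 * alpha_sc * (1.0 - lam)
    else:
        shift, pref, dpref, dshift = 0.0, 1.0, 0.0, 0.0
        if np.any(r <= 0):
            raise ZeroDivisionError("vdW pair at zero separation without softcore")
    if form == "lj":
        x6 = (r / r_min) ** 6
        e0, de_dx6, de_ds = _lj(x6, eps, shift)
        dU_dr = pref * de_dx6 * 6.0 * x6 / np.where(r > 0, r, 1.0)
    else:
        rho = r / r_min
        e0, de_drho, de_ds = _buffered(rho, eps, shift)
        dU_dr = pref * de_drho / r_min
    energy = pref * e0
    dU_dlam = dpref * e0 + pref * de_ds * dshift
    return energy, dU_dr, dU_dlam


def softcore_vdw(r, lam, params, alpha_sc=SOFTCORE_ALPHA,
                 power=SOFTCORE_POWER):
    """Spec surface: softcore evaluation of one pair record."""
    return vdw_pair(r, params.r_min, params.epsilon, params.form, lam,
                    softcore=True, alpha_sc=alpha_sc, power=power)


def vdw_energy_forces(positions, box, pairs, rmin_pair, eps_pair, form_lj,
                      scales, softcore_mask=None, lam=1.0, cutoff=None,
                      taper_start=0.9):
    """Vectorised vdW over a half pair list.

    rmin_pair/eps_pair are per-pair combined parameters, ``form_lj`` a boolean
    array selecting the LJ functional form, ``scales`` masking factors, and
    ``softcore_mask`` the pairs coupled through the softcore potential at λ.
    A quintic switching window over the outer (1-taper_start) fraction of the
    cutoff makes the truncation C²; no long-range tail correction is applied.
    Returns (energy, forces, dU/dλ).
    """
    n = positions.shape[0]
    if len(pairs[0]) == 0:
        return 0.0, np.zeros((n, 3)), 0.0
    pi, pj = pairs
    dr = box.minimum_image(positions[pi] - positions[pj])
    r = np.sqrt(np.sum(dr * dr, axis=1))
    energy = np.zeros(len(r))
    dudr = np.zeros(len(r))
    dudl = np.zeros(len(r))
    sc = (np.zeros(len(r), dtype=bool) if softcore_mask is None
          else softcore_mask)
    for isc in (False, True):
        for islj in (False, True):
            sel = (sc == isc) & (form_lj == islj) & (scales != 0.0)
            if not np.any(sel):
                continue
            e, f, dl = vdw_pair(r[sel], rmin_pair[sel], eps_pair[sel],
                                "lj" if islj else "buffered-14-7",
                                lam=lam if isc else 1.0, softcore=isc)
            energy[sel] = e * scales[sel]
            dudr[sel] = f * scales[sel]
            dudl[sel] = (dl * scales[sel]) if isc else 0.0
    if cutoff is not None and np.isfinite(cutoff):
        rs = taper_start * cutoff
        t = np.clip((r - rs) / (cutoff - rs), 0.0, 1.0)
        S = 1.0 - t**3 * (10.0 - 15.0 * t + 6.0 * t * t)
        dS = -30.0 * t * t * (1.0 - t) ** 2 / (cutoff - rs)
        dudr = S * dudr + dS * energy
        energy = S * energy
        dudl = S * dudl
    forces = np.zeros((n, 3))
    with np.errstate(invalid="ignore"):
        fvec = -(dudr / np.where(r > 0, r, 1.0))[:, None] * dr
    np.add.at(forces, pi, fvec)
    np.add.at(forces, pj, -fvec)
    return float(energy.sum()), forces, float(dudl.sum())
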