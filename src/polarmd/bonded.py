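"""Bonded terms: harmonic bonds and angles (energy convention k·Δ², no ½)
and 3-term Fourier torsions U = Σ_n (V_n/2)(1 + cos(nφ - γ_n))."""

from __future__ import annotations

import numpy as np

from .system import ParameterError


def enumerate_angles(bonds, n_sites):
    """All i-j-k angle triples (j central) from the bond table."""
    adj = [[] for _ in range(n_sites)]
    for i, j in bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    out = []
    for j in range(n_sites):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                out.append((nb[a], j, nb[b]))
    return out


def enumerate_torsions(bonds, n_sites):
    """All i-j-k-l proper torsions around each central bond j-k."""
    adj = [[] for _ in range(n_sites)]
    for i, j in bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    out = []
    for j, k in ((int(a), int(b)) for a, b in bonds):
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                out.append((i, j, k, l))
    return out


def bond_energy_forces(positions, box, idx, k, r0):
    """Harmonic bonds, E = k (r - r0)²."""
    n = positions.shape[0]
    F = np.zeros((n, 3))
    if len(idx) == 0:
        return 0.0, F
    i, j = idx[:, 0], idx[:, 1]
    dr = box.minimum_image(positions[i] - positions[j])
    r = np.linalg.norm(dr, axis=1)
    delta = r - r0
    e = float(np.sum(k * delta**2))
    coef = (2.0 * k * delta / np.where(r > 0, r, 1.0))[:, None]
    np.add.at(F, i, -coef * dr)
    np.add.at(F, j, coef * dr)
    return e, F


def angle_energy_forces(positions, box, idx, k, theta0):
    """Harmonic angles, E = k (θ - θ0)², θ in radians."""
    n = positions.shape[0]
    F = np.zeros((n, 3))
    if len(idx) == 0:
        return 0.0, F
    i, j, l = idx[:, 0], idx[:, 1], idx[:, 2]
    u = box.minimum_image(positions[i] - positions[j])
    v = box.minimum_image(positions[l] - positions[j])
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos = np.einsum("ka,ka->k", u, v) / (nu * nv)
    cos = np.clip(cos, -1.0, 1.0)
    theta = np.arccos(cos)
    delta = theta - theta0
    e = float(np.sum(k * delta**2))
    sin = np.sqrt(np.maximum(1.0 - cos**2, 1e-12))
    dEdth = 2.0 * k * delta
    # dθ/du and dθ/dv
    du = (cos[:, None] * u / nu[:, None]**2 - v / (nu * nv)[:, None]) / sin[:, None]
    dv = (cos[:, None] * v / nv[:, None]**2 - u / (nu * nv)[:, None]) / sin[:, None]
    Fi = -dEdth[:, None] * du
    Fl = -dEdth[:, None] * dv
    np.add.at(F, i, Fi)
    np.add.at(F, l, Fl)
    np.add.at(F, j, -(Fi + Fl))
    return e, F


def torsion_energy_forces(positions, box, idx, amplitudes, phases):
    """Fourier torsions; amplitudes (nt, 3), phases (nt, 3)."""
    n = positions.shape[0]
    F = np.zeros((n, 3))
    if len(idx) == 0:
        return 0.0, F
    i, j, k, l = idx[:, 0], idx[:, 1], idx[:, 2], idx[:, 3]
    b1 = box.minimum_image(positions[j] - positions[i])
    b2 = box.minimum_image(positions[k] - positions[j])
    b3 = box.minimum_image(positions[l] - positions[k])
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    x = np.einsum("ka,ka->k", n1, n2)
    y = np.einsum("ka,ka->k", m1, n2)
    phi = np.arctan2(y, x)
    e = 0.0
    dEdphi = np.zeros(len(phi))
    for t in range(amplitudes.shape[1]):
        Vn = amplitudes[:, t]
        gam = phases[:, t]
        nn = t + 1
        e += float(np.sum(0.5 * Vn * (1.0 + np.cos(nn * phi - gam))))
        dEdphi += -0.5 * Vn * nn * np.sin(nn * phi - gam)
    # standard analytic torsion gradient
    n1sq = np.einsum("ka,ka->k", n1, n1)
    n2sq = np.einsum("ka,ka->k", n2, n2)
    dphi_di = nb2[:, None] * n1 / n1sq[:, None]
    dphi_dl = -nb2[:, None] * n2 / n2sq[:, None]
    s1 = np.einsum("ka,ka->k", b1, b2) / nb2**2
    s2 = np.einsum("ka,ka->k", b3, b2) / nb2**2
    dphi_dj = -(1.0 + s1)[:, None] * dphi_di + s2[:, None] * dphi_dl
    dphi_dk = s1[:, None] * dphi_di - (1.0 + s2)[:, None] * dphi_dl
    for at, dphi in ((i, dphi_di), (j, dphi_dj), (k, dphi_dk), (l, dphi_dl)):
        np.add.at(F, at, -dEdphi[:, None] * dphi)
    return e, F


class BondedTerms:
    """Resolved bonded-term lists for one system."""

    def __init__(self, system, params):
        cls = system.atom_classes
        b_idx, b_k, b_r0 = [], [], []
        for i, j in system.bonds:
            key = tuple(sorted((int(cls[i]), int(cls[j]))))
            rec = params.bonds.get(key)
            if rec is None:
                if params.bonds:
                    raise ParameterError(f"no bond parameters for classes {key}")
                continue
            b_idx.append((int(i), int(j)))
            b_k.append(rec.k)
            b_r0.append(rec.r0)
        self.bond_idx = np.array(b_idx, dtype=np.int64).reshape(-1, 2)
        self.bond_k = np.array(b_k)
        self.bond_r0 = np.array(b_r0)

        a_idx, a_k, a_t0 = [], [], []
        for (i, j, l) in enumerate_angles(system.bonds, system.n_sites):
            c = (int(cls[i]), int(cls[j]), int(cls[l]))
            rec = params.angles.get(c) or params.angles.get(c[::-1])
            if rec is None:
                if params.angles:
                    raise ParameterError(f"no angle parameters for classes {c}")
                continue
            a_idx.append((i, j, l))
            a_k.append(rec.k)
            a_t0.append(rec.theta0)
        self.angle_idx = np.array(a_idx, dtype=np.int64).reshape(-1, 3)
        self.angle_k = np.array(a_k)
        self.angle_t0 = np.array(a_t0)

        t_idx, t_amp, t_ph = [], [], []
        seen = set()
        for (i, j, k, l) in enumerate_torsions(system.bonds, system.n_sites):
            key = (i, j, k, l) if (j, k) <= (k, j) else (l, k, j, i)
            if (min(key), max(key), key) in seen:
                continue
            c = (int(cls[i]), int(cls[j]), int(cls[k]), int(cls[l]))
            rec = params.torsions.get(c) or params.torsions.get(c[::-1])
            if rec is None:
                continue
            tkey = tuple(sorted((i, l))) + tuple(sorted((j, k)))
            if tkey in seen:
                continue
            seen.add(tkey)
            t_idx.append((i, j, k, l))
            t_amp.append(rec.amplitudes)
            t_ph.append(rec.phases)
        self.torsion_idx = np.array(t_idx, dtype=np.int64).reshape(-1, 4)
        self.torsion_amp = np.array(t_amp).reshape(-1, 3)
        self.torsion_ph = np.array(t_ph).reshape(-1, 3)

    def energy_forces(self, positions, box):
        eb, Fb = bond_energy_forces(positions, box, self.bond_idx,
                                    self.bond_k, self.bond_r0)
        ea, Fa = angle_energy_forces(positions, box, self.angle_idx,
                                     self.angle_k, self.angle_t0)
        et, Ft = torsion_energy_forces(positions, box, self.torsion_idx,
                                       self.torsion_amp, self.torsion_ph)
        return {"bond": eb, "angle": ea, "torsion": et,
                "forces": Fb + Fa + Ft}


def bonded_terms(system, params, positions=None):
    """Spec surface: total bonded energy and forces."""
    terms = BondedTerms(system, params)
    pos = system.positions if positions is None else positions
    return terms.energy_forces(pos, system.box)
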