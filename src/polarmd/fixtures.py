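"""Deterministic generators for the test systems: polarizable water boxes,
rock-salt lattices, random multipole gases, dimers and ion-in-water setups.

The bundled 3-site water model uses AMOEBA-like illustrative constants
(charges, dipoles, traceless quadrupoles, Thole-damped polarizabilities and
buffered 14-7 vdW sites); it is *not* the published AMOEBA water
parameterization, but has the same structure and realistic magnitudes.  All
generators are bitwise reproducible from (spec, seed).
"""

from __future__ import annotations

import math

import numpy as np

from .system import (FRAME_BISECTOR, FRAME_Z_THEN_X, AngleRecord, BondRecord,
                     ForceFieldParams, MultipoleRecord, ParticleSystem,
                     PolarizeRecord, SimulationBox, VdwRecord)

#: water density used for box sizing, g·cm⁻³
WATER_DENSITY = 0.997
WATER_MOLAR_MASS = 18.01528
#: Å³ per molecule at the density above
WATER_VOLUME = WATER_MOLAR_MASS / (WATER_DENSITY * 0.6022141)

O_TYPE, H_TYPE = 1, 2
ION_TYPE = 9

#: Named presets for the benchmark water boxes (edge Å, PME grid edge).
WATER_BOX_PRESETS = {
    "puddle": (98.5, 120),
    "pond": (145.0, 144),
    "lake": (205.19, 250),
    "sea": (426.82, 432),
    "ocean": (615.57, 648),
}


def water_params() -> ForceFieldParams:
    """AMOEBA-like illustrative parameters for 3-site polarizable water."""
    p = ForceFieldParams()
    p.masses = {O_TYPE: 15.999, H_TYPE: 1.008}
    p.names = {O_TYPE: "O", H_TYPE: "H"}
    p.vdw = {O_TYPE: VdwRecord(3.405, 0.110),
             H_TYPE: VdwRecord(2.655, 0.0135)}
    qO = np.zeros((3, 3))
    qO[0, 0], qO[1, 1], qO[2, 2] = 0.1062, -0.1171, 0.0109
    qH = np.zeros((3, 3))
    qH[0, 0], qH[1, 1], qH[2, 2] = -0.0103, -0.0301, 0.0404
    qH[0, 2] = qH[2, 0] = -0.0006
    p.multipoles = {
        O_TYPE: MultipoleRecord(-0.51966, np.array([0.0, 0.0, 0.0755]), qO,
                                FRAME_BISECTOR, H_TYPE, H_TYPE),
        H_TYPE: MultipoleRecord(0.25983, np.array([-0.0204, 0.0, -0.0308]),
                                qH, FRAME_Z_THEN_X, O_TYPE, H_TYPE),
    }
    for rec in p.multipoles.values():
        rec.detrace()
    p.polarize = {O_TYPE: PolarizeRecord(0.837, 0.39, (H_TYPE,)),
                  H_TYPE: PolarizeRecord(0.496, 0.39, (O_TYPE,))}
    p.bonds = {(O_TYPE, H_TYPE): BondRecord(260.0, 0.9572)}
    p.angles = {(H_TYPE, O_TYPE, H_TYPE):
                AngleRecord(24.0, math.radians(104.52))}
    return p


def _water_geometry():
    """Local coordinates of one water molecule (O at origin)."""
    r0 = 0.9572
    th = math.radians(104.52)
    h1 = np.array([r0 * math.sin(th / 2), 0.0, r0 * math.cos(th / 2)])
    h2 = np.array([-r0 * math.sin(th / 2), 0.0, r0 * math.cos(th / 2)])
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def _random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian, det +1)."""
    A = rng.normal(size=(3, 3))
    Qm, R = np.linalg.qr(A)
    Qm *= np.sign(np.diag(R))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] = -Qm[:, 0]
    return Qm


def gen_water_box(edge=None, n_waters=None, seed=0, jitter=0.05):
    """Lattice-placed polarizable water box at 0.997 g/cm³.

    Give either the box ``edge`` (Å) or the number of molecules; the other is
    derived from the density.  Molecules get seeded random orientations and a
    small positional jitter; they are kept whole (no wrapping).
    """
    if (edge is None) == (n_waters is None):
        raise ValueError("give exactly one of edge, n_waters")
    if edge is not None:
        n_waters = int(round(edge**3 / WATER_VOLUME))
    else:
        edge = (n_waters * WATER_VOLUME) ** (1.0 / 3.0)
    if n_waters < 1:
        raise ValueError("box smaller than one molecule")
    rng = np.random.default_rng(seed)
    ns = int(math.ceil(n_waters ** (1.0 / 3.0)))
    spacing = edge / ns
    cells = [(i, j, k) for i in range(ns) for j in range(ns) for k in range(ns)]
    geo = _water_geometry()
    pos = np.zeros((3 * n_waters, 3))
    for m, (i, j, k) in enumerate(cells[:n_waters]):
        center = (np.array([i, j, k]) + 0.5) * spacing
        center += rng.uniform(-jitter, jitter, 3)
        R = _random_rotation(rng)
        pos[3 * m:3 * m + 3] = center + geo @ R.T
    types = np.tile([O_TYPE, H_TYPE, H_TYPE], n_waters)
    masses = np.tile([15.999, 1.008, 1.008], n_waters)
    bonds = []
    names = []
    for m in range(n_waters):
        o = 3 * m
        bonds += [(o, o + 1), (o, o + 2)]
        names += ["O", "H", "H"]
    system = ParticleSystem(pos, masses, types, types, np.array(bonds),
                            SimulationBox.cubic(edge), names=names)
    return system, water_params()


def water_box_preset(name, seed=0):
    """Named benchmark boxes with the published edge/grid sizes attached."""
    edge, grid = WATER_BOX_PRESETS[name.lower()]
    system, params = gen_water_box(edge=edge, seed=seed)
    return system, params, (grid, grid, grid)


def gen_water_dimer(oo_distance=2.9, seed=0):
    """Hydrogen-bonded water dimer in an open box."""
    geo = _water_geometry()
    rng = np.random.default_rng(seed)
    pos = np.zeros((6, 3))
    pos[0:3] = geo
    R = _random_rotation(rng)
    pos[3:6] = geo @ R.T + np.array([0.0, 0.0, -oo_distance])
    types = np.array([O_TYPE, H_TYPE, H_TYPE] * 2)
    masses = np.array([15.999, 1.008, 1.008] * 2)
    bonds = np.array([(0, 1), (0, 2), (3, 4), (3, 5)])
    system = ParticleSystem(pos, masses, types, types, bonds,
                            SimulationBox.open_boundary(),
                            names=["O", "H", "H"] * 2)
    return system, water_params()


def gen_rocksalt(lattice_constant=5.6402, cells=1):
    """±1 point-charge rock-salt lattice (NaCl structure), net charge zero."""
    a = lattice_constant
    basis_plus = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    basis_minus = [(0.5, 0, 0), (0, 0.5, 0), (0, 0, 0.5), (0.5, 0.5, 0.5)]
    pos, qsign = [], []
    for i in range(cells):
        for j in range(cells):
            for k in range(cells):
                off = np.array([i, j, k], dtype=float)
                for b in basis_plus:
                    pos.append((off + b) * a)
                    qsign.append(1.0)
                for b in basis_minus:
                    pos.append((off + b) * a)
                    qsign.append(-1.0)
    pos = np.array(pos)
    n = len(pos)
    types = np.where(np.array(qsign) > 0, ION_TYPE, ION_TYPE + 1)
    params = ForceFieldParams()
    params.multipoles = {
        ION_TYPE: MultipoleRecord(1.0, np.zeros(3), np.zeros((3, 3))),
        ION_TYPE + 1: MultipoleRecord(-1.0, np.zeros(3), np.zeros((3, 3))),
    }
    params.masses = {ION_TYPE: 22.99, ION_TYPE + 1: 35.45}
    system = ParticleSystem(pos, np.where(np.array(qsign) > 0, 22.99, 35.45),
                            types, types, np.zeros((0, 2)),
                            SimulationBox.cubic(a * cells))
    return system, params


def gen_random_multipole_gas(n, edge=None, seed=0, neutral=True,
                             polarizable=True, min_dist=1.8,
                             charge_range=0.4, dipole_range=0.25,
                             quad_range=0.15):
    """Seeded random multipole gas with non-overlapping sites.

    Every site gets its own atom type with lab-frame (frame ``none``)
    moments; quadrupoles are de-traced.  Intended for oracle comparisons.
    """
    if edge is None:
        edge = max((n * 25.0) ** (1.0 / 3.0), 4 * min_dist)
    rng = np.random.default_rng(seed)
    pos = []
    box = SimulationBox.cubic(edge)
    attempts = 0
    while len(pos) < n:
        x = rng.uniform(0, edge, 3)
        if all(np.linalg.norm(box.minimum_image(x - p)) > min_dist
               for p in pos):
            pos.append(x)
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("cannot place non-overlapping sites")
    pos = np.array(pos)
    q = rng.uniform(-charge_range, charge_range, n)
    if neutral:
        q -= q.mean()
    mu = rng.uniform(-dipole_range, dipole_range, (n, 3))
    Q = rng.uniform(-quad_range, quad_range, (n, 3, 3))
    Q = 0.5 * (Q + np.transpose(Q, (0, 2, 1)))
    Q -= np.trace(Q, axis1=1, axis2=2)[:, None, None] / 3.0 * np.eye(3)
    params = ForceFieldParams()
    types = np.arange(100, 100 + n)
    for t in range(n):
        params.multipoles[100 + t] = MultipoleRecord(q[t], mu[t], Q[t])
        if polarizable:
            params.polarize[100 + t] = PolarizeRecord(
                float(rng.uniform(0.3, 1.0)), 0.39)
        params.masses[100 + t] = 20.0
    system = ParticleSystem(pos, np.full(n, 20.0), types, types,
                            np.zeros((0, 2)), box)
    return system, params


def gen_ion_in_water(n_waters=64, charge=1.0, alpha=0.0, r_min=3.3,
                     epsilon=0.1, seed=0):
    """One monatomic ion (optionally charged/polarizable) in a water box."""
    wsys, params = gen_water_box(n_waters=n_waters, seed=seed)
    edge = wsys.box.a
    center = np.full(3, edge / 2.0)
    # remove the molecule closest to the centre to make room
    oo = wsys.positions[::3]
    kill = int(np.argmin(np.linalg.norm(oo - center, axis=1)))
    keep = np.ones(wsys.n_sites, dtype=bool)
    keep[3 * kill:3 * kill + 3] = False
    pos = np.vstack([center, wsys.positions[keep]])
    nw = n_waters - 1
    types = np.concatenate([[ION_TYPE], np.tile([O_TYPE, H_TYPE, H_TYPE], nw)])
    masses = np.concatenate([[22.99], np.tile([15.999, 1.008, 1.008], nw)])
    bonds = []
    for m in range(nw):
        o = 1 + 3 * m
        bonds += [(o, o + 1), (o, o + 2)]
    params.multipoles[ION_TYPE] = MultipoleRecord(charge, np.zeros(3),
                                                  np.zeros((3, 3)))
    if alpha > 0:
        params.polarize[ION_TYPE] = PolarizeRecord(alpha, 0.39)
    params.vdw[ION_TYPE] = VdwRecord(r_min, epsilon)
    params.masses[ION_TYPE] = 22.99
    system = ParticleSystem(pos, masses, types, types, np.array(bonds),
                            SimulationBox.cubic(edge))
    return system, params
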