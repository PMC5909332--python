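"""Local multipole frames: rotation into the lab frame, and the analytic
frame-anchor forces that replace explicit torque bookkeeping.

Supported frame definitions: ``none``, ``z-then-x`` (z axis toward one
anchor, x axis Gram-Schmidt-orthogonalised toward a second) and ``bisector``
(z axis along the bisector of two anchor directions).  Because lab-frame
multipoles M = R M_local depend on anchor positions only through the rotation
matrix R, the chain-rule force on an anchor is
-(∂U/∂M)·(∂R/∂x)·M_local, with ∂R/∂x assembled analytically from the
normalisation/orthogonalisation Jacobians.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .system import FRAME_BISECTOR, FRAME_NONE, FRAME_Z_THEN_X


class FrameError(ValueError):
    """Degenerate frame geometry (collinear anchors)."""


def _norm_jac(v):
    """normalize(v) and its Jacobian (I - n nᵀ)/|v|."""
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise FrameError("zero-length frame vector")
    e = v / n
    J = (np.eye(3) - np.outer(e, e)) / n
    return e, J


def _rotation_from_axes(vz, vx):
    """R (columns ex, ey, ez) and its derivatives wrt vz and vx.

    Returns (R, dR_dvz, dR_dvx) with dR_dv*[c] = ∂R/∂v*_c (3×3 each).
    """
    ez, Jz = _norm_jac(vz)
    u = vx - np.dot(vx, ez) * ez
    nu = np.linalg.norm(u)
    if nu < 1e-8:
        raise FrameError("collinear frame anchors")
    ex = u / nu
    Ju = (np.eye(3) - np.outer(ex, ex)) / nu     # dex/du
    # du/dvx and du/dez
    du_dvx = np.eye(3) - np.outer(ez, ez)
    du_dez = -np.dot(vx, ez) * np.eye(3) - np.outer(ez, vx)
    ey = np.cross(ez, ex)

    R = np.column_stack([ex, ey, ez])
    dR_dvz = np.zeros((3, 3, 3))
    dR_dvx = np.zeros((3, 3, 3))
    for c in range(3):
        dez = Jz[:, c]
        dex = Ju @ (du_dez @ dez)
        dey = np.cross(dez, ex) + np.cross(ez, dex)
        dR_dvz[c] = np.column_stack([dex, dey, dez])
        dex_x = Ju @ du_dvx[:, c]
        dey_x = np.cross(ez, dex_x)
        dR_dvx[c] = np.column_stack([dex_x, np.asarray(dey_x), np.zeros(3)])
    return R, dR_dvz, dR_dvx


def _frame_vectors(kind, xs, xz, xx, box):
    """(vz, vx) raw frame vectors plus the chain factors onto the three
    participating atom positions (site, z-anchor, x-anchor)."""
    dz = box.minimum_image(xz - xs)
    dx = box.minimum_image(xx - xs) if xx is not None else None
    if kind == FRAME_Z_THEN_X:
        vz = dz
        # ∂vz/∂(s, z, x) = (-I, I, 0)
        Az = (-np.eye(3), np.eye(3), np.zeros((3, 3)))
    elif kind == FRAME_BISECTOR:
        n1, J1 = _norm_jac(dz)
        n2, J2 = _norm_jac(dx)
        vz = n1 + n2
        Az = (-(J1 + J2), J1, J2)
    else:
        raise FrameError(f"unknown frame kind {kind}")
    vx = dx
    Ax = (-np.eye(3), np.zeros((3, 3)), np.eye(3))
    return vz, vx, Az, Ax


def site_rotation(kind, xs, xz, xx, box, with_jacobian=False):
    """Rotation matrix of one site; optionally ∂R/∂(site, z-anchor, x-anchor)
    as an array dR[atom 0..2][coord 0..2] of 3×3 matrices."""
    if kind == FRAME_NONE:
        R = np.eye(3)
        if with_jacobian:
            return R, np.zeros((3, 3, 3, 3))
        return R
    vz, vx, Az, Ax = _frame_vectors(kind, xs, xz, xx, box)
    R, dR_dvz, dR_dvx = _rotation_from_axes(vz, vx)
    if not with_jacobian:
        return R
    dR = np.zeros((3, 3, 3, 3))          # [which atom, coord, 3, 3]
    for atom in range(3):
        for c in range(3):
            acc = np.zeros((3, 3))
            for k in range(3):
                acc += dR_dvz[k] * Az[atom][k, c]
                acc += dR_dvx[k] * Ax[atom][k, c]
            dR[atom, c] = acc
    return R, dR


@njit(cache=True)
def _frame_core(kind, xs, xz, xx, L, periodic,
                R, Az, Ax, vx_out, jac_buffers):
    """Rotation matrix of one site plus the ingredients of its Jacobian.

    Fills R (3,3); Az/Ax are the 3×3 chain factors of vz/vx onto the three
    participating atoms; jac_buffers = (Jz, Ju, du_dvx, du_dez, ez, ex).
    Returns 0 on success, 1 on a degenerate frame.
    """
    dz = np.empty(3)
    dx = np.empty(3)
    for c in range(3):
        d = xz[c] - xs[c]
        if periodic:
            d -= L[c] * round(d / L[c])
        dz[c] = d
        d = xx[c] - xs[c]
        if periodic:
            d -= L[c] * round(d / L[c])
        dx[c] = d
    vz = np.empty(3)
    if kind == 1:  # z-then-x
        for c in range(3):
            vz[c] = dz[c]
        for a in range(3):
            for b in range(3):
                Az[0, a, b] = -1.0 if a == b else 0.0
                Az[1, a, b] = 1.0 if a == b else 0.0
                Az[2, a, b] = 0.0
    else:          # bisector
        ndz = np.sqrt(dz[0]**2 + dz[1]**2 + dz[2]**2)
        ndx = np.sqrt(dx[0]**2 + dx[1]**2 + dx[2]**2)
        if ndz < 1e-10 or ndx < 1e-10:
            return 1
        for a in range(3):
            for b in range(3):
                d_ab = 1.0 if a == b else 0.0
                J1 = (d_ab - dz[a] * dz[b] / ndz**2) / ndz
                J2 = (d_ab - dx[a] * dx[b] / ndx**2) / ndx
                Az[1, a, b] = J1
                Az[2, a, b] = J2
                Az[0, a, b] = -(J1 + J2)
        for c in range(3):
            vz[c] = dz[c] / ndz + dx[c] / ndx
    for a in range(3):
        for b in range(3):
            d_ab = 1.0 if a == b else 0.0
            Ax[0, a, b] = -d_ab
            Ax[1, a, b] = 0.0
            Ax[2, a, b] = d_ab
    nvz = np.sqrt(vz[0]**2 + vz[1]**2 + vz[2]**2)
    if nvz < 1e-10:
        return 1
    Jz, Ju, du_dvx, du_dez, ez, ex = jac_buffers
    for c in range(3):
        ez[c] = vz[c] / nvz
        vx_out[c] = dx[c]
    for a in range(3):
        for b in range(3):
            d_ab = 1.0 if a == b else 0.0
            Jz[a, b] = (d_ab - ez[a] * ez[b]) / nvz
    vxez = dx[0] * ez[0] + dx[1] * ez[1] + dx[2] * ez[2]
    u0 = dx[0] - vxez * ez[0]
    u1 = dx[1] - vxez * ez[1]
    u2 = dx[2] - vxez * ez[2]
    nu = np.sqrt(u0 * u0 + u1 * u1 + u2 * u2)
    if nu < 1e-8:
        return 1
    ex[0], ex[1], ex[2] = u0 / nu, u1 / nu, u2 / nu
    for a in range(3):
        for b in range(3):
            d_ab = 1.0 if a == b else 0.0
            Ju[a, b] = (d_ab - ex[a] * ex[b]) / nu
            du_dvx[a, b] = d_ab - ez[a] * ez[b]
            du_dez[a, b] = -vxez * d_ab - ez[a] * dx[b]
    ey0 = ez[1] * ex[2] - ez[2] * ex[1]
    ey1 = ez[2] * ex[0] - ez[0] * ex[2]
    ey2 = ez[0] * ex[1] - ez[1] * ex[0]
    R[0, 0], R[1, 0], R[2, 0] = ex[0], ex[1], ex[2]
    R[0, 1], R[1, 1], R[2, 1] = ey0, ey1, ey2
    R[0, 2], R[1, 2], R[2, 2] = ez[0], ez[1], ez[2]
    return 0


@njit(cache=True)
def _rotate_kernel(positions, L, periodic, kind, zi, xi, mu_loc, Q_loc,
                   mu_out, Q_out, R_out):
    n = positions.shape[0]
    R = np.empty((3, 3))
    Az = np.empty((3, 3, 3))
    Ax = np.empty((3, 3, 3))
    vx = np.empty(3)
    bufs = (np.empty((3, 3)), np.empty((3, 3)), np.empty((3, 3)),
            np.empty((3, 3)), np.empty(3), np.empty(3))
    for i in range(n):
        if kind[i] == 0:
            for a in range(3):
                mu_out[i, a] = mu_loc[i, a]
                for b in range(3):
                    Q_out[i, a, b] = Q_loc[i, a, b]
                    R_out[i, a, b] = 1.0 if a == b else 0.0
            continue
        bad = _frame_core(kind[i], positions[i], positions[zi[i]],
                          positions[xi[i]], L, periodic, R, Az, Ax, vx, bufs)
        if bad:
            return i + 1
        for a in range(3):
            s = 0.0
            for b in range(3):
                s += R[a, b] * mu_loc[i, b]
                R_out[i, a, b] = R[a, b]
            mu_out[i, a] = s
        for a in range(3):
            for b in range(3):
                s = 0.0
                for c in range(3):
                    for d in range(3):
                        s += R[a, c] * Q_loc[i, c, d] * R[b, d]
                Q_out[i, a, b] = s
    return 0


@njit(cache=True)
def _frame_force_kernel(positions, L, periodic, kind, zi, xi, mu_loc, Q_loc,
                        dUdmu, dUdQ, F):
    n = positions.shape[0]
    R = np.empty((3, 3))
    Az = np.empty((3, 3, 3))
    Ax = np.empty((3, 3, 3))
    vx = np.empty(3)
    Jz = np.empty((3, 3))
    Ju = np.empty((3, 3))
    du_dvx = np.empty((3, 3))
    du_dez = np.empty((3, 3))
    ez = np.empty(3)
    ex = np.empty(3)
    bufs = (Jz, Ju, du_dvx, du_dez, ez, ex)
    dvz = np.empty(3)
    dvx = np.empty(3)
    dez = np.empty(3)
    du = np.empty(3)
    dex = np.empty(3)
    dR = np.empty((3, 3))
    QRt = np.empty((3, 3))
    for i in range(n):
        if kind[i] == 0:
            continue
        bad = _frame_core(kind[i], positions[i], positions[zi[i]],
                          positions[xi[i]], L, periodic, R, Az, Ax, vx, bufs)
        if bad:
            return i + 1
        # Q_loc · Rᵀ reused for every coordinate
        for a in range(3):
            for b in range(3):
                s = 0.0
                for c in range(3):
                    s += Q_loc[i, a, c] * R[b, c]
                QRt[a, b] = s
        for atom_loc in range(3):
            atom = i if atom_loc == 0 else (zi[i] if atom_loc == 1 else xi[i])
            for cc in range(3):
                for a in range(3):
                    dvz[a] = Az[atom_loc, a, cc]
                    dvx[a] = Ax[atom_loc, a, cc]
                for a in range(3):
                    s = 0.0
                    for b in range(3):
                        s += Jz[a, b] * dvz[b]
                    dez[a] = s
                for a in range(3):
                    s = 0.0
                    for b in range(3):
                        s += du_dvx[a, b] * dvx[b] + du_dez[a, b] * dez[b]
                    du[a] = s
                for a in range(3):
                    s = 0.0
                    for b in range(3):
                        s += Ju[a, b] * du[b]
                    dex[a] = s
                dey0 = (dez[1] * ex[2] - dez[2] * ex[1]
                        + ez[1] * dex[2] - ez[2] * dex[1])
                dey1 = (dez[2] * ex[0] - dez[0] * ex[2]
                        + ez[2] * dex[0] - ez[0] * dex[2])
                dey2 = (dez[0] * ex[1] - dez[1] * ex[0]
                        + ez[0] * dex[1] - ez[1] * dex[0])
                dR[0, 0], dR[1, 0], dR[2, 0] = dex[0], dex[1], dex[2]
                dR[0, 1], dR[1, 1], dR[2, 1] = dey0, dey1, dey2
                dR[0, 2], dR[1, 2], dR[2, 2] = dez[0], dez[1], dez[2]
                dU = 0.0
                for a in range(3):
                    s = 0.0
                    for b in range(3):
                        s += dR[a, b] * mu_loc[i, b]
                    dU += dUdmu[i, a] * s
                for a in range(3):
                    for b in range(3):
                        s = 0.0
                        for c in range(3):
                            s += dR[a, c] * QRt[c, b]
                        # dQ = s + sᵀ contracted against symmetric dUdQ
                        dU += 2.0 * dUdQ[i, a, b] * s
                F[atom, cc] -= dU
    return 0


def rotate_multipoles(positions, box, frames, q_loc, mu_loc, Q_loc):
    """Rotate local multipoles into the lab frame.

    ``frames`` is (kind, z_anchor, x_anchor) integer arrays; anchors are site
    indices (ignored for kind none).  Charges are frame-independent; dipoles
    rotate as R μ, quadrupoles conjugate as R Q Rᵀ (trace preserved).
    """
    n = positions.shape[0]
    kind, zi, xi = frames
    mu = np.empty((n, 3))
    Q = np.empty((n, 3, 3))
    Rs = np.empty((n, 3, 3))
    bad = _rotate_kernel(np.ascontiguousarray(positions), box.lengths,
                         box.periodic, kind, zi, xi,
                         np.ascontiguousarray(mu_loc),
                         np.ascontiguousarray(Q_loc), mu, Q, Rs)
    if bad:
        raise FrameError(f"degenerate frame at site {bad - 1}")
    return np.asarray(q_loc, dtype=float), mu, Q, Rs


def frame_forces(positions, box, frames, mu_loc, Q_loc, dUdmu, dUdQ):
    """Forces on frame-participating atoms from the orientation dependence of
    the lab multipoles: F = -(∂U/∂M)·(∂M/∂x)."""
    n = positions.shape[0]
    kind, zi, xi = frames
    F = np.zeros((n, 3))
    bad = _frame_force_kernel(np.ascontiguousarray(positions), box.lengths,
                              box.periodic, kind, zi, xi,
                              np.ascontiguousarray(mu_loc),
                              np.ascontiguousarray(Q_loc),
                              np.ascontiguousarray(dUdmu),
                              np.ascontiguousarray(dUdQ), F)
    if bad:
        raise FrameError(f"degenerate frame at site {bad - 1}")
    return F


def torques_to_forces(positions, box, frames, torques):
    """Distribute per-site torques onto frame-anchor atoms.

    Uses the identity δU = -τ·δθ with δθ the axial vector of δR Rᵀ, so the
    force on anchor coordinate x is τ·∂θ/∂x.  The returned increments sum to
    zero and cancel each site's torque about its own position.
    """
    n = positions.shape[0]
    kind, zi, xi = frames
    F = np.zeros((n, 3))
    for i in range(n):
        if kind[i] == FRAME_NONE or not np.any(torques[i]):
            continue
        xx = positions[xi[i]] if xi[i] >= 0 else None
        R, dR = site_rotation(kind[i], positions[i], positions[zi[i]], xx,
                              box, with_jacobian=True)
        atoms = (i, zi[i], xi[i] if xi[i] >= 0 else i)
        for a_loc, atom in enumerate(atoms):
            for c in range(3):
                skew = dR[a_loc, c] @ R.T
                dtheta = np.array([skew[2, 1], skew[0, 2], skew[1, 0]])
                F[atom, c] += float(torques[i] @ dtheta)
    return F


def build_frames(system, params):
    """Resolve frame anchors for every site from its multipole record.

    Anchors are chosen among bonded neighbours whose atom type matches the
    record's z/x anchor types (a second matching neighbour serves as the x
    anchor when both types coincide, as in the water bisector frame).
    """
    n = system.n_sites
    kind = np.zeros(n, dtype=np.int64)
    zi = np.full(n, -1, dtype=np.int64)
    xi = np.full(n, -1, dtype=np.int64)
    adj = system.neighbors_of()
    types = system.atom_types
    for i in range(n):
        rec = params.multipoles.get(int(types[i]))
        if rec is None or rec.frame == FRAME_NONE:
            continue
        kind[i] = rec.frame
        cand = list(adj[i]) + [k for j in adj[i] for k in adj[j] if k != i]
        z_pick = x_pick = -1
        for c in cand:
            if types[c] == rec.z_type and z_pick < 0:
                z_pick = c
            elif types[c] == rec.x_type and x_pick < 0 and c != z_pick:
                x_pick = c
        if z_pick < 0 or x_pick < 0:
            raise FrameError(
                f"cannot resolve frame anchors for site {i} "
                f"(types z={rec.z_type}, x={rec.x_type})")
        zi[i] = z_pick
        xi[i] = x_pick
    return kind, zi, xi
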