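"""Readers and writers for the Tinker-style file dialects.

txyz coordinates: first line ``natoms [title]``, optional second line with
six box numbers (a b c alpha beta gamma; orthorhombic only), then one line
per atom: index, name, x, y, z, type, bonded indices (1-based, listed on
both partners).  Multi-frame trajectories append frames to the same file.

key files: one case-insensitive ``keyword value...`` pair per line; ``#``
comments.

prm parameter files: ``atom``, ``vdw``, ``multipole``, ``polarize``,
``bond``, ``angle``, ``torsion`` and ``scale-*`` records (a reduced dialect;
quadrupoles are given as the six upper-triangle Cartesian components in
e·Å² and are de-traced on input with a warning).
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .system import (AngleRecord, BondRecord, ForceFieldParams,
                     MultipoleRecord, ParameterError, ParticleSystem,
                     PolarizeRecord, SimulationBox, TopologyError,
                     TorsionRecord, VdwRecord, _FRAME_TAGS)

log = logging.getLogger("polarmd")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# txyz
# ---------------------------------------------------------------------------


def read_txyz(path, masses_from=None):
    """Read one Tinker-dialect coordinate frame into a ParticleSystem
    skeleton (positions, names, types, symmetrised connectivity)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    return parse_txyz_lines(lines, path, masses_from)


def parse_txyz_lines(lines, label="<txyz>", masses_from=None):
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError(f"{label}:1: expected an atom count")
    start = 1
    box = SimulationBox.open_boundary()
    if n > 0 and len(lines) > 1:
        tok = lines[1].split()
        if len(tok) == 6:
            try:
                vals = [float(t) for t in tok]
                if not all(abs(a - 90.0) < 1e-6 for a in vals[3:]):
                    raise ParseError(f"{label}:2: only orthorhombic boxes")
                box = SimulationBox(vals[0], vals[1], vals[2])
                start = 2
            except ValueError:
                pass
    pos = np.zeros((n, 3))
    names = []
    types = np.zeros(n, dtype=np.int64)
    bonds = set()
    for k in range(n):
        lineno = start + k + 1
        try:
            tok = lines[start + k].split()
        except IndexError:
            raise ParseError(f"{label}: truncated file, expected {n} atoms")
        try:
            names.append(tok[1])
            pos[k] = [float(tok[2]), float(tok[3]), float(tok[4])]
            types[k] = int(tok[5])
            nbrs = [int(t) for t in tok[6:]]
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{label}:{lineno}: malformed atom line ({exc})")
        for b in nbrs:
            if b < 1 or b > n:
                raise TopologyError(
                    f"{label}:{lineno}: bond references atom {b} of {n}")
            if b - 1 != k:
                bonds.add((min(k, b - 1), max(k, b - 1)))
    bonds = np.array(sorted(bonds), dtype=np.int64).reshape(-1, 2)
    masses = np.ones(n)
    if masses_from is not None:
        for k in range(n):
            masses[k] = masses_from.masses.get(int(types[k]), 1.0)
    sys_ = ParticleSystem(pos, masses, types, types, bonds, box, names=names)
    return sys_, start + n


def read_txyz_frames(path, masses_from=None):
    """All frames of a multi-frame txyz trajectory."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    frames = []
    k = 0
    while k < len(lines):
        sys_, used = parse_txyz_lines(lines[k:], f"{path}@{k}", masses_from)
        frames.append(sys_)
        k += used
    return frames


def write_txyz(system: ParticleSystem, path, title="polarmd", append=False,
               precision=8):
    """Write (or append) one frame; round-trips through read_txyz."""
    adj = [[] for _ in range(system.n_sites)]
    for i, j in system.bonds:
        adj[int(i)].append(int(j) + 1)
        adj[int(j)].append(int(i) + 1)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{system.n_sites:6d}  {title}\n")
        if system.box.periodic and system.n_sites > 0:
            b = system.box
            fh.write(f" {b.a:.6f} {b.b:.6f} {b.c:.6f} 90.0 90.0 90.0\n")
        for k in range(system.n_sites):
            x, y, z = system.positions[k]
            nb = " ".join(f"{j:6d}" for j in sorted(adj[k]))
            fh.write(f"{k + 1:6d}  {system.names[k]:<4s}"
                     f"{x:{precision + 8}.{precision}f}"
                     f"{y:{precision + 8}.{precision}f}"
                     f"{z:{precision + 8}.{precision}f}"
                     f"{int(system.atom_types[k]):6d} {nb}\n")
    return path


# ---------------------------------------------------------------------------
# prm
# ---------------------------------------------------------------------------


def read_params(path) -> ForceFieldParams:
    with open(path) as fh:
        lines = fh.readlines()
    return parse_params_lines(lines, path)


def parse_params_lines(lines, label="<prm>") -> ForceFieldParams:
    p = ForceFieldParams()

    def warn_dup(table, key, what, lineno):
        if key in table:
            log.warning("%s:%d: duplicate %s record %s; last wins",
                        label, lineno, what, key)

    for lineno, raw in enumerate(lines, 1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        tok = line.split()
        kw = tok[0].lower()
        try:
            if kw == "atom":
                c = int(tok[1])
                warn_dup(p.masses, c, "atom", lineno)
                p.names[c] = tok[2]
                p.masses[c] = float(tok[3])
            elif kw == "vdw":
                c = int(tok[1])
                warn_dup(p.vdw, c, "vdw", lineno)
                form = tok[4] if len(tok) > 4 else "buffered-14-7"
                p.vdw[c] = VdwRecord(float(tok[2]), float(tok[3]), form)
            elif kw == "multipole":
                t = int(tok[1])
                warn_dup(p.multipoles, t, "multipole", lineno)
                frame = _FRAME_TAGS.get(tok[2].lower())
                if frame is None:
                    raise ParameterError(f"unknown frame tag '{tok[2]}'")
                zt, xt = int(tok[3]), int(tok[4])
                vals = [float(v) for v in tok[5:15]]
                if len(vals) != 10:
                    raise ParameterError("multipole needs q, 3 dipole and 6 "
                                         "quadrupole components")
                q = vals[0]
                dip = np.array(vals[1:4])
                qxx, qxy, qxz, qyy, qyz, qzz = vals[4:]
                Q = np.array([[qxx, qxy, qxz], [qxy, qyy, qyz],
                              [qxz, qyz, qzz]])
                tr = np.trace(Q)
                if abs(tr) > 1e-6:
                    raise ParameterError(
                        f"{label}:{lineno}: quadrupole trace {tr:.3g} != 0")
                if abs(tr) > 1e-10:
                    log.warning("%s:%d: de-tracing quadrupole (trace %.2e)",
                                label, lineno, tr)
                rec = MultipoleRecord(q, dip, Q, frame, zt, xt)
                rec.detrace()
                p.multipoles[t] = rec
            elif kw == "polarize":
                t = int(tok[1])
                warn_dup(p.polarize, t, "polarize", lineno)
                alpha = float(tok[2])
                if alpha < 0:
                    raise ParameterError(
                        f"{label}:{lineno}: negative polarizability")
                group = tuple(int(g) for g in tok[4:])
                p.polarize[t] = PolarizeRecord(alpha, float(tok[3]), group)
            elif kw == "bond":
                key = tuple(sorted((int(tok[1]), int(tok[2]))))
                warn_dup(p.bonds, key, "bond", lineno)
                p.bonds[key] = BondRecord(float(tok[3]), float(tok[4]))
            elif kw == "angle":
                key = (int(tok[1]), int(tok[2]), int(tok[3]))
                warn_dup(p.angles, key, "angle", lineno)
                p.angles[key] = AngleRecord(float(tok[4]),
                                            math.radians(float(tok[5])))
            elif kw == "torsion":
                key = tuple(int(t) for t in tok[1:5])
                warn_dup(p.torsions, key, "torsion", lineno)
                p.torsions[key] = TorsionRecord(
                    tuple(float(v) for v in tok[5:8]))
            elif kw == "scale-mpole":
                cls = int(tok[1].split("-")[1])
                p.mpole_scales[cls] = float(tok[2])
            elif kw == "scale-vdw":
                cls = int(tok[1].split("-")[1])
                p.vdw_scales[cls] = float(tok[2])
            else:
                log.warning("%s:%d: unknown keyword '%s' skipped",
                            label, lineno, kw)
        except ParameterError:
            raise
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{label}:{lineno}: malformed record ({exc})")
    p.validate()
    return p


def write_params(params: ForceFieldParams, path):
    with open(path, "w") as fh:
        for c in sorted(params.masses):
            fh.write(f"atom {c} {params.names.get(c, 'X')} "
                     f"{params.masses[c]:.4f}\n")
        for c, r in sorted(params.vdw.items()):
            fh.write(f"vdw {c} {r.r_min:.4f} {r.epsilon:.6f} {r.form}\n")
        frame_names = {0: "none", 1: "z-then-x", 2: "bisector"}
        for t, r in sorted(params.multipoles.items()):
            Q = r.quadrupole
            fh.write(f"multipole {t} {frame_names[r.frame]} {r.z_type} "
                     f"{r.x_type} {r.charge:.6f} "
                     + " ".join(f"{v:.6f}" for v in r.dipole) + " "
                     + " ".join(f"{v:.6f}" for v in
                                (Q[0, 0], Q[0, 1], Q[0, 2],
                                 Q[1, 1], Q[1, 2], Q[2, 2])) + "\n")
        for t, r in sorted(params.polarize.items()):
            grp = " ".join(str(g) for g in r.group_types)
            fh.write(f"polarize {t} {r.alpha:.4f} {r.thole:.4f} {grp}\n")
        for (a, b), r in sorted(params.bonds.items()):
            fh.write(f"bond {a} {b} {r.k:.3f} {r.r0:.5f}\n")
        for key, r in sorted(params.angles.items()):
            fh.write(f"angle {key[0]} {key[1]} {key[2]} {r.k:.3f} "
                     f"{math.degrees(r.theta0):.3f}\n")
        for key, r in sorted(params.torsions.items()):
            fh.write("torsion " + " ".join(str(c) for c in key) + " "
                     + " ".join(f"{v:.4f}" for v in r.amplitudes) + "\n")
    return path


# ---------------------------------------------------------------------------
# key files
# ---------------------------------------------------------------------------


def read_key(path):
    """Parse a key file into {keyword: [tokens]} (last occurrence wins,
    except restraint lines which accumulate under 'restraints')."""
    out = {"restraints": []}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#")[0].strip()
            if not line:
                continue
            tok = line.split()
            kw = tok[0].lower()
            if kw.startswith("restrain-"):
                out["restraints"].append((kw, tok[1:]))
            else:
                out[kw] = tok[1:]
    return out


def apply_key(config, key: dict):
    """Apply parsed key settings onto an MDConfig (in place)."""
    simple = {
        "integrator": ("integrator", str),
        "thermostat": ("thermostat", str),
        "barostat": ("barostat", str),
        "temperature": ("temperature", float),
        "tau-temperature": ("tau_t", float),
        "pressure": ("pressure", float),
        "tau-pressure": ("tau_p", float),
        "polar-solver": ("polar_solver", str),
        "polar-eps": ("polar_eps", float),
        "polar-maxiter": ("polar_maxiter", int),
        "aspc-order": ("aspc_order", int),
        "ewald-cutoff": ("ewald_cutoff", float),
        "ewald-beta": ("ewald_beta", float),
        "bspline-order": ("bspline_order", int),
        "vdw-cutoff": ("vdw_cutoff", float),
        "skin": ("neighbor_skin", float),
        "seed": ("seed", int),
        "inner-steps": ("inner_steps", int),
        "dt": ("dt", float),
    }
    for kw, (attr, conv) in simple.items():
        if kw in key:
            setattr(config, attr, conv(key[kw][0]))
    if "tcg-peek" in key:
        config.tcg_peek = key["tcg-peek"][0].lower() in ("1", "true", "yes")
    if "pme-grid" in key:
        vals = [int(v) for v in key["pme-grid"]]
        config.pme_grid = tuple(vals * 3 if len(vals) == 1 else vals)
    return config


def restraints_from_key(key: dict):
    from .restraints import (AngleRestraint, CentroidRestraint,
                             DistanceRestraint, PositionRestraint,
                             RestraintSet, TorsionRestraint)
    rs = RestraintSet()
    for kw, tok in key.get("restraints", []):
        if kw == "restrain-position":
            rs.add(PositionRestraint(int(tok[0]) - 1,
                                     np.array([float(t) for t in tok[1:4]]),
                                     float(tok[4])))
        elif kw == "restrain-distance":
            rs.add(DistanceRestraint(int(tok[0]) - 1, int(tok[1]) - 1,
                                     float(tok[2]), float(tok[3])))
        elif kw == "restrain-angle":
            rs.add(AngleRestraint(int(tok[0]) - 1, int(tok[1]) - 1,
                                  int(tok[2]) - 1,
                                  math.radians(float(tok[3])), float(tok[4])))
        elif kw == "restrain-torsion":
            rs.add(TorsionRestraint(*(int(t) - 1 for t in tok[:4]),
                                    math.radians(float(tok[4])),
                                    float(tok[5])))
        elif kw == "restrain-group":
            rs.add(CentroidRestraint(
                [int(t) - 1 for t in tok[4:]],
                np.array([float(t) for t in tok[:3]]), float(tok[3])))
        else:
            raise ParseError(f"unknown restraint keyword '{kw}'")
    return rs if rs.items else None
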