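"""Harmonic restraints: position, distance, angle, torsion, and mass-weighted
centroid (group) restraints.  Energy convention k·Δ² (no ½), matching the
bonded terms."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bonded import angle_energy_forces


class RestraintSpecError(ValueError):
    pass


@dataclass
class PositionRestraint:
    atom: int
    target: np.ndarray
    k: float


@dataclass
class DistanceRestraint:
    i: int
    j: int
    r0: float
    k: float


@dataclass
class AngleRestraint:
    i: int
    j: int
    k_atom: int
    theta0: float              # radians
    k: float


@dataclass
class TorsionRestraint:
    i: int
    j: int
    k_atom: int
    l: int
    phi0: float                # radians
    k: float


@dataclass
class CentroidRestraint:
    """Mass-weighted centre of a group restrained to a target point."""
    atoms: Sequence[int]
    target: np.ndarray
    k: float


@dataclass
class RestraintSet:
    items: list = field(default_factory=list)

    def add(self, r):
        if isinstance(r, CentroidRestraint) and len(r.atoms) == 0:
            raise RestraintSpecError("empty restraint group")
        self.items.append(r)
        return self

    def energy_forces(self, positions, box, masses=None):
        n = positions.shape[0]
        F = np.zeros((n, 3))
        e = 0.0
        for r in self.items:
            if isinstance(r, PositionRestraint):
                d = positions[r.atom] - np.asarray(r.target, dtype=float)
                e += r.k * float(d @ d)
                F[r.atom] -= 2.0 * r.k * d
            elif isinstance(r, DistanceRestraint):
                dr = box.minimum_image(positions[r.i] - positions[r.j])
                dist = float(np.linalg.norm(dr))
                delta = dist - r.r0
                e += r.k * delta**2
                g = 2.0 * r.k * delta * dr / max(dist, 1e-12)
                F[r.i] -= g
                F[r.j] += g
            elif isinstance(r, AngleRestraint):
                ea, Fa = angle_energy_forces(
                    positions, box,
                    np.array([[r.i, r.j, r.k_atom]]),
                    np.array([r.k]), np.array([r.theta0]))
                e += ea
                F += Fa
            elif isinstance(r, TorsionRestraint):
                # true harmonic in the wrapped dihedral difference
                b1 = box.minimum_image(positions[r.j] - positions[r.i])
                b2 = box.minimum_image(positions[r.k_atom] - positions[r.j])
                b3 = box.minimum_image(positions[r.l] - positions[r.k_atom])
                n1 = np.cross(b1, b2)
                n2 = np.cross(b2, b3)
                nb2 = np.linalg.norm(b2)
                m1 = np.cross(n1, b2 / nb2)
                phi = float(np.arctan2(m1 @ n2, n1 @ n2))
                dphi = np.arctan2(np.sin(phi - r.phi0), np.cos(phi - r.phi0))
                e += r.k * dphi**2
                dEdphi = 2.0 * r.k * dphi
                dphi_di = nb2 * n1 / (n1 @ n1)
                dphi_dl = -nb2 * n2 / (n2 @ n2)
                s1 = (b1 @ b2) / nb2**2
                s2 = (b3 @ b2) / nb2**2
                dphi_dj = -(1.0 + s1) * dphi_di + s2 * dphi_dl
                dphi_dk = s1 * dphi_di - (1.0 + s2) * dphi_dl
                for at, d in ((r.i, dphi_di), (r.j, dphi_dj),
                              (r.k_atom, dphi_dk), (r.l, dphi_dl)):
                    F[at] -= dEdphi * d
            elif isinstance(r, CentroidRestraint):
                atoms = np.asarray(r.atoms, dtype=int)
                m = (np.ones(len(atoms)) if masses is None
                     else np.asarray(masses)[atoms])
                w = m / m.sum()
                com = np.sum(w[:, None] * positions[atoms], axis=0)
                d = com - np.asarray(r.target, dtype=float)
                e += r.k * float(d @ d)
                F[atoms] -= 2.0 * r.k * np.outer(w, d)
            else:
                raise RestraintSpecError(f"unknown restraint {type(r)}")
        return e, F


def restraints(positions, box, spec: RestraintSet, masses=None):
    """Spec surface: evaluate a restraint set."""
    return spec.energy_forces(positions, box, masses)
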