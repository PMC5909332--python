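"""Core domain types: simulation box, particle system, force-field parameters,
and the run configuration.

A :class:`ParticleSystem` couples geometry (positions, box) with topology
(bonds) and per-site parameter assignments (atom type/class ids that resolve
in a :class:`ForceFieldParams`).  All container types are plain dataclasses
over numpy arrays; validation lives in ``validate()`` methods so readers can
construct partially-filled skeletons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class TopologyError(ValueError):
    """Inconsistent connectivity (bad bond indices, isolated hydrogens, ...)."""


class ParameterError(ValueError):
    """Invalid or missing force-field parameter records."""


class ConfigurationError(ValueError):
    """A run setting is inconsistent with the system (cutoffs vs box, ...)."""


@dataclass
class SimulationBox:
    """Orthorhombic periodic (or open) simulation cell, edges in Å."""

    a: float
    b: float
    c: float
    periodic: bool = True

    @classmethod
    def cubic(cls, edge: float, periodic: bool = True) -> "SimulationBox":
        return cls(edge, edge, edge, periodic)

    @classmethod
    def open_boundary(cls) -> "SimulationBox":
        return cls(math.inf, math.inf, math.inf, periodic=False)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @property
    def volume(self) -> float:
        return self.a * self.b * self.c

    @property
    def min_edge(self) -> float:
        return min(self.a, self.b, self.c)

    def validate(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ConfigurationError("box edges must be positive")

    def check_cutoff(self, cutoff: float) -> None:
        """Enforce the minimum-image requirement cutoff <= min(edge)/2."""
        if self.periodic and cutoff > self.min_edge / 2.0 + 1e-9:
            raise ConfigurationError(
                f"cutoff {cutoff:.3f} Å exceeds half the smallest box edge "
                f"({self.min_edge / 2.0:.3f} Å)"
            )

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap positions into [0, L) along periodic axes."""
        if not self.periodic:
            return np.asarray(positions, dtype=float)
        return np.mod(positions, self.lengths)

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Minimum-image convention applied to displacement vectors."""
        if not self.periodic:
            return dr
        L = self.lengths
        return dr - L * np.round(dr / L)


@dataclass
class ParticleSystem:
    """Sites, masses, topology and parameter assignments of one system."""

    positions: np.ndarray            # (N, 3) Å
    masses: np.ndarray               # (N,) amu
    atom_types: np.ndarray           # (N,) int, resolve multipole/polarize records
    atom_classes: np.ndarray         # (N,) int, resolve vdw/bonded records
    bonds: np.ndarray                # (nb, 2) 0-based site indices, i < j
    box: SimulationBox
    names: Optional[list] = None
    polarization_groups: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.atom_types = np.asarray(self.atom_types, dtype=np.int64)
        self.atom_classes = np.asarray(self.atom_classes, dtype=np.int64)
        self.bonds = (np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
                      if np.size(self.bonds) else np.zeros((0, 2), dtype=np.int64))
        if self.names is None:
            self.names = [f"X{i+1}" for i in range(self.n_sites)]

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        n = self.n_sites
        if not np.all(np.isfinite(self.positions)):
            raise TopologyError("non-finite positions")
        if self.bonds.size:
            if self.bonds.min() < 0 or self.bonds.max() >= n:
                bad = int(self.bonds.max())
                raise TopologyError(f"bond references atom {bad + 1} of {n}")
            if np.any(self.bonds[:, 0] == self.bonds[:, 1]):
                raise TopologyError("self-bond in connectivity")
        self.box.validate()

    def neighbors_of(self) -> list:
        """Adjacency list from the bond table."""
        adj = [[] for _ in range(self.n_sites)]
        for i, j in self.bonds:
            adj[int(i)].append(int(j))
            adj[int(j)].append(int(i))
        return adj

    def copy(self) -> "ParticleSystem":
        return replace(
            self,
            positions=self.positions.copy(),
            masses=self.masses.copy(),
            bonds=self.bonds.copy(),
            box=replace(self.box),
            names=list(self.names),
        )


# ---------------------------------------------------------------------------
# Force-field parameter records
# ---------------------------------------------------------------------------

FRAME_NONE = 0
FRAME_Z_THEN_X = 1
FRAME_BISECTOR = 2

_FRAME_TAGS = {"none": FRAME_NONE, "z-then-x": FRAME_Z_THEN_X,
               "zthenx": FRAME_Z_THEN_X, "bisector": FRAME_BISECTOR}


@dataclass
class VdwRecord:
    r_min: float                  # Å (σ for LJ form)
    epsilon: float                # kcal/mol
    form: str = "buffered-14-7"   # or "lj"


@dataclass
class MultipoleRecord:
    """Local-frame permanent multipole of one atom type.

    ``quadrupole`` is the traceless Cartesian quadrupole in e·Å²; the energy
    convention is U = (1/3) Q : ∇∇φ (see docs/methods.md), applied
    consistently in every kernel.
    """

    charge: float                 # e
    dipole: np.ndarray            # (3,) e·Å, local frame
    quadrupole: np.ndarray        # (3,3) e·Å², traceless symmetric, local frame
    frame: int = FRAME_NONE       # FRAME_* constant
    z_type: int = -1              # atom type of the z-axis anchor (-1: bonded pick)
    x_type: int = -1

    def __post_init__(self):
        self.dipole = np.asarray(self.dipole, dtype=float)
        self.quadrupole = np.asarray(self.quadrupole, dtype=float)

    def detrace(self):
        tr = np.trace(self.quadrupole) / 3.0
        self.quadrupole = 0.5 * (self.quadrupole + self.quadrupole.T)
        self.quadrupole -= tr * np.eye(3)


@dataclass
class PolarizeRecord:
    alpha: float                  # Å³ isotropic polarizability
    thole: float                  # dimensionless damping factor
    group_types: tuple = ()       # bonded types in the same polarization group


@dataclass
class BondRecord:
    k: float                      # kcal/mol/Å², energy = k (r - r0)^2
    r0: float


@dataclass
class AngleRecord:
    k: float                      # kcal/mol/rad², energy = k (θ - θ0)^2
    theta0: float                 # degrees in files, stored radians


@dataclass
class TorsionRecord:
    amplitudes: tuple             # (V1, V2, V3) kcal/mol
    phases: tuple = (0.0, math.pi, 0.0)


#: Default AMOEBA-convention masking factors for permanent multipole
#: interactions between 1-2 ... 1-5 bonded neighbours.  The same single table
#: also masks the permanent-field right-hand side of the polarization
#: equations (documented convention; overridable in the parameter file).
DEFAULT_MPOLE_SCALES = {2: 0.0, 3: 0.0, 4: 0.4, 5: 0.8}

#: vdW masking (1-2 and 1-3 excluded, 1-4 onward full).
DEFAULT_VDW_SCALES = {2: 0.0, 3: 0.0, 4: 1.0, 5: 1.0}


@dataclass
class ForceFieldParams:
    """Typed parameter tables keyed by atom type/class ids."""

    vdw: dict = field(default_factory=dict)            # class -> VdwRecord
    multipoles: dict = field(default_factory=dict)     # type -> MultipoleRecord
    polarize: dict = field(default_factory=dict)       # type -> PolarizeRecord
    bonds: dict = field(default_factory=dict)          # (c1,c2) sorted -> BondRecord
    angles: dict = field(default_factory=dict)         # (c1,c2,c3) -> AngleRecord
    torsions: dict = field(default_factory=dict)       # (c1..c4) -> TorsionRecord
    masses: dict = field(default_factory=dict)         # class -> amu
    names: dict = field(default_factory=dict)          # class -> str
    mpole_scales: dict = field(default_factory=lambda: dict(DEFAULT_MPOLE_SCALES))
    vdw_scales: dict = field(default_factory=lambda: dict(DEFAULT_VDW_SCALES))

    def validate(self) -> None:
        for t, rec in self.multipoles.items():
            tr = abs(float(np.trace(rec.quadrupole)))
            if tr > 1e-10:
                raise ParameterError(f"multipole type {t}: quadrupole trace {tr:.3e}")
        for t, rec in self.polarize.items():
            if rec.alpha < 0:
                raise ParameterError(f"polarize type {t}: negative alpha")
        for c, rec in self.vdw.items():
            if rec.epsilon < 0 or rec.r_min <= 0:
                raise ParameterError(f"vdw class {c}: invalid r_min/epsilon")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class MDConfig:
    """Run settings; defaults follow the reference production setup
    (7.0 Å real-space Ewald cutoff, 9.0 Å vdW cutoff with no long-range
    correction, PCG with diagonal preconditioner converged to 1e-5 D)."""

    integrator: str = "verlet"            # verlet | beeman | respa
    dt: float = 1.0                       # outer timestep, fs
    inner_steps: int = 2                  # RESPA substeps (bonded at dt/inner)
    thermostat: Optional[str] = None      # bussi | berendsen | None
    temperature: float = 298.0            # K
    tau_t: float = 100.0                  # fs
    barostat: Optional[str] = None        # berendsen | None
    pressure: float = 1.0                 # atm
    tau_p: float = 1000.0                 # fs

    polar_solver: str = "pcg"             # jor | pcg | jidiis | tcg1 | tcg2
    polar_eps: float = 1e-5               # D, RMS change per iteration
    polar_maxiter: int = 100
    preconditioner: str = "diagonal"      # none | diagonal
    tcg_peek: bool = False
    aspc_order: int = 6
    polar_guess: str = "direct"           # zero | direct | aspc

    ewald_cutoff: float = 7.0             # Å real-space
    ewald_beta: Optional[float] = None    # Å⁻¹; None -> from tail criterion
    pme_grid: Optional[tuple] = None      # (K1,K2,K3); None -> auto
    bspline_order: int = 5
    vdw_cutoff: float = 9.0               # Å

    neighbor_skin: float = 1.0            # Å
    seed: int = 0

    def resolved_beta(self) -> float:
        from .electrostatics import beta_from_cutoff
        if self.ewald_beta is not None:
            return self.ewald_beta
        return beta_from_cutoff(self.ewald_cutoff)
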