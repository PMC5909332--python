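# polarmd

Desk-scale molecular dynamics with a polarizable point-dipole force field,
written for method development and validation rather than production speed.
It implements, in plain Python/NumPy with a few numba kernels:

- **Multipolar electrostatics** — atomic charges, dipoles and traceless
  quadrupoles in local molecular frames, evaluated under periodic boundary
  conditions with smooth particle-mesh Ewald (SPME): erfc-screened real-space
  kernels, B-spline charge/dipole/quadrupole spreading, FFT convolution with
  the reciprocal influence function, and analytic forces *and* frame-anchor
  torque forces.
- **Induced-dipole polarization** — per-site isotropic polarizabilities with
  Thole exponential damping. The linear system **T μ = E** is solved by JOR,
  preconditioned conjugate gradient (PCG), Jacobi/DIIS, or the *truncated*
  conjugate gradient (TCG1/TCG2): a fixed-cost, non-iterative Krylov
  approximation equal to the k-step PCG iterate, with exact analytic forces
  obtained by reverse-mode differentiation of the Krylov recursion. An
  always-stable predictor-corrector (ASPC) seeds the iterative solvers along
  MD trajectories.
- **Short-range terms** — Halgren buffered 14-7 and Lennard-Jones van der
  Waals (with softcore alchemical variants), harmonic bonds/angles, Fourier
  torsions, and harmonic position/distance/angle/torsion/centroid restraints.
- **Dynamics** — velocity Verlet, Beeman, and multi-timestep r-RESPA
  integrators; Bussi and Berendsen thermostats; Berendsen barostat; hydrogen
  mass repartitioning; an L-BFGS minimizer.
- **Domain decomposition (serial emulation)** — linked-cell O(N) neighbour
  search, 3D spatial blocks with midpoint pair ownership, halo-import
  accounting and iterative load rebalancing, for studying the algorithmic
  structure of spatially decomposed polarizable MD without MPI.
- **Free energies** — λ schedules, softcore vdW / scaled-electrostatics
  coupling, the Bennett acceptance ratio (BAR) estimator with asymptotic
  errors, the 1 M ↔ 1 atm standard-state correction, and a three-leg
  hydration-cycle driver (discharge in vacuum, vdW coupling in solvent,
  recharge in solvent).

The model energy is

```
U = U_bonded + U_vdW + U_perm + U_pol,
U_perm = ½ Σ_{ij} M_i T_ij M_j          (Ewald: real + reciprocal + self)
U_pol  = ½ μᵀT μ − μᵀE,   with T μ = E at convergence,
```

where `M_i = (q_i, μ_i, Θ_i)` are permanent multipoles rotated from local
frames, `E` is the Thole-damped permanent field at polarizable sites, and `μ`
the induced dipoles. Induced-dipole convergence is reported as the RMS change
per iteration in debye.

## Worked example

```bash
polarmd genbox --n 64 --out water.xyz          # 64-water box + parameters
cat > run.key <<EOF
parameters water.prm
ewald-cutoff 6.0
vdw-cutoff 6.0
pme-grid 30
bspline-order 6
polar-solver pcg
polar-eps 1e-5
EOF
polarmd analyze water.xyz -k run.key
```

prints the energy breakdown of the generated box (values for seed 0):

```
term                    kcal/mol
angle                   0.000000
background              0.000000
bond                    0.000000
polarization          -74.572099
real                 3027.327108
recip                 443.263665
self                -3477.766147
vdw                    76.951518
total                  -4.795955
```

`real + recip + self` is the permanent Ewald electrostatics (the large self
term is the usual constant Gaussian self-interaction removal), `polarization`
the many-body induction energy from the converged dipoles, and the bonded/vdW
rows the short-range terms. `polarmd dynamic water.xyz 1000 -k run.key` runs
1 ps of MD with per-interval energy, temperature and solver-iteration logs;
`polarmd minimize`, and `polarmd bar` (BAR from cross-energy tables) complete
the command set.

The same functionality is available as a library:

```python
from polarmd.fixtures import gen_water_box
from polarmd.engine import Engine
from polarmd.system import MDConfig

system, params = gen_water_box(n_waters=64, seed=0)
cfg = MDConfig(polar_solver="tcg2", ewald_cutoff=6.0, vdw_cutoff=6.0,
               pme_grid=(30, 30, 30), bspline_order=6)
out = Engine(system, params, cfg).evaluate(system.positions)
print(out["components"], out["dipoles"].iterations)
```

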