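# Methods

This note records the model conventions, the numerical choices, and the
limits of what the bundled synthetic systems can demonstrate.

## Units and conventions

Internal units are Å, kcal·mol⁻¹, elementary charge, amu and fs, with the
Tinker electrostatic conversion constant k_C = 332.063713 kcal·Å·mol⁻¹·e⁻²
and k_B = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹. Dipoles are stored in e·Å and
reported in debye (1 e·Å = 4.803205 D). Newton's law uses
a[Å·fs⁻²] = 4.184×10⁻⁴·F/m.

Quadrupoles are traceless Cartesian tensors Θ (e·Å²) with the energy
convention **U = (1/3) Θ : ∇∇φ**, applied consistently in the real-space
kernels, the mesh spreading/interpolation, the Ewald self terms and the
torque route; parameter readers de-trace input tensors (with a warning) so
the convention cannot drift. Harmonic bonded terms and restraints use the
**k·Δ² convention (no ½)**; this is stated here because a silent factor of
two between codes is a classic source of disagreement.

## Electrostatics

Real-space interactions are generated from radial kernel coefficients
B_l with B_{l+1} = −(1/r) dB_l/dr (bare: (2l−1)!!/r^(2l+1); Ewald: the erfc
recursion). Masking and Thole damping enter as per-l multipliers on the
*bare* part of each listed pair, C_l = B_l^erfc + (m_l − 1)B_l^bare, so the
reciprocal sum can always include all pairs at full strength.

- **Splitting parameter.** β is derived from the requirement that the
  discarded real-space tail be < 10⁻⁸ of a unit-charge pair energy at the
  cutoff: β = erfc⁻¹(10⁻⁸)/r_c (≈ 0.58 Å⁻¹ at the default 7.0 Å cutoff).
  User-overridable.
- **Masking.** One scale table (AMOEBA-style 0/0/0.4/0.8 for 1-2…1-5
  neighbours) masks both the permanent–permanent energy and the permanent
  field driving polarization. Induced–induced pairs are unmasked but
  Thole-damped. vdW masking excludes 1-2/1-3.
- **Thole damping** uses the exponential smearing factors λ₃…λ₉ with
  u = r/(α_i α_j)^(1/6) and the pairwise damping factor min(a_i, a_j);
  it applies to every dipole-involving kernel (permanent field at
  polarizable sites, induced–induced interactions) and not to the
  permanent–permanent energy.
- **Boundary.** Tinfoil (conducting): the k = 0 term is dropped and no
  surface-dipole term is added. Non-neutral cells get the uniform-background
  correction −k_C πQ²/(2β²V).
- **SPME.** Cardinal B-splines of order n (default 5; n ≥ 5 is required with
  quadrupoles because forces need third derivatives of the interpolated
  potential; order 8 in accuracy studies). Default grid sizes are the
  smallest 2-3-5-smooth integers covering max(1, 2.8β) points/Å — enough to
  resolve the reciprocal Gaussian to ~10⁻⁸ — and never below 2n. The
  published benchmark-box grids are available as named presets, since no
  single points-per-Å rule reproduces all of them. Grid accumulation is
  atom-major and sequential, so evaluations are bitwise reproducible.
- **Net mesh force.** Interpolated SPME leaves a small spurious net force
  (it is not exactly translation invariant). The engine reports the raw
  analytic gradient — finite-difference audits match it to ~10⁻⁹ — and the
  MD runner removes the mean force so linear momentum is conserved exactly.

## Polarization

Isotropic site polarizabilities only. T v = v/α − F(v), with F(v) the
Thole-damped Ewald field of the dipole set v (real pairs + mesh + the
4β³/3√π self term). Solvers: JOR (ω = 0.7), PCG with diagonal (α)
preconditioner, Jacobi/DIIS (window 6), and TCG1/TCG2. The convergence
metric is the RMS over the 3N components of the per-iteration change in μ,
in debye (the PCG monitor uses the preconditioned residual, which is exactly
the next Jacobi change); default tolerance 10⁻⁵ D.

The polarization energy is always evaluated as the functional
E_pol = k_C(½μᵀTμ − μᵀE), which is valid for truncated dipoles and reduces
to −½k_C μᵀE at convergence. Forces:

- converged solvers use the variational (Hellmann–Feynman) gradient — the
  neglected term is proportional to the residual and is far below the 10⁻⁶
  relative force tolerance at tolerances of 10⁻⁸ D;
- TCG uses exact reverse-mode differentiation of the k-step preconditioned
  CG recursion. The adjoint reduces to a handful of contraction primitives —
  position gradients of u·T·v for dipole-set pairs and of v·E against the
  permanent multipoles — each evaluated with the same real-space kernels and
  mesh as the forward model, so the TCG force is the exact analytic gradient
  of the TCG energy (verified to ~10⁻⁹ by central differences). An optional
  Jacobi "peek" refinement step is supported (default off) and is included
  in the adjoint.

ASPC uses Kolafa predictor coefficients generated from
A_j = (−1)^(j+1) j·C(2k, k−j)/C(2k−2, k−1) for a history of length k
(default 6; they sum to one and reproduce linear drifts), with corrector
mixing ω = (k+2)/(2k+3) applied to the stored history. The history is kept
across thermostat rescalings (dipoles track positions, not velocities) and
invalidated on alchemical-state changes.

## Short-range terms

Halgren buffered 14-7 with δ = 0.07, γ = 0.12; cubic-mean/HHG combining
rules (Lorentz–Berthelot for LJ). The form passes through −ε at r_min by
construction; its true stationary point lies a fraction of a percent inside
r_min, which the tests acknowledge rather than hide. A quintic switching
window over the outer 10 % of the vdW cutoff makes the truncation C² — this
is a smoothness device, not a long-range correction (no mean-field tail term
is added). The softcore form inserts α_sc(1−λ)² (α_sc = 0.7) into both
buffered denominators and scales by λ⁵, so λ = 1 reproduces the plain
potential bitwise and λ = 0 vanishes while staying finite at r = 0.

## Dynamics

Velocity Verlet, Beeman (first step bootstrapped from the current
acceleration), and impulse r-RESPA with bonded forces on the inner loop and
all non-bonded forces (including polarization) on the outer step; with one
substep and a merged provider RESPA is bit-equivalent to Verlet. H-mass
repartitioning moves mass from each hydrogen's unique heavy partner
(default target 3.024 amu = 3×H). The Bussi thermostat is the standard
stochastic velocity rescale with a seeded generator; Berendsen thermostat
and barostat are weak-coupling. The barostat's instantaneous pressure uses a
central-difference volume derivative of the *full* potential under isotropic
strain (strain 5×10⁻⁴) — this includes the reciprocal-space contribution
exactly, at the cost of two extra energy evaluations per barostat step,
which at desk scale is cheaper to maintain than a per-term analytic virial.
Initial velocities are Maxwell–Boltzmann with the net momentum removed.
L-BFGS minimisation is terminated on the RMS gradient.

## Free energies

Reduced-unit bookkeeping (u = E/kT). BAR solves the implicit Bennett
equation by bracketed bisection (brentq) plus a Newton polish to 10⁻¹⁰, with
the standard asymptotic variance; with no reverse samples it falls back to
exponential averaging. The default schedule has 21 evenly spaced λ per
channel and the cycle order discharge (vacuum) → vdW coupling → recharge
(solvent). The 1 M ↔ 1 atm standard-state correction is RT·ln(V_molar/1 L);
at 298.15 K this evaluates to ≈ 1.89 kcal·mol⁻¹, close to — but not exactly —
the conventionally quoted 1.87; both the computed closed form and the
convention are surfaced rather than silently reconciled.

## Synthetic systems and what the tests show

The bundled 3-site water model uses AMOEBA-like illustrative constants
(charges/dipoles/quadrupoles with bisector and z-then-x frames, Thole-damped
polarizabilities, buffered 14-7 sites, harmonic flexible bonds); it is *not*
a published parameterization, and no claim is made about reproducing real
water properties. Boxes are lattice-placed with seeded random orientations
and jitter at 0.997 g/cm³, then briefly thermalised — they probe numerical
correctness (conservation, reversibility, solver behaviour, estimator
recovery), not liquid-state structure. Random multipole gases (seeded,
non-overlapping, de-traced quadrupoles, optional neutrality) exist purely
for oracle comparisons.

Problem sizes used by the validation protocol: the conservation runs use the
64-water box (192 atoms) for 5 ps at 1 fs with 6.0 Å cutoffs — the box edge
(≈12.4 Å) caps the cutoffs below the 7.0/9.0 Å production defaults, which
remain the `MDConfig` defaults for normal-sized boxes — with a 30³ mesh at
order 6; ASPC utility uses a 32-water box over 1 ps; solver oracles use
30-site gases (dense T is built column-by-column only at this scale);
splitting-invariance and mesh-oracle checks use 50-site gases. The
reversibility run uses a zero neighbour-list skin so the force field is a
pure function of positions.

## Known limitations

Orthorhombic boxes only; serial execution (the decomposition module emulates
ownership/halo geometry, it does not message-pass); isotropic
polarizabilities; no charge-penetration corrections; no anharmonic
bond/angle cross terms; the exact "dual Thole" variant is not implemented
(single-parameter Thole only); SPME is not exactly translation invariant
(mesh error, quantified in the tests); hydration-cycle sampling at desk
scale is too short for converged solvation free energies of real solutes —
the driver is exercised on solutes whose exact answer is known (zero
coupling) and on synthetic BAR problems.
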