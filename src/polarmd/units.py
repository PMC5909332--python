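"""Unit system used throughout the package.

Internal units follow the Tinker convention:

========  =======================
length    Å (angstrom)
energy    kcal·mol⁻¹
charge    e (elementary charge)
mass      amu
time      fs (dynamics only)
========  =======================

Electrostatic energies carry the Coulomb conversion constant
``COULOMB = 332.063713`` kcal·Å·mol⁻¹·e⁻², so two unit charges 1 Å apart
interact with exactly that energy.  Induced-dipole convergence criteria are
reported in debye (1 e·Å = 4.803205 D).
"""

import math

#: Coulomb constant, kcal·Å·mol⁻¹·e⁻².
COULOMB = 332.063713

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹.
BOLTZMANN = 1.987204e-3

#: 1 e·Å expressed in debye.
DEBYE_PER_EA = 4.803205

#: Conversion for Newton's second law: a[Å·fs⁻²] = MD_ACCEL * F[kcal·mol⁻¹·Å⁻¹] / m[amu].
#: Numerically 4.184e-4 (1 kcal = 4184 J exactly, SI Avogadro/amu).
MD_ACCEL = 4.184e-4

#: Molar gas constant in kcal·mol⁻¹·K⁻¹ (alias of BOLTZMANN on a molar basis).
GAS_CONSTANT = BOLTZMANN

#: Molar volume of an ideal gas at 1 atm, 298.15 K, in litres (used by the
#: 1 M ↔ 1 atm standard-state correction).
MOLAR_VOLUME_298 = 24.465


def ea_to_debye(x):
    """Convert a dipole (or RMS of dipole components) from e·Å to debye."""
    return x * DEBYE_PER_EA


def debye_to_ea(x):
    """Convert from debye to e·Å."""
    return x / DEBYE_PER_EA


def kinetic_temperature(kinetic_energy, ndof):
    """Instantaneous temperature (K) from kinetic energy (kcal/mol)."""
    if ndof <= 0:
        return 0.0
    return 2.0 * kinetic_energy / (ndof * BOLTZMANN)


def maxwell_sigma(temperature, mass):
    """Std-dev of one velocity component (Å/fs) at ``temperature`` for ``mass`` amu."""
    return math.sqrt(MD_ACCEL * BOLTZMANN * temperature / mass)
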