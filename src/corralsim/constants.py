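"""Physical constants and the unit system.

corralsim works in an AKMA-like unit system: lengths in Angstrom (A),
energies in kcal/mol, masses in amu, charges in elementary charges (e),
time in picoseconds.  In these units an acceleration is obtained from a
force (kcal/mol/A) divided by a mass (amu) times ``ACCEL_CONVERSION``.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Coulomb constant k_e in kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0636

#: Boltzmann constant in kcal/(mol*K).
BOLTZMANN_KCAL = 0.0019872041

#: 1 kcal/mol expressed in amu*A^2/ps^2 (energy -> kinetic units).
KCAL_TO_AKMA = 418.4

#: Acceleration conversion: (kcal/mol/A) / amu -> A/ps^2.
ACCEL_CONVERSION = KCAL_TO_AKMA

#: Avogadro-based conversion used for ionic strength: mol/L -> ions/A^3.
MOLAR_TO_PER_A3 = 6.02214076e-4

#: Relative dielectric of water screening PIP2-PIP2 pair interactions.
PAIR_DIELECTRIC = 80.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the constants entering the energy function."""

    coulomb_constant: float = COULOMB_CONSTANT
    boltzmann: float = BOLTZMANN_KCAL
    water_dielectric_for_pairs: float = PAIR_DIELECTRIC


CONSTANTS = PhysicalConstants()


def thermal_energy(temperature: float) -> float:
    """k_B*T in kcal/mol."""
    return BOLTZMANN_KCAL * temperature


def debye_kappa(salt_molar: float, dielectric: float, temperature: float) -> float:
    """Inverse Debye screening length (1/A) of a 1:1 salt solution.

    kappa^2 = 8*pi*k_e*I / (eps * k_B*T) with the ionic strength I
    expressed as a number density of elementary charges (ions/A^3).
    At 150 mM, eps=80 and 300 K this gives a screening length of ~8 A.
    """
    import math

    if salt_molar < 0:
        raise ValueError("salt concentration must be non-negative")
    if salt_molar == 0:
        return 0.0
    ionic = salt_molar * MOLAR_TO_PER_A3
    kappa2 = 8.0 * math.pi * COULOMB_CONSTANT * ionic / (
        dielectric * BOLTZMANN_KCAL * temperature
    )
    return math.sqrt(kappa2)


def diffusion_constant_cm2_per_s(temperature: float, mass: float, friction: float) -> float:
    """Einstein diffusion constant D = k_B*T/(m*gamma) in cm^2/s.

    temperature in K, mass in amu, friction in 1/ps.  The AKMA value
    (A^2/ps) is converted via 1 A^2/ps = 1e-4 cm^2/s.
    """
    if friction <= 0 or mass <= 0:
        raise ValueError("mass and friction must be positive")
    d_akma = thermal_energy(temperature) * KCAL_TO_AKMA / (mass * friction)
    return d_akma * 1e-4


def diffusion_constant_A2_per_ps(temperature: float, mass: float, friction: float) -> float:
    """Einstein diffusion constant in A^2/ps."""
    return diffusion_constant_cm2_per_s(temperature, mass, friction) * 1e4
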