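"""Physical constants and unit conversions (CODATA 2018).

Internal unit system: energies in eV, lengths in Å, masses in amu,
temperatures in K.  Vibrational frequencies are reported in cm⁻¹ but
carried internally in "natural" units sqrt(eV / (amu·Å²)) where the
harmonic identity λ = κ·Δq² needs no conversion factor.
"""

import math

HBAR_EV_S = 6.582119569e-16       # reduced Planck constant, eV·s
KB_EV_K = 8.617333262e-5          # Boltzmann constant, eV/K
E_CHARGE_C = 1.602176634e-19      # elementary charge, C (= J per eV)
AMU_KG = 1.66053906660e-27        # atomic mass unit, kg
C_CM_S = 2.99792458e10            # speed of light, cm/s
ANGSTROM_M = 1e-10
ANGSTROM_CM = 1e-8

# ħ·(2πc·1 cm⁻¹) in eV: photon energy of a 1 cm⁻¹ mode.
EV_PER_WAVENUMBER = 1.239841984332e-4

# 1 sqrt(eV/(amu·Å²)) expressed in cm⁻¹:
#   ω [rad/s] = sqrt(E_CHARGE/AMU) / 1e-10 * sqrt(κ) ;  ν̃ = ω / (2πc)
WAVENUMBER_PER_NATURAL = (
    math.sqrt(E_CHARGE_C / AMU_KG) / ANGSTROM_M / (2.0 * math.pi * C_CM_S)
)


def thermal_energy_ev(temperature: float) -> float:
    """k_B·T in eV (≈ 25.9 meV at 300 K)."""
    return KB_EV_K * temperature


def wavenumber_to_natural(omega_cm: float) -> float:
    """cm⁻¹ → sqrt(eV/(amu·Å²))."""
    return omega_cm / WAVENUMBER_PER_NATURAL


def natural_to_wavenumber(omega_nat: float) -> float:
    """sqrt(eV/(amu·Å²)) → cm⁻¹."""
    return omega_nat * WAVENUMBER_PER_NATURAL


def mode_quantum_ev(omega_cm: float) -> float:
    """Vibrational quantum ħω in eV for a mode frequency in cm⁻¹."""
    return omega_cm * EV_PER_WAVENUMBER
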