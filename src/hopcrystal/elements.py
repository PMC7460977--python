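"""Element data used for bond detection, contacts and mass-weighting."""

# Covalent radii (Å), Cordero et al. consensus values for the organic set.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

# Bondi van der Waals radii (Å).
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

# Standard atomic weights (amu).
ATOMIC_MASSES = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "Br": 79.904, "I": 126.904,
}

BOND_TOLERANCE = 0.4  # Å added to the covalent-radius sum


def covalent_radius(symbol: str) -> float:
    try:
        return COVALENT_RADII[symbol]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {symbol!r}")


def vdw_radius(symbol: str) -> float:
    try:
        return VDW_RADII[symbol]
    except KeyError:
        raise KeyError(f"no van der Waals radius tabulated for element {symbol!r}")


def atomic_mass(symbol: str) -> float:
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element {symbol!r}")
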