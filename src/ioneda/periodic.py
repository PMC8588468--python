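"""Element data and physical constants shared across the pipeline.

Coordinates are carried in angstrom everywhere and converted to bohr only
inside the quantum-mechanical layers.
"""

from __future__ import annotations

# unit conversions
BOHR_PER_ANGSTROM = 1.8897261255
HARTREE_TO_KCAL = 627.5095
AU_TO_DEBYE = 2.541746
# Coulomb constant in kcal/mol * angstrom / e^2
COULOMB_KCAL_ANGSTROM = 332.0637

SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe",
]

Z_OF = {s: z for z, s in enumerate(SYMBOLS) if z > 0}

# atomic masses (u), enough for the species handled here
MASS = {
    "H": 1.008, "He": 4.0026, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "S": 32.06, "Cl": 35.45, "K": 39.098,
    "Br": 79.904, "I": 126.904,
}

# Slater's empirical atomic radii (angstrom), used for the Becke
# size adjustments.  Hydrogen is Slater's 0.25 A, not Becke's 0.35 A variant.
SLATER_RADII = {
    "H": 0.25, "C": 0.70, "N": 0.65, "O": 0.60, "F": 0.50,
    "S": 1.00, "Cl": 1.00, "Br": 1.15, "I": 1.40,
}

# Bondi van der Waals radii (angstrom), used for dispersion damping ranges
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}


def symbol_of(z: int) -> str:
    return SYMBOLS[z]


def z_of(symbol: str) -> int:
    try:
        return Z_OF[symbol.capitalize() if len(symbol) > 1 else symbol.upper()]
    except KeyError:
        raise KeyError(f"unknown element symbol {symbol!r}") from None


def mass_of(symbol: str) -> float:
    return MASS[symbol]
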