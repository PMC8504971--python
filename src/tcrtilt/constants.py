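"""Physical constants and atomic masses shared across the package.

Units policy: lengths in nm, angles in degrees at module surfaces (the force
model converts to radians internally), energies in pN*nm, temperatures in K.
RMSD values are reported in Angstrom, labelled as such.
"""

# Boltzmann constant in pN*nm/K; kB*T at 303 K is ~4.183 pN*nm.
KB = 0.0138065

DEFAULT_TEMPERATURE = 303.0  # K, the production-simulation temperature

# EC-complex extension along the tilt axis used by the force-tilt model (nm).
DEFAULT_EC_EXTENSION = 13.0

ANGSTROM_PER_NM = 10.0

# Standard atomic masses (u). COM computations are mass-weighted over all
# atoms of a selection, including hydrogens, unless switched off.
ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.973762,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.0983,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
    "SE": 78.971,
}

HYDROGEN_ELEMENTS = frozenset({"H", "D"})


def atomic_mass(element: str) -> float:
    """Mass of an element symbol (case-insensitive); unknown symbols raise."""
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise ValueError(f"no atomic mass tabulated for element {element!r}") from None
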