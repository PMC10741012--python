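"""Physical and chemical constants used throughout the package.

Monoisotopic atomic masses are the IUPAC/CODATA values for the most abundant
isotope; residue masses are derived from elemental formulas rather than being
hard-coded, so every peptide mass in the package traces back to this one table.
"""

from __future__ import annotations

import re

# Monoisotopic atomic masses (Da), most abundant isotope.
ATOMIC_MONOISOTOPIC: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
}

#: Mass of a proton (Da), used for m/z arithmetic.
PROTON_MASS = 1.007276

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula such as ``"C6H7NO2"``."""
    mass = 0.0
    consumed = 0
    for element, count in _FORMULA_RE.findall(formula):
        if not element:
            continue
        if element not in ATOMIC_MONOISOTOPIC:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        mass += ATOMIC_MONOISOTOPIC[element] * (int(count) if count else 1)
        consumed += len(element) + len(count)
    if consumed != len(formula):
        raise ValueError(f"could not parse formula {formula!r}")
    return mass


# Elemental formulas of amino-acid residues (the chain-internal form, i.e.
# minus one water relative to the free amino acid).
RESIDUE_FORMULAS: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

RESIDUE_MONOISOTOPIC: dict[str, float] = {
    aa: formula_mass(f) for aa, f in RESIDUE_FORMULAS.items()
}

WATER_MASS = formula_mass("H2O")

#: Mass added to a cysteine thiol by N-ethylmaleimide (Michael addition).
NEM_DELTA = formula_mass("C6H7NO2")
#: Mass added by carboxymethylation with sodium iodoacetate.
CAM_DELTA = formula_mass("C2H2O2")

# Boltzmann constant in kcal/(mol K) and the thermal energy at 300 K, the
# temperature at which bond stiffness kappa_SS = kB*T / sigma^2 is reported.
KB_KCAL_PER_MOL_K = 0.0019872041
KBT_300K = KB_KCAL_PER_MOL_K * 300.0  # 0.596161 kcal/mol

# Bondi van der Waals radii (Angstrom) for solvent-accessibility calculations.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}

#: Default water-probe radius for SASA (Angstrom).
DEFAULT_PROBE_RADIUS = 1.4
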