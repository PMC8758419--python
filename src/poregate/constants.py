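"""Physical constants and unit conventions.

Coordinates are Angstrom throughout; energies are stored in kJ/mol with
kcal/mol available as an output conversion (kT at 300 K = 2.4943 kJ/mol =
0.5961 kcal/mol).
"""

#: Boltzmann constant x Avogadro, kJ/(mol K)
KB_KJ_MOL_K = 8.3145e-3

#: Gas constant, J/(mol K)
R_J_MOL_K = 8.3145

#: kJ per kcal
KJ_PER_KCAL = 4.184

#: Coulomb prefactor in MD units, kJ nm / (mol e^2)
COULOMB_PREFACTOR = 138.935

#: van der Waals radii by element, Angstrom (CHAP-like defaults)
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}
#: fallback radius for elements not in the table, Angstrom
VDW_DEFAULT = 1.70

#: ambient-water-like bulk number density, nm^-3
BULK_WATER_DENSITY = 33.4

#: residue names recognised as water
WATER_RESNAMES = frozenset({"HOH", "SOL", "TIP3", "TIP3P", "WAT", "TIP4"})


def kt(temperature: float) -> float:
    """Thermal energy kT in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KJ_MOL_K * temperature


def vdw_radius(element: str) -> float:
    """Van der Waals radius (Angstrom) for an element symbol."""
    return VDW_RADII.get(element.upper().strip(), VDW_DEFAULT)
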