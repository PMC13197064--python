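"""Unit conversions between measurement (g/L) and model (mM) scales.

The kinetic model runs in mM because the Michaelis constants are in mM;
measurements come in g/L.  Levan is tracked in fructosyl-monomer
equivalents (one unit = one anhydrofructose residue in the polymer).
"""

from __future__ import annotations

# molar masses, g/mol
MW_SUCROSE = 342.30
MW_GLUCOSE = 180.16
MW_FRUCTOSE = 180.16
#: anhydrofructose residue mass inside the levan chain
MW_LEVAN_MONOMER = 162.14

#: molar masses per model species (biomass is carried in gDW/L and not converted)
SPECIES_MW = {
    "sucrose": MW_SUCROSE,
    "glucose": MW_GLUCOSE,
    "fructose": MW_FRUCTOSE,
    "levan": MW_LEVAN_MONOMER,
}

#: canonical measured species order used in CSV I/O and objectives
MEASURED_SPECIES = ("biomass", "sucrose", "glucose", "fructose", "levan")


def g_per_l_to_mm(value, species: str):
    """Convert g/L to mM for a named species ('sucrose', 'glucose', 'fructose', 'levan')."""
    return value * 1000.0 / SPECIES_MW[species]


def mm_to_g_per_l(value, species: str):
    """Convert mM back to g/L for a named species."""
    return value * SPECIES_MW[species] / 1000.0
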