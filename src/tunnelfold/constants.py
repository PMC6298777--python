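"""Physical constants and unit conversions.

Internal force/length convention: piconewtons and angstroms for the kinetic
model; reduced units (energy in epsilon, length in angstrom) for the
structure-based simulations, with a configurable epsilon in kcal/mol bridging
the two.
"""

# Boltzmann constant in pN*A/K (1.380649e-23 J/K; 1 pN*A = 1e-22 J)
KB_PN_ANGSTROM_PER_K = 0.1380649

# 1 kcal/mol/A expressed in pN
KCAL_PER_MOL_PER_ANGSTROM_IN_PN = 69.4786

# Boltzmann constant in kcal/mol/K (for reduced <-> physical temperature maps)
KB_KCAL_PER_MOL_K = 1.987204259e-3


def kBT(temperature_K: float) -> float:
    """Thermal energy in pN*A at the given absolute temperature."""
    return KB_PN_ANGSTROM_PER_K * temperature_K
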