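"""Physical constants and unit conventions.

Units are fixed throughout the package: lengths in Å, times in ns,
energies in kcal/mol, temperatures in K.
"""

#: Boltzmann constant, kcal/mol/K
KB = 1.9872041e-3

#: Default water probe radius for SASA, Å
PROBE_RADIUS = 1.4

#: Bondi-style van der Waals radii (Å), overridable wherever radii are assigned
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "NA": 2.27,
    "K": 2.75,
    "BR": 1.85,
    "I": 1.98,
}

#: fallback radius for unknown elements, Å
DEFAULT_RADIUS = 1.70
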