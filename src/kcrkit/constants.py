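"""Physical constants used throughout the electrophysiology calculations."""

FARADAY = 96485.0  # C/mol
GAS_CONSTANT = 8.314  # J/(K*mol)
DEFAULT_TEMPERATURE_K = 298.0

#: Ion names accepted in solution definitions. Divalents (Ca, Mg) and the
#: organic cation guanidinium (Gu) are carried for bookkeeping only; the
#: GHK quotient uses K, Na and Cl exclusively.
KNOWN_IONS = frozenset({"K", "Na", "Cl", "Cs", "Li", "Gu", "Ca", "Mg"})
MONOVALENT_CATIONS = ("K", "Na")
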