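"""Physical constants and unit conventions.

Units are fixed package-wide: energies in kJ/mol, lengths in nm, times in ps,
temperatures in K.  Nearest-neighbor source tables are kcal-denominated and
converted at 4.184 kJ/kcal.
"""

#: Boltzmann constant in kJ/(mol K)
KB = 0.0083144621

#: kcal -> kJ conversion
KCAL_TO_KJ = 4.184


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature in K."""
    return KB * temperature
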