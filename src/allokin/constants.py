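"""Physical constants (SI unless noted)."""

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Boltzmann-factor helper: R in kJ mol^-1 K^-1 for energies in kJ/mol.
R_KJ = R_GAS / 1000.0

#: Default simulation temperature, K (physiological; heating target of the
#: source simulations).
DEFAULT_TEMPERATURE = 310.0

#: Surface-tension coefficient for the nonpolar solvation term
#: dG_SA = GAMMA_SASA * dSASA, kJ mol^-1 A^-2.
GAMMA_SASA = 0.02267
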