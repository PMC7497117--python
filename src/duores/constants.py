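"""Physical constants in GROMACS-style units (nm, ps, kJ/mol, K, amu, e)."""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083144621

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
F_COULOMB = 138.935458

#: Standard-state volume of one molecule at 1 M, nm^3
STANDARD_VOLUME = 1.661

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 298.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    return KB * temperature
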