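"""Physical constants — single source of truth for the whole package.

Units follow biophysical convention: energies in kcal/mol, temperatures in
kelvin, rate constants in M^-1 s^-1 / s^-1, concentrations in mol/L.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Boltzmann constant over Planck constant, s^-1 K^-1 (k_B*T/h is the
#: Eyring frequency factor once multiplied by T).
KB_OVER_H = 1.380649e-23 / 6.62607015e-34

#: Reference temperature for "at 25 degC" quantities, K.
T_REF = 298.15

#: Coulomb constant, kcal mol^-1 Angstrom e^-2.
COULOMB_KCAL = 332.0637

#: Default solvent-mimicking relative dielectric constant.
DIELECTRIC_DEFAULT = 80.0
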