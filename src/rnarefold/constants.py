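"""Physical constants and unit helpers.

Internally everything is SI (J, mol, K, s, L, M). Reports convert to
kJ/mol, degrees Celsius, micromolar and 1e-3 / s at the boundary.
"""

#: Gas constant, J/(mol K). The value used throughout the analysis.
R = 8.314

#: Boltzmann constant, J/K (CODATA).
K_B = 1.380649e-23

#: Planck constant, J s (CODATA).
H_PLANCK = 6.62607015e-34

#: Reference temperature for reported free energies, K (25 degrees C).
T_REF = 298.15


def celsius_to_kelvin(t_celsius):
    return t_celsius + 273.15


def kelvin_to_celsius(t_kelvin):
    return t_kelvin - 273.15
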