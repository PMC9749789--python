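"""Physical constants used throughout the package (SI units)."""

#: Molar gas constant, J/(mol K)
R_GAS = 8.314462618

#: Boltzmann constant, J/K
K_BOLTZMANN = 1.380649e-23

#: Default temperature: cells imaged at 37 degrees C, in kelvin
T_CELL = 310.15
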