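"""Physical constants, in the kcal/mol unit system used throughout.

Public interfaces take energies in kcal/mol; conversion to eV happens
only inside the tunneling rate law, which is calibrated in eV.
"""

#: kcal/mol per eV (CODATA-consistent to the precision the rate law needs).
KCAL_PER_EV = 23.061

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 0.0019872

#: Gas constant equals KB_KCAL on a per-mole energy scale.
R_KCAL = KB_KCAL

#: Faraday constant expressed as kcal/mol per volt (numerically KCAL_PER_EV).
F_KCAL_PER_V = KCAL_PER_EV

#: Boltzmann constant, J/K (for the Eyring prefactor).
KB_J = 1.380649e-23

#: Planck constant, J·s.
H_J = 6.62607015e-34

#: Default temperature for condensed-phase rate estimates, K.
T_DEFAULT = 298.15
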