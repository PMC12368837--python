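"""Physical constants (CODATA 2018) used across the simulator."""

BOLTZMANN = 1.380649e-23        # J/K
GAS_CONSTANT = 8.314462618      # J/(mol K)
DALTON = 1.66053906660e-27      # kg
ELEMENTARY_CHARGE = 1.602176634e-19  # C
AVOGADRO = 6.02214076e23        # 1/mol

ELECTRON_MASS_DA = 5.48579909065e-4   # Da
PROTON_MASS_DA = 1.007276466621      # Da
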