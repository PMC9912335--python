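"""Physical constants (SI) used across the package."""

ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23             # J/K
AVOGADRO = 6.02214076e23             # 1/mol
FARADAY = ELEMENTARY_CHARGE * AVOGADRO  # C/mol
GAS_CONSTANT = BOLTZMANN * AVOGADRO     # J/(mol K)
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

NM = 1e-9  # metres per nanometre
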