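"""Physical constants in the unit system used throughout: Å, kcal/mol, e, amu, ps, K."""

import math

#: Coulomb constant, kcal·Å/(mol·e²) — Amber convention.
K_E = 332.0636

#: Boltzmann constant, kcal/(mol·K).
K_B = 0.0019872041

#: Boltzmann constant, J/K (SI, for the Schlitter prefactor).
K_B_SI = 1.380649e-23

#: Reduced Planck constant, J·s.
HBAR_SI = 1.054571817e-34

#: Atomic mass unit, kg.
AMU_KG = 1.66053906660e-27

#: Å² in m².
A2_M2 = 1.0e-20

#: Euler's number squared (appears in the Schlitter upper-bound formula).
E_EULER_SQ = math.e ** 2

#: Default analysis temperature, K (replica at which the dimer trajectory is analysed).
DEFAULT_TEMPERATURE = 305.0
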