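"""Physical constants and unit conversions.

Internal units follow the GROMACS convention: length nm, mass amu (g/mol),
energy kJ/mol, time ps.  In this system 1 amu·nm²·ps⁻² = 1 kJ/mol exactly,
so mode frequencies ω = √(k/m) come out directly in rad/ps.
"""

import math

#: Boltzmann constant, kJ·mol⁻¹·K⁻¹ (CODATA 2018, exact SI definition).
KB = 8.314462618e-3

#: Reduced Planck constant, kJ·mol⁻¹·ps.
#: ħ = 1.054571817e-34 J·s × N_A / 1000 × 1e12 ps/s.
HBAR = 1.054571817e-34 * 6.02214076e23 * 1e12 / 1000.0

#: Avogadro constant, mol⁻¹.
NA = 6.02214076e23

#: Conversion: 1 kJ·mol⁻¹·nm⁻¹ in pN (≈ 1.661 pN).
PN_PER_KJ_MOL_NM = 1000.0 / NA / 1e-9 * 1e12

#: kcal per kJ.
KCAL_PER_KJ = 1.0 / 4.184

#: Coulomb prefactor 1/(4πε₀) in kJ·mol⁻¹·nm·e⁻² (MD convention).
COULOMB_KE = 138.935458

#: B-factor prefactor: B = (8π²/3)·RMSF² with RMSF in Å.
BFACTOR_PREFACTOR = 8.0 * math.pi**2 / 3.0
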