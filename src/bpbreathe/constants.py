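"""Physical constants (CODATA 2018) and unit conversions.

Internal unit system: lengths in Å, times in ns (trajectories) or ps
(sampler), energies in kcal/mol, masses in amu, temperatures in K,
angles in degrees.
"""

# SI
KB_SI = 1.380649e-23        # J/K
HBAR_SI = 1.054571817e-34   # J·s
AMU_KG = 1.66053906660e-27  # kg
ANGSTROM_M = 1.0e-10        # m

# molar gas constant, the per-mole Boltzmann constant
R_CAL = 1.987204258640832       # cal·mol⁻¹·K⁻¹
KB_KCAL = R_CAL / 1000.0        # kcal·mol⁻¹·K⁻¹

# Coulomb constant in the CHARMM convention
COULOMB_KCAL = 332.0636         # kcal·Å·mol⁻¹·e⁻²

# standard atomic weights (amu) for the elements this package touches
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "F": 18.998, "NA": 22.990, "MG": 24.305, "CL": 35.45,
    "K": 39.098, "CA": 40.078, "FE": 55.845, "ZN": 65.38, "BR": 79.904,
    "I": 126.904,
}
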