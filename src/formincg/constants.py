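"""Physical constants and lookup tables.

Repo-wide unit system: lengths in angstrom (A), energies in kcal/mol,
time in fs for integration (trajectory timestamps in ps), masses in amu,
charges in units of the elementary charge e, temperatures in kelvin.
"""

from __future__ import annotations

# Boltzmann constant, kcal mol^-1 K^-1
KB = 0.0019872041

# Coulomb prefactor k_e = 1/(4 pi eps_0), kcal A mol^-1 e^-2
KE = 332.0636

# 1 kcal/mol expressed in amu A^2 fs^-2 (the "MD" energy unit for this
# unit system); divides forces in kcal mol^-1 A^-1 to get accelerations
# in A fs^-2 when further divided by mass in amu.
KCAL_PER_MOL_IN_MD_UNITS = 4.184e-4

# Average residue masses (amu), standard amino acids.
RESIDUE_MASSES = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09,
    "CYS": 103.14, "GLN": 128.13, "GLU": 129.12, "GLY": 57.05,
    "HIS": 137.14, "ILE": 113.16, "LEU": 113.16, "LYS": 128.17,
    "MET": 131.19, "PHE": 147.18, "PRO": 97.12, "SER": 87.08,
    "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}
DEFAULT_RESIDUE_MASS = 110.0

# Formal side-chain charges at pH 7 (His neutral by default; termini
# handled separately if requested).
RESIDUE_CHARGES = {
    "ASP": -1.0, "GLU": -1.0, "LYS": +1.0, "ARG": +1.0, "HIS": 0.0,
}

# Van der Waals radii by element (A), used for buried-surface-area work.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "MG": 1.73,
    "K": 2.75, "NA": 2.27, "CA": 2.31, "ZN": 1.39, "FE": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

# Side-chain atoms participating in salt bridges.
BASIC_NITROGEN_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
HIS_NITROGEN_ATOMS = ("ND1", "NE2")  # counted only if His is flagged protonated
ACIDIC_OXYGEN_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
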