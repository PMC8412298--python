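"""Model constants: amino-acid alphabet, bead masses, idealised geometry.

The model represents each residue by four interaction sites (beads):
backbone nitrogen N, alpha carbon CA, carbonyl carbon C, and the sidechain
heavy-atom centroid SC.  Masses are unitless model masses: backbone masses
fold the bonded hydrogens/oxygen into the heavy atom (N=15 includes the
amide H, CA=13 includes H-alpha, C=28 includes the carbonyl O), and the
sidechain mass is the summed mass of the all-atom sidechain including its
hydrogens.  Glycine has no heavy sidechain atoms and carries an artificial
SC bead of mass 10.
"""

from __future__ import annotations

import numpy as np

# One-letter codes, alphabetical; index into this string is the amino-acid
# type index used throughout.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = 20

BEAD_NAMES = ("N", "CA", "C", "SC")
N_BEADS = 4
N_ATOM_TYPES = N_AA * N_BEADS  # 80

# Backbone bead masses (unitless; bonded H / carbonyl O folded in).
MASS_N = 15.0
MASS_CA = 13.0
MASS_C = 28.0

# Sidechain masses: sum of sidechain atom masses including hydrogens,
# integer atomic masses (C=12, N=14, O=16, S=32, H=1). Glycine is special.
SC_MASS = {
    "A": 15.0,   # CH3
    "C": 47.0,   # CH2-SH
    "D": 59.0,   # CH2-COOH (C2H3O2)
    "E": 73.0,   # (CH2)2-COOH
    "F": 91.0,   # CH2-C6H5
    "G": 10.0,   # no heavy sidechain atoms; artificial mass
    "H": 81.0,   # CH2-imidazole (C4H5N2)
    "I": 57.0,   # C4H9
    "K": 72.0,   # (CH2)4-NH2
    "L": 57.0,   # C4H9
    "M": 75.0,   # (CH2)2-S-CH3
    "N": 58.0,   # CH2-CO-NH2
    "P": 42.0,   # C3H6 ring
    "Q": 72.0,   # (CH2)2-CO-NH2
    "R": 100.0,  # (CH2)3-NH-C(NH2)2 (C4H10N3)
    "S": 31.0,   # CH2-OH
    "T": 45.0,   # CH(OH)-CH3
    "V": 43.0,   # C3H7
    "W": 130.0,  # CH2-indole (C9H8N)
    "Y": 107.0,  # CH2-C6H4-OH
}

# Idealised distance (Angstrom) from CA to the sidechain centroid, used by
# the internal peptide builder when no learned potential supplies a minimum.
# Typical values from all-atom geometry of the common rotamers.
CA_SC_DISTANCE = {
    "A": 1.53, "C": 2.07, "D": 2.44, "E": 3.11, "F": 3.41,
    "G": 1.53, "H": 3.16, "I": 2.31, "K": 3.50, "L": 2.60,
    "M": 2.95, "N": 2.47, "P": 1.88, "Q": 3.09, "R": 4.11,
    "S": 1.90, "T": 1.93, "V": 1.97, "W": 3.86, "Y": 3.83,
}

# Ideal backbone internal coordinates for the builder (Engh-Huber-like).
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.0
ANGLE_C_N_CA = 122.0
# Tetrahedral angle from backbone neighbours to the pseudo-C-beta direction.
ANGLE_SC_TETRAHEDRAL = 110.4

# Background amino-acid composition of the PDB (fractions, sum to 1),
# used for drawing non-native residues in threading/design.
BACKGROUND_FREQS = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.054, "C": 0.014,
    "Q": 0.039, "E": 0.065, "G": 0.071, "H": 0.022, "I": 0.059,
    "L": 0.096, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.046,
    "S": 0.060, "T": 0.054, "V": 0.074, "W": 0.012, "Y": 0.034,
}

# Three-letter residue name to one-letter code, plus accepted substitutions.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified-residue mapping
    "MSE": "M",  # selenomethionine
}

SS_STATES = "HEC"
SS_INDEX = {s: i for i, s in enumerate(SS_STATES)}


def residue_masses(aa: str) -> np.ndarray:
    """Masses of the four beads (N, CA, C, SC) of one residue."""
    return np.array([MASS_N, MASS_CA, MASS_C, SC_MASS[aa]], dtype=float)


def background_vector() -> np.ndarray:
    """Background frequencies ordered by :data:`AMINO_ACIDS`, normalised."""
    v = np.array([BACKGROUND_FREQS[aa] for aa in AMINO_ACIDS], dtype=float)
    return v / v.sum()
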