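"""Chemical reference tables shared across the package.

All tables are module-level constants so that results are reproducible
bit-for-bit given the same tables.  Sources:

* average residue masses: standard amino-acid residue masses (average
  isotopic composition), as used for electrophoretic size prediction;
* maximum accessible surface areas: the theoretical Gly-X-Gly values of
  Tien et al. (2013), used to normalise SASA into relative solvent
  accessibility;
* van der Waals radii: Bondi (1964) element radii, used by the
  Shrake-Rupley solvent-accessibility calculation (heavy atoms only).
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Average (not monoisotopic) residue masses in Da; add one water for a peptide.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: Theoretical maximum ASA (A^2) of residue X: largest central-residue SASA
#: of a Gly-X-Gly tripeptide over a grid of extended conformations and chi1
#: rotamers, computed with this package's geometry, Bondi radii, probe 1.4 A
#: and 3840 sphere points (frozen output of
#: structure_features.reference_max_asa()).  Using maxima derived with the
#: same radii as the numerator keeps RSA calibrated; published tables built
#: with other radius sets shift RSA by ~10% systematically.
MAX_ASA = {
    "A": 116.9, "R": 252.8, "N": 174.4, "D": 172.9, "C": 153.3,
    "E": 201.0, "Q": 202.9, "G": 95.2, "H": 205.6, "I": 184.2,
    "L": 187.5, "K": 217.7, "M": 208.0, "F": 226.4, "P": 160.8,
    "S": 135.3, "T": 155.2, "W": 267.6, "Y": 244.0, "V": 163.8,
}

#: Published alternative: Tien et al. (2013) theoretical maxima (A^2),
#: selectable via compute_rsa(max_asa=TIEN_MAX_ASA).
TIEN_MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Bondi (1964) van der Waals radii in Angstrom, by element symbol.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}

#: Thresholds of the analysis, kept in one place.
BURIED_RSA_THRESHOLD = 0.07     # buried iff rsa < 7% of the reference maximum
CONTACT_DISTANCE = 8.0          # any-atom residue-residue contact cutoff (A)
DISORDER_HIGH = 0.8             # high-disorder window: every score >= 0.8
DISORDER_LOW = 0.2              # low-disorder window: every score <= 0.2
TERMINUS_LENGTH = 25            # first/last 25 residues define the terminus
WB_BAND_TOLERANCE = 0.2         # +-20% of predicted mass counts as in-range
MAX_IMMUNOGEN_LENGTH = 50       # immunogen-length inclusion filter
MIN_PROTEIN_LENGTH = 100        # protein-length inclusion filters
MAX_PROTEIN_LENGTH = 2000
SIGNIFICANCE_ALPHA = 0.05
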