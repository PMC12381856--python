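"""Bundled residue-level reference tables.

All tables are keyed by one-letter amino-acid code and cover the 20
standard residues.

``MAX_SASA_TIEN``
    Theoretical maximum solvent-accessible surface areas (Å²) of residue X
    in an extended Gly-X-Gly tripeptide, from Tien et al. (2013),
    PLoS ONE 8:e80635 ("theoretical" column).  Used to normalise absolute
    SASA to relative SASA (rASA = SASA / SASA_max).

``KYTE_DOOLITTLE`` / ``EISENBERG``
    Hydrophobicity scales: Kyte & Doolittle (1982) hydropathy and the
    Eisenberg et al. (1984) consensus scale.  Raw published values;
    min-max normalisation to [0, 1] is applied where sums across residues
    are compared.

``VDW_RADII``
    Van der Waals radii (Å) per element, Bondi (1964) set, used by the
    Shrake-Rupley SASA calculation.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Tien et al. 2013, theoretical maxima (Å²)
MAX_SASA_TIEN = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Kyte & Doolittle 1982 hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Eisenberg et al. 1984 consensus
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

HYDROPHOBICITY_SCALES = {
    "kyte-doolittle": KYTE_DOOLITTLE,
    "eisenberg": EISENBERG,
}

# Bondi 1964 van der Waals radii (Å); fallback used for unknown elements
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70


def normalized_scale(scale: dict[str, float]) -> dict[str, float]:
    """Min-max normalise a residue scale to [0, 1]."""
    lo = min(scale.values())
    hi = max(scale.values())
    return {aa: (v - lo) / (hi - lo) for aa, v in scale.items()}
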