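"""Shared amino-acid and atomic constant tables."""

from __future__ import annotations

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA1TO3 = {v: k for k, v in AA3TO1.items()}

# Common chemically modified residues mapped to their parent amino acid.
# Anything not listed here (and not standard) becomes 'X', which the
# sequence/structure mapper always flags as a mismatch.
NONSTANDARD_PARENT = {
    "MSE": "M",  # selenomethionine
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "CSO": "C",  # S-hydroxycysteine
    "CME": "C",
    "CSD": "C",
    "OCS": "C",
    "MLY": "K",  # methyllysine
    "M3L": "K",
    "KCX": "K",
    "LLP": "K",
    "HYP": "P",  # hydroxyproline
    "PCA": "Q",  # pyroglutamate
    "FME": "M",
    "SAC": "S",
    "AIB": "A",
    "ABA": "A",
}


def three_to_one(resname: str) -> str:
    """Map a 3-letter residue name to its 1-letter code ('X' if unknown)."""
    resname = resname.strip().upper()
    if resname in AA3TO1:
        return AA3TO1[resname]
    return NONSTANDARD_PARENT.get(resname, "X")


# Bondi (1964) van der Waals radii in Angstrom, heavy atoms of proteins.
BONDI_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.8

# Theoretical maximum accessible surface areas (A^2) per residue type,
# Tien et al. 2013, used to normalize ASA into relative solvent accessibility.
MAX_ASA_TIEN2013 = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
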