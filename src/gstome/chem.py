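"""Chemical reference data shared across modules.

Only the four heavy elements found in protein residues (N, C, O, S) are
needed by the elastic-network and contact machinery; ligands transplanted
into the G site are built from the same elements.
"""

from __future__ import annotations

# Standard atomic weights, Da (IUPAC 2021, rounded)
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

HEAVY_ELEMENTS = frozenset({"N", "C", "O", "S"})

# van der Waals radii used for solvent accessibility, Å (Bondi)
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

# Water residue names dropped on parsing
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# Glutathione-like cofactor codes kept as ligands by default (reduced GSH,
# oxidized GSSG, sulfonate GTS, S-hexyl GTX, and the GSF analogue).
DEFAULT_LIGAND_NAMES = frozenset({"GSH", "GDS", "GSF", "GTX", "GTS", "GTT", "GSM"})

AA3_TO_1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

AMINO_ACIDS = frozenset(AA3_TO_1.values())

POSITIVE_AA = frozenset({"K", "R"})
NEGATIVE_AA = frozenset({"D", "E"})

# Atom defining the chi1 dihedral N-CA-CB-X for each residue type.
# Gly and Ala have no chi1.
CHI1_GAMMA_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}


def atomic_mass(element: str) -> float:
    """Mass in Da for an element symbol; raises KeyError for unknown symbols."""
    return ATOMIC_MASSES[element.upper()]
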