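"""Physical constants, atomic masses and residue bookkeeping tables.

Units follow the AKMA-like convention used throughout the package:
energies in kcal/mol, lengths in Angstrom, masses in amu, times in ps.
"""

from __future__ import annotations

# Boltzmann constant, kcal/mol/K
KB = 0.0019872

# 1 kcal/mol expressed in amu * Angstrom^2 / ps^2
# (1 kcal/mol = 4184 J/mol; 1 amu A^2/ps^2 = 10 J/mol)
KCAL_PER_AMU_A2_PS2 = 418.4

# Atomic masses (amu) for the elements occurring in standard amino acids.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "SE": 78.971,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

# Backbone atom names for the two-bead mapping: everything else is side chain.
# Backbone hydrogens (when present) belong to the backbone bead.
BACKBONE_ATOMS = frozenset({
    "N", "CA", "C", "O", "OXT", "OT1", "OT2",
    "H", "HN", "HA", "HA1", "HA2", "HA3",
    "H1", "H2", "H3", "HT1", "HT2", "HT3",
})

# Expected number of side-chain heavy atoms per residue type (CB and beyond).
# Used to flag truncated residues before placing the side-chain bead.
SIDECHAIN_HEAVY_COUNT = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2,
    "GLN": 5, "GLU": 5, "GLY": 0, "HIS": 6, "ILE": 4,
    "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7, "PRO": 3,
    "SER": 2, "THR": 3, "TRP": 10, "TYR": 8, "VAL": 3,
}


def element_mass(element: str) -> float:
    """Mass in amu for an element symbol; raises KeyError for exotic ones."""
    return ATOMIC_MASS[element.upper()]


def guess_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when the element column is blank.

    Handles leading digits ("1HB") and the standard amino-acid elements only.
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[:2].upper() in ("SE",) and len(stripped) >= 2:
        return "SE"
    return stripped[0].upper()
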