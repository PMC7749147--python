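"""Amino-acid chemistry tables: codes, bond templates, radii, hybridization.

Bond templates list heavy-atom bonds within each standard residue together
with a bond class: ``1`` for a freely rotatable single bond (five bars in the
body-bar network) and ``2`` for double / partial-double / delocalized bonds
whose dihedral is locked (six bars).  Peptide C-N bonds between residues are
added by the network builder and are treated as partial double bonds.
Hydrogen atoms are attached by name (see :func:`hydrogen_parent`).
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: non-standard residues remapped to a standard parent type (coordinates kept)
PARENT_RESIDUE = {
    "MSE": "MET",   # selenomethionine
    "HYP": "PRO",
    "SEC": "CYS",
    "CSO": "CYS",
    "PTR": "TYR",
    "SEP": "SER",
    "TPO": "THR",
}

STANDARD_RESIDUES = set(THREE_TO_ONE)

# Backbone bonds common to every residue.  C=O is a double bond; the
# C-terminal carboxylate O/OXT pair is delocalized, handled in the builder.
BACKBONE_BONDS = [
    ("N", "CA", 1),
    ("CA", "C", 1),
    ("C", "O", 2),
]

SIDECHAIN_BONDS = {
    "ALA": [("CA", "CB", 1)],
    "ARG": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
            ("CD", "NE", 1), ("NE", "CZ", 2), ("CZ", "NH1", 2),
            ("CZ", "NH2", 2)],
    "ASN": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2),
            ("CG", "ND2", 2)],
    "ASP": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2),
            ("CG", "OD2", 2)],
    "CYS": [("CA", "CB", 1), ("CB", "SG", 1)],
    "GLN": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
            ("CD", "OE1", 2), ("CD", "NE2", 2)],
    "GLU": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
            ("CD", "OE1", 2), ("CD", "OE2", 2)],
    "GLY": [],
    "HIS": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "ND1", 2),
            ("ND1", "CE1", 2), ("CE1", "NE2", 2), ("NE2", "CD2", 2),
            ("CD2", "CG", 2)],
    "ILE": [("CA", "CB", 1), ("CB", "CG1", 1), ("CG1", "CD1", 1),
            ("CB", "CG2", 1)],
    "LEU": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 1),
            ("CG", "CD2", 1)],
    "LYS": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
            ("CD", "CE", 1), ("CE", "NZ", 1)],
    "MET": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "SD", 1),
            ("SD", "CE", 1)],
    "PHE": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 2),
            ("CD1", "CE1", 2), ("CE1", "CZ", 2), ("CZ", "CE2", 2),
            ("CE2", "CD2", 2), ("CD2", "CG", 2)],
    "PRO": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
            ("CD", "N", 1)],
    "SER": [("CA", "CB", 1), ("CB", "OG", 1)],
    "THR": [("CA", "CB", 1), ("CB", "OG1", 1), ("CB", "CG2", 1)],
    "TRP": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 2),
            ("CD1", "NE1", 2), ("NE1", "CE2", 2), ("CE2", "CD2", 2),
            ("CD2", "CG", 2), ("CD2", "CE3", 2), ("CE3", "CZ3", 2),
            ("CZ3", "CH2", 2), ("CH2", "CZ2", 2), ("CZ2", "CE2", 2)],
    "TYR": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 2),
            ("CD1", "CE1", 2), ("CE1", "CZ", 2), ("CZ", "CE2", 2),
            ("CE2", "CD2", 2), ("CD2", "CG", 2), ("CZ", "OH", 1)],
    "VAL": [("CA", "CB", 1), ("CB", "CG1", 1), ("CB", "CG2", 1)],
}


def residue_bonds(restype: str) -> list[tuple[str, str, int]]:
    """Heavy-atom bond template (backbone + sidechain) for one residue type."""
    if restype not in SIDECHAIN_BONDS:
        raise KeyError(f"no bond template for residue type {restype!r}")
    return BACKBONE_BONDS + SIDECHAIN_BONDS[restype]


VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "SE": 1.90}


def hydrogen_parent(h_name: str, heavy_names: set[str]) -> str | None:
    """Resolve the heavy atom a hydrogen is bonded to, from PDBv3 names.

    ``H`` -> ``N``; otherwise the position code after the leading H is
    matched against heavy-atom names with their element letter stripped
    (``HB2`` -> ``CB``; ``HG`` -> ``OG``/``SG``; ``HH11`` -> ``NH1``).
    """
    if h_name in ("H", "H1", "H2", "H3", "HN"):
        return "N" if "N" in heavy_names else None
    if not h_name.startswith("H"):
        return None
    code = h_name[1:]
    for suffix in (code, code[:-1], code[:-2]):
        if not suffix:
            continue
        for heavy in heavy_names:
            if heavy[0] in "CNOS" and heavy[1:] == suffix:
                return heavy
    return None


def acceptor_hybridization(restype: str, atom_name: str) -> str:
    """Coarse sp2/sp3 classification of N/O/S hydrogen-bond partners."""
    if atom_name.startswith("S"):
        return "sp3"
    if atom_name in ("OG", "OG1"):
        return "sp3"
    if atom_name == "NZ":
        return "sp3"
    return "sp2"
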