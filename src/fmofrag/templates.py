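"""Residue topology templates.

Each amino-acid template lists the side-chain atoms as a tree rooted at CA
(``(name, element, parent_name)``) plus any ring-closing bonds.  The same
tables drive covalent-bond perception for named residues and atom placement
in the ideal-geometry peptide builder.

Histidine is stored in its Nδ (HD1) tautomer so that NE2 is available as a
metal donor; charge assignment is always re-derived from the hydrogens that
are actually present, so other tautomers parse fine.
"""

from __future__ import annotations

# --- side-chain trees --------------------------------------------------
# (atom name, element, parent atom name); parents must appear earlier or be
# backbone atoms (N, CA, C).

_SC = dict  # alias for readability

SIDECHAINS: dict[str, list[tuple[str, str, str]]] = {
    "GLY": [],
    "ALA": [("CB", "C", "CA"),
            ("HB1", "H", "CB"), ("HB2", "H", "CB"), ("HB3", "H", "CB")],
    "SER": [("CB", "C", "CA"), ("OG", "O", "CB"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"), ("HG", "H", "OG")],
    "CYS": [("CB", "C", "CA"), ("SG", "S", "CB"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"), ("HG", "H", "SG")],
    "THR": [("CB", "C", "CA"), ("OG1", "O", "CB"), ("CG2", "C", "CB"),
            ("HB", "H", "CB"), ("HG1", "H", "OG1"),
            ("HG21", "H", "CG2"), ("HG22", "H", "CG2"), ("HG23", "H", "CG2")],
    "VAL": [("CB", "C", "CA"), ("CG1", "C", "CB"), ("CG2", "C", "CB"),
            ("HB", "H", "CB"),
            ("HG11", "H", "CG1"), ("HG12", "H", "CG1"), ("HG13", "H", "CG1"),
            ("HG21", "H", "CG2"), ("HG22", "H", "CG2"), ("HG23", "H", "CG2")],
    "LEU": [("CB", "C", "CA"), ("CG", "C", "CB"),
            ("CD1", "C", "CG"), ("CD2", "C", "CG"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"), ("HG", "H", "CG"),
            ("HD11", "H", "CD1"), ("HD12", "H", "CD1"), ("HD13", "H", "CD1"),
            ("HD21", "H", "CD2"), ("HD22", "H", "CD2"), ("HD23", "H", "CD2")],
    "ILE": [("CB", "C", "CA"), ("CG1", "C", "CB"), ("CG2", "C", "CB"),
            ("CD1", "C", "CG1"),
            ("HB", "H", "CB"),
            ("HG12", "H", "CG1"), ("HG13", "H", "CG1"),
            ("HG21", "H", "CG2"), ("HG22", "H", "CG2"), ("HG23", "H", "CG2"),
            ("HD11", "H", "CD1"), ("HD12", "H", "CD1"), ("HD13", "H", "CD1")],
    "MET": [("CB", "C", "CA"), ("CG", "C", "CB"), ("SD", "S", "CG"),
            ("CE", "C", "SD"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"),
            ("HG2", "H", "CG"), ("HG3", "H", "CG"),
            ("HE1", "H", "CE"), ("HE2", "H", "CE"), ("HE3", "H", "CE")],
    "PRO": [("CB", "C", "CA"), ("CG", "C", "CB"), ("CD", "C", "CG"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"),
            ("HG2", "H", "CG"), ("HG3", "H", "CG"),
            ("HD2", "H", "CD"), ("HD3", "H", "CD")],
    "PHE": [("CB", "C", "CA"), ("CG", "C", "CB"),
            ("CD1", "C", "CG"), ("CD2", "C", "CG"),
            ("CE1", "C", "CD1"), ("CE2", "C", "CD2"), ("CZ", "C", "CE1"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"),
            ("HD1", "H", "CD1"), ("HD2", "H", "CD2"),
            ("HE1", "H", "CE1"), ("HE2", "H", "CE2"), ("HZ", "H", "CZ")],
    "TYR": [("CB", "C", "CA"), ("CG", "C", "CB"),
            ("CD1", "C", "CG"), ("CD2", "C", "CG"),
            ("CE1", "C", "CD1"), ("CE2", "C", "CD2"), ("CZ", "C", "CE1"),
            ("OH", "O", "CZ"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"),
            ("HD1", "H", "CD1"), ("HD2", "H", "CD2"),
            ("HE1", "H", "CE1"), ("HE2", "H", "CE2"), ("HH", "H", "OH")],
    "TRP": [("CB", "C", "CA"), ("CG", "C", "CB"),
            ("CD1", "C", "CG"), ("CD2", "C", "CG"),
            ("NE1", "N", "CD1"), ("CE2", "C", "NE1"), ("CE3", "C", "CD2"),
            ("CZ2", "C", "CE2"), ("CZ3", "C", "CE3"), ("CH2", "C", "CZ2"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"),
            ("HD1", "H", "CD1"), ("HE1", "H", "NE1"), ("HE3", "H", "CE3"),
            ("HZ2", "H", "CZ2"), ("HZ3", "H", "CZ3"), ("HH2", "H", "CH2")],
    "ASP": [("CB", "C", "CA"), ("CG", "C", "CB"),
            ("OD1", "O", "CG"), ("OD2", "O", "CG"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB")],
    "GLU": [("CB", "C", "CA"), ("CG", "C", "CB"), ("CD", "C", "CG"),
            ("OE1", "O", "CD"), ("OE2", "O", "CD"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"),
            ("HG2", "H", "CG"), ("HG3", "H", "CG")],
    "ASN": [("CB", "C", "CA"), ("CG", "C", "CB"),
            ("OD1", "O", "CG"), ("ND2", "N", "CG"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"),
            ("HD21", "H", "ND2"), ("HD22", "H", "ND2")],
    "GLN": [("CB", "C", "CA"), ("CG", "C", "CB"), ("CD", "C", "CG"),
            ("OE1", "O", "CD"), ("NE2", "N", "CD"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"),
            ("HG2", "H", "CG"), ("HG3", "H", "CG"),
            ("HE21", "H", "NE2"), ("HE22", "H", "NE2")],
    "LYS": [("CB", "C", "CA"), ("CG", "C", "CB"), ("CD", "C", "CG"),
            ("CE", "C", "CD"), ("NZ", "N", "CE"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"),
            ("HG2", "H", "CG"), ("HG3", "H", "CG"),
            ("HD2", "H", "CD"), ("HD3", "H", "CD"),
            ("HE2", "H", "CE"), ("HE3", "H", "CE"),
            ("HZ1", "H", "NZ"), ("HZ2", "H", "NZ"), ("HZ3", "H", "NZ")],
    "ARG": [("CB", "C", "CA"), ("CG", "C", "CB"), ("CD", "C", "CG"),
            ("NE", "N", "CD"), ("CZ", "C", "NE"),
            ("NH1", "N", "CZ"), ("NH2", "N", "CZ"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"),
            ("HG2", "H", "CG"), ("HG3", "H", "CG"),
            ("HD2", "H", "CD"), ("HD3", "H", "CD"), ("HE", "H", "NE"),
            ("HH11", "H", "NH1"), ("HH12", "H", "NH1"),
            ("HH21", "H", "NH2"), ("HH22", "H", "NH2")],
    "HIS": [("CB", "C", "CA"), ("CG", "C", "CB"),
            ("ND1", "N", "CG"), ("CD2", "C", "CG"),
            ("CE1", "C", "ND1"), ("NE2", "N", "CE1"),
            ("HB2", "H", "CB"), ("HB3", "H", "CB"),
            ("HD1", "H", "ND1"), ("HD2", "H", "CD2"), ("HE1", "H", "CE1")],
    # alpha-aminoisobutyric acid: two beta carbons, no HA
    "AIB": [("CB1", "C", "CA"), ("CB2", "C", "CA"),
            ("HB11", "H", "CB1"), ("HB12", "H", "CB1"), ("HB13", "H", "CB1"),
            ("HB21", "H", "CB2"), ("HB22", "H", "CB2"), ("HB23", "H", "CB2")],
}

#: Ring-closing bonds not expressible in the parent tree.
RING_BONDS: dict[str, list[tuple[str, str]]] = {
    "PRO": [("CD", "N")],
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "TRP": [("CE2", "CD2"), ("CH2", "CZ3")],
    "HIS": [("NE2", "CD2")],
}

#: PDB names of D-amino acids mapped to their L topology template.
D_RESIDUES: dict[str, str] = {
    "DAL": "ALA", "DAR": "ARG", "DSG": "ASN", "DAS": "ASP", "DCY": "CYS",
    "DGN": "GLN", "DGL": "GLU", "DHI": "HIS", "DIL": "ILE", "DLE": "LEU",
    "DLY": "LYS", "MED": "MET", "DPN": "PHE", "DPR": "PRO", "DSN": "SER",
    "DTH": "THR", "DTR": "TRP", "DTY": "TYR", "DVA": "VAL",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: One-letter codes for the peptide builder; lower case selects the
#: D-enantiomer (PDB D-residue name).  X = AIB (achiral).
ONE_LETTER: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "AIB",
}
_L_TO_D = {v: k for k, v in D_RESIDUES.items()}


def template_for(resname: str) -> str | None:
    """Return the L-template name for a residue name, or None if unknown."""
    name = resname.strip().upper()
    if name in SIDECHAINS:
        return name
    if name in D_RESIDUES:
        return D_RESIDUES[name]
    # common His tautomer/protonation variant names
    if name in {"HID", "HIE", "HIP", "HSD", "HSE", "HSP"}:
        return "HIS"
    return None


def is_d_residue(resname: str) -> bool:
    return resname.strip().upper() in D_RESIDUES


def d_name_for(template: str) -> str:
    """PDB residue name of the D-enantiomer of an L template."""
    try:
        return _L_TO_D[template]
    except KeyError:
        raise ValueError(f"no D-enantiomer residue name for {template}")


def template_bonds(resname: str,
                   n_terminal: bool = False,
                   c_terminal: bool = False) -> list[tuple[str, str]]:
    """All intra-residue bonds (by atom name) for a templated residue.

    Includes backbone bonds and every hydrogen the template knows about,
    plus terminal variants (H1/H2/H3, OXT, HXT).  Bonds whose atoms are
    absent from an actual residue are simply skipped by the caller.
    """
    tmpl = template_for(resname)
    if tmpl is None:
        raise KeyError(resname)
    bonds: list[tuple[str, str]] = [("N", "CA"), ("CA", "C"), ("C", "O")]
    # backbone hydrogens
    bonds += [("N", "H"), ("N", "H1"), ("N", "H2"), ("N", "H3"),
              ("CA", "HA"), ("CA", "HA2"), ("CA", "HA3"),
              ("C", "OXT"), ("OXT", "HXT")]
    for name, _el, parent in SIDECHAINS[tmpl]:
        bonds.append((parent, name))
    bonds += RING_BONDS.get(tmpl, [])
    return bonds
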