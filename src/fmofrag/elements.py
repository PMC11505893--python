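"""Element data used for bond perception and PDB element inference."""

from __future__ import annotations

# Covalent radii (Å), Cordero et al. consensus values, rounded.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "NA": 1.66, "MG": 1.41, "P": 1.07, "S": 1.05, "CL": 1.02,
    "K": 2.03, "CA": 1.76, "MN": 1.39, "FE": 1.32, "CO": 1.26,
    "NI": 1.24, "CU": 1.32, "ZN": 1.22, "SE": 1.20, "BR": 1.20, "I": 1.39,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26,
    "CO": 27, "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}

#: Elements treated as metal ions: never covalently bonded, only coordinated.
METALS = {"NA", "MG", "K", "CA", "MN", "FE", "CO", "NI", "CU", "ZN"}

#: Default formal charges for monoatomic ion residues when the PDB charge
#: column is absent.  Transition metals default to their common oxidation
#: state in biological structures.
ION_CHARGES = {"NA": 1, "K": 1, "MG": 2, "CA": 2, "ZN": 2, "MN": 2,
               "FE": 2, "CO": 2, "NI": 2, "CU": 2, "CL": -1, "BR": -1, "I": -1}

#: Two-letter element symbols recognized when inferring elements from PDB
#: atom names (the element column may be blank in older files).
TWO_LETTER = {"ZN", "FE", "MG", "NA", "CL", "CA", "MN", "CO", "NI", "CU",
              "BR", "SE"}

#: Donor elements for metal coordination.
DONOR_ELEMENTS = {"N", "O", "S"}


def normalize_element(symbol: str) -> str:
    """Return a canonical (upper-case) element symbol, or '' if unknown."""
    s = symbol.strip().upper()
    return s if s in COVALENT_RADII else ""


def infer_element(atom_name: str, resname: str, is_hetero: bool) -> str:
    """Infer the element from a PDB atom name.

    The leading alphabetic characters are used.  Two-letter symbols are
    accepted only from the curated list (so 'CA' in an amino acid is carbon,
    while 'CA' in a calcium-ion residue is calcium).
    """
    letters = "".join(ch for ch in atom_name if ch.isalpha()).upper()
    if not letters:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = letters[:2]
    if two in TWO_LETTER:
        # Metal/halide names clash with organic names (CA = C-alpha); only
        # accept the two-letter reading for single-atom hetero residues or
        # when the residue name itself is the symbol.
        if is_hetero and resname.strip().upper() in (two, two + "2", letters):
            return two
        if atom_name[:2].strip().upper() == two and len(atom_name.strip()) == 2 \
                and atom_name[0].isalpha() and is_hetero:
            return two
    one = letters[0]
    if one in COVALENT_RADII:
        return one
    if two in COVALENT_RADII:
        return two
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def covalent_cutoff(el_a: str, el_b: str, factor: float = 1.25) -> float:
    """Distance below which two atoms are considered covalently bonded."""
    return factor * (COVALENT_RADII[el_a] + COVALENT_RADII[el_b])
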