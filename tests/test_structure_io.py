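"""Structure I/O: PDB parsing, bond perception, residue sequencing."""

import numpy as np
import pytest

import fmofrag as ff
from fmofrag.structure import (PDBFormatError, StructureError, read_pdb,
                               residue_sequence, write_pdb)

MINIMAL = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
END
"""

ALTLOC = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
END
"""


def _read_text(tmp_path, text, name="x.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return read_pdb(p)


class TestReadPdb:
    def test_minimal_two_atoms_one_residue(self, tmp_path):
        st = _read_text(tmp_path, MINIMAL)
        assert len(st.atoms) == 2
        assert len(st.residues) == 1
        assert [a.element for a in st.atoms] == ["N", "C"]

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        st = _read_text(tmp_path, ALTLOC)
        assert len(st.atoms) == 2
        ca = st.residues[0].atom("CA")
        assert ca.altloc == "A"
        assert ca.coords[0] == pytest.approx(1.0)

    def test_d_histidine_classified(self, tmp_path):
        text = ("HETATM    1  N   DHI A  12       0.000   0.000   0.000"
                "  1.00  0.00           N\nEND\n")
        st = _read_text(tmp_path, text)
        assert st.residues[0].canonical_type == "D-amino"

    def test_unparseable_record_names_line(self, tmp_path):
        text = MINIMAL.replace("11.639", "xx.xxx")
        with pytest.raises(PDBFormatError, match="line 2"):
            _read_text(tmp_path, text)

    def test_duplicate_serial_rejected(self, tmp_path):
        text = MINIMAL.replace("ATOM      2  CA ", "ATOM      1  CA ")
        with pytest.raises(PDBFormatError, match="duplicate"):
            _read_text(tmp_path, text)

    def test_element_heuristics_zn_vs_calpha(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00\n"
            "HETATM    2 ZN    ZN A   2       5.000   0.000   0.000"
            "  1.00  0.00\nEND\n")
        st = _read_text(tmp_path, text)
        assert st.atoms[0].element == "C"
        assert st.atoms[1].element == "ZN"

    def test_charge_column_hint(self, tmp_path):
        text = ("HETATM    1 ZN    ZN A   1       0.000   0.000   0.000"
                "  1.00  0.00          ZN2+\nEND\n")
        st = _read_text(tmp_path, text)
        assert st.atoms[0].formal_charge_hint == 2


class TestWritePdb:
    @pytest.mark.parametrize("fixture_name",
                             ["ala3", "zn_peptide"])
    def test_roundtrip_identity(self, request, tmp_path, fixture_name):
        st = request.getfixturevalue(fixture_name)
        p = tmp_path / "rt.pdb"
        write_pdb(st, p)
        st2 = read_pdb(p)
        assert len(st2.atoms) == len(st.atoms)
        for a, b in zip(st.atoms, st2.atoms):
            assert (a.name, a.element, a.residue_key) == \
                (b.name, b.element, b.residue_key)
            assert np.abs(a.coords - b.coords).max() < 1.5e-3

    def test_conect_preserved(self, tmp_path, ligand_complex):
        st, serials = ligand_complex
        p = tmp_path / "lig.pdb"
        write_pdb(st, p)
        st2 = read_pdb(p)
        assert tuple(st2.conect_pairs[0]) == \
            (serials["SG"], serials["C1"])

    def test_long_atom_name_rejected(self, ala3, tmp_path):
        import copy
        st = copy.deepcopy(ala3)
        st.atoms[0].name = "HXT12"
        with pytest.raises(PDBFormatError, match="4-character"):
            write_pdb(st, tmp_path / "bad.pdb")

    def test_atom_count_limit(self, ala3, tmp_path):
        import copy
        st = copy.copy(ala3)
        st.atoms = list(ala3.atoms) * 4000  # > 99,999 entries
        with pytest.raises(PDBFormatError, match="99,999"):
            write_pdb(st, tmp_path / "big.pdb")


class TestPerceiveBonds:
    def test_linear_chain_has_n_minus_1_peptide_bonds(self, ala3):
        n_pep = _count_peptide_bonds(ala3)
        assert n_pep == 2

    def test_cyclic_chain_has_n_peptide_bonds(self, zn_peptide):
        assert _count_peptide_bonds(zn_peptide) == 24
        assert zn_peptide.chain_topology["A"] == "cyclic"

    def test_metal_never_bonded(self, zn_peptide, zn_atom):
        assert zn_peptide.bonds.degree(zn_atom.serial) == 0
        donors = [c for c in zn_peptide.coordination_candidates
                  if c[0] == zn_atom.serial]
        assert donors, "coordination candidates should be recorded"

    def test_deterministic(self, zn_peptide):
        edges1 = set(map(frozenset, zn_peptide.bonds.edges))
        st2 = ff.build_zn_cyclic_peptide()
        edges2 = set(map(frozenset, st2.bonds.edges))
        assert edges1 == edges2

    def test_missing_backbone_atom_errors(self, tmp_path):
        # alanine with hydrogens but no C
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      3  HA  ALA A   1       1.800   1.000   0.000"
            "  1.00  0.00           H\nEND\n")
        st = read_pdb(_write(tmp_path, text))
        with pytest.raises(StructureError, match="missing backbone"):
            ff.perceive_bonds(st)

    def test_unprotonated_polymer_rejected(self, tmp_path):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1       2.000   1.400   0.000"
            "  1.00  0.00           C\nEND\n")
        st = read_pdb(_write(tmp_path, text))
        with pytest.raises(StructureError, match="hydrogens"):
            ff.perceive_bonds(st)


class TestResidueSequence:
    def test_linear_tripeptide_has_termini(self, ala3):
        chains = residue_sequence(ala3)
        pep = chains[0]
        assert len(pep.residues) == 3
        assert pep.has_termini

    def test_cyclic_24mer_no_termini(self, zn_peptide):
        pep = next(cs for cs in residue_sequence(zn_peptide)
                   if cs.residues[0].is_amino)
        assert len(pep.residues) == 24
        assert pep.cyclic and not pep.has_termini

    def test_waters_are_independent_units(self, zn_peptide):
        chains = residue_sequence(zn_peptide)
        waters = [cs for cs in chains
                  if cs.residues[0].canonical_type == "water"]
        assert len(waters) == 2
        assert all(len(cs.residues) == 1 for cs in waters)


def _count_peptide_bonds(st):
    n = 0
    for a, b in st.bonds.edges:
        aa, ab = st.atom_by_serial(a), st.atom_by_serial(b)
        if {aa.name, ab.name} == {"C", "N"} and \
                aa.residue_key != ab.residue_key:
            n += 1
    return n


def _write(tmp_path, text):
    p = tmp_path / "t.pdb"
    p.write_text(text)
    return p
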