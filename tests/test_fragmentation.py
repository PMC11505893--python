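"""Fragmentation operations: auto scheme, cuts, splits, merges, metal sites.

The brute-force oracles (connected components, cross-fragment bond scan,
charge summation) live in ``validate`` and in local helpers here.
"""

import warnings

import numpy as np
import pytest

import fmofrag as ff
from fmofrag.fragmentation import FragmentationError


def _fragment_of(frag, serial):
    return frag.fragment_of(serial)


class TestAutoFragment:
    def test_carbonyl_shifts_to_next_fragment(self):
        # Glu-Leu: the Glu carbonyl C/O belong to the Leu fragment
        st = ff.build_polypeptide("EL")
        frag = ff.auto_fragment(st)
        glu = next(r for r in st.residues if r.name == "GLU")
        leu_frag = frag.by_name("Leu2")
        assert glu.atom("C").serial in leu_frag.atom_serials
        assert glu.atom("O").serial in leu_frag.atom_serials
        # but Glu keeps its CA
        assert glu.atom("CA").serial in frag.by_name("Glu1").atom_serials

    def test_carbonyl_shift_across_cyclic_closure(self, zn_peptide, zn_auto):
        pep = next(cs for cs in ff.residue_sequence(zn_peptide)
                   if cs.residues[0].is_amino)
        last = pep.residues[-1]
        first = pep.residues[0]
        f_first = zn_auto.fragment_of(first.atom("CA").serial)
        assert last.atom("C").serial in f_first.atom_serials

    def test_charged_termini_bookkeeping(self, kae):
        frag = ff.auto_fragment(kae)
        charges = [f.formal_charge for f in frag.fragments]
        assert charges == [2, 0, -2]
        assert sum(charges) == kae.total_formal_charge == 0

    def test_cyclic_counts(self, zn_peptide, zn_auto):
        # 24 peptide fragments + 1 Zn + 2 waters
        assert zn_auto.n_fragments == 27
        assert len(zn_auto.detached_bonds) == 24
        assert ff.validate(zn_auto).ok

    def test_linear_detached_bond_count(self, ala3):
        frag = ff.auto_fragment(ala3)
        assert len(frag.detached_bonds) == 2  # n-1 cuts


class TestCutBonds:
    def test_zero_cuts_is_identity(self, ligand_auto):
        out = ff.cut_bonds(ligand_auto, [])
        assert [(f.name, f.atom_serials) for f in out.fragments] == \
            [(f.name, f.atom_serials) for f in ligand_auto.fragments]

    def test_three_acyclic_cuts_give_four_ligand_pieces(
            self, ligand_complex, ligand_auto):
        st, s = ligand_complex
        before = ligand_auto.n_fragments
        out = ff.cut_bonds(ligand_auto, [(s["C1"], s["C2"]),
                                         (s["C3"], s["C4"]),
                                         (s["C5"], s["C6"])])
        assert out.n_fragments == before + 3
        assert ff.validate(out).ok

    def test_cys_side_chain_joins_ligand(self, ligand_complex, ligand_auto):
        st, s = ligand_complex
        out = ff.cut_bonds(ligand_auto, [(s["CA2"], s["CB2"])])
        side = out.fragment_of(s["SG"])
        assert s["C1"] in side.atom_serials  # thioether + ligand together
        assert s["CA2"] not in side.atom_serials

    def test_cut_count_property(self, ligand_complex, ligand_auto):
        # cutting c acyclic bonds yields exactly c+1 pieces of the fragment
        st, s = ligand_complex
        cuts_pool = [(s["C1"], s["C2"]), (s["C2"], s["C3"]),
                     (s["C3"], s["C4"]), (s["C4"], s["C5"]),
                     (s["C5"], s["C6"])]
        for c in range(1, 6):
            out = ff.cut_bonds(ligand_auto, cuts_pool[:c])
            assert out.n_fragments == ligand_auto.n_fragments + c
            assert ff.validate(out).ok

    def test_ring_cut_rejected(self, zn_peptide, zn_auto):
        his = next(r for r in zn_peptide.residues if r.name == "HIS")
        cg, nd1 = his.atom("CG"), his.atom("ND1")
        with pytest.raises(FragmentationError, match="ring cut"):
            ff.cut_bonds(zn_auto, [(cg.serial, nd1.serial)])

    def test_bda_on_hydrogen_rejected(self, ala3):
        frag = ff.auto_fragment(ala3)
        h = next(a for a in ala3.atoms if a.element == "H")
        heavy = next(iter(ala3.bonds.neighbors(h.serial)))
        with pytest.raises(FragmentationError, match="hydrogen"):
            ff.cut_bonds(frag, [(h.serial, heavy)])

    def test_noncovalent_pair_rejected(self, ala3):
        frag = ff.auto_fragment(ala3)
        with pytest.raises(FragmentationError, match="not a covalent"):
            ff.cut_bonds(frag, [(1, len(ala3.atoms))])


class TestSplitSideChain:
    def test_cb_ca_side_piece_contains_ring_and_cb(self, zn_peptide,
                                                   zn_auto):
        his = next(r for r in zn_peptide.residues if r.name == "HIS")
        out = ff.split_side_chain(zn_auto, his.key, ff.CB_CA)
        side = out.fragment_of(his.atom("CB").serial)
        names = {zn_peptide.atom_by_serial(s).name
                 for s in side.atom_serials}
        assert {"CB", "CG", "ND1", "CD2", "CE1", "NE2"} <= names
        assert "CA" not in names

    def test_cb_cg_side_piece_excludes_cb(self, zn_peptide, zn_auto):
        his = next(r for r in zn_peptide.residues if r.name == "HIS")
        out = ff.split_side_chain(zn_auto, his.key, ff.CB_CG)
        side = out.fragment_of(his.atom("CG").serial)
        names = {zn_peptide.atom_by_serial(s).name
                 for s in side.atom_serials}
        assert "CB" not in names and "CG" in names
        main = out.fragment_of(his.atom("CB").serial)
        assert his.atom("CA").serial in main.atom_serials

    def test_charge_conservation_on_split(self, zn_peptide, zn_auto):
        his = next(r for r in zn_peptide.residues if r.name == "HIS")
        orig = zn_auto.fragment_of(his.atom("CB").serial)
        out = ff.split_side_chain(zn_auto, his.key, ff.CB_CA)
        main = out.fragment_of(his.atom("CA").serial)
        side = out.fragment_of(his.atom("CB").serial)
        assert main.formal_charge + side.formal_charge == orig.formal_charge

    def test_gly_has_no_cb(self):
        st = ff.build_polypeptide("AGA")
        frag = ff.auto_fragment(st)
        gly = next(r for r in st.residues if r.name == "GLY")
        with pytest.raises(FragmentationError, match="no CB"):
            ff.split_side_chain(frag, gly.key, ff.CB_CA)

    def test_ala_has_no_cg_for_cb_cg(self, ala3):
        frag = ff.auto_fragment(ala3)
        ala = ala3.residues[1]
        with pytest.raises(FragmentationError, match="no CG"):
            ff.split_side_chain(frag, ala.key, ff.CB_CG)

    def test_split_then_merge_restores_original(self, zn_peptide, zn_auto):
        his = next(r for r in zn_peptide.residues if r.name == "HIS")
        split = ff.split_side_chain(zn_auto, his.key, ff.CB_CG)
        main = split.fragment_of(his.atom("CB").serial)
        side = split.fragment_of(his.atom("CG").serial)
        merged = ff.merge_fragments(split, {main.id, side.id}, his.label)
        assert [f.atom_serials for f in merged.fragments] == \
            [f.atom_serials for f in zn_auto.fragments]
        assert {db.pair() for db in merged.detached_bonds} == \
            {db.pair() for db in zn_auto.detached_bonds}


class TestMergeFragments:
    def test_count_decreases_by_k_minus_1(self, zn_auto):
        before = zn_auto.n_fragments
        out = ff.merge_fragments(zn_auto, {1, 2, 3}, "tri")
        assert out.n_fragments == before - 2

    def test_internal_detached_bond_removed(self, zn_auto):
        db = zn_auto.detached_bonds[0]
        i = zn_auto.fragment_of(db.bda).id
        j = zn_auto.fragment_of(db.baa).id
        out = ff.merge_fragments(zn_auto, {i, j}, "pair")
        assert db.pair() not in {d.pair() for d in out.detached_bonds}
        assert ff.validate(out).ok

    def test_unknown_id_rejected(self, zn_auto):
        with pytest.raises(FragmentationError, match="no fragment"):
            ff.merge_fragments(zn_auto, {999}, "x")


class TestMetalSite:
    def test_four_his_donors(self, zn_peptide, zn_atom):
        donors = ff.detect_coordination(zn_peptide, zn_atom.serial, 2.8)
        assert len(donors) == 4
        assert {r.name for _a, r in donors} == {"HIS", "DHI"}
        assert len({r.key for _a, r in donors}) == 4
        assert all(a.name == "NE2" for a, _r in donors)

    def test_zero_cutoff_empty(self, zn_peptide, zn_atom):
        assert ff.detect_coordination(zn_peptide, zn_atom.serial, 0.0) == []

    def test_water_donor_included_by_distance(self):
        st = ff.build_zn_cyclic_peptide(n_waters=1, water_distance=2.3)
        zn = next(a for a in st.atoms if a.element == "ZN")
        donors = ff.detect_coordination(st, zn.serial, 2.8)
        assert any(r.canonical_type == "water" for _a, r in donors)

    def test_whole_residue_merge_counts(self, zn_peptide, zn_auto, zn_atom):
        out = ff.merge_metal_site(zn_peptide, zn_auto, zn_atom.serial,
                                  scheme="whole-residue")
        assert _peptide_derived(zn_peptide, out) == 21
        assert out.by_name("ZN+sites").formal_charge == 2

    @pytest.mark.parametrize("scheme", ["CB-CA", "CB-CG"])
    def test_side_chain_merge_counts(self, zn_peptide, zn_auto, zn_atom,
                                     scheme):
        out = ff.merge_metal_site(zn_peptide, zn_auto, zn_atom.serial,
                                  scheme=scheme)
        assert _peptide_derived(zn_peptide, out) == 25
        assert out.by_name("ZN+sites").formal_charge == 2
        assert len(out.detached_bonds) == 28  # 24 backbone + 4 side cuts
        assert ff.validate(out).ok

    def test_coordinating_water_merges(self):
        st = ff.build_zn_cyclic_peptide(n_waters=1, water_distance=2.3)
        zn = next(a for a in st.atoms if a.element == "ZN")
        frag = ff.auto_fragment(st)
        out = ff.merge_metal_site(st, frag, zn.serial, scheme="CB-CG")
        merged = out.by_name("ZN+sites")
        water_o = next(a for a in st.atoms
                       if a.residue_key[1] == "HOH" and a.element == "O")
        assert water_o.serial in merged.atom_serials

    def test_no_donors_warns_and_leaves_metal(self, zn_peptide, zn_auto,
                                              zn_atom):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = ff.merge_metal_site(zn_peptide, zn_auto, zn_atom.serial,
                                      cutoff=0.5)
        assert any("no coordination donors" in str(x.message) for x in w)
        assert out.n_fragments == zn_auto.n_fragments


def _peptide_derived(st, frag):
    """Number of fragments containing at least one amino-residue atom."""
    return sum(1 for f in frag.fragments
               if any(st.residue_of(s).is_amino for s in f.atom_serials))


class TestValidateAndSerialize:
    def test_tampered_partition_flagged(self, zn_auto):
        bad = zn_auto.copy()
        # register a cross-fragment bond removal: drop one detached bond
        bad.detached_bonds = bad.detached_bonds[:-1]
        rep = ff.validate(bad)
        assert not rep.ok
        assert any("not in detached_bonds" in v for v in rep.violations)

    def test_bad_charge_flagged(self, zn_auto):
        bad = zn_auto.copy()
        bad.fragments[0].formal_charge += 1
        rep = ff.validate(bad)
        assert any("charges sum" in v for v in rep.violations)

    def test_serialization_roundtrip(self, tmp_path, zn_peptide, zn_auto):
        p = tmp_path / "frag.txt"
        ff.save_fragmentation(zn_auto, p)
        back = ff.load_fragmentation(p, zn_peptide)
        assert [(f.name, f.formal_charge, f.atom_serials)
                for f in back.fragments] == \
            [(f.name, f.formal_charge, f.atom_serials)
             for f in zn_auto.fragments]
        assert {db.pair() for db in back.detached_bonds} == \
            {db.pair() for db in zn_auto.detached_bonds}


class TestRandomizedPeptides:
    """Property suite on randomized synthetic peptides (seeded)."""

    ALPHABET = "ACDEFGHIKLMNPQRSTVWYX" + "acdefhiklmnpqrstvwy"

    @pytest.mark.parametrize("case", range(10))
    def test_partition_charge_and_detachment_invariants(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(2, 31))
        seq = "".join(rng.choice(list(self.ALPHABET), size=n))
        cyclic = bool(rng.integers(0, 2)) and n >= 3
        st = ff.build_polypeptide(seq, cyclic=cyclic)
        frag = ff.auto_fragment(st)
        rep = ff.validate(frag)
        assert rep.ok, rep.violations
        assert frag.total_charge() == st.total_formal_charge
        # atom partition completeness
        assert sum(len(f.atom_serials) for f in frag.fragments) == \
            len(st.atoms)
        expected_cuts = n if cyclic else n - 1
        assert len(frag.detached_bonds) == expected_cuts


try:
    from hypothesis import given, settings, strategies as hst

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seq=hst.text(alphabet=TestRandomizedPeptides.ALPHABET,
                        min_size=2, max_size=10),
           cyclic=hst.booleans())
    def test_auto_fragment_invariants_property(seq, cyclic):
        """Partition, charge and detachment invariants over the sequence
        space (linear and cyclic, D-residues and AIB included)."""
        if cyclic and len(seq) < 3:
            cyclic = False
        st = ff.build_polypeptide(seq, cyclic=cyclic)
        frag = ff.auto_fragment(st)
        assert ff.validate(frag).ok
        assert frag.total_charge() == st.total_formal_charge
        assert len(frag.detached_bonds) == \
            (len(seq) if cyclic else len(seq) - 1)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass
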