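"""IFIE/PIEDA aggregation, remapping, comparison, charges, cube grids.

The hand-built five-fragment result below has dimer totals chosen so the
aggregates can be checked against explicit sums; larger cases use a
brute-force double loop over dimer records as the oracle.
"""

import numpy as np
import pytest

import fmofrag as ff
from fmofrag.analysis import (AnalysisError, FragmentGroup, aggregate_ifie,
                              charge_table, compare_results, identity_map,
                              ligand_residue_profile, remap_result)
from fmofrag.cpf import DimerRecord, FMOResult, FragmentMeta, MonomerRecord


def _dimer(i, j, es=0.0, ex=0.0, ct=0.0, di=0.0, dist=5.0):
    return DimerRecord(i, j, dist, es, ex, ct, di,
                       total_hf=es + ex + ct, total_mp2=es + ex + ct + di)


@pytest.fixture()
def hand_result():
    """Five fragments; fragment 1 is the 'ligand'; 1-2 share a cut bond."""
    res = FMOResult()
    for fid in range(1, 6):
        atoms = tuple(range(10 * fid, 10 * fid + 3))
        res.fragments.append(FragmentMeta(fid, f"F{fid}", 0, atoms))
        res.monomers.append(MonomerRecord(fid, -10.0 - fid))
    res.detached_bonds = [(10, 20)]  # fragments 1 and 2 are adjacent
    res.dimers = [
        _dimer(1, 2, es=-2.0, ct=100.0),        # adjacency artifact
        _dimer(1, 3, es=-3.0),
        _dimer(1, 4, es=1.0, di=0.5),
        _dimer(1, 5, es=-1.0, ex=0.5, di=-1.0),
        _dimer(2, 3, es=-4.0),
        _dimer(4, 5, di=-2.0),
    ]
    return res


class TestAggregate:
    def test_hand_summed_pair_groups(self, hand_result):
        ga = FragmentGroup("A", frozenset([1]))
        gb = FragmentGroup("B", frozenset([3, 4]))
        # dimers (1,3) total -3.0 and (1,4) total +1.5 -> -1.5
        t = aggregate_ifie(hand_result, ga, gb)
        assert t.df.iloc[0]["total"] == pytest.approx(-1.5)

    def test_symmetry(self, hand_result):
        ga = FragmentGroup("A", frozenset([1]))
        gb = FragmentGroup("B", frozenset([3, 4, 5]))
        ta = aggregate_ifie(hand_result, ga, gb)
        tb = aggregate_ifie(hand_result, gb, ga)
        for c in ("ES", "EX", "CT+mix", "DI", "total"):
            assert ta.df.iloc[0][c] == tb.df.iloc[0][c]

    def test_adjacent_pair_excluded_by_default(self, hand_result):
        ga = FragmentGroup("A", frozenset([1]))
        gb = FragmentGroup("B", frozenset([2, 3]))
        t = aggregate_ifie(hand_result, ga, gb)
        assert t.excluded_pairs == [(1, 2)]
        assert t.df.iloc[0]["total"] == pytest.approx(-3.0)
        # override keeps the artifact pair
        t2 = aggregate_ifie(hand_result, ga, gb, exclude_adjacent=False)
        assert t2.df.iloc[0]["total"] == pytest.approx(-3.0 + 98.0)

    def test_overlapping_groups_rejected(self, hand_result):
        with pytest.raises(AnalysisError, match="overlap"):
            aggregate_ifie(hand_result,
                           FragmentGroup("A", frozenset([1, 2])),
                           FragmentGroup("B", frozenset([2, 3])))

    def test_linearity_over_disjoint_union(self, hand_result):
        ga = FragmentGroup("A", frozenset([1]))
        parts = [FragmentGroup("p1", frozenset([3])),
                 FragmentGroup("p2", frozenset([4, 5]))]
        whole = FragmentGroup("w", frozenset([3, 4, 5]))
        s = sum(aggregate_ifie(hand_result, ga, p).df.iloc[0]["total"]
                for p in parts)
        w = aggregate_ifie(hand_result, ga, whole).df.iloc[0]["total"]
        assert w == pytest.approx(s, abs=1e-9)


class TestProfile:
    def test_row_count_and_brute_force_sums(self, hand_result):
        lig = FragmentGroup("lig", frozenset([1]))
        t = ligand_residue_profile(hand_result, lig)
        assert len(t) == 3  # fragment 2 drops (adjacency), 3/4/5 remain
        dm = hand_result.dimer_map()
        for row in t.df.itertuples():
            fid = hand_result.fragment_by_name(row.unit_b).id
            d = dm[(min(1, fid), max(1, fid))]
            assert row.total == pytest.approx(d.total_mp2)

    def test_component_selection_di_only(self, hand_result):
        lig = FragmentGroup("lig", frozenset([1]))
        t = ligand_residue_profile(hand_result, lig, components=("DI",))
        assert np.allclose(t.df["total"], t.df["DI"])

    def test_sorted_by_total(self, hand_result):
        lig = FragmentGroup("lig", frozenset([1]))
        t = ligand_residue_profile(hand_result, lig)
        assert list(t.df["total"]) == sorted(t.df["total"])


class TestRemap:
    def test_identity_map_preserves_rows(self, hand_result):
        t = remap_result(hand_result, identity_map(hand_result))
        dm = hand_result.dimer_map()
        assert len(t) == len(dm)
        for row in t.df.itertuples():
            i = hand_result.fragment_by_name(row.unit_a).id
            j = hand_result.fragment_by_name(row.unit_b).id
            assert row.total == pytest.approx(
                dm[(min(i, j), max(i, j))].total_mp2)

    def test_merged_unit_drops_mutual_dimer(self, hand_result):
        mapping = {1: "U12", 2: "U12", 3: "F3", 4: "F4", 5: "F5"}
        t = remap_result(hand_result, mapping)
        # (1,2) is intra-unit and vanishes; (1,3)+(2,3) sum under (U12,F3)
        pairs = {tuple(sorted((r.unit_a, r.unit_b))) for r in
                 t.df.itertuples()}
        assert ("F3", "U12") in pairs
        assert t.row("U12", "F3")["total"] == pytest.approx(-7.0)

    def test_missing_fine_fragment_rejected(self, hand_result):
        with pytest.raises(AnalysisError, match="missing"):
            remap_result(hand_result, {1: "a", 2: "a"})

    def test_exclusion_propagates_to_coarse_pair(self, hand_result):
        mapping = {1: "A", 2: "B", 3: "B", 4: "C", 5: "C"}
        t = remap_result(hand_result, mapping)
        row = t.row("A", "B")
        assert bool(row["excluded"])
        assert "1, 2" in row["reason"].replace(",", ", ").replace(
            "  ", " ") or "(1, 2)" in row["reason"]

    def test_conservation_on_seeded_toy(self, zn_peptide, zn_auto):
        res = ff.make_toy_result(zn_auto, seed=5)
        mapping = {f.id: ("pep" if f.id <= 12 else "rest")
                   for f in res.fragments}
        t = remap_result(res, mapping)
        brute = sum(d.total_mp2 for d in res.dimers
                    if mapping[d.i] != mapping[d.j])
        assert t.df["total"].sum() == pytest.approx(brute, abs=1e-9)


class TestCompare:
    def test_self_comparison_is_zero(self, hand_result):
        t = remap_result(hand_result, identity_map(hand_result))
        c = compare_results(t, t)
        assert c.max_abs_total == 0.0
        assert (c.df.filter(like="d").abs().to_numpy() == 0).all()

    def test_single_row_perturbation(self, hand_result):
        t = remap_result(hand_result, identity_map(hand_result))
        t2 = remap_result(hand_result, identity_map(hand_result))
        kept = t2.df.index[~t2.df.excluded]
        t2.df.loc[kept[0], "total"] += 0.5
        c = compare_results(t2, t)
        assert c.max_abs_total == pytest.approx(0.5)

    def test_unit_mismatch_rejected(self, hand_result):
        t = remap_result(hand_result, identity_map(hand_result))
        mapping = {1: "U12", 2: "U12", 3: "F3", 4: "F4", 5: "F5"}
        t2 = remap_result(hand_result, mapping)
        with pytest.raises(AnalysisError, match="symmetric difference"):
            compare_results(t, t2)

    def test_excluded_rows_dropped_and_listed(self, hand_result):
        mapping = {1: "A", 2: "B", 3: "B", 4: "C", 5: "C"}
        t = remap_result(hand_result, mapping)
        c = compare_results(t, t)
        assert ("A", "B") in c.excluded_units
        assert not ((c.df.unit_a == "A") & (c.df.unit_b == "B")).any()


class TestChargeTable:
    def test_self_reference_zero_delta(self, toy_result):
        t = charge_table(toy_result, scheme="npa", reference=toy_result)
        assert t.delta.abs().max() == 0.0
        assert not t.flagged.any()

    def test_shifted_atom_flagged_at_threshold(self, toy_result):
        import copy
        ref = copy.deepcopy(toy_result)
        pert = copy.deepcopy(toy_result)
        pert.monomers[0].charges["mulliken"] = \
            pert.monomers[0].charges["mulliken"].copy()
        pert.monomers[0].charges["mulliken"][0] += 0.07
        t = charge_table(pert, scheme="mulliken", reference=ref,
                         flag_threshold=0.05)
        assert int(t.flagged.sum()) == 1
        serial = pert.fragment_by_id(
            pert.monomers[0].fragment_id).atom_serials[0]
        assert t[t.flagged].iloc[0]["serial"] == serial

    def test_absent_scheme_rejected(self, toy_result):
        import copy
        res = copy.deepcopy(toy_result)
        for m in res.monomers:
            m.charges.pop("esp")
        with pytest.raises(AnalysisError, match="absent"):
            charge_table(res, scheme="esp")


class TestCubeDiff:
    def test_self_difference_zero(self):
        g = ff.gaussian_grid((0, 0, 0), 1.0, 0.2, (-5, -5, -5), 0.5,
                             (20, 20, 20))
        d, s = ff.cube_diff(g, g)
        assert s.max_abs == 0.0
        assert all(v == 0 for v in s.exceed_counts.values())

    def test_shifted_gaussian_integral_vanishes(self):
        # same total density, displaced: the signed difference integrates
        # to ~0 within quadrature error
        kw = dict(sigma=0.8, amplitude=0.3, origin=(-8, -8, -8),
                  step=0.4, counts=(40, 40, 40))
        g1 = ff.gaussian_grid(center=(0, 0, 0), **kw)
        g2 = ff.gaussian_grid(center=(0.8, 0.4, 0), **kw)
        d, s = ff.cube_diff(g1, g2)
        assert abs(s.integral) < 1e-6
        assert s.max_abs > 0.05

    def test_exceedance_counts_monotone(self):
        kw = dict(sigma=0.8, amplitude=0.3, origin=(-8, -8, -8),
                  step=0.4, counts=(40, 40, 40))
        g1 = ff.gaussian_grid(center=(0, 0, 0), **kw)
        g2 = ff.gaussian_grid(center=(1.0, 0, 0), **kw)
        _d, s = ff.cube_diff(g1, g2)
        levels = sorted(s.exceed_counts)
        counts = [s.exceed_counts[L] for L in levels]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] < counts[0]

    def test_grid_mismatch_rejected(self):
        g1 = ff.gaussian_grid((0, 0, 0), 1.0, 0.1, (-5, -5, -5), 0.5,
                              (20, 20, 20))
        g2 = ff.gaussian_grid((0, 0, 0), 1.0, 0.1, (-5, -5, -5), 0.4,
                              (20, 20, 20))
        with pytest.raises(ff.CubeError, match="grids differ"):
            ff.cube_diff(g1, g2)

    def test_cube_file_roundtrip(self, tmp_path):
        g = ff.gaussian_grid((0.3, -0.2, 0), 1.1, 0.25, (-5, -5, -5), 0.5,
                             (12, 14, 16))
        g.atoms = [(30, 2.0, np.zeros(3))]
        p = tmp_path / "g.cube"
        ff.write_cube(g, p)
        back = ff.read_cube(p)
        assert back.same_grid_as(g)
        np.testing.assert_allclose(back.values, g.values, rtol=1e-5)
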