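"""Per-fragment IFIE/PIEDA profile of a merged metal fragment.

Uses a seeded toy CPF result (real numbers would come from an FMO
engine) and shows default adjacency exclusion: pairs sharing a detached
bond carry unphysical CT+mix values and are dropped.
"""

import fmofrag as ff
from fmofrag.analysis import FragmentGroup, ligand_residue_profile

st = ff.build_zn_cyclic_peptide()
zn = next(a for a in st.atoms if a.element == "ZN")
frag = ff.merge_metal_site(st, ff.auto_fragment(st), zn.serial,
                           scheme="CB-CG")

res = ff.make_toy_result(frag, seed=1)
gid = res.fragment_by_name("ZN+sites").id
group = FragmentGroup("ZN+sites", frozenset([gid]))

table = ligand_residue_profile(res, group)
print("strongest interactions (kcal/mol, 1-decimal report rounding):")
print(table.rounded().head(8).to_string(index=False))
print("\nexcluded BDA-adjacent pairs:", table.excluded_pairs)

# restricting the total to one PIEDA component:
di_only = ligand_residue_profile(res, group, components=("DI",))
print("\nDI-only totals equal the DI column:",
      bool((di_only.df["total"] == di_only.df["DI"]).all()))
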