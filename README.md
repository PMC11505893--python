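# fmofrag

Preprocessing and postprocessing toolkit for fragment molecular orbital
(FMO) calculations: fragmentation of biomolecules with bond detached /
bond attached atom (BDA/BAA) bookkeeping, metal-site fragment merging,
ABINIT-MP-style input generation, and IFIE/PIEDA result analysis.

FMO divides a macromolecule into fragments, solves monomers and dimers
in each other's electrostatic field, and reports interfragment
interaction energies (IFIE) with their PIEDA components — ES
(electrostatics), EX (exchange repulsion), CT+mix (charge transfer +
mixing) and DI (dispersion).  Standard protein fragmentation is
automatic (one fragment per residue, cut at the Cα–C bond), but two
common situations need manual control and are this package's focus:

* **covalent ligands** — an inhibitor bound to a catalytic cysteine must
  be divided into functional-group fragments by hand, with the cysteine
  split into main chain and side chain;
* **metal sites** — a Zn²⁺ ion must be merged with its coordinating
  histidines into one fragment to keep the coordination bonds inside a
  fragment; merging only the side chains (the CB–CA or CB–CG split
  schemes, BDA at Cβ) keeps fragments small and calculations cheap.

The package is aimed at computational chemists preparing ABINIT-MP-style
FMO inputs and analysing CPF-style result tables.  The quantum-chemical
calculation itself is out of scope — an external engine does that.

## Worked example: Zn-site fragmentation and IFIE profile

```python
import fmofrag as ff
from fmofrag.analysis import FragmentGroup, ligand_residue_profile

# cyclic 24-mer with D-residues and AIB, a central Zn2+ and 4 His donors
st = ff.build_zn_cyclic_peptide()
zn = next(a for a in st.atoms if a.element == "ZN")

# main-chain fragmentation, then merge the His side chains (CB-CG split)
# with the metal
frag = ff.merge_metal_site(st, ff.auto_fragment(st), zn.serial,
                           scheme="CB-CG")
print(f"{frag.n_fragments} fragments, "
      f"{len(frag.detached_bonds)} detached bonds")
merged = frag.by_name("ZN+sites")
print(f"merged fragment: {merged.name}, charge {merged.formal_charge:+d}, "
      f"{len(merged.atom_serials)} atoms")

# seeded toy FMO result; profile the merged fragment vs everything else
res = ff.make_toy_result(frag, seed=1)
group = FragmentGroup("ZN+sites",
                      frozenset([res.fragment_by_name("ZN+sites").id]))
table = ligand_residue_profile(res, group)
print(table.rounded().head(5).to_string(index=False))
print("excluded BDA-adjacent pairs:", table.excluded_pairs)
```

prints

```
27 fragments, 28 detached bonds
merged fragment: ZN+sites, charge +2, 33 atoms
  unit_a unit_b   ES  EX  CT+mix   DI  total  excluded reason
ZN+sites  Dgl16 -7.1 1.2    -2.0 -0.5   -8.3     False
ZN+sites  Dle20 -5.1 0.3    -1.8 -0.7   -7.3     False
ZN+sites   Gln9 -4.2 0.4    -1.0 -1.7   -6.6     False
ZN+sites  Dly19 -3.1 0.8    -2.4 -0.2   -4.9     False
ZN+sites  Gln21 -2.3 0.7    -1.6 -0.6   -3.8     False
excluded BDA-adjacent pairs: [(6, 8), (8, 13), (8, 19), (8, 25)]
```

28 detached bonds are the 24 backbone Cα–C cuts of the cyclic chain
plus the 4 CB–CG side-chain cuts; the merged fragment carries the Zn²⁺
charge (+2, four neutral histidines).  Each profile row is the
componentwise sum of the dimer records between the merged fragment and
one environment fragment, in kcal/mol, sorted by total.  The four
excluded pairs share a detached bond with the merged fragment (the BDA
sits right next to the BAA); such pairs show unphysical CT+mix values
and are dropped from analyses by default.

The `examples/` directory has one short script per capability
(building/fragmenting, covalent-ligand cuts, metal-site schemes,
profiles, remapping/comparison, density differencing); each prints what
it computes and what the numbers mean.  A thin CLI mirrors the library
(`fmofrag fixture|fragment|deck|parse|profile|remap|compare`).

File formats (input deck, CPF result dialect, fragmentation table) are
specified in `docs/formats.md`; the scientific conventions and their
rationale in `docs/methods.md`.

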