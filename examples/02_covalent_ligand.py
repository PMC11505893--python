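"""Manual fragmentation of a covalent ligand on a cysteine.

The synthetic complex has a ligand bound to the Cys thiol, so automatic
fragmentation keeps ligand and cysteine together.  We then (1) cut the
Cys CA-CB bond so the side chain (the thioether) stays with the ligand,
and (2) cut three acyclic ligand bonds to get functional-group pieces -
the workflow used for covalent inhibitors.
"""

import warnings

import fmofrag as ff

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # the covalent attachment is expected
    st, s = ff.build_covalent_ligand_complex()
    frag = ff.auto_fragment(st)

print("automatic fragments:",
      [(f.name, len(f.atom_serials)) for f in frag.fragments])

frag = ff.cut_bonds(frag, [(s["CA2"], s["CB2"])])      # Cys main vs side
frag = ff.cut_bonds(frag, [(s["C1"], s["C2"]),
                           (s["C3"], s["C4"]),
                           (s["C5"], s["C6"])])        # 3 ligand cuts

print("after manual cuts:")
for f in frag.fragments:
    print(f"  {f.id}: {f.name:<10s} {len(f.atom_serials)} atoms")
print(f"{len(frag.detached_bonds)} detached bonds; "
      f"valid: {ff.validate(frag).ok}")

# Three acyclic cuts turned the ligand into four pieces (one of them
# still carrying the Cys side chain through the S-C bond), exactly the
# granularity needed for functional-group-level IFIE analysis.
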