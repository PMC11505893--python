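"""Build an ideal-geometry peptide and fragment it automatically.

The automatic scheme gives one fragment per residue with the boundary at
the CA-C bond, so each residue's carbonyl migrates into the next
fragment; fragment charges come from explicit protonation (charged
termini, Lys +1, Glu -1).
"""

import fmofrag as ff

st = ff.build_polypeptide("KAE")  # Lys-Ala-Glu, charged termini
frag = ff.auto_fragment(st)

print(f"{len(st.atoms)} atoms, total charge {st.total_formal_charge:+d}")
for f in frag.fragments:
    print(f"  fragment {f.id}: {f.name:<6s} charge {f.formal_charge:+d} "
          f"({len(f.atom_serials)} atoms)")
print(f"detached bonds (BDA, BAA): "
      f"{[(d.bda, d.baa) for d in frag.detached_bonds]}")
print(f"validation clean: {ff.validate(frag).ok}")

# The +2 on fragment 1 is the protonated N-terminus plus the Lys
# ammonium; the -2 on fragment 3 is the Glu carboxylate plus the
# C-terminal carboxylate.  Charges always sum to the structure total.
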