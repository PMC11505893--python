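# File formats

All formats are plain text, deterministic, and fully round-trippable by
the package itself.

## Input deck (ABINIT-MP-style)

Written by `fmofrag.abinitmp.write_input`, parsed by `read_input`.
Section keywords start in column one; value lines are indented by one
space and wrap at 10 items per line.

```
deck        := cntrl fragment geom
cntrl       := "&CNTRL" NL kv* "&END" NL
kv          := "  " KEY "=" "'" VALUE "'" NL          ; Title, Method, Basis, extras
fragment    := "&FRAGMENT" NL
               "NF=" INT NL
               "NATOMS" NL intlines                   ; per-fragment atom counts
               "CHARGES" NL intlines                  ; per-fragment formal charges
               "NAMES" NL namelines                   ; per-fragment labels
               assign+                                ; one block per fragment
               "BONDS " INT NL bondline*              ; detached-bond count, pairs
               "&END" NL
assign      := "ASSIGN " INT NL intlines              ; 1-based atom serials
bondline    := " " BDA_SERIAL " " BAA_SERIAL NL
geom        := "&GEOM" NL atomline* "&END" NL
atomline    := " " SERIAL " " ELEMENT " " NAME " " X " " Y " " Z NL
```

`Method` is `HF` or `MP2`; `Basis` is `6-31G` or `6-31G*`.  The parser
checks `NF` against the NATOMS/CHARGES lengths and each `ASSIGN` block
against its declared atom count; fragment blocks may appear in any order
(fragments are renumbered stably by lowest atom serial on load).

## CPF result file

Written by `fmofrag.cpf.write_cpf`, parsed by `read_cpf`.  The first
line is the version header `CPF FMOFRAG 1.0`; an unknown header is a
hard error (the hook where further dialects would be auto-detected).
**All energies in the file are hartree**; the reader converts dimer
records to kcal/mol (factor 627.5095).

```
cpf         := version meta atoms frags detached monomer* ndimer dimer* total
version     := "CPF FMOFRAG 1.0" NL
meta        := "METHOD " M NL "BASIS " B NL "TITLE " TEXT NL
atoms       := "NATOM " INT NL ("ATOM " SERIAL NAME ELEMENT RESNAME CHAIN RESNUM NL)*
frags       := "NFRAG " INT NL frag*
frag        := "FRAGMENT " ID NAME CHARGE NATOMS NL "  " SERIAL+ NL
detached    := "DETACHED " INT NL ("  " BDA BAA NL)*
monomer     := "MONOMER " ID ENERGY NL charges*
charges     := "  CHARGES " ("MULLIKEN"|"NPA"|"ESP") FLOAT+ NL
ndimer      := "NDIMER " INT NL
dimer       := "DIMER " I J MINDIST ES EX CTMIX DI TOTAL_HF TOTAL_MP2 NL
total       := "TOTAL_ENERGY " FLOAT NL
```

Invariants checked on read:

* `NDIMER` matches the number of `DIMER` records (truncation error);
* each monomer charge array length matches its fragment's atom count;
* per dimer, `ES + EX + CT+mix + DI = TOTAL_MP2` within 0.01 kcal/mol —
  violations are collected in `FMOResult.additivity_deviations`, never
  silently repaired.  `write_cpf` refuses to emit records that violate
  the invariant.

## Fragmentation table

Written by `save_fragmentation` / read by `load_fragmentation`:

```
# fmofrag fragmentation v1
fragment <id> <name> <+charge>
atoms <serial> <serial> ...
...
detached <bda serial> <baa serial>
```

## Interaction tables (CSV)

Column order: `unit_a, unit_b, ES, EX, CT+mix, DI, total, excluded,
reason` (kcal/mol, full precision; report rounding to 1 decimal is a
presentation choice).  Difference tables from `compare` use `dES, dEX,
dCT+mix, dDI, dtotal`.
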