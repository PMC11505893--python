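# Methods

## Background

The fragment molecular orbital (FMO) method makes quantum chemistry
tractable for biomolecules by partitioning the system into fragments,
solving each monomer and dimer in the embedding electrostatic field of
the rest, and assembling total properties.  Its central observable for
molecular-recognition work is the interfragment interaction energy
(IFIE) and its PIEDA decomposition into electrostatics (ES), exchange
repulsion (EX), charge transfer plus mixing (CT+mix) and
dispersion/correlation (DI).

`fmofrag` covers everything *around* the quantum-chemical engine: it
builds and edits fragmentations, writes the engine input, and analyses
tabulated results.  It deliberately does not compute energies, charges
or densities — those are inputs.

## Fragmentation model

A fragmentation is a partition of all atoms into fragments plus the list
of detached bonds.  A detached bond is a single covalent bond whose two
atoms sit in different fragments: the bond detached atom (BDA) hosts the
projection operator, and the detached electron pair is assigned to the
fragment of the bond attached atom (BAA) — the standard heterolytic FMO
convention.  Because we place every formal charge on a specific atom
(NZ, OE2, OXT, the metal, ...) and define a fragment's charge as the sum
over its atoms, every editing operation (cut, split, merge) conserves
total charge by construction; `validate` re-derives all charges
independently as a check.

**Automatic (main-chain) fragmentation** produces one fragment per amino
residue with the boundary at the CA–C bond: residue *i*'s carbonyl C and
O migrate into fragment *i*+1 (so, e.g., a Glu residue's backbone
carbonyl lives in the following Leu fragment).  Linear chains keep the
N-terminal amine and the C-terminal carboxylate in their own terminal
fragments (*n*−1 cuts); cyclic chains are cut at every CA–C bond (*n*
cuts).  Waters, metal ions and non-covalently bound ligands are lone
fragments.  A ligand covalently attached to the polymer (a covalent
inhibitor on a cysteine thiol) is deliberately kept in its host
residue's fragment: automatic schemes cannot guess sensible ligand cut
points, and the merged fragment is exactly what `cut_bonds` then splits
under user control.  Proline is fragmented like any other residue — the
CA–C boundary does not cross its ring.

**Manual cuts** delete the chosen bonds inside one fragment and take the
resulting connected components as the new fragments (brute-force graph
traversal is also the test oracle: *c* acyclic cuts give *c*+1 pieces).
A cut whose deletion does not disconnect anything (an in-ring bond) is
rejected, as is a BDA designated on a hydrogen.

**Metal sites.**  Coordination contacts are *not* covalent bonds; a
metal ion never appears in the bond graph.  `detect_coordination`
returns N/O/S donors within a cutoff (default 2.8 Å — generous for
Zn–N at ~2.0–2.2 Å, short of the second shell).  `merge_metal_site`
supports three schemes for a Zn-like centre:

* *whole-residue*: merge each coordinating residue's full fragment with
  the metal (fewest fragmentation points, biggest fragment);
* *CB–CA*: split each coordinating residue at CA–CB (BDA=CB, BAA=CA)
  and merge only the side-chain piece, CB included;
* *CB–CG*: split at CB–CG (BDA=CB, BAA=CG), leaving CB with the main
  chain, and merge the side-chain piece from CG outward.

Coordinating waters are merged whole by default (an explicit option,
since conventions differ).  On the bundled cyclic 24-mer fixture these
schemes give 21 and 25 peptide-derived fragments respectively, with a
+2 merged fragment for four neutral histidines around Zn²⁺.

**Adjacency exclusion.**  Fragment pairs sharing a detached bond carry
unphysical IFIE/CT+mix values (the projection operators sit right at the
interface), so aggregation and remapping flag and drop them by default,
with an override.  This matters especially after side-chain merging,
where the residue *following* each coordinating one becomes adjacent to
the merged metal fragment and shows a spuriously repulsive CT+mix on
the order of +100 kcal/mol.  Exclusion only removes contributions; it
never rescales retained values.

## Structure handling

PDB parsing is strict fixed-column with a whitespace fallback, and
errors cite line numbers.  Altlocs keep the highest occupancy (ties by
altloc letter).  Elements come from the element column, else from
atom-name heuristics with a curated two-letter list so Cα is never read
as calcium.  Bonds inside named residues come from topology templates
(all 20 L-amino acids, their D counterparts mapped onto the same
topology, AIB, water); unknown residues use a covalent-radius rule
(d ≤ 1.25·(r_a+r_b)) that also captures covalent attachment to the
polymer.  Inter-residue bonds are peptide C–N at ≤ 1.8 Å (which detects
cyclic closure) and disulfide SG–SG at ≤ 2.3 Å; CONECT records are
honoured, except that CONECTs to metals are recorded as coordination
candidates.  Hydrogens are required on the polymer: charge bookkeeping
is derived from explicit protons (e.g. His tautomers, Lys NH₃⁺,
carboxylates), and guessing protonation is out of scope.

## Synthetic systems

The peptide builder emulates the study conditions rather than real
geometry: ideal bond lengths/angles, an extended backbone for linear
chains, and for cyclic peptides a backbone laid on a circle so the
closing peptide bond falls inside the perception cutoff.  Lower-case
letters select D-residues (mirrored Cβ placement; chirality is
otherwise metadata), `X` is AIB.  Defaults follow common protonation:
charged termini on linear chains, Lys/Arg +1, Asp/Glu −1, neutral
Nδ-protonated histidine so NE2 can coordinate a metal.

A flat circle cannot put four His NE2 atoms within coordination
distance of a central ion, so the Zn fixture rebuilds the coordinating
side chains as rigid idealized imidazoles aimed at the metal with NE2
at 2.1 Å — topologically exact, geometrically synthetic (bonds for
named residues come from templates, not distances).  Passing tests on
these fixtures therefore demonstrate bookkeeping, invariants and I/O —
not geometric realism, conformational plausibility, or the quantum
chemistry itself, which is delegated to the external engine.

Toy CPF results are seeded: PIEDA components are drawn reproducibly,
the MP2 total is the exact component sum (so additivity holds by
construction), the HF total omits DI, and BDA-adjacent pairs receive a
deliberately large repulsive CT+mix (default ≈ +100 kcal/mol) to
exercise the exclusion logic.

## Numerical choices

* 1 hartree = 627.5095 kcal/mol, stated explicitly for reproducibility;
  files store hartree, memory holds kcal/mol, and the round trip is
  exact to better than 1e−9 kcal/mol at the 12-digit mantissa used.
* PIEDA additivity tolerance: 0.01 kcal/mol (storage/report level).
* Charge-difference flagging threshold: 0.05 e by default, configurable
  — differences at or above this level concentrate at BDAs, BAAs and
  their neighbours when fragmentation schemes are compared.
* Report tables round to 1 decimal kcal/mol; internal math is double
  precision throughout.
* Cube grids follow Gaussian conventions (bohr, last axis fastest);
  difference summaries count voxels exceeding the conventional 0.05 /
  0.01 / 0.005 e/bohr³ isolevels and integrate the signed difference.
* Fragment renumbering after any edit is stable: ascending by lowest
  atom serial, 1-based — identical inputs give byte-identical decks.

## Limitations

* No mmCIF, no missing-atom completion, no protonation assignment.
* One reference CPF dialect; files from other FMO stacks need a
  dialect hook keyed on their header line.
* The builder's geometry is not energy-minimized and must not be used
  for actual energy evaluation — it exists to make topology,
  fragmentation and analysis testable offline.
* Automatic selection of ligand cut points is intentionally out of
  scope; choosing chemically meaningful functional-group boundaries is
  the user's decision.
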