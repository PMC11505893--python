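"""Fragmentations: partitions of a structure into charged fragments.

A fragmentation assigns every atom to exactly one fragment and records each
covalent bond crossing a fragment boundary as a detached bond: the bond
detached atom (BDA) keeps the projection operator, the bond attached atom
(BAA) side keeps the detached electron pair.  Fragment charges are sums of
the per-atom formal charges, so every edit operation conserves total charge
by construction.

The automatic scheme is the conventional main-chain fragmentation: one
fragment per amino residue with the cut at the CA-C bond, which shifts each
residue's carbonyl C/O into the next residue's fragment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx

from .structure import Atom, Residue, ResidueKey, Structure, StructureError

DEFAULT_COORDINATION_CUTOFF = 2.8  # Å, metal to N/O/S donor


class FragmentationError(ValueError):
    pass


@dataclass(frozen=True)
class DetachedBond:
    """A cut covalent bond: (BDA, BAA) atom serials."""
    bda: int
    baa: int

    def pair(self) -> frozenset[int]:
        return frozenset((self.bda, self.baa))


@dataclass
class Fragment:
    id: int
    name: str
    atom_serials: frozenset[int]
    formal_charge: int

    def __contains__(self, serial: int) -> bool:
        return serial in self.atom_serials


@dataclass
class Fragmentation:
    structure: Structure
    fragments: list[Fragment] = field(default_factory=list)
    detached_bonds: list[DetachedBond] = field(default_factory=list)

    # -- lookups --------------------------------------------------------
    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def fragment_of(self, serial: int) -> Fragment:
        for f in self.fragments:
            if serial in f.atom_serials:
                return f
        raise FragmentationError(f"atom {serial} is in no fragment")

    def atom_to_fragment(self) -> dict[int, int]:
        return {s: f.id for f in self.fragments for s in f.atom_serials}

    def by_id(self, fid: int) -> Fragment:
        for f in self.fragments:
            if f.id == fid:
                return f
        raise FragmentationError(f"no fragment with id {fid}")

    def by_name(self, name: str) -> Fragment:
        for f in self.fragments:
            if f.name == name:
                return f
        raise FragmentationError(f"no fragment named {name!r}")

    def adjacency_pairs(self) -> set[tuple[int, int]]:
        """Fragment id pairs (i<j) sharing at least one detached bond."""
        a2f = self.atom_to_fragment()
        pairs = set()
        for db in self.detached_bonds:
            i, j = a2f[db.bda], a2f[db.baa]
            if i != j:
                pairs.add((min(i, j), max(i, j)))
        return pairs

    def total_charge(self) -> int:
        return sum(f.formal_charge for f in self.fragments)

    def copy(self) -> "Fragmentation":
        return Fragmentation(self.structure,
                             [replace(f) for f in self.fragments],
                             list(self.detached_bonds))

    # -- internal helpers ------------------------------------------------
    def _renumber(self) -> None:
        """Stable 1-based renumbering by first (lowest) atom serial."""
        self.fragments.sort(key=lambda f: min(f.atom_serials))
        for i, f in enumerate(self.fragments, start=1):
            f.id = i

    def _charge_of(self, serials) -> int:
        st = self.structure
        return int(sum(st.atom_by_serial(s).formal_charge for s in serials))


# ---------------------------------------------------------------------------
# automatic fragmentation
# ---------------------------------------------------------------------------

def _residue_label(res: Residue) -> str:
    return res.label


def auto_fragment(structure: Structure) -> Fragmentation:
    """One fragment per amino residue (CA-C boundary) plus lone units.

    Residue i's carbonyl C and O (and any hydrogens on that carbon) move
    into fragment i+1; the detached bond is (BDA=CA(i), BAA=C(i)).  In a
    linear chain the N-terminal fragment keeps its amine and the C-terminal
    fragment keeps its own carbonyl/carboxylate; a cyclic chain is cut at
    every CA-C bond.  Waters, metal ions and non-covalently-bound ligands
    become their own fragments; a ligand covalently attached to the polymer
    joins its host residue's fragment (cut it manually afterwards).
    """
    from .structure import residue_sequence

    if not structure._bonds_perceived:
        raise FragmentationError("perceive_bonds must run before "
                                 "auto_fragment")
    g = structure.bonds
    frag = Fragmentation(structure)
    assigned: set[int] = set()

    chains = residue_sequence(structure)
    # polymer chains first
    for cs in chains:
        if not cs.residues or not cs.residues[0].is_amino:
            continue
        seq = cs.residues
        n = len(seq)
        for res in seq:
            for role in ("CA", "C"):
                if res.atom(role) is None:
                    raise FragmentationError(
                        f"residue {res.key} lacks backbone atom {role}; "
                        f"cannot auto-fragment")
        base_sets: list[set[int]] = []
        for i, res in enumerate(seq):
            s = {a.serial for a in res.atoms}
            base_sets.append(s)
        # shift carbonyls; determine cut list
        cuts: list[tuple[int, int, int]] = []  # (donor index i, bda, baa)
        for i, res in enumerate(seq):
            last = i == n - 1
            if last and not cs.cyclic:
                continue
            ca = res.atom("CA"); c = res.atom("C")
            if not g.has_edge(ca.serial, c.serial):
                continue  # chain break handled as terminal
            nxt = 0 if (last and cs.cyclic) else i + 1
            # skip shifting across an actual chain break
            if i in cs.breaks:
                continue
            carbonyl = {c.serial}
            for nb in g.neighbors(c.serial):
                b = structure.atom_by_serial(nb)
                if b.residue_key == res.key and b.name != "CA" \
                        and (b.element in ("O", "H")) and b.name != "OXT":
                    carbonyl.add(nb)
            base_sets[i] -= carbonyl
            base_sets[nxt] |= carbonyl
            cuts.append((i, ca.serial, c.serial))
        for i, res in enumerate(seq):
            frag.fragments.append(Fragment(
                id=0, name=_residue_label(res),
                atom_serials=frozenset(base_sets[i]),
                formal_charge=0))
            assigned |= base_sets[i]
        for _i, bda, baa in cuts:
            frag.detached_bonds.append(DetachedBond(bda=bda, baa=baa))

    # covalently attached hetero residues join their host fragment
    leftover = [r for r in structure.residues
                if not r.is_amino]
    for res in leftover:
        serials = {a.serial for a in res.atoms}
        host = None
        if res.canonical_type not in ("water", "metal ion"):
            for s in serials:
                for nb in g.neighbors(s):
                    if nb in assigned:
                        host = nb
                        break
                if host is not None:
                    break
        if host is not None:
            f = frag.fragment_of(host)
            f.atom_serials = frozenset(f.atom_serials | serials)
            warnings.warn(
                f"hetero residue {res.key} is covalently bonded to the "
                f"polymer; merged into fragment {f.name!r} (use cut_bonds "
                f"for a custom split)")
        else:
            frag.fragments.append(Fragment(
                id=0, name=_residue_label(res),
                atom_serials=frozenset(serials), formal_charge=0))
        assigned |= serials

    if len(assigned) != len(structure.atoms):
        missing = [a.serial for a in structure.atoms
                   if a.serial not in assigned]
        raise FragmentationError(f"atoms not assigned to any fragment: "
                                 f"{missing[:10]}")
    for f in frag.fragments:
        f.formal_charge = frag._charge_of(f.atom_serials)
    frag._renumber()
    _check_charges(frag)
    return frag


def _check_charges(frag: Fragmentation) -> None:
    total = frag.total_charge()
    expect = frag.structure.total_formal_charge
    if total != expect:
        raise FragmentationError(
            f"fragment charges sum to {total} but the structure's total "
            f"formal charge is {expect}")


# ---------------------------------------------------------------------------
# manual editing operations
# ---------------------------------------------------------------------------

def cut_bonds(fragmentation: Fragmentation,
              cuts: list[tuple[int, int]]) -> Fragmentation:
    """Split fragments by cutting covalent bonds; (bda, baa) per cut.

    Each cut must be an existing covalent bond that is not already
    detached.  Cutting an in-ring bond whose deletion does not disconnect
    its fragment is an error.  Returns a new Fragmentation.
    """
    frag = fragmentation.copy()
    st = frag.structure
    g = st.bonds
    if not cuts:
        return frag
    existing = {db.pair() for db in frag.detached_bonds}
    for bda, baa in cuts:
        if st.atom_by_serial(bda).element == "H":
            raise FragmentationError(
                f"BDA designated on hydrogen atom {bda}")
        if not g.has_edge(bda, baa):
            raise FragmentationError(
                f"({bda}, {baa}) is not a covalent bond")
        if frozenset((bda, baa)) in existing:
            raise FragmentationError(
                f"bond ({bda}, {baa}) is already detached")

    cut_pairs = {frozenset(c) for c in cuts}
    by_fragment: dict[int, list[tuple[int, int]]] = {}
    for bda, baa in cuts:
        fa = frag.fragment_of(bda)
        fb = frag.fragment_of(baa)
        if fa.id != fb.id:
            raise FragmentationError(
                f"bond ({bda}, {baa}) already crosses fragments "
                f"{fa.id} and {fb.id}")
        by_fragment.setdefault(fa.id, []).append((bda, baa))

    new_fragments: list[Fragment] = []
    for f in frag.fragments:
        if f.id not in by_fragment:
            new_fragments.append(f)
            continue
        sub = g.subgraph(f.atom_serials).copy()
        sub.remove_edges_from(by_fragment[f.id])
        comps = list(nx.connected_components(sub))
        comp_of = {s: i for i, c in enumerate(comps) for s in c}
        for bda, baa in by_fragment[f.id]:
            if comp_of[bda] == comp_of[baa]:
                raise FragmentationError(
                    f"ring cut unsupported: deleting bond ({bda}, {baa}) "
                    f"does not disconnect fragment {f.name!r}")
        for i, comp in enumerate(comps):
            suffix = "" if len(comps) == 1 else f"({i + 1})"
            new_fragments.append(Fragment(
                id=0, name=f.name + suffix,
                atom_serials=frozenset(comp),
                formal_charge=frag._charge_of(comp)))
        for bda, baa in by_fragment[f.id]:
            frag.detached_bonds.append(DetachedBond(bda=bda, baa=baa))
    frag.fragments = new_fragments
    frag._renumber()
    _check_charges(frag)
    return frag


@dataclass(frozen=True)
class SideChainScheme:
    """A side-chain split of an amino residue; BDA is always CB.

    CB-CA cuts the CA-CB bond: the side-chain piece starts at CB and the
    main chain (BAA=CA) keeps the electron pair.  CB-CG cuts CB-CG: CB
    stays with the main chain and the side-chain piece (BAA=CG) keeps it.
    """
    label: str  # "CB-CA" | "CB-CG"

    @property
    def cut_bond_roles(self) -> tuple[str, str]:
        return ("CA", "CB") if self.label == "CB-CA" else ("CB", "CG")

    @property
    def bda_role(self) -> str:
        return "CB"

    @property
    def baa_role(self) -> str:
        return "CA" if self.label == "CB-CA" else "CG"

    @property
    def side_root(self) -> str:
        """First atom of the side-chain piece."""
        return "CB" if self.label == "CB-CA" else "CG"


CB_CA = SideChainScheme("CB-CA")
CB_CG = SideChainScheme("CB-CG")
_SCHEMES = {"CB-CA": CB_CA, "CB-CG": CB_CG}


def split_side_chain(fragmentation: Fragmentation, residue: ResidueKey,
                     scheme: SideChainScheme | str) -> Fragmentation:
    """Split one residue's fragment into main-chain and side-chain pieces."""
    if isinstance(scheme, str):
        scheme = _SCHEMES[scheme]
    frag = fragmentation.copy()
    st = frag.structure
    res = st._residue_by_key.get(residue)
    if res is None:
        raise FragmentationError(f"unknown residue {residue}")
    if not res.is_amino:
        raise FragmentationError(f"{residue} is not an amino residue")
    for role in ("CB", scheme.baa_role):
        if res.atom(role) is None:
            raise FragmentationError(
                f"residue {residue} has no {role} atom; scheme "
                f"{scheme.label} not applicable")
    a = res.atom(scheme.cut_bond_roles[0]).serial
    b = res.atom(scheme.cut_bond_roles[1]).serial
    f = frag.fragment_of(res.atom("CB").serial)
    sub = st.bonds.subgraph(f.atom_serials).copy()
    sub.remove_edge(a, b)
    side = nx.node_connected_component(sub, res.atom(scheme.side_root).serial)
    main = set(f.atom_serials) - set(side)
    base = res.label
    new = [Fragment(0, f"{base}/main", frozenset(main),
                    frag._charge_of(main)),
           Fragment(0, f"{base}/side", frozenset(side),
                    frag._charge_of(side))]
    frag.fragments = [x for x in frag.fragments if x.id != f.id] + new
    frag.detached_bonds.append(
        DetachedBond(bda=res.atom(scheme.bda_role).serial,
                     baa=res.atom(scheme.baa_role).serial))
    frag._renumber()
    _check_charges(frag)
    return frag


def merge_fragments(fragmentation: Fragmentation, ids: set[int],
                    name: str) -> Fragmentation:
    """Merge fragments into one; detached bonds internal to the union go."""
    if not ids:
        raise FragmentationError("merge requires at least one fragment id")
    frag = fragmentation.copy()
    members = [frag.by_id(i) for i in sorted(ids)]
    union: set[int] = set()
    for m in members:
        union |= m.atom_serials
    charge = sum(m.formal_charge for m in members)
    frag.fragments = [f for f in frag.fragments if f.id not in ids]
    frag.fragments.append(Fragment(0, name, frozenset(union), charge))
    frag.detached_bonds = [db for db in frag.detached_bonds
                           if not (db.bda in union and db.baa in union)]
    frag._renumber()
    _check_charges(frag)
    return frag


# ---------------------------------------------------------------------------
# metal coordination
# ---------------------------------------------------------------------------

def detect_coordination(structure: Structure, metal: int | Atom,
                        cutoff: float = DEFAULT_COORDINATION_CUTOFF
                        ) -> list[tuple[Atom, Residue]]:
    """N/O/S atoms within ``cutoff`` of a metal ion, sorted by distance."""
    import numpy as np
    from .elements import DONOR_ELEMENTS

    m = metal if isinstance(metal, Atom) else structure.atom_by_serial(metal)
    res = structure._residue_by_key[m.residue_key]
    if res.canonical_type != "metal ion":
        raise FragmentationError(f"atom {m.serial} is not a metal ion")
    out = []
    for a in structure.atoms:
        if a.residue_key == m.residue_key:
            continue
        if a.element not in DONOR_ELEMENTS:
            continue
        d = float(np.linalg.norm(a.coords - m.coords))
        if d <= cutoff:
            out.append((d, a))
    out.sort(key=lambda t: t[0])
    return [(a, structure._residue_by_key[a.residue_key]) for _d, a in out]


def merge_metal_site(structure: Structure, fragmentation: Fragmentation,
                     metal: int | Atom, scheme: str = "CB-CG",
                     cutoff: float = DEFAULT_COORDINATION_CUTOFF,
                     merge_waters: bool = True) -> Fragmentation:
    """Merge a metal ion's coordinating groups into one fragment.

    ``scheme`` is ``whole-residue`` (full residue fragments merge with the
    metal), or ``CB-CA`` / ``CB-CG`` (each coordinating amino residue is
    first split into main/side pieces and only the side piece merges).
    Coordinating waters are merged whole when ``merge_waters``.
    """
    if scheme not in ("whole-residue", "CB-CA", "CB-CG"):
        raise FragmentationError(f"unknown metal-site scheme {scheme!r}")
    m = metal if isinstance(metal, Atom) else structure.atom_by_serial(metal)
    donors = detect_coordination(structure, m, cutoff)
    frag = fragmentation.copy()
    if not donors:
        warnings.warn(f"no coordination donors within {cutoff} Å of "
                      f"{m.name} {m.residue_key}; metal left as a lone "
                      f"fragment")
        return frag
    amino_res: list[Residue] = []
    water_res: list[Residue] = []
    seen: set[ResidueKey] = set()
    for _a, res in donors:
        if res.key in seen:
            continue
        seen.add(res.key)
        if res.is_amino:
            amino_res.append(res)
        elif res.canonical_type == "water":
            water_res.append(res)

    # track fragments to merge by a marker atom serial; ids renumber after
    # every split
    markers: list[int] = [m.serial]
    if scheme == "whole-residue":
        markers += [res.atom("CA").serial for res in amino_res]
    else:
        root = "CB" if scheme == "CB-CA" else "CG"
        for res in amino_res:
            if res.atom("CB") is None:
                raise FragmentationError(
                    f"donor residue {res.key} has no CB atom; side-chain "
                    f"scheme {scheme} not applicable")
            frag = split_side_chain(frag, res.key, scheme)
            markers.append(res.atom(root).serial)
    if merge_waters:
        markers += [res.atoms[0].serial for res in water_res]
    to_merge = {frag.fragment_of(s).id for s in markers}
    name = f"{m.element}+sites"
    return merge_fragments(frag, to_merge, name)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    adjacency: set[tuple[int, int]] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate(fragmentation: Fragmentation) -> ValidationReport:
    """Check partition, detached-bond completeness and charge bookkeeping."""
    rep = ValidationReport()
    frag = fragmentation
    st = frag.structure

    all_serials = [a.serial for a in st.atoms]
    counted: dict[int, int] = {s: 0 for s in all_serials}
    for f in frag.fragments:
        if not f.atom_serials:
            rep.violations.append(f"fragment {f.id} {f.name!r} is empty")
        for s in f.atom_serials:
            if s not in counted:
                rep.violations.append(
                    f"fragment {f.id} references unknown atom {s}")
            else:
                counted[s] += 1
    missing = [s for s, c in counted.items() if c == 0]
    dupes = [s for s, c in counted.items() if c > 1]
    if missing:
        rep.violations.append(f"atoms in no fragment: {missing[:10]}")
    if dupes:
        rep.violations.append(f"atoms in multiple fragments: {dupes[:10]}")

    # detached-bond completeness vs brute-force cross-fragment scan
    a2f = frag.atom_to_fragment()
    crossing = set()
    for a, b in st.bonds.edges:
        if a in a2f and b in a2f and a2f[a] != a2f[b]:
            crossing.add(frozenset((a, b)))
    declared = [db.pair() for db in frag.detached_bonds]
    declared_set = set(declared)
    if len(declared) != len(declared_set):
        rep.violations.append("duplicate detached bonds")
    for pair in crossing - declared_set:
        rep.violations.append(
            f"cross-fragment bond {sorted(pair)} not in detached_bonds")
    for pair in declared_set - crossing:
        rep.violations.append(
            f"detached bond {sorted(pair)} does not cross fragments "
            f"(or is not a covalent bond)")

    total = frag.total_charge()
    if total != st.total_formal_charge:
        rep.violations.append(
            f"fragment charges sum to {total}, structure total is "
            f"{st.total_formal_charge}")
    for f in frag.fragments:
        if f.formal_charge != frag._charge_of(f.atom_serials):
            rep.violations.append(
                f"fragment {f.id} {f.name!r} charge {f.formal_charge} "
                f"disagrees with atomic bookkeeping")

    for db in frag.detached_bonds:
        el = st.atom_by_serial(db.bda).element
        if el != "C":
            rep.warnings.append(
                f"BDA {db.bda} is {el}, not carbon; projection operators "
                f"are parameterized for carbon BDAs")
    rep.adjacency = frag.adjacency_pairs()
    return rep


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def save_fragmentation(frag: Fragmentation, path) -> None:
    lines = ["# fmofrag fragmentation v1"]
    for f in frag.fragments:
        lines.append(f"fragment {f.id} {f.name} {f.formal_charge:+d}")
        serials = " ".join(str(s) for s in sorted(f.atom_serials))
        lines.append(f"atoms {serials}")
    for db in frag.detached_bonds:
        lines.append(f"detached {db.bda} {db.baa}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_fragmentation(path, structure: Structure) -> Fragmentation:
    frag = Fragmentation(structure)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("# fmofrag fragmentation"):
        raise FragmentationError(f"{path} is not a fragmentation file")
    current: Fragment | None = None
    for ln in lines[1:]:
        toks = ln.split()
        if toks[0] == "fragment":
            current = Fragment(int(toks[1]), toks[2], frozenset(),
                               int(toks[3]))
            frag.fragments.append(current)
        elif toks[0] == "atoms":
            assert current is not None
            serials = frozenset(int(t) for t in toks[1:])
            for s in serials:
                structure.atom_by_serial(s)  # existence check
            current.atom_serials = serials
        elif toks[0] == "detached":
            frag.detached_bonds.append(
                DetachedBond(int(toks[1]), int(toks[2])))
        else:
            raise FragmentationError(f"unknown directive {toks[0]!r}")
    frag._renumber()
    return frag
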