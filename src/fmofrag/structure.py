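"""Molecular structures: PDB I/O, covalent-bond perception, residue order.

The central container is :class:`Structure`: an ordered list of atoms, a
covalent bond graph (:mod:`networkx`), and residues organized per chain.
Metal ions are never covalently bonded; contacts to potential donor atoms
are recorded separately as coordination candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import templates
from .elements import (COVALENT_RADII, DONOR_ELEMENTS, ION_CHARGES, METALS,
                       covalent_cutoff, infer_element, normalize_element)

PEPTIDE_CN_CUTOFF = 1.8     # Å, C(i)-N(i+1)
DISULFIDE_SS_CUTOFF = 2.3   # Å, SG-SG
COORDINATION_SCAN = 3.0     # Å, metal-donor candidates recorded at parse time


class PDBFormatError(ValueError):
    """Raised for unparseable or inconsistent PDB content."""


class StructureError(ValueError):
    """Raised for chemically inconsistent structures."""


ResidueKey = tuple[str, str, int, str]  # chain, resname, resnum, icode


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_key: ResidueKey
    coords: np.ndarray
    is_hetero: bool = False
    formal_charge_hint: int | None = None
    occupancy: float = 1.0
    altloc: str = ""
    formal_charge: int = 0  # assigned by assign_formal_charges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        ch, rn, num, _ = self.residue_key
        return f"<Atom {self.serial} {self.name} {rn}{num}:{ch}>"


@dataclass
class Bond:
    a: int
    b: int
    order: str = "single"  # single | double | aromatic | unspecified


@dataclass
class Residue:
    key: ResidueKey
    atoms: list[Atom] = field(default_factory=list)
    canonical_type: str = "other"
    # roles N, CA, C, O, CB, CG ... -> Atom
    backbone_atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.key[1]

    @property
    def number(self) -> int:
        return self.key[2]

    @property
    def chain(self) -> str:
        return self.key[0]

    @property
    def label(self) -> str:
        """Human-readable label like ``Leu167`` (DHI12 keeps its D name)."""
        return f"{self.name.capitalize()}{self.number}"

    @property
    def is_amino(self) -> bool:
        return self.canonical_type in ("L-amino", "D-amino",
                                       "non-natural amino")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


class Structure:
    """Atoms + covalent bond graph + residue/chain organization."""

    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self._by_serial: dict[int, Atom] = {}
        self.bonds: nx.Graph = nx.Graph()
        self.residues: list[Residue] = []
        self._residue_by_key: dict[ResidueKey, Residue] = {}
        self.chain_topology: dict[str, str] = {}
        self.conect_pairs: list[tuple[int, int]] = []
        #: (metal serial, donor serial, distance Å) recorded by perceive_bonds
        self.coordination_candidates: list[tuple[int, int, float]] = []
        self._bonds_perceived = False

    # -- construction ---------------------------------------------------
    def add_atom(self, atom: Atom) -> None:
        if atom.serial in self._by_serial:
            raise PDBFormatError(f"duplicate atom serial {atom.serial}")
        if not np.all(np.isfinite(atom.coords)):
            raise StructureError(f"non-finite coordinates on atom "
                                 f"{atom.serial} {atom.name}")
        self.atoms.append(atom)
        self._by_serial[atom.serial] = atom
        res = self._residue_by_key.get(atom.residue_key)
        if res is None:
            res = Residue(key=atom.residue_key)
            self._residue_by_key[atom.residue_key] = res
            self.residues.append(res)
        res.atoms.append(atom)

    def atom_by_serial(self, serial: int) -> Atom:
        try:
            return self._by_serial[serial]
        except KeyError:
            raise StructureError(f"no atom with serial {serial}")

    def residue_of(self, serial: int) -> Residue:
        return self._residue_by_key[self.atom_by_serial(serial).residue_key]

    @property
    def total_formal_charge(self) -> int:
        return int(sum(a.formal_charge for a in self.atoms))

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def classify_residues(self) -> None:
        """Assign canonical_type and backbone roles for every residue."""
        for res in self.residues:
            name = res.name.upper()
            tmpl = templates.template_for(name)
            if name in templates.WATER_NAMES:
                res.canonical_type = "water"
            elif len(res.atoms) == 1 and res.atoms[0].element in METALS:
                res.canonical_type = "metal ion"
            elif tmpl == "AIB" or name == "AIB":
                res.canonical_type = "non-natural amino"
            elif tmpl is not None and templates.is_d_residue(name):
                res.canonical_type = "D-amino"
            elif tmpl is not None:
                res.canonical_type = "L-amino"
            elif any(a.is_hetero for a in res.atoms):
                res.canonical_type = "ligand"
            else:
                res.canonical_type = "other"
            res.backbone_atoms = {}
            if res.is_amino:
                for role in ("N", "CA", "C", "O", "CB", "CG", "SG", "OXT"):
                    a = res.atom(role)
                    if a is not None:
                        res.backbone_atoms[role] = a
            elif res.canonical_type == "water":
                a = res.atom("O") or res.atom("OW")
                if a is not None:
                    res.backbone_atoms["O"] = a


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_coordinate_record(line: str, lineno: int):
    rec = line[:6].strip()
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        chargef = line[78:80].strip() if len(line) >= 80 else ""
    except (ValueError, IndexError):
        # lenient whitespace fallback for hand-made files
        toks = line.split()
        try:
            serial = int(toks[1]); name = toks[2]; resname = toks[3]
            chain = toks[4]; resnum = int(toks[5])
            x, y, z = (float(t) for t in toks[6:9])
            altloc = icode = element = chargef = ""
            occ = 1.0
        except (ValueError, IndexError):
            raise PDBFormatError(
                f"unparseable {rec or 'coordinate'} record at line {lineno}")
    hint = None
    if chargef:
        digits = "".join(c for c in chargef if c.isdigit())
        if digits:
            hint = int(digits) * (-1 if "-" in chargef else 1)
    return (rec, serial, name, altloc, resname, chain, resnum, icode,
            x, y, z, occ, element, hint)


def read_pdb(path) -> Structure:
    """Read a PDB file into a :class:`Structure` (bonds not yet perceived).

    Alternate locations are resolved by keeping the highest-occupancy copy
    of each atom (ties broken by altloc letter order).  Elements come from
    the element column when present, else from atom-name heuristics.
    """
    with open(path) as fh:
        lines = fh.readlines()

    raw: list[tuple] = []
    conect: list[tuple[int, int]] = []
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            raw.append(_parse_coordinate_record(line, lineno))
        elif rec == "CONECT":
            try:
                serials = [int(line[i:i + 5])
                           for i in range(6, min(len(line.rstrip()), 31), 5)
                           if line[i:i + 5].strip()]
            except ValueError:
                raise PDBFormatError(f"unparseable CONECT record at line "
                                     f"{lineno}")
            for other in serials[1:]:
                pair = tuple(sorted((serials[0], other)))
                if pair not in conect:
                    conect.append(pair)  # type: ignore[arg-type]

    # altloc resolution: keep highest occupancy per (residue key, atom name)
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for entry in raw:
        (rec, serial, name, altloc, resname, chain, resnum, icode,
         x, y, z, occ, element, hint) = entry
        key = (chain, resname, resnum, icode, name)
        prev = best.get(key)
        if prev is None:
            best[key] = entry
            order.append(key)
        else:
            if occ > prev[11] or (occ == prev[11]
                                  and _alt_rank(altloc) > _alt_rank(prev[3])):
                best[key] = entry

    st = Structure()
    for key in order:
        (rec, serial, name, altloc, resname, chain, resnum, icode,
         x, y, z, occ, element, hint) = best[key]
        is_het = rec == "HETATM"
        el = normalize_element(element) if element else ""
        if not el:
            el = infer_element(name, resname, is_het)
        try:
            st.add_atom(Atom(serial=serial, name=name, element=el,
                             residue_key=(chain, resname, resnum, icode),
                             coords=np.array([x, y, z], dtype=float),
                             is_hetero=is_het, formal_charge_hint=hint,
                             occupancy=occ, altloc=altloc))
        except PDBFormatError:
            raise PDBFormatError(
                f"duplicate atom serial {serial} after altloc resolution")
    st.conect_pairs = conect
    st.classify_residues()
    return st


def _alt_rank(altloc: str) -> int:
    """Higher rank wins ties; 'A' beats 'B', blank beats all."""
    if not altloc:
        return 1000
    return 255 - ord(altloc)


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as PDB text; round-trips through :func:`read_pdb`."""
    if len(structure.atoms) > 99999:
        raise PDBFormatError("PDB format supports at most 99,999 atoms")
    lines: list[str] = []
    last_chain = None
    for atom in structure.atoms:
        chain, resname, resnum, icode = atom.residue_key
        if len(atom.name) > 4:
            raise PDBFormatError(f"atom name {atom.name!r} exceeds the "
                                 f"4-character PDB field")
        if last_chain is not None and chain != last_chain:
            lines.append("TER")
        last_chain = chain
        rec = "HETATM" if atom.is_hetero else "ATOM  "
        # standard alignment: 1-letter elements start in column 14
        if len(atom.element) == 1 and len(atom.name) < 4:
            name_field = f" {atom.name:<3s}"
        else:
            name_field = f"{atom.name:<4s}"
        charge_field = "  "
        if atom.formal_charge_hint:
            sign = "-" if atom.formal_charge_hint < 0 else "+"
            charge_field = f"{abs(atom.formal_charge_hint)}{sign}"
        x, y, z = atom.coords
        lines.append(
            f"{rec}{atom.serial:>5d} {name_field}{atom.altloc or ' ':1s}"
            f"{resname:>3s} {chain:1s}{resnum:>4d}{icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}{charge_field}")
    for a, b in structure.conect_pairs:
        lines.append(f"CONECT{a:>5d}{b:>5d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Bond perception
# ---------------------------------------------------------------------------

def perceive_bonds(structure: Structure) -> Structure:
    """Populate the covalent bond graph in place (and return the structure).

    Named residues get template bonds; unknown residues are bonded by the
    covalent-radius rule (also to neighbouring residues, which captures
    covalent ligands); inter-residue peptide and disulfide bonds are added
    by distance; CONECT records are honoured.  Metal ions get no bonds —
    nearby donors are stored as coordination candidates.
    """
    structure.classify_residues()
    g = nx.Graph()
    g.add_nodes_from(a.serial for a in structure.atoms)

    # hydrogen presence check on the polymer
    amino = [r for r in structure.residues if r.is_amino]
    bare = [r.key for r in amino
            if not any(a.element == "H" for a in r.atoms)]
    if amino and len(bare) == len(amino):
        raise StructureError(
            "no hydrogens found on any amino residue; protonate the "
            "structure before fragmentation")

    coords = structure.coords_array()
    tree = cKDTree(coords) if len(structure.atoms) else None
    serials = [a.serial for a in structure.atoms]
    index_of = {s: i for i, s in enumerate(serials)}

    def dist(a: Atom, b: Atom) -> float:
        return float(np.linalg.norm(a.coords - b.coords))

    metal_serials = {a.serial for r in structure.residues
                     if r.canonical_type == "metal ion" for a in r.atoms}

    # 1. intra-residue bonds
    for res in structure.residues:
        if res.canonical_type == "metal ion":
            continue
        if res.canonical_type == "water":
            o = res.backbone_atoms.get("O")
            for a in res.atoms:
                if a.element == "H" and o is not None:
                    g.add_edge(o.serial, a.serial, order="single")
            continue
        tmpl = templates.template_for(res.name)
        if res.is_amino and tmpl is not None:
            for role in ("N", "CA", "C"):
                if res.atom(role) is None:
                    raise StructureError(
                        f"amino residue {res.key} is missing backbone "
                        f"atom {role}")
            by_name = {a.name: a for a in res.atoms}
            for na, nb in templates.template_bonds(res.name):
                if na in by_name and nb in by_name:
                    g.add_edge(by_name[na].serial, by_name[nb].serial,
                               order="single")
            # hydrogens or atoms the template does not know (rare variants):
            leftover = [a for a in res.atoms
                        if g.degree(a.serial) == 0 and a.element == "H"]
            for h in leftover:
                heavy = min((a for a in res.atoms if a.element != "H"),
                            key=lambda a: dist(a, h))
                if dist(heavy, h) <= covalent_cutoff(heavy.element, "H"):
                    g.add_edge(heavy.serial, h.serial, order="single")
        else:
            # unknown residue / ligand: covalent-radius rule, including
            # bonds to atoms of other residues (covalent attachment)
            for a in res.atoms:
                cut = 1.25 * (COVALENT_RADII[a.element] + 0.84)
                for j in tree.query_ball_point(a.coords, cut + 0.6):
                    b = structure.atoms[j]
                    if b.serial == a.serial or b.serial in metal_serials:
                        continue
                    if a.element == "H" and b.element == "H":
                        continue
                    if a.element == "H" and g.degree(a.serial):
                        continue
                    d = dist(a, b)
                    if d <= covalent_cutoff(a.element, b.element):
                        if b.residue_key == a.residue_key or \
                                structure._residue_by_key[b.residue_key].canonical_type != "metal ion":
                            g.add_edge(a.serial, b.serial, order="single")

    # 2. inter-residue peptide bonds C(i)-N(j)
    carbons = [r.backbone_atoms["C"] for r in amino if "C" in r.backbone_atoms]
    nitrogens = [r.backbone_atoms["N"] for r in amino
                 if "N" in r.backbone_atoms]
    for c in carbons:
        for n in nitrogens:
            if c.residue_key == n.residue_key:
                continue
            if dist(c, n) <= PEPTIDE_CN_CUTOFF:
                g.add_edge(c.serial, n.serial, order="single")

    # 3. disulfides
    sgs = [a for r in amino for a in r.atoms if a.name == "SG"]
    for i, a in enumerate(sgs):
        for b in sgs[i + 1:]:
            if dist(a, b) <= DISULFIDE_SS_CUTOFF:
                g.add_edge(a.serial, b.serial, order="single")

    # 4. CONECT records (metal CONECTs become coordination candidates)
    candidates: list[tuple[int, int, float]] = []
    for a_s, b_s in structure.conect_pairs:
        if a_s not in index_of or b_s not in index_of:
            continue
        a, b = structure.atom_by_serial(a_s), structure.atom_by_serial(b_s)
        if a_s in metal_serials or b_s in metal_serials:
            m, d_at = (a, b) if a_s in metal_serials else (b, a)
            candidates.append((m.serial, d_at.serial, dist(a, b)))
            continue
        g.add_edge(a_s, b_s, order="single")

    # 5. metal coordination candidates by distance
    for m_serial in metal_serials:
        m = structure.atom_by_serial(m_serial)
        for j in tree.query_ball_point(m.coords, COORDINATION_SCAN):
            b = structure.atoms[j]
            if b.serial == m_serial or b.element not in DONOR_ELEMENTS:
                continue
            d = dist(m, b)
            if not any(c[0] == m_serial and c[1] == b.serial
                       for c in candidates):
                candidates.append((m_serial, b.serial, d))
    candidates.sort(key=lambda t: (t[0], t[2]))

    structure.bonds = g
    structure.coordination_candidates = candidates
    structure._bonds_perceived = True
    assign_formal_charges(structure)
    # chain topology needs the sequence walk
    for chain in structure.chains():
        try:
            _, cyclic = _walk_chain(structure, chain)
            structure.chain_topology[chain] = "cyclic" if cyclic else "linear"
        except StructureError:
            structure.chain_topology[chain] = "linear"
    return structure


# ---------------------------------------------------------------------------
# Formal charges
# ---------------------------------------------------------------------------

def _h_count(structure: Structure, atom: Atom) -> int:
    return sum(1 for n in structure.bonds.neighbors(atom.serial)
               if structure.atom_by_serial(n).element == "H")


def assign_formal_charges(structure: Structure) -> None:
    """Derive per-atom formal charges from templates + explicit hydrogens.

    The charge sits on a specific atom (NZ, OE2, OXT, ...) so that any
    partition of atoms into fragments conserves total charge by summation.
    """
    for a in structure.atoms:
        a.formal_charge = 0
    for res in structure.residues:
        if res.canonical_type == "metal ion":
            a = res.atoms[0]
            hint = a.formal_charge_hint
            a.formal_charge = hint if hint is not None \
                else ION_CHARGES.get(a.element, 0)
            continue
        if res.canonical_type == "water":
            continue
        if not res.is_amino:
            # ligands: use explicit PDB charge hints only
            for a in res.atoms:
                if a.formal_charge_hint:
                    a.formal_charge = a.formal_charge_hint
            continue
        tmpl = templates.template_for(res.name)
        by_name = {a.name: a for a in res.atoms}

        def hc(name: str) -> int:
            a = by_name.get(name)
            return _h_count(structure, a) if a is not None else 0

        # N-terminus / protonated amine
        n = by_name.get("N")
        if n is not None and _h_count(structure, n) == 3:
            n.formal_charge = 1
        if tmpl == "PRO" and n is not None and _h_count(structure, n) == 2:
            n.formal_charge = 1
        # C-terminal carboxylate
        oxt = by_name.get("OXT")
        if oxt is not None and _h_count(structure, oxt) == 0:
            oxt.formal_charge = -1
        if tmpl == "LYS" and hc("NZ") == 3:
            by_name["NZ"].formal_charge = 1
        elif tmpl == "ARG" and (hc("NE") + hc("NH1") + hc("NH2")) >= 5:
            by_name["NH2"].formal_charge = 1
        elif tmpl == "ASP" and "OD2" in by_name \
                and hc("OD1") + hc("OD2") == 0:
            by_name["OD2"].formal_charge = -1
        elif tmpl == "GLU" and "OE2" in by_name \
                and hc("OE1") + hc("OE2") == 0:
            by_name["OE2"].formal_charge = -1
        elif tmpl == "HIS" and hc("ND1") >= 1 and hc("NE2") >= 1:
            by_name["ND1"].formal_charge = 1
        elif tmpl == "CYS" and "SG" in by_name:
            sg = by_name["SG"]
            if _h_count(structure, sg) == 0 \
                    and structure.bonds.degree(sg.serial) == 1:
                sg.formal_charge = -1
        elif tmpl == "TYR" and "OH" in by_name and hc("OH") == 0:
            by_name["OH"].formal_charge = -1


# ---------------------------------------------------------------------------
# Residue sequence
# ---------------------------------------------------------------------------

@dataclass
class ChainSequence:
    chain: str
    residues: list[Residue]
    cyclic: bool
    breaks: list[int] = field(default_factory=list)  # index after which break

    @property
    def has_termini(self) -> bool:
        return not self.cyclic


def _walk_chain(structure: Structure, chain: str):
    """Order a chain's amino residues by peptide connectivity."""
    amino = [r for r in structure.residues
             if r.chain == chain and r.is_amino]
    if not amino:
        return [], False
    succ: dict[ResidueKey, ResidueKey] = {}
    pred: dict[ResidueKey, ResidueKey] = {}
    keys = {r.key for r in amino}
    for r in amino:
        c = r.backbone_atoms.get("C")
        if c is None:
            continue
        nxts = []
        for nb in structure.bonds.neighbors(c.serial):
            b = structure.atom_by_serial(nb)
            if b.name == "N" and b.residue_key in keys \
                    and b.residue_key != r.key:
                nxts.append(b.residue_key)
        if len(nxts) > 1:
            raise StructureError(f"branched backbone at residue {r.key}")
        if nxts:
            if nxts[0] in pred:
                raise StructureError(f"branched backbone at residue "
                                     f"{nxts[0]}")
            succ[r.key] = nxts[0]
            pred[nxts[0]] = r.key
    starts = [r for r in amino if r.key not in pred]
    by_key = {r.key: r for r in amino}
    if not starts:
        # cyclic: every residue has a predecessor
        start = min(amino, key=lambda r: (r.number, r.key[3]))
        ordered = [start]
        cur = start.key
        while True:
            nxt = succ.get(cur)
            if nxt is None or nxt == start.key:
                break
            ordered.append(by_key[nxt])
            cur = nxt
        if len(ordered) != len(amino) or succ.get(cur) != start.key:
            raise StructureError(f"inconsistent cyclic backbone in chain "
                                 f"{chain}")
        return ordered, True
    ordered = []
    for s in sorted(starts, key=lambda r: (r.number, r.key[3])):
        cur: ResidueKey | None = s.key
        while cur is not None:
            ordered.append(by_key[cur])
            cur = succ.get(cur)
    if len(ordered) != len(amino):
        raise StructureError(f"backbone connectivity does not cover chain "
                             f"{chain}")
    return ordered, False


def residue_sequence(structure: Structure) -> list[ChainSequence]:
    """Peptide-connectivity-ordered residues per chain, plus lone units.

    Waters, ions and ligands are returned as independent single-residue
    chains (``cyclic=False``).
    """
    if not structure._bonds_perceived:
        raise StructureError("perceive_bonds must run before "
                             "residue_sequence")
    out: list[ChainSequence] = []
    for chain in structure.chains():
        ordered, cyclic = _walk_chain(structure, chain)
        if ordered:
            breaks = []
            for i in range(len(ordered) - 1):
                c = ordered[i].backbone_atoms.get("C")
                n = ordered[i + 1].backbone_atoms.get("N")
                if c is None or n is None or \
                        not structure.bonds.has_edge(c.serial, n.serial):
                    breaks.append(i)
            out.append(ChainSequence(chain, ordered, cyclic, breaks))
        for r in structure.residues:
            if r.chain == chain and not r.is_amino:
                out.append(ChainSequence(chain, [r], False))
    return out
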