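"""CPF-style FMO result files: monomer properties and dimer IFIE/PIEDA.

The on-disk dialect is this package's versioned reference format (header
``CPF FMOFRAG 1.0``; grammar in ``docs/formats.md``).  Files store energies
in hartree; in memory, dimer PIEDA components and IFIE totals are kept in
kcal/mol (1 hartree = 627.5095 kcal/mol).  The PIEDA additivity invariant
ES + EX + (CT+mix) + DI = MP2 total is checked on read and surfaced as a
list of deviations — never silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HARTREE_TO_KCAL = 627.5095
ADDITIVITY_TOL = 0.01  # kcal/mol
VERSION_LINE = "CPF FMOFRAG 1.0"


class CPFError(ValueError):
    pass


@dataclass
class AtomMeta:
    serial: int
    name: str
    element: str
    resname: str
    chain: str
    resnum: int


@dataclass
class FragmentMeta:
    id: int
    name: str
    charge: int
    atom_serials: tuple[int, ...]


@dataclass
class MonomerRecord:
    fragment_id: int
    energy: float  # hartree
    charges: dict[str, np.ndarray] = field(default_factory=dict)
    # keys: mulliken | npa | esp; arrays aligned to the fragment atom order


@dataclass
class DimerRecord:
    i: int
    j: int
    min_distance: float  # Å
    es: float            # kcal/mol
    ex: float
    ct_mix: float
    di: float
    total_hf: float
    total_mp2: float

    def components(self) -> dict[str, float]:
        return {"ES": self.es, "EX": self.ex, "CT+mix": self.ct_mix,
                "DI": self.di}

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class FMOResult:
    version: str = VERSION_LINE
    method: str = "MP2"
    basis: str = "6-31G*"
    title: str = ""
    atoms: list[AtomMeta] = field(default_factory=list)
    fragments: list[FragmentMeta] = field(default_factory=list)
    detached_bonds: list[tuple[int, int]] = field(default_factory=list)
    monomers: list[MonomerRecord] = field(default_factory=list)
    dimers: list[DimerRecord] = field(default_factory=list)
    total_energy: float = 0.0  # hartree
    additivity_deviations: list[tuple[int, int, float]] = \
        field(default_factory=list)

    # -- lookups --------------------------------------------------------
    def fragment_by_id(self, fid: int) -> FragmentMeta:
        for f in self.fragments:
            if f.id == fid:
                return f
        raise CPFError(f"no fragment with id {fid}")

    def fragment_by_name(self, name: str) -> FragmentMeta:
        for f in self.fragments:
            if f.name == name:
                return f
        raise CPFError(f"no fragment named {name!r}")

    def atom_to_fragment(self) -> dict[int, int]:
        return {s: f.id for f in self.fragments for s in f.atom_serials}

    def dimer_map(self) -> dict[tuple[int, int], DimerRecord]:
        return {(d.i, d.j): d for d in self.dimers}

    def adjacency_pairs(self) -> set[tuple[int, int]]:
        """Fragment pairs sharing a detached bond (BDA next to BAA)."""
        a2f = self.atom_to_fragment()
        out = set()
        for a, b in self.detached_bonds:
            fa, fb = a2f.get(a), a2f.get(b)
            if fa is not None and fb is not None and fa != fb:
                out.add((min(fa, fb), max(fa, fb)))
        return out

    def monomer_by_id(self, fid: int) -> MonomerRecord:
        for m in self.monomers:
            if m.fragment_id == fid:
                return m
        raise CPFError(f"no monomer record for fragment {fid}")

    def atom_meta(self, serial: int) -> AtomMeta:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise CPFError(f"no atom metadata for serial {serial}")

    def validate_echo(self) -> list[str]:
        """Check the fragmentation echo: partition + dimer uniqueness."""
        problems = []
        seen: dict[int, int] = {}
        for f in self.fragments:
            for s in f.atom_serials:
                seen[s] = seen.get(s, 0) + 1
        if self.atoms:
            serials = {a.serial for a in self.atoms}
            missing = serials - set(seen)
            if missing:
                problems.append(f"atoms in no fragment: "
                                f"{sorted(missing)[:10]}")
        dupes = [s for s, c in seen.items() if c > 1]
        if dupes:
            problems.append(f"atoms in multiple fragments: {dupes[:10]}")
        pairs = [d.pair for d in self.dimers]
        if len(pairs) != len(set(pairs)):
            problems.append("duplicate dimer records")
        for d in self.dimers:
            if not d.i < d.j:
                problems.append(f"dimer ({d.i},{d.j}) not ordered i<j")
        return problems


_F = "{:+.12e}"


def write_cpf(result: FMOResult, path) -> None:
    """Write the reference dialect; ``read_cpf`` inverts it exactly."""
    for d in result.dimers:
        dev = d.es + d.ex + d.ct_mix + d.di - d.total_mp2
        if abs(dev) > ADDITIVITY_TOL:
            raise CPFError(
                f"dimer ({d.i},{d.j}): ES+EX+CT+mix+DI deviates from the "
                f"MP2 total by {dev:.4f} kcal/mol (tolerance "
                f"{ADDITIVITY_TOL})")
    lines = [VERSION_LINE]
    lines.append(f"METHOD {result.method}")
    lines.append(f"BASIS {result.basis}")
    lines.append(f"TITLE {result.title}")
    lines.append(f"NATOM {len(result.atoms)}")
    for a in result.atoms:
        lines.append(f"ATOM {a.serial} {a.name} {a.element} {a.resname} "
                     f"{a.chain} {a.resnum}")
    lines.append(f"NFRAG {len(result.fragments)}")
    for f in result.fragments:
        lines.append(f"FRAGMENT {f.id} {f.name} {f.charge:+d} "
                     f"{len(f.atom_serials)}")
        lines.append("  " + " ".join(str(s) for s in f.atom_serials))
    lines.append(f"DETACHED {len(result.detached_bonds)}")
    for a, b in result.detached_bonds:
        lines.append(f"  {a} {b}")
    for m in result.monomers:
        lines.append(f"MONOMER {m.fragment_id} " + _F.format(m.energy))
        for scheme in ("mulliken", "npa", "esp"):
            if scheme in m.charges:
                vals = " ".join(_F.format(v) for v in m.charges[scheme])
                lines.append(f"  CHARGES {scheme.upper()} {vals}")
    lines.append(f"NDIMER {len(result.dimers)}")
    for d in result.dimers:
        h = [v / HARTREE_TO_KCAL
             for v in (d.es, d.ex, d.ct_mix, d.di, d.total_hf, d.total_mp2)]
        lines.append(f"DIMER {d.i} {d.j} {d.min_distance:.4f} "
                     + " ".join(_F.format(v) for v in h))
    lines.append("TOTAL_ENERGY " + _F.format(result.total_energy))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cpf(path) -> FMOResult:
    """Parse a CPF file; dimer energies are converted to kcal/mol."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0].strip() != VERSION_LINE:
        head = lines[0].strip() if lines else "<empty file>"
        raise CPFError(f"unknown CPF version header {head!r}; this reader "
                       f"supports {VERSION_LINE!r}")
    res = FMOResult(version=lines[0].strip())
    i = 1
    ndimer_declared = None
    while i < len(lines):
        ln = lines[i].strip()
        if not ln:
            i += 1
            continue
        toks = ln.split()
        key = toks[0]
        if key == "METHOD":
            res.method = toks[1]
        elif key == "BASIS":
            res.basis = toks[1]
        elif key == "TITLE":
            res.title = ln[6:]
        elif key == "NATOM":
            pass
        elif key == "ATOM":
            res.atoms.append(AtomMeta(int(toks[1]), toks[2], toks[3],
                                      toks[4], toks[5], int(toks[6])))
        elif key == "NFRAG":
            pass
        elif key == "FRAGMENT":
            fid, name, charge, nat = (int(toks[1]), toks[2], int(toks[3]),
                                      int(toks[4]))
            i += 1
            serials = tuple(int(t) for t in lines[i].split())
            if len(serials) != nat:
                raise CPFError(f"fragment {fid}: expected {nat} atom "
                               f"serials, found {len(serials)}")
            res.fragments.append(FragmentMeta(fid, name, charge, serials))
        elif key == "DETACHED":
            nb = int(toks[1])
            for _ in range(nb):
                i += 1
                a, b = lines[i].split()
                res.detached_bonds.append((int(a), int(b)))
        elif key == "MONOMER":
            mon = MonomerRecord(int(toks[1]), float(toks[2]))
            while i + 1 < len(lines) and \
                    lines[i + 1].strip().startswith("CHARGES"):
                i += 1
                ct = lines[i].split()
                mon.charges[ct[1].lower()] = np.array(
                    [float(v) for v in ct[2:]])
            res.monomers.append(mon)
        elif key == "NDIMER":
            ndimer_declared = int(toks[1])
        elif key == "DIMER":
            if len(toks) != 10:
                raise CPFError(f"truncated dimer record: {ln!r}")
            fi, fj = int(toks[1]), int(toks[2])
            dist = float(toks[3])
            es, ex, ct, di, thf, tmp2 = (
                float(t) * HARTREE_TO_KCAL for t in toks[4:10])
            res.dimers.append(DimerRecord(fi, fj, dist, es, ex, ct, di,
                                          thf, tmp2))
        elif key == "TOTAL_ENERGY":
            res.total_energy = float(toks[1])
        else:
            raise CPFError(f"unknown CPF directive {key!r} at line {i + 1}")
        i += 1
    if ndimer_declared is not None and ndimer_declared != len(res.dimers):
        raise CPFError(f"truncated dimer table: header declares "
                       f"{ndimer_declared} dimers, file has "
                       f"{len(res.dimers)}")
    for d in res.dimers:
        dev = d.es + d.ex + d.ct_mix + d.di - d.total_mp2
        if abs(dev) > ADDITIVITY_TOL:
            res.additivity_deviations.append((d.i, d.j, dev))
    # charge arrays must align with fragment atom counts
    frag_sizes = {f.id: len(f.atom_serials) for f in res.fragments}
    for m in res.monomers:
        for scheme, arr in m.charges.items():
            want = frag_sizes.get(m.fragment_id)
            if want is not None and len(arr) != want:
                raise CPFError(
                    f"monomer {m.fragment_id}: {scheme} charge array has "
                    f"{len(arr)} values for a {want}-atom fragment")
    return res
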