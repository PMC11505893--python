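"""ABINIT-MP-style input decks: writing from a Fragmentation, reading back.

The deck layout (block names, 10-indices-per-line wrapping) is this
package's documented reference dialect — see ``docs/formats.md`` for the
grammar.  Output is byte-stable for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fragmentation import (DetachedBond, Fragment, Fragmentation,
                            FragmentationError, validate)
from .structure import Structure

WRAP = 10  # indices per line

METHODS = ("HF", "MP2")
BASES = ("6-31G", "6-31G*")


class DeckError(ValueError):
    pass


@dataclass
class JobConfig:
    method: str = "MP2"
    basis: str = "6-31G*"
    title: str = "fmofrag job"
    extra: dict[str, str] = field(default_factory=dict)  # opaque pass-through

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DeckError(f"unsupported method {self.method!r}; "
                            f"choose from {METHODS}")
        if self.basis not in BASES:
            raise DeckError(f"unsupported basis {self.basis!r}; "
                            f"choose from {BASES}")


def _wrap(values, fmt: str = "{}") -> list[str]:
    out = []
    for i in range(0, len(values), WRAP):
        out.append(" " + " ".join(fmt.format(v)
                                  for v in values[i:i + WRAP]))
    return out


def write_input(structure: Structure, fragmentation: Fragmentation,
                job: JobConfig) -> str:
    """Render the input deck as text; raises on validation violations."""
    rep = validate(fragmentation)
    if not rep.ok:
        raise DeckError("fragmentation does not validate:\n  "
                        + "\n  ".join(rep.violations))
    for f in fragmentation.fragments:
        if not isinstance(f.formal_charge, int):
            raise DeckError(f"fragment {f.id} has non-integral charge "
                            f"{f.formal_charge!r}")
    lines: list[str] = []
    lines.append("&CNTRL")
    lines.append(f"  Title='{job.title}'")
    lines.append(f"  Method='{job.method}'")
    lines.append(f"  Basis='{job.basis}'")
    for k, v in sorted(job.extra.items()):
        lines.append(f"  {k}='{v}'")
    lines.append("&END")

    frags = fragmentation.fragments
    lines.append("&FRAGMENT")
    lines.append(f"NF={len(frags)}")
    lines.append("NATOMS")
    lines += _wrap([len(f.atom_serials) for f in frags])
    lines.append("CHARGES")
    lines += _wrap([f.formal_charge for f in frags])
    lines.append("NAMES")
    lines += _wrap([f.name for f in frags])
    for f in frags:
        lines.append(f"ASSIGN {f.id}")
        lines += _wrap(sorted(f.atom_serials))
    lines.append(f"BONDS {len(fragmentation.detached_bonds)}")
    for db in fragmentation.detached_bonds:
        lines.append(f" {db.bda} {db.baa}")
    lines.append("&END")

    lines.append("&GEOM")
    for a in structure.atoms:
        x, y, z = a.coords
        lines.append(f" {a.serial:>6d} {a.element:>2s} {a.name:<4s} "
                     f"{x:14.8f} {y:14.8f} {z:14.8f}")
    lines.append("&END")
    return "\n".join(lines) + "\n"


@dataclass
class FragmentationSkeleton:
    """Atom-to-fragment assignment parsed from a deck (no structure)."""
    assignments: dict[int, int]          # atom serial -> fragment id
    charges: dict[int, int]              # fragment id -> charge
    names: dict[int, str]                # fragment id -> name
    detached_bonds: list[tuple[int, int]]

    def canonical(self):
        """Order-independent form: partition keyed by lowest atom serial."""
        groups: dict[int, set[int]] = {}
        for serial, fid in self.assignments.items():
            groups.setdefault(fid, set()).add(serial)
        parts = sorted(groups.items(), key=lambda kv: min(kv[1]))
        return (tuple((frozenset(s), self.charges.get(fid),
                       self.names.get(fid)) for fid, s in parts),
                frozenset(frozenset(p) for p in self.detached_bonds))

    def to_fragmentation(self, structure: Structure) -> Fragmentation:
        frag = Fragmentation(structure)
        groups: dict[int, set[int]] = {}
        for serial, fid in self.assignments.items():
            groups.setdefault(fid, set()).add(serial)
        for fid, serials in sorted(groups.items()):
            frag.fragments.append(Fragment(
                fid, self.names.get(fid, f"F{fid}"), frozenset(serials),
                self.charges.get(fid, 0)))
        frag.detached_bonds = [DetachedBond(a, b)
                               for a, b in self.detached_bonds]
        frag._renumber()
        return frag


def read_input(text: str) -> tuple[FragmentationSkeleton, JobConfig]:
    """Parse a deck produced by :func:`write_input` (or a conforming one)."""
    lines = [ln.rstrip() for ln in text.splitlines()]
    i = 0
    job_kv: dict[str, str] = {}
    nf = None
    natoms: list[int] = []
    charges: list[int] = []
    names: list[str] = []
    assigns: dict[int, list[int]] = {}
    bonds: list[tuple[int, int]] = []

    def tokens_until_count(start: int, count: int):
        # value lines are emitted with a leading space; section keywords
        # start in column one
        vals: list[str] = []
        j = start
        while len(vals) < count and j < len(lines):
            ln = lines[j]
            if not ln.strip() or not ln.startswith(" "):
                break
            vals += ln.split()
            j += 1
        return vals, j

    while i < len(lines):
        ln = lines[i].strip()
        if ln == "&CNTRL":
            i += 1
            while i < len(lines) and lines[i].strip() != "&END":
                key, _, val = lines[i].strip().partition("=")
                job_kv[key.strip()] = val.strip().strip("'")
                i += 1
        elif ln == "&FRAGMENT":
            i += 1
            while i < len(lines) and lines[i].strip() != "&END":
                s = lines[i].strip()
                if s.startswith("NF="):
                    nf = int(s[3:])
                    i += 1
                elif s == "NATOMS":
                    vals, i = tokens_until_count(i + 1, nf or 10 ** 9)
                    natoms = [int(v) for v in vals]
                elif s == "CHARGES":
                    vals, i = tokens_until_count(i + 1, nf or 10 ** 9)
                    charges = [int(v) for v in vals]
                elif s == "NAMES":
                    vals, i = tokens_until_count(i + 1, nf or 10 ** 9)
                    names = vals
                elif s.startswith("ASSIGN"):
                    fid = int(s.split()[1])
                    if fid in assigns:
                        raise DeckError(f"duplicate ASSIGN block for "
                                        f"fragment {fid}")
                    idx = fid - 1
                    want = natoms[idx] if idx < len(natoms) else 10 ** 9
                    vals, i = tokens_until_count(i + 1, want)
                    assigns[fid] = [int(v) for v in vals]
                elif s.startswith("BONDS"):
                    nb = int(s.split()[1])
                    i += 1
                    for _ in range(nb):
                        a, bb = lines[i].split()
                        bonds.append((int(a), int(bb)))
                        i += 1
                else:
                    i += 1
        elif ln == "&GEOM":
            i += 1
            while i < len(lines) and lines[i].strip() != "&END":
                i += 1
        i += 1

    if nf is None:
        raise DeckError("deck has no NF entry")
    for seq, label in ((natoms, "NATOMS"), (charges, "CHARGES")):
        if len(seq) != nf:
            raise DeckError(f"NF={nf} but {label} lists {len(seq)} entries")
    if set(assigns) != set(range(1, nf + 1)):
        raise DeckError(f"NF={nf} but ASSIGN blocks cover fragments "
                        f"{sorted(assigns)}")
    for fid, serials in assigns.items():
        if len(serials) != natoms[fid - 1]:
            raise DeckError(f"fragment {fid}: NATOMS says "
                            f"{natoms[fid - 1]} but ASSIGN lists "
                            f"{len(serials)}")
    assignments = {s: fid for fid, serials in assigns.items()
                   for s in serials}
    skel = FragmentationSkeleton(
        assignments=assignments,
        charges={fid: charges[fid - 1] for fid in assigns},
        names={fid: names[fid - 1] for fid in assigns
               if fid - 1 < len(names)},
        detached_bonds=bonds)
    job = JobConfig(method=job_kv.get("Method", "MP2"),
                    basis=job_kv.get("Basis", "6-31G*"),
                    title=job_kv.get("Title", ""),
                    extra={k: v for k, v in job_kv.items()
                           if k not in ("Method", "Basis", "Title")})
    return skel, job
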