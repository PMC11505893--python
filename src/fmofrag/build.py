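"""Deterministic ideal-geometry polypeptide builder.

Builds fully protonated peptides from a one-letter sequence in which lower
case selects the D-enantiomer and ``X`` is the non-natural residue AIB
(alpha-aminoisobutyric acid).  Linear chains are extended; cyclic chains
place the backbone on a circle so the closing C-N distance falls inside
the peptide-bond cutoff.  Geometric realism is explicitly not a goal —
bond topology, atom naming, protonation and chirality bookkeeping are.
"""

from __future__ import annotations

import math

import numpy as np

from . import templates
from .structure import Atom, Structure, perceive_bonds

# canonical bond lengths (Å) by element pair
_BOND_LENGTHS = {
    frozenset(["C"]): 1.53,
    frozenset(["C", "N"]): 1.47,
    frozenset(["C", "O"]): 1.43,
    frozenset(["C", "S"]): 1.81,
    frozenset(["C", "H"]): 1.09,
    frozenset(["N", "H"]): 1.01,
    frozenset(["O", "H"]): 0.96,
    frozenset(["S", "H"]): 1.34,
}
N_CA, CA_C, C_N = 1.458, 1.525, 1.329
C_O = 1.231
TETRA = math.radians(109.47)


def bond_length(el_a: str, el_b: str) -> float:
    return _BOND_LENGTHS.get(frozenset([el_a, el_b]), 1.5)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        return np.array([0.0, 0.0, 1.0])
    return v / n


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given reference atoms a-b-c (natural extension frame)."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d2 = bond * np.array([-math.cos(ang),
                          math.cos(dih) * math.sin(ang),
                          math.sin(dih) * math.sin(ang)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _perp_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(ref, axis))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(ref - np.dot(ref, axis) * axis)
    return u, np.cross(axis, u)


def _cone_positions(center: np.ndarray, known: list[np.ndarray],
                    n_new: int, length: float,
                    phase: float = 0.0) -> list[np.ndarray]:
    """Distribute ``n_new`` substituents around ``center``.

    The axis points away from the mean of the known neighbours; new bonds
    sit on a tetrahedral-ish cone around it.  Deterministic.
    """
    if known:
        axis = _unit(-sum((_unit(k - center) for k in known),
                          np.zeros(3)))
    else:
        axis = np.array([0.0, 0.0, 1.0])
    if n_new == 1 and len(known) >= 2:
        return [center + length * axis]
    u, v = _perp_frame(axis)
    half = math.pi - TETRA  # ~70.5 deg off-axis
    out = []
    for j in range(n_new):
        az = phase + 2.0 * math.pi * j / max(n_new, 1)
        d = (math.cos(half) * axis
             + math.sin(half) * (math.cos(az) * u + math.sin(az) * v))
        out.append(center + length * _unit(d))
    return out


def _tetrahedral_pair(center: np.ndarray, a: np.ndarray,
                      b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two remaining substituent directions at an sp3 center."""
    ua, ub = _unit(a - center), _unit(b - center)
    m = _unit(ua + ub)
    p = _unit(np.cross(ua, ub))
    return _unit(-m + p), _unit(-m - p)


class _Builder:
    def __init__(self) -> None:
        self.names: list[str] = []
        self.elements: list[str] = []
        self.coords: list[np.ndarray] = []
        self.reskeys: list[tuple] = []
        self.het: list[bool] = []

    def add(self, name: str, element: str, pos: np.ndarray, reskey,
            het: bool = False) -> None:
        self.names.append(name)
        self.elements.append(element)
        self.coords.append(np.asarray(pos, dtype=float))
        self.reskeys.append(reskey)
        self.het.append(het)

    def pos(self, reskey, name: str) -> np.ndarray:
        for i in range(len(self.names) - 1, -1, -1):
            if self.reskeys[i] == reskey and self.names[i] == name:
                return self.coords[i]
        raise KeyError((reskey, name))

    def to_structure(self) -> Structure:
        st = Structure()
        for i in range(len(self.names)):
            st.add_atom(Atom(serial=i + 1, name=self.names[i],
                             element=self.elements[i],
                             residue_key=self.reskeys[i],
                             coords=self.coords[i],
                             is_hetero=self.het[i]))
        st.classify_residues()
        return st


def _parse_sequence(sequence: str) -> list[tuple[str, bool]]:
    """One-letter sequence -> [(PDB residue name, is_D)]."""
    out = []
    for ch in sequence:
        upper = ch.upper()
        if upper not in templates.ONE_LETTER:
            raise ValueError(f"unsupported sequence letter {ch!r}")
        tmpl = templates.ONE_LETTER[upper]
        if ch.islower():
            if tmpl in ("GLY", "AIB"):
                raise ValueError(f"{tmpl} has no D-enantiomer "
                                 f"(letter {ch!r})")
            out.append((templates.d_name_for(tmpl), True))
        else:
            out.append((tmpl, False))
    return out


def _backbone_linear(n: int) -> list[dict[str, np.ndarray]]:
    """Extended backbone (phi=-135, psi=135, omega=180)."""
    bb: list[dict[str, np.ndarray]] = []
    N0 = np.zeros(3)
    CA0 = np.array([N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - 111.0)
    C0 = CA0 + CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    bb.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n):
        prev = bb[-1]
        Ni = nerf(prev["N"], prev["CA"], prev["C"], C_N, 116.6, 135.0)
        CAi = nerf(prev["CA"], prev["C"], Ni, N_CA, 121.7, 180.0)
        Ci = nerf(prev["C"], Ni, CAi, CA_C, 111.0, -135.0)
        bb.append({"N": Ni, "CA": CAi, "C": Ci})
    return bb


def _backbone_cyclic(n: int) -> tuple[list[dict[str, np.ndarray]], float]:
    """Backbone atoms evenly spaced on a circle in the xy-plane."""
    spacings = []
    for _ in range(n):
        spacings += [N_CA, CA_C, C_N]  # N->CA, CA->C, C->N(next)
    total = sum(spacings)
    radius = total / (2.0 * math.pi)
    bb = []
    arc = 0.0
    for i in range(n):
        res = {}
        for j, name in enumerate(("N", "CA", "C")):
            theta = 2.0 * math.pi * arc / total
            res[name] = radius * np.array([math.cos(theta),
                                           math.sin(theta), 0.0])
            arc += spacings[3 * i + j]
        bb.append(res)
    return bb, radius


def _place_side_chain(b: _Builder, reskey, tmpl: str, d_form: bool,
                      outward: np.ndarray | None = None) -> None:
    """Place template side-chain atoms (BFS over the parent tree)."""
    tree = templates.SIDECHAINS[tmpl]
    children: dict[str, list[tuple[str, str]]] = {}
    parent_of: dict[str, str] = {}
    for name, el, parent in tree:
        children.setdefault(parent, []).append((name, el))
        parent_of[name] = parent
    placed = {"N", "CA", "C"}
    order = ["CA"]
    queue = [name for name, _el, parent in tree if parent == "CA"]
    # BFS ensures parents are placed before children
    while queue:
        nm = queue.pop(0)
        order.append(nm)
        queue += [c for c, _e in children.get(nm, [])]

    for parent in order:
        kids = children.get(parent, [])
        if parent == "CA":
            continue  # CA substituents handled by the chirality-aware caller
        if not kids:
            continue
        ppos = b.pos(reskey, parent)
        gname = parent_of.get(parent, "CA")
        known = [b.pos(reskey, gname)]
        kid_pos = _cone_positions(ppos, known, len(kids), 1.0, phase=0.3)
        p_el = _element_of(parent, tmpl)
        for (nm, el), d in zip(kids, kid_pos):
            direction = _unit(d - ppos)
            # chain heavies keep marching outward to avoid fold-back
            if el != "H" and outward is not None:
                direction = _unit(direction + 0.8 * outward)
            b.add(nm, el, ppos + bond_length(p_el, el) * direction, reskey)


def _element_of(name: str, tmpl: str) -> str:
    if name in ("N",):
        return "N"
    if name in ("CA", "C"):
        return "C"
    for nm, el, _p in templates.SIDECHAINS[tmpl]:
        if nm == name:
            return el
    return name[0]


def build_polypeptide(sequence: str, cyclic: bool = False,
                      chain: str = "A") -> Structure:
    """Build an ideal-geometry, fully protonated peptide.

    Parameters
    ----------
    sequence:
        One-letter codes; lower case = D-residue, ``X`` = AIB.
    cyclic:
        Close the backbone head-to-tail (no termini, no terminal charges).

    Returns a :class:`Structure` with bonds perceived and formal charges
    assigned.  Linear peptides get charged termini (NH3+ / COO-).
    """
    resdefs = _parse_sequence(sequence)
    n = len(resdefs)
    if n == 0:
        raise ValueError("empty sequence")
    if cyclic and n < 3:
        raise ValueError("a cyclic peptide needs at least 3 residues")

    if cyclic:
        bb, _radius = _backbone_cyclic(n)
    else:
        bb = _backbone_linear(n)

    b = _Builder()
    for i, (resname, is_d) in enumerate(resdefs):
        tmpl = templates.template_for(resname)
        reskey = (chain, resname, i + 1, "")
        Npos, CApos, Cpos = bb[i]["N"], bb[i]["CA"], bb[i]["C"]
        b.add("N", "N", Npos, reskey)
        b.add("CA", "C", CApos, reskey)
        b.add("C", "C", Cpos, reskey)

        # carbonyl O (and OXT on a linear C-terminus)
        if cyclic:
            next_n = bb[(i + 1) % n]["N"]
        else:
            next_n = bb[i + 1]["N"] if i + 1 < n else None
        if next_n is not None:
            o_dir = _unit(_unit(Cpos - CApos) + _unit(Cpos - next_n))
            b.add("O", "O", Cpos + C_O * o_dir, reskey)
        else:
            d1, d2 = _tetrahedral_pair(Cpos, CApos,
                                       Cpos + np.array([0, 0, 1.0]))
            b.add("O", "O", Cpos + C_O * _unit(d1), reskey)
            b.add("OXT", "O", nerf(Npos, CApos, Cpos, 1.25, 117.0, 135.0),
                  reskey)

        # amide / terminal hydrogens on N
        prev_c = bb[i - 1]["C"] if (i > 0 or cyclic) else None
        if prev_c is None:
            if tmpl == "PRO":
                hs = _cone_positions(Npos, [CApos], 2,
                                     bond_length("N", "H"))
                for k, hp in enumerate(hs, start=1):
                    b.add(f"H{k}", "H", hp, reskey)
            else:
                hs = _cone_positions(Npos, [CApos], 3,
                                     bond_length("N", "H"))
                for k, hp in enumerate(hs, start=1):
                    b.add(f"H{k}", "H", hp, reskey)
        elif tmpl != "PRO":
            hp = _cone_positions(Npos, [prev_c, CApos], 1,
                                 bond_length("N", "H"))[0]
            b.add("H", "H", hp, reskey)

        # CA substituents: chirality-aware
        d1, d2 = _tetrahedral_pair(CApos, Npos, Cpos)
        cb_dir, ha_dir = (d2, d1) if is_d else (d1, d2)
        if tmpl == "GLY":
            b.add("HA2", "H", CApos + bond_length("C", "H") * d1, reskey)
            b.add("HA3", "H", CApos + bond_length("C", "H") * d2, reskey)
        elif tmpl == "AIB":
            b.add("CB1", "C", CApos + bond_length("C", "C") * d1, reskey)
            b.add("CB2", "C", CApos + bond_length("C", "C") * d2, reskey)
        else:
            b.add("CB", "C", CApos + bond_length("C", "C") * cb_dir, reskey)
            b.add("HA", "H", CApos + bond_length("C", "H") * ha_dir, reskey)

        outward = _unit(cb_dir) if tmpl not in ("GLY",) else None
        _place_side_chain(b, reskey, tmpl, is_d, outward=outward)

    st = b.to_structure()
    return perceive_bonds(st)
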