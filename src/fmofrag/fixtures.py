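"""Synthetic test systems and seeded toy FMO results.

These fixtures make the whole pipeline exercisable offline:

* a Zn-centred cyclic peptide emulating the topology of a zinc-bound
  24-mer (D-residues, AIB, four coordinating histidines);
* a small peptide carrying a covalently bound ligand on a cysteine
  thiol, for manual-fragmentation workflows;
* :func:`make_toy_cpf`, a seeded generator of internally consistent
  CPF result files.

All geometry here is synthetic and idealized: topology, protonation and
charge bookkeeping are faithful, coordinates are not meant to be
physically realistic.  In the Zn fixture the coordinating histidine side
chains are rebuilt as rigid idealized imidazoles aimed at the metal so
that NE2 sits at a realistic coordination distance; their CA-CB distances
are consequently unphysical (bonds for named residues come from topology
templates, not distances, so perception is unaffected).
"""

from __future__ import annotations

import math

import numpy as np

from .build import build_polypeptide, _unit
from .cpf import (AtomMeta, DimerRecord, FMOResult, FragmentMeta,
                  MonomerRecord, write_cpf)
from .fragmentation import Fragmentation
from .structure import Atom, Structure, perceive_bonds

#: the zinc-bound cyclic 24-mer sequence (X = AIB, lower case = D)
ZN_CYCLIC_SEQUENCE = "KLqeXHklQEXhKLqeXHklQEXh"

_IMIDAZOLE_SIDE = 1.37            # Å, ring edge
_IMIDAZOLE_R = _IMIDAZOLE_SIDE / (2.0 * math.sin(math.pi / 5.0))
#: ring vertex angles (deg) around the ring centre, NE2 facing the metal
_RING_ANGLES = {"NE2": 0.0, "CE1": 72.0, "ND1": 144.0,
                "CG": 216.0, "CD2": 288.0}


def _aim_his_at(structure: Structure, reskey, target: np.ndarray,
                ne2_distance: float) -> None:
    """Rebuild one His side chain as an idealized imidazole aimed at a point."""
    res = structure._residue_by_key[reskey]
    ca = res.atom("CA").coords
    d = _unit(target - ca)
    # choose an in-plane up-vector not parallel to d
    up = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(up, d))) > 0.9:
        up = np.array([1.0, 0.0, 0.0])
    up = _unit(up - np.dot(up, d) * d)
    ne2 = target - ne2_distance * d
    center = ne2 - _IMIDAZOLE_R * d
    pos: dict[str, np.ndarray] = {}
    for name, ang in _RING_ANGLES.items():
        t = math.radians(ang)
        pos[name] = center + _IMIDAZOLE_R * (math.cos(t) * d
                                             + math.sin(t) * up)
    pos["CB"] = pos["CG"] + 1.50 * _unit(ca - pos["CG"])
    # ring hydrogens point away from the ring centre
    for hname, heavy, blen in (("HD1", "ND1", 1.01), ("HD2", "CD2", 1.09),
                               ("HE1", "CE1", 1.09)):
        pos[hname] = pos[heavy] + blen * _unit(pos[heavy] - center)
    perp = np.cross(d, up)
    pos["HB2"] = pos["CB"] + 1.09 * perp
    pos["HB3"] = pos["CB"] - 1.09 * perp
    for name, p in pos.items():
        atom = res.atom(name)
        if atom is not None:
            atom.coords = np.asarray(p, dtype=float)


def build_zn_cyclic_peptide(sequence: str = ZN_CYCLIC_SEQUENCE,
                            n_waters: int = 2,
                            water_distance: float = 5.0,
                            ne2_distance: float = 2.1,
                            chain: str = "A") -> Structure:
    """Cyclic peptide with a central Zn2+ coordinated by its histidines.

    The backbone lies on a circle around the origin; every His/D-His side
    chain is aimed at the metal with NE2 at ``ne2_distance`` (default
    2.1 Å, a typical Zn-N distance).  ``n_waters`` water molecules are
    placed on the ring axis at ``water_distance`` from the metal (the
    default keeps them outside the standard 2.8 Å coordination cutoff).
    """
    st = build_polypeptide(sequence, cyclic=True, chain=chain)
    center = np.zeros(3)
    his_keys = [r.key for r in st.residues
                if r.is_amino and r.name in ("HIS", "DHI")]
    for key in his_keys:
        _aim_his_at(st, key, center, ne2_distance)
    serial = max(a.serial for a in st.atoms)
    resnum = max(r.number for r in st.residues)
    serial += 1
    resnum += 1
    st.add_atom(Atom(serial=serial, name="ZN", element="ZN",
                     residue_key=(chain, "ZN", resnum, ""),
                     coords=center.copy(), is_hetero=True,
                     formal_charge_hint=2))
    for w in range(n_waters):
        resnum += 1
        sign = 1.0 if w % 2 == 0 else -1.0
        shift = water_distance + 1.5 * (w // 2)
        o = center + np.array([0.0, 0.0, sign * shift])
        for name, off in (("O", (0.0, 0.0, 0.0)),
                          ("H1", (0.76, 0.0, sign * 0.59)),
                          ("H2", (-0.76, 0.0, sign * 0.59))):
            serial += 1
            st.add_atom(Atom(serial=serial, name=name,
                             element="H" if name.startswith("H") else "O",
                             residue_key=(chain, "HOH", resnum, ""),
                             coords=o + np.array(off), is_hetero=True))
    return perceive_bonds(st)


def build_covalent_ligand_complex(chain: str = "A"
                                  ) -> tuple[Structure, dict[str, int]]:
    """Ala-Cys-Ala peptide with a synthetic ligand bound to the Cys thiol.

    Emulates the covalent-inhibitor situation: the cysteine HG is gone and
    an 8-heavy-atom ligand (residue LIG, HETATM) is attached at SG.  The
    ligand is an unknown residue, so its bonds are perceived by the
    covalent-radius rule; the SG-C1 attachment is also declared via a
    CONECT-equivalent pair for robustness.

    Returns the structure and a map of handy atom serials
    (``SG, CA2, CB2, C1..C6, O1, N1``).
    """
    pep = build_polypeptide("ACA", cyclic=False, chain=chain)
    cys = next(r for r in pep.residues if r.name == "CYS")
    sg_old = cys.atom("SG")
    cb_old = cys.atom("CB")
    drop = {a.serial for a in cys.atoms if a.name == "HG"}

    st = Structure()
    remap: dict[int, int] = {}
    serial = 0
    for a in pep.atoms:
        if a.serial in drop:
            continue
        serial += 1
        remap[a.serial] = serial
        st.add_atom(Atom(serial=serial, name=a.name, element=a.element,
                         residue_key=a.residue_key, coords=a.coords.copy(),
                         is_hetero=a.is_hetero))
    d = _unit(sg_old.coords - cb_old.coords)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(ref, d))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = _unit(np.cross(d, ref))
    zhat = _unit(np.cross(d, perp))
    resnum = max(r.number for r in pep.residues) + 1
    lig_key = (chain, "LIG", resnum, "")

    def chain_pos(k: int) -> np.ndarray:
        # zigzag marching away from SG; consecutive spacing 1.52 A
        return (sg_old.coords + 1.81 * d + 1.35 * k * d
                + 0.35 * ((-1) ** k) * perp)

    heavy = {}
    names = ["C1", "C2", "C3", "C4", "C5", "C6"]
    for k, nm in enumerate(names):
        heavy[nm] = chain_pos(k)
    heavy["O1"] = heavy["C3"] + 1.23 * zhat
    heavy["N1"] = heavy["C5"] + 1.40 * zhat
    hydrogens = {
        "H11": heavy["C1"] + 1.09 * zhat, "H12": heavy["C1"] - 1.09 * zhat,
        "H21": heavy["C2"] + 1.09 * zhat, "H22": heavy["C2"] - 1.09 * zhat,
        "H31": heavy["C3"] - 1.09 * zhat,
        "H41": heavy["C4"] + 1.09 * zhat, "H42": heavy["C4"] - 1.09 * zhat,
        "H51": heavy["C5"] - 1.09 * zhat,
        "H61": heavy["C6"] + 1.09 * zhat, "H62": heavy["C6"] - 1.09 * zhat,
        "HN1": heavy["N1"] + 1.01 * _unit(zhat + 0.5 * d),
        "HN2": heavy["N1"] + 1.01 * _unit(zhat - 0.5 * d),
    }
    serials: dict[str, int] = {}
    for nm, p in {**heavy, **hydrogens}.items():
        serial += 1
        serials[nm] = serial
        el = "O" if nm.startswith("O") else \
            "N" if nm.startswith("N") and not nm.startswith("H") else \
            "H" if nm.startswith("H") else "C"
        st.add_atom(Atom(serial=serial, name=nm, element=el,
                         residue_key=lig_key, coords=p, is_hetero=True))
    st.conect_pairs = [(remap[sg_old.serial], serials["C1"])]
    perceive_bonds(st)
    out = {"SG": remap[sg_old.serial],
           "CA2": remap[cys.atom("CA").serial],
           "CB2": remap[cb_old.serial],
           **serials}
    return st, out


# ---------------------------------------------------------------------------
# toy CPF results
# ---------------------------------------------------------------------------

def result_skeleton(fragmentation: Fragmentation) -> FMOResult:
    """FMOResult carrying only the fragmentation echo (no energies)."""
    st = fragmentation.structure
    res = FMOResult()
    for a in st.atoms:
        ch, rn, num, _ic = a.residue_key
        res.atoms.append(AtomMeta(a.serial, a.name, a.element, rn, ch, num))
    for f in fragmentation.fragments:
        res.fragments.append(FragmentMeta(
            f.id, f.name, f.formal_charge, tuple(sorted(f.atom_serials))))
    res.detached_bonds = [(db.bda, db.baa)
                          for db in fragmentation.detached_bonds]
    return res


def make_toy_result(fragmentation: Fragmentation, seed: int,
                    artifact_ct: float = 100.0) -> FMOResult:
    """Seeded, internally consistent toy FMO result for a fragmentation.

    Dimer PIEDA components are drawn reproducibly; the MP2 total is the
    exact component sum (additivity holds by construction) and the HF
    total omits the dispersion term.  Pairs sharing a detached bond get a
    deliberately large repulsive CT+mix of about ``artifact_ct`` kcal/mol
    and a short contact distance, mimicking the unphysical values real
    calculations show for BDA-adjacent fragment pairs.
    """
    rng = np.random.default_rng(seed)
    res = result_skeleton(fragmentation)
    res.title = f"toy result seed={seed}"
    adjacency = {tuple(sorted(p)) for p in fragmentation.adjacency_pairs()}
    for f in fragmentation.fragments:
        n = len(f.atom_serials)
        mon = MonomerRecord(f.id, float(rng.normal(-50.0, 5.0)))
        for scheme in ("mulliken", "npa", "esp"):
            mon.charges[scheme] = rng.normal(0.0, 0.2, size=n)
        res.monomers.append(mon)
    ids = sorted(f.id for f in fragmentation.fragments)
    for ii, i in enumerate(ids):
        for j in ids[ii + 1:]:
            es = float(rng.normal(-2.0, 3.0))
            ex = float(abs(rng.normal(0.0, 1.0)))
            di = float(-abs(rng.normal(1.0, 0.7)))
            if (i, j) in adjacency:
                ct = float(artifact_ct + rng.normal(0.0, 5.0))
                dist = 1.5
            else:
                ct = float(rng.normal(-1.0, 1.0))
                dist = float(rng.uniform(2.0, 15.0))
            res.dimers.append(DimerRecord(
                i, j, dist, es, ex, ct, di,
                total_hf=es + ex + ct, total_mp2=es + ex + ct + di))
    res.total_energy = float(rng.normal(-5000.0, 10.0))
    return res


def make_toy_cpf(fragmentation: Fragmentation, seed: int, path,
                 artifact_ct: float = 100.0) -> FMOResult:
    """Write a seeded toy CPF file (byte-identical for identical seeds)."""
    res = make_toy_result(fragmentation, seed, artifact_ct)
    write_cpf(res, path)
    return res
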