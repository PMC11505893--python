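"""IFIE/PIEDA aggregation, remapping between fragmentation schemes,
scheme-to-scheme comparison, and atomic-charge tabulation.

All energies are kcal/mol.  Tables are pandas DataFrames wrapped in
:class:`InteractionTable`; internal math runs at full precision and report
rounding (1 decimal) is left to the presentation layer.

Fragment pairs that share a detached bond (the BDA sits next to the BAA)
show unphysical IFIE/CT+mix values and are excluded from aggregates by
default; exclusion only removes contributions, it never alters retained
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpf import DimerRecord, FMOResult

COMPONENTS = ("ES", "EX", "CT+mix", "DI")
CHARGE_FLAG_THRESHOLD = 0.05  # e; working level for charge differences

_COLS = ["unit_a", "unit_b", "ES", "EX", "CT+mix", "DI", "total",
         "excluded", "reason"]


class AnalysisError(ValueError):
    pass


@dataclass
class FragmentGroup:
    name: str
    member_ids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise AnalysisError(f"fragment group {self.name!r} is empty")
        self.member_ids = frozenset(self.member_ids)

    @classmethod
    def from_names(cls, result: FMOResult, name: str,
                   fragment_names) -> "FragmentGroup":
        ids = frozenset(result.fragment_by_name(n).id
                        for n in fragment_names)
        return cls(name, ids)


@dataclass
class InteractionTable:
    """Rows of aggregated interactions between fragment units."""
    df: pd.DataFrame
    excluded_pairs: list[tuple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def row(self, unit_a: str, unit_b: str) -> pd.Series:
        m = self.df[((self.df.unit_a == unit_a) & (self.df.unit_b == unit_b))
                    | ((self.df.unit_a == unit_b)
                       & (self.df.unit_b == unit_a))]
        if m.empty:
            raise AnalysisError(f"no row for units ({unit_a}, {unit_b})")
        return m.iloc[0]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.6f")

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        """Report view at the conventional 1-decimal kcal/mol precision."""
        out = self.df.copy()
        for c in [*COMPONENTS, "total"]:
            if c in out:
                out[c] = out[c].round(decimals)
        return out


def _check_groups(result: FMOResult, a: FragmentGroup,
                  b: FragmentGroup) -> None:
    known = {f.id for f in result.fragments}
    for g in (a, b):
        unknown = g.member_ids - known
        if unknown:
            raise AnalysisError(f"group {g.name!r} references unknown "
                                f"fragment ids {sorted(unknown)}")
    if a.member_ids & b.member_ids:
        raise AnalysisError(
            f"groups {a.name!r} and {b.name!r} overlap: "
            f"{sorted(a.member_ids & b.member_ids)}")


def _sum_components(dimers) -> dict[str, float]:
    acc = {c: 0.0 for c in COMPONENTS}
    tot = 0.0
    for d in dimers:
        acc["ES"] += d.es
        acc["EX"] += d.ex
        acc["CT+mix"] += d.ct_mix
        acc["DI"] += d.di
        tot += d.total_mp2
    acc["total"] = tot
    return acc


def aggregate_ifie(result: FMOResult, group_a: FragmentGroup,
                   group_b: FragmentGroup,
                   exclude_adjacent: bool = True) -> InteractionTable:
    """Componentwise sum of all dimers with one member in each group.

    Returns a one-row table; dropped (adjacency-excluded) pairs are listed
    in ``excluded_pairs``.
    """
    _check_groups(result, group_a, group_b)
    adjacency = result.adjacency_pairs()
    picked: list[DimerRecord] = []
    dropped: list[tuple[int, int]] = []
    for d in result.dimers:
        ina = d.i in group_a.member_ids and d.j in group_b.member_ids
        inb = d.i in group_b.member_ids and d.j in group_a.member_ids
        if not (ina or inb):
            continue
        if exclude_adjacent and (d.i, d.j) in adjacency:
            dropped.append((d.i, d.j))
            continue
        picked.append(d)
    acc = _sum_components(picked)
    df = pd.DataFrame([{
        "unit_a": group_a.name, "unit_b": group_b.name, **{
            c: acc[c] for c in COMPONENTS},
        "total": acc["total"], "excluded": False,
        "reason": ""}], columns=_COLS)
    return InteractionTable(df, excluded_pairs=dropped)


def ligand_residue_profile(result: FMOResult, ligand_group: FragmentGroup,
                           components=None,
                           per_fragment: bool = False,
                           exclude_adjacent: bool = True
                           ) -> InteractionTable:
    """One row per environment fragment vs the ligand group, sorted by total.

    ``components`` selects the PIEDA components summed into ``total``
    (default: the stored MP2 IFIE).  With ``per_fragment`` each ligand
    member gets its own rows (unit_a = ligand fragment name).
    """
    known = {f.id for f in result.fragments}
    if ligand_group.member_ids - known:
        raise AnalysisError(f"ligand group references unknown ids")
    if components is not None:
        bad = set(components) - set(COMPONENTS)
        if bad:
            raise AnalysisError(f"unknown PIEDA components {sorted(bad)}")
    adjacency = result.adjacency_pairs()
    env = [f for f in result.fragments if f.id not in ligand_group.member_ids]
    dm = result.dimer_map()
    lig_units = ([(result.fragment_by_id(i).name, frozenset([i]))
                  for i in sorted(ligand_group.member_ids)]
                 if per_fragment else
                 [(ligand_group.name, ligand_group.member_ids)])
    rows = []
    dropped = []
    for lname, lids in lig_units:
        for f in env:
            ds = []
            for i in lids:
                key = (min(i, f.id), max(i, f.id))
                d = dm.get(key)
                if d is None:
                    continue
                if exclude_adjacent and key in adjacency:
                    dropped.append(key)
                    continue
                ds.append(d)
            if not ds:
                continue
            acc = _sum_components(ds)
            total = (sum(acc[c] for c in components)
                     if components is not None else acc["total"])
            rows.append({"unit_a": lname, "unit_b": f.name,
                         **{c: acc[c] for c in COMPONENTS},
                         "total": total, "excluded": False, "reason": ""})
    df = pd.DataFrame(rows, columns=_COLS)
    df = df.sort_values(["unit_a", "total"],
                        kind="stable").reset_index(drop=True)
    return InteractionTable(df, excluded_pairs=dropped)


# ---------------------------------------------------------------------------
# remapping between fragmentation schemes
# ---------------------------------------------------------------------------

def remap_result(result: FMOResult,
                 mapping: dict[int, str],
                 exclude_adjacent: bool = True) -> InteractionTable:
    """Re-express dimer interactions on coarser units.

    ``mapping`` sends every fine fragment id to a coarse unit label
    (many-to-one).  Fine pairs inside one coarse unit are dropped
    (intra-unit); a coarse pair is flagged excluded if any contributing
    fine pair was adjacency-excluded.
    """
    fine_ids = {f.id for f in result.fragments}
    missing = fine_ids - set(mapping)
    if missing:
        raise AnalysisError(f"fine fragments missing from the map: "
                            f"{sorted(missing)}")
    adjacency = result.adjacency_pairs()
    acc: dict[tuple[str, str], dict[str, float]] = {}
    flagged: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for d in result.dimers:
        ua, ub = mapping[d.i], mapping[d.j]
        if ua == ub:
            continue  # intra-unit
        key = tuple(sorted((ua, ub)))
        slot = acc.setdefault(
            key, {c: 0.0 for c in (*COMPONENTS, "total")})
        slot["ES"] += d.es
        slot["EX"] += d.ex
        slot["CT+mix"] += d.ct_mix
        slot["DI"] += d.di
        slot["total"] += d.total_mp2
        if (d.i, d.j) in adjacency:
            flagged.setdefault(key, []).append((d.i, d.j))
    rows = []
    for key in sorted(acc):
        bad = flagged.get(key, [])
        rows.append({"unit_a": key[0], "unit_b": key[1],
                     **{c: acc[key][c] for c in COMPONENTS},
                     "total": acc[key]["total"],
                     "excluded": bool(bad) and exclude_adjacent,
                     "reason": ("adjacent detached bond: "
                                + ",".join(map(str, bad)) if bad else "")})
    return InteractionTable(pd.DataFrame(rows, columns=_COLS),
                            excluded_pairs=sorted(
                                p for ps in flagged.values() for p in ps))


def identity_map(result: FMOResult) -> dict[int, str]:
    return {f.id: f.name for f in result.fragments}


@dataclass
class ComparisonResult:
    df: pd.DataFrame
    max_abs_total: float
    excluded_units: list[tuple[str, str]] = field(default_factory=list)


def compare_results(a: InteractionTable,
                    b: InteractionTable) -> ComparisonResult:
    """Per-unit, per-component differences a - b on a common unit set."""
    def keyed(t: InteractionTable) -> dict[tuple[str, str], dict]:
        out: dict[tuple[str, str], dict] = {}
        for rec in t.df.to_dict("records"):
            key = tuple(sorted((str(rec["unit_a"]), str(rec["unit_b"]))))
            out[key] = rec
        return out

    da, db = keyed(a), keyed(b)
    if set(da) != set(db):
        diff = set(da) ^ set(db)
        raise AnalysisError(f"unit sets differ; symmetric difference: "
                            f"{sorted(diff)}")
    excluded = sorted(k for k in da
                      if bool(da[k]["excluded"]) or bool(db[k]["excluded"]))
    keep = [k for k in sorted(da) if k not in set(excluded)]
    rows = []
    for k in keep:
        row = {"unit_a": k[0], "unit_b": k[1]}
        for c in (*COMPONENTS, "total"):
            row[f"d{c}"] = float(da[k][c]) - float(db[k][c])
        rows.append(row)
    df = pd.DataFrame(rows)
    max_abs = float(df["dtotal"].abs().max()) if len(df) else 0.0
    return ComparisonResult(df, max_abs, excluded)


# ---------------------------------------------------------------------------
# atomic charges
# ---------------------------------------------------------------------------

def charge_table(result: FMOResult, residues=None, scheme: str = "mulliken",
                 reference: FMOResult | None = None,
                 flag_threshold: float = CHARGE_FLAG_THRESHOLD
                 ) -> pd.DataFrame:
    """Per-atom charges of one population scheme, optionally vs a reference.

    ``residues`` filters by residue label (e.g. ``["His6", "Dhi12"]``);
    with ``reference``, a ``delta`` column is computed by atom serial and
    atoms with ``|delta| >= flag_threshold`` are flagged (the conventional
    working level is 0.05 e).
    """
    scheme = scheme.lower()

    def charges_by_serial(res: FMOResult) -> dict[int, float]:
        out: dict[int, float] = {}
        found = False
        for m in res.monomers:
            if scheme not in m.charges:
                continue
            found = True
            frag = res.fragment_by_id(m.fragment_id)
            for s, q in zip(frag.atom_serials, m.charges[scheme]):
                out[s] = float(q)
        if not found:
            raise AnalysisError(f"charge scheme {scheme!r} absent from "
                                f"the result")
        return out

    qs = charges_by_serial(result)
    ref_qs = charges_by_serial(reference) if reference is not None else None
    rows = []
    for a in result.atoms:
        if a.serial not in qs:
            continue
        label = f"{a.resname.capitalize()}{a.resnum}"
        if residues is not None and label not in residues:
            continue
        row = {"serial": a.serial, "atom": a.name, "residue": label,
               "scheme": scheme, "value": qs[a.serial]}
        if ref_qs is not None:
            ref = ref_qs.get(a.serial)
            row["delta"] = (qs[a.serial] - ref) if ref is not None \
                else np.nan
            row["flagged"] = (abs(row["delta"]) >= flag_threshold
                              if ref is not None else False)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_profile(table: InteractionTable, path, components=False) -> None:
    """Bar chart of a per-residue interaction profile (PNG/SVG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.df
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(df)), 4))
    x = np.arange(len(df))
    if components:
        bottom_pos = np.zeros(len(df))
        bottom_neg = np.zeros(len(df))
        for c in COMPONENTS:
            vals = df[c].to_numpy()
            bottoms = np.where(vals >= 0, bottom_pos, bottom_neg)
            ax.bar(x, vals, bottom=bottoms, label=c)
            bottom_pos = np.where(vals >= 0, bottom_pos + vals, bottom_pos)
            bottom_neg = np.where(vals < 0, bottom_neg + vals, bottom_neg)
        ax.legend()
    else:
        ax.bar(x, df["total"].to_numpy(), color="tab:blue")
    ax.set_xticks(x)
    ax.set_xticklabels(df["unit_b"], rotation=90, fontsize=7)
    ax.set_ylabel("interaction energy (kcal/mol)")
    ax.axhline(0.0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
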