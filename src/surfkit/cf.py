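"""The complementarity function and its three application modes.

The complementarity function between two structural units is

    CF(unit1, unit2) = sum_i sum_j  eps(t_i, t_j) * S_ij

summing over atoms *i* of unit 1 and *j* of unit 2, where ``eps`` is the
pairwise atom-type pseudo-energy (per Å²) and ``S_ij`` the contact surface
area (Å²).  Units can be residues, whole chain groups, a ligand, or single
ligand atoms.  CF is bilinear in the units: splitting a unit and summing
the parts reproduces the whole.

The three analysis modes mirror the typical questions asked of a complex:

* :func:`protein_protein` — residues of one chain group vs residues of
  another (interfaces, also ligands given their own chain id);
* :func:`protein_ligand` — every residue vs every atom of every copy of a
  ligand named by its three-letter code (per-atom decomposition);
* :func:`particular_residues` — all inter- and intra-chain partners of a
  selected residue list.

Contact areas are computed once on the full cleaned structure and shared by
all unit pairs, so each ``S_ij`` reflects occlusion by the whole
environment.  Structures must be cleaned and typeable; nothing is removed
implicitly here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .atomtypes import TypeTable, TypedAtom, assign_types
from .energy import EnergyMatrix
from .geometry import DEFAULT_RADII, ContactMap, RadiiTable, contact_areas
from .structure import Structure, residue_key, split_units

__all__ = [
    "UnitSpec",
    "CFReport",
    "pair_cf",
    "protein_protein",
    "protein_ligand",
    "particular_residues",
    "residue_totals",
    "residue_label",
    "resolve_residue_label",
]


@dataclass(frozen=True)
class UnitSpec:
    """A named group of atoms acting as one unit of the CF sum."""

    kind: str  # "chain-group" | "residue" | "ligand-atom"
    label: str
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise ValueError(f"unit {self.label!r} has no atoms")


@dataclass
class CFReport:
    """Unit-by-unit CF matrix with per-unit net totals."""

    rows: list[UnitSpec]
    cols: list[UnitSpec]
    cf: np.ndarray  # shape (len(rows), len(cols))
    structure_id: str = ""
    mode: str = ""

    def __post_init__(self) -> None:
        if self.cf.shape != (len(self.rows), len(self.cols)):
            raise ValueError("CF matrix shape does not match unit lists")
        if not np.all(np.isfinite(self.cf)):
            raise ValueError("CF values must be finite")

    @property
    def row_totals(self) -> np.ndarray:
        return self.cf.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.cf.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.cf.sum())

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.cf,
                            index=[u.label for u in self.rows],
                            columns=[u.label for u in self.cols])


def residue_label(key: tuple[str, int, str, str]) -> str:
    """Label ``RESNAME RESSEQ CHAIN [ICODE]``, e.g. ``GLY614A``."""
    chain, seq, icode, name = key
    return f"{name}{seq}{chain}{icode}"


_LABEL_RE = re.compile(
    r"^(?P<res>[A-Za-z0-9]{1,3}?)(?P<seq>-?\d+)(?P<chain>[A-Za-z]?)(?P<icode>[A-Za-z]?)$")


def resolve_residue_label(s: Structure, label: str) -> tuple[str, int, str, str]:
    """Resolve ``RESNAME RESSEQ [CHAIN] [ICODE]`` to a unique residue key.

    The chain may be omitted only when the (name, seq) pair is unambiguous
    across chains.  Ambiguous or missing labels raise with the candidate
    list.
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse residue label {label!r} "
                         "(expected e.g. GLY614 or GLY614A)")
    want_res = m.group("res").upper()
    want_seq = int(m.group("seq"))
    want_chain = m.group("chain").upper()
    want_icode = m.group("icode").upper()
    hits = []
    for key in s.residues():
        chain, seq, icode, name = key
        if name.upper() != want_res or seq != want_seq:
            continue
        if want_chain and chain.upper() != want_chain:
            continue
        if want_icode and icode.upper() != want_icode:
            continue
        hits.append(key)
    if not hits:
        raise ValueError(f"residue {label!r} not found")
    if len(hits) > 1:
        pretty = ", ".join(residue_label(k) for k in hits)
        raise ValueError(f"residue label {label!r} is ambiguous: {pretty}")
    return hits[0]


def pair_cf(
    set1: tuple[int, ...] | list[int],
    set2: tuple[int, ...] | list[int],
    typed: list[TypedAtom],
    cmap: ContactMap,
    matrix: EnergyMatrix,
) -> float:
    """CF between two disjoint atom-index sets; absent pairs contribute 0."""
    s1, s2 = set(set1), set(set2)
    if s1 & s2:
        raise ValueError(f"atom sets overlap: {sorted(s1 & s2)[:5]} ...")
    total = 0.0
    for (i, j), area in cmap.areas.items():
        if (i in s1 and j in s2) or (j in s1 and i in s2):
            total += matrix.epsilon(typed[i].type_id, typed[j].type_id) * area
    return total


@dataclass
class _Context:
    """Typed atoms + shared contact map for one structure/config."""

    typed: list[TypedAtom]
    cmap: ContactMap
    residues: dict[tuple[str, int, str, str], list[int]] = field(default_factory=dict)


def _prepare(
    s: Structure,
    table: TypeTable,
    radii: RadiiTable,
    resolution: int,
) -> _Context:
    typed = assign_types(s, table, radii)
    cmap = contact_areas(typed, radii, resolution)
    return _Context(typed=typed, cmap=cmap, residues=s.residues())


def _cell_matrix(
    rows: list[UnitSpec], cols: list[UnitSpec], ctx: _Context, matrix: EnergyMatrix
) -> np.ndarray:
    """Evaluate all cells off the sparse contact map in one pass."""
    row_of: dict[int, list[int]] = {}
    col_of: dict[int, list[int]] = {}
    for r, u in enumerate(rows):
        for i in u.atom_indices:
            row_of.setdefault(i, []).append(r)
    for c, u in enumerate(cols):
        for i in u.atom_indices:
            col_of.setdefault(i, []).append(c)
    cf = np.zeros((len(rows), len(cols)))
    typed = ctx.typed
    for (i, j), area in ctx.cmap.areas.items():
        e = None
        for a, b in ((i, j), (j, i)):
            ra = row_of.get(a)
            cb = col_of.get(b)
            if ra and cb:
                if e is None:
                    e = matrix.epsilon(typed[i].type_id, typed[j].type_id) * area
                for r in ra:
                    for c in cb:
                        if rows[r].label != cols[c].label:
                            cf[r, c] += e
    return cf


def _residue_units(ctx: _Context, indices: list[int], kind: str = "residue") -> list[UnitSpec]:
    by_res: dict[tuple, list[int]] = {}
    wanted = set(indices)
    for key, atom_idx in ctx.residues.items():
        members = [i for i in atom_idx if i in wanted]
        if members:
            by_res[key] = members
    return [UnitSpec(kind=kind, label=residue_label(k), atom_indices=tuple(v))
            for k, v in by_res.items()]


def protein_protein(
    s: Structure,
    table: TypeTable,
    group_a: list[str],
    group_b: list[str],
    matrix: EnergyMatrix,
    radii: RadiiTable = DEFAULT_RADII,
    resolution: int = 5120,
) -> CFReport:
    """Per-residue CF between two chain groups.

    Rows are residues of ``group_a``, columns residues of ``group_b``;
    intra-group pairs never contribute.  Assigning a ligand its own chain id
    and placing it in one group evaluates whole-ligand interactions.
    """
    ia, ib = split_units(s, group_a, group_b)
    ctx = _prepare(s, table, radii, resolution)
    rows = _residue_units(ctx, ia)
    cols = _residue_units(ctx, ib)
    cf = _cell_matrix(rows, cols, ctx, matrix)
    return CFReport(rows=rows, cols=cols, cf=cf, structure_id=s.id, mode="protein-protein")


def protein_ligand(
    s: Structure,
    table: TypeTable,
    ligand_code: str,
    matrix: EnergyMatrix,
    radii: RadiiTable = DEFAULT_RADII,
    resolution: int = 5120,
) -> CFReport:
    """Per-residue vs per-ligand-atom CF decomposition.

    Columns are the atoms of every instance of the ligand (three-letter
    ``ligand_code``), labeled ``ATOM.RESSEQCHAIN`` so copies stay distinct;
    rows are all other residues.
    """
    code = ligand_code.upper()
    ctx = _prepare(s, table, radii, resolution)
    lig_keys = [k for k in ctx.residues if k[3].upper() == code]
    if not lig_keys:
        raise ValueError(f"ligand code {ligand_code!r} not present in structure")
    lig_atoms = {i for k in lig_keys for i in ctx.residues[k]}
    protein_idx = [i for i in range(len(s.atoms)) if i not in lig_atoms]
    if not protein_idx:
        raise ValueError("structure contains only the ligand")
    rows = _residue_units(ctx, protein_idx)
    cols = []
    for k in lig_keys:
        inst = residue_label(k)
        for i in ctx.residues[k]:
            cols.append(UnitSpec(kind="ligand-atom",
                                 label=f"{s.atoms[i].atom_name}.{inst}",
                                 atom_indices=(i,)))
    cf = _cell_matrix(rows, cols, ctx, matrix)
    return CFReport(rows=rows, cols=cols, cf=cf, structure_id=s.id, mode="protein-ligand")


def particular_residues(
    s: Structure,
    table: TypeTable,
    labels: list[str],
    matrix: EnergyMatrix,
    radii: RadiiTable = DEFAULT_RADII,
    resolution: int = 5120,
    skip_adjacent: bool = False,
) -> CFReport:
    """All inter- and intra-chain interactions of selected residues.

    Rows are the selected residues; columns are every other residue with at
    least one nonzero-contact atom pair to a selected residue.  Same-residue
    pairs are excluded; sequence neighbors (i±1 on the same chain) are
    included unless ``skip_adjacent``.  When two selected residues contact
    each other, each appears among the other's columns with the same CF.
    """
    ctx = _prepare(s, table, radii, resolution)
    selected = [resolve_residue_label(s, lbl) for lbl in labels]
    sel_set = set(selected)
    res_of_atom: dict[int, tuple] = {}
    for key, idxs in ctx.residues.items():
        for i in idxs:
            res_of_atom[i] = key
    partners: set[tuple] = set()
    for (i, j), _ in ctx.cmap.areas.items():
        ki, kj = res_of_atom[i], res_of_atom[j]
        if ki == kj:
            continue
        for a, b in ((ki, kj), (kj, ki)):
            if a in sel_set:
                if skip_adjacent and _adjacent(a, b):
                    continue
                partners.add(b)
    rows = [UnitSpec(kind="residue", label=residue_label(k),
                     atom_indices=tuple(ctx.residues[k])) for k in selected]
    col_keys = sorted(partners, key=lambda k: (k[0], k[1], k[2]))
    cols = [UnitSpec(kind="residue", label=residue_label(k),
                     atom_indices=tuple(ctx.residues[k])) for k in col_keys]
    cf = _cell_matrix(rows, cols, ctx, matrix)
    if skip_adjacent:
        for r, rk in enumerate(selected):
            for c, ck in enumerate(col_keys):
                if _adjacent(rk, ck):
                    cf[r, c] = 0.0
    return CFReport(rows=rows, cols=cols, cf=cf, structure_id=s.id,
                    mode="particular-residues")


def _adjacent(k1: tuple, k2: tuple) -> bool:
    """Covalent sequence neighbors: same chain, |res_seq| difference of 1."""
    return k1[0] == k2[0] and abs(k1[1] - k2[1]) == 1


def residue_totals(rep: CFReport) -> dict[str, float]:
    """Net interaction value per unit (sum of its row or column cells).

    Used to color unit surfaces; negative = net favorable (blue), positive
    = net unfavorable (red).
    """
    nets: dict[str, float] = {}
    for u, t in zip(rep.rows, rep.row_totals):
        nets[u.label] = float(t)
    for u, t in zip(rep.cols, rep.col_totals):
        nets.setdefault(u.label, float(t))
    return nets
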