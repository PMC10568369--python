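"""SYBYL atom typing from a customizable ``.DEF`` table.

Each heavy atom is assigned one of 40 SYBYL atom types (``C.3``, ``N.am``,
``O.co2``, ...) by looking up its (residue name, atom name) pair in a plain
text ``.DEF`` table.  The shipped protein table follows standard SYBYL
typing conventions for the 20 canonical amino acids (amide backbone nitrogen
is ``N.am``, carbonyl carbon ``C.2``, carboxylates ``O.co2``, aromatic rings
``C.ar``/``N.ar``, ...).  Ligands and modified residues are covered by
extending the table, either by hand or with the crude element-level fallback
generator :func:`element_fallback_def`.

``.DEF`` grammar: one whitespace-separated ``RES_NAME ATOM_NAME TYPE_ID``
entry per line, ``#`` starts a comment, later duplicates override earlier
ones (with a warning).  Name matching is case-insensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

from .structure import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "SYBYL_TYPES",
    "TypeTable",
    "TypedAtom",
    "TypingError",
    "load_def",
    "default_def",
    "assign_types",
    "element_fallback_def",
    "merge_def",
]

#: The 40-label SYBYL atom-type vocabulary, in type-id order (ids 1..40).
SYBYL_TYPES: tuple[str, ...] = (
    "C.1", "C.2", "C.3", "C.ar", "C.cat",
    "N.1", "N.2", "N.3", "N.4", "N.am", "N.ar", "N.pl3",
    "O.2", "O.3", "O.co2",
    "S.2", "S.3", "S.o", "S.o2",
    "P.3",
    "F", "Cl", "Br", "I",
    "Li", "Na", "K", "Mg", "Ca", "Al", "Si",
    "Mn", "Fe", "Co.oh", "Ni", "Cu", "Zn", "Se", "Mo",
    "Du",
)

N_TYPES = len(SYBYL_TYPES)

#: Generic per-element SYBYL type used by the fallback generator.
ELEMENT_FALLBACK: dict[str, str] = {
    "C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3",
    "F": "F", "CL": "Cl", "BR": "Br", "I": "I",
    "LI": "Li", "NA": "Na", "K": "K", "MG": "Mg", "CA": "Ca",
    "AL": "Al", "SI": "Si", "MN": "Mn", "FE": "Fe", "CO": "Co.oh",
    "NI": "Ni", "CU": "Cu", "ZN": "Zn", "SE": "Se", "MO": "Mo",
}
#: Documented default for elements outside the table above: the dummy type.
UNKNOWN_ELEMENT_TYPE = "Du"


class TypingError(ValueError):
    """Raised when atoms cannot be assigned a type (cleaning was skipped?)."""


@dataclass(frozen=True)
class TypedAtom:
    """An atom together with its assigned type id and van der Waals radius."""

    atom: "Atom"  # noqa: F821 - forward ref to structure.Atom
    type_id: int
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


class TypeTable:
    """Mapping (res_name, atom_name) -> type id in 1..40, case-insensitive."""

    def __init__(self, entries: dict[tuple[str, str], int] | None = None,
                 type_names: tuple[str, ...] = SYBYL_TYPES) -> None:
        if len(type_names) != len(set(type_names)):
            raise ValueError("type labels must be distinct")
        self.type_names = tuple(type_names)
        self.entries: dict[tuple[str, str], int] = {}
        for (res, name), tid in (entries or {}).items():
            self._check_id(tid)
            self.entries[(res.upper(), name.upper())] = tid

    def _check_id(self, tid: int) -> None:
        if not 1 <= tid <= len(self.type_names):
            raise ValueError(
                f"type id {tid} outside 1..{len(self.type_names)}")

    def lookup(self, res_name: str, atom_name: str) -> int | None:
        return self.entries.get((res_name.upper(), atom_name.upper()))

    def type_label(self, tid: int) -> str:
        self._check_id(tid)
        return self.type_names[tid - 1]

    def add(self, res_name: str, atom_name: str, tid: int,
            warn_override: bool = True) -> None:
        self._check_id(tid)
        key = (res_name.upper(), atom_name.upper())
        if key in self.entries and self.entries[key] != tid and warn_override:
            logger.warning("override: (%s, %s) %d -> %d",
                           res_name, atom_name, self.entries[key], tid)
        self.entries[key] = tid

    def __len__(self) -> int:
        return len(self.entries)

    def to_def(self) -> str:
        lines = [f"{res} {name} {tid}" for (res, name), tid in self.entries.items()]
        return "\n".join(lines) + ("\n" if lines else "")


def load_def(text: str, type_names: tuple[str, ...] = SYBYL_TYPES) -> TypeTable:
    """Parse ``.DEF`` text into a :class:`TypeTable`.

    Later duplicate (res, atom) keys override earlier ones with a warning.
    """
    table = TypeTable(type_names=type_names)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f".DEF line {lineno}: expected 'RES ATOM TYPE_ID'")
        res, name, tid_s = fields[0], fields[1], fields[2]
        try:
            tid = int(tid_s)
        except ValueError as exc:
            raise ValueError(f".DEF line {lineno}: type id {tid_s!r} is not an integer") from exc
        if not 1 <= tid <= len(type_names):
            raise ValueError(
                f".DEF line {lineno}: type id {tid} outside 1..{len(type_names)}")
        table.add(res, name, tid)
    return table


def default_def() -> TypeTable:
    """The shipped protein table covering all heavy atoms of the 20
    standard amino acids (plus terminal OXT)."""
    text = resources.files("surfkit.data").joinpath("protein.def").read_text()
    return load_def(text)


def assign_types(s: Structure, table: TypeTable,
                 radii: "RadiiTable | None" = None) -> list[TypedAtom]:  # noqa: F821
    """Type every atom of a cleaned structure.

    Raises :class:`TypingError` listing *all* untypeable atoms — a signal
    that the explicit cleaning step was skipped.
    """
    from .geometry import DEFAULT_RADII

    radii = radii if radii is not None else DEFAULT_RADII
    missing: list[tuple[str, str]] = []
    out: list[TypedAtom] = []
    for a in s.atoms:
        tid = table.lookup(a.res_name, a.atom_name)
        if tid is None:
            missing.append((a.res_name, a.atom_name))
            continue
        out.append(TypedAtom(atom=a, type_id=tid,
                             vdw_radius=radii.vdw_radius(a.element)))
    if missing:
        uniq = sorted(set(missing))
        raise TypingError(
            f"{len(missing)} atom(s) without a .DEF entry "
            f"(was the structure cleaned?): {uniq}")
    return out


def element_fallback_def(s: Structure, base: TypeTable | None = None) -> TypeTable:
    """Generate a ``.DEF`` fragment typing by element only.

    Emits one entry for every (res_name, atom_name) pair of ``s`` not
    already covered by ``base``, mapping each element to a generic SYBYL
    type (C→C.3, N→N.3, O→O.3, ..., unknown→``Du``).  Deliberately crude;
    meant as a starting point for hand curation of ligand entries.
    """
    names = base.type_names if base is not None else SYBYL_TYPES
    label_to_id = {lbl: i + 1 for i, lbl in enumerate(names)}
    frag = TypeTable(type_names=names)
    for a in s.atoms:
        key = (a.res_name.upper(), a.atom_name.upper())
        if base is not None and base.lookup(*key) is not None:
            continue
        if frag.lookup(*key) is not None:
            continue
        label = ELEMENT_FALLBACK.get(a.element.upper())
        if label is None:
            logger.warning("unknown element %r for %s %s: using %s",
                           a.element, a.res_name, a.atom_name,
                           UNKNOWN_ELEMENT_TYPE)
            label = UNKNOWN_ELEMENT_TYPE
        frag.add(*key, label_to_id[label])
    return frag


def merge_def(base: TypeTable, extra: TypeTable) -> TypeTable:
    """Union of two tables; ``extra`` overrides ``base`` on conflicts."""
    for lbl in extra.type_names:
        if lbl not in base.type_names:
            raise ValueError(f"type label {lbl!r} absent from base vocabulary")
    merged = TypeTable(type_names=base.type_names)
    for (res, name), tid in base.entries.items():
        merged.add(res, name, tid, warn_override=False)
    for (res, name), tid in extra.entries.items():
        merged.add(res, name, tid, warn_override=False)
    return merged
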