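"""Reading, cleaning and writing of PDB structures.

Only fixed-column ``ATOM``/``HETATM`` records of the first model are
interpreted; everything else (``ANISOU``, ``CONECT``, header metadata) is
ignored.  Cleaning is an explicit, user-invoked step: analysis functions in
:mod:`surfkit.cf` never remove atoms silently, so that hetero-atoms a user
wants to ignore can simply be deleted (or left undefined) beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .atomtypes import TypeTable

__all__ = [
    "Atom",
    "Structure",
    "CleanReport",
    "PDBParseError",
    "parse_pdb",
    "write_pdb",
    "clean_structure",
    "split_units",
    "residue_key",
]

WATER_CODES = frozenset({"HOH", "WAT", "DOD", "H2O"})
HYDROGEN_ELEMENTS = frozenset({"H", "D"})

# Two-character element symbols that may appear right-justified in the
# atom-name field (columns 13-16) of standard PDB files.
_TWO_CHAR_ELEMENTS = frozenset(
    {"FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "CU", "CO", "NI",
     "SE", "MO", "CD", "HG", "PT", "AU", "AG", "LI", "AL", "SI"}
)


class PDBParseError(ValueError):
    """Raised for unusable PDB input (empty, or malformed records)."""


@dataclass(frozen=True)
class Atom:
    """One heavy-atom (or, before cleaning, any-atom) coordinate record."""

    serial: int
    atom_name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str
    x: float
    y: float
    z: float
    occupancy: float
    element: str
    is_hetatm: bool

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


def residue_key(a: Atom) -> tuple[str, int, str, str]:
    """Residue identity 4-tuple: (chain, res_seq, insertion code, res_name)."""
    return (a.chain_id, a.res_seq, a.insertion_code, a.res_name)


@dataclass
class Structure:
    """An ordered collection of atoms with a residue index."""

    atoms: list[Atom]
    id: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            k = (a.chain_id, a.res_seq, a.insertion_code, a.atom_name, a.alt_loc)
            if k in seen:
                raise ValueError(f"duplicate atom record {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    def residues(self) -> dict[tuple[str, int, str, str], list[int]]:
        """Residue key -> indices into ``atoms``, in order of first appearance."""
        out: dict[tuple[str, int, str, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(residue_key(a), []).append(i)
        return out

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen


@dataclass
class CleanReport:
    removed_waters: int = 0
    removed_hydrogens: int = 0
    removed_altlocs: int = 0
    removed_undefined: list[tuple[str, str]] = field(default_factory=list)
    kept_atoms: int = 0

    @property
    def total_removed(self) -> int:
        return (self.removed_waters + self.removed_hydrogens
                + self.removed_altlocs + len(self.removed_undefined))


def _guess_element(atom_name: str, res_name: str, is_hetatm: bool) -> str:
    """Infer the element from the atom-name field when columns 77-78 are blank.

    PDB convention right-justifies one-letter elements so that column 13 is
    blank for C/N/O/S/P atoms of standard residues; two-letter elements
    (FE, ZN, ...) occupy columns 13-14.
    """
    name = atom_name.strip()
    if not name:
        return ""
    # strip leading digits (e.g. "1HB" hydrogens, "2HO")
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if len(stripped) >= 2 and two in _TWO_CHAR_ELEMENTS:
        # avoid eating "CA"/"CD"/... of amino-acid carbons: only trust the
        # two-letter reading for HETATM records or non-standard names
        if is_hetatm and res_name not in WATER_CODES:
            return two
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> Atom:
    def col(a: int, b: int) -> str:
        return line[a:b]

    try:
        serial = int(col(6, 11).strip() or "0")
        x = float(col(30, 38))
        y = float(col(38, 46))
        z = float(col(46, 54))
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed numeric field: {exc}") from exc
    occ_field = col(54, 60).strip()
    occupancy = float(occ_field) if occ_field else 1.0
    atom_name = col(12, 16).strip()
    res_name = col(17, 20).strip()
    is_het = line.startswith("HETATM")
    element = col(76, 78).strip().upper()
    if not element:
        element = _guess_element(col(12, 16), res_name, is_het)
    return Atom(
        serial=serial,
        atom_name=atom_name,
        alt_loc=col(16, 17).strip(),
        res_name=res_name,
        chain_id=col(21, 22).strip(),
        res_seq=int(col(22, 26).strip() or "0"),
        insertion_code=col(26, 27).strip(),
        x=x, y=y, z=z,
        occupancy=occupancy,
        element=element,
        is_hetatm=is_het,
    )


def parse_pdb(text: str, structure_id: str = "") -> Structure:
    """Parse fixed-column PDB text into a :class:`Structure`.

    Only the first ``MODEL`` block is read.  The element is taken from
    columns 77-78, with a name-based heuristic fallback when blank.
    """
    atoms: list[Atom] = []
    in_model = 0  # 0 = no MODEL seen yet, 1 = first model, 2 = past it
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            in_model += 1
            if in_model > 1:
                break
            continue
        if rec.startswith("ENDMDL"):
            if in_model >= 1:
                break
            continue
        if rec in ("ATOM  ", "HETATM") or line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: truncated coordinate record")
            atoms.append(_parse_atom_line(line.ljust(80), lineno))
    if not atoms:
        raise PDBParseError("no ATOM/HETATM records found")
    return Structure(atoms=atoms, id=structure_id)


def write_pdb(s: Structure) -> str:
    """Serialize a structure back to fixed-column PDB text.

    Round-trips through :func:`parse_pdb` on every parsed field.
    """
    if not s.atoms:
        raise ValueError("cannot write an empty structure")
    lines = []
    for a in s.atoms:
        rec = "HETATM" if a.is_hetatm else "ATOM  "
        # PDB name justification: 1-letter elements start at column 14
        name = a.atom_name
        if len(name) < 4 and len(a.element) < 2:
            name = " " + name
        lines.append(
            f"{rec}{a.serial:>5d} {name:<4s}{a.alt_loc or ' ':1s}"
            f"{a.res_name:>3s} {a.chain_id:1s}{a.res_seq:>4d}"
            f"{a.insertion_code or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def clean_structure(
    s: Structure,
    table: "TypeTable",
    keep_het_codes: Iterable[str] = (),
    remove_hydrogens: bool = True,
) -> tuple[Structure, CleanReport]:
    """Remove waters, hydrogens, alternate locations and untypeable atoms.

    Waters (HOH/WAT) are always removed.  Of alternate locations only the
    highest-occupancy conformer is kept (ties broken by the lexicographically
    smallest alt_loc).  Atoms with no entry in ``table`` are always removed
    and reported.  When ``keep_het_codes`` is non-empty it acts as a
    whitelist: hetero residues outside it are removed even if typed.  This is
    an explicit pre-processing step — analysis functions never call it.
    """
    keep_het = {c.upper() for c in keep_het_codes}
    report = CleanReport()
    stage1: list[Atom] = []
    for a in s.atoms:
        if a.res_name.upper() in WATER_CODES:
            report.removed_waters += 1
        elif remove_hydrogens and a.element.upper() in HYDROGEN_ELEMENTS:
            report.removed_hydrogens += 1
        else:
            stage1.append(a)

    # alternate locations: group by (chain, seq, icode, atom_name)
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in stage1:
        k = (a.chain_id, a.res_seq, a.insertion_code, a.atom_name)
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            report.removed_altlocs += 1
            if a.occupancy > b.occupancy or (
                    a.occupancy == b.occupancy and a.alt_loc < b.alt_loc):
                best[k] = a
    stage2 = [best[k] for k in order]

    kept: list[Atom] = []
    for a in stage2:
        typed = table.lookup(a.res_name, a.atom_name) is not None
        if not typed:
            report.removed_undefined.append((a.res_name, a.atom_name))
            continue
        if a.is_hetatm and keep_het and a.res_name.upper() not in keep_het:
            report.removed_undefined.append((a.res_name, a.atom_name))
            continue
        kept.append(replace(a, alt_loc=""))

    report.kept_atoms = len(kept)
    if not kept:
        raise ValueError("cleaning removed every atom; check the .DEF table")
    return Structure(atoms=kept, id=s.id), report


def split_units(
    s: Structure, group_a: Iterable[str], group_b: Iterable[str]
) -> tuple[list[int], list[int]]:
    """Split atoms into two chain groups; returns index lists into ``s.atoms``.

    Atoms in neither group are excluded from both sets.
    """
    a_set = set(group_a)
    b_set = set(group_b)
    if not a_set or not b_set:
        raise ValueError("both chain groups must be non-empty")
    overlap = a_set & b_set
    if overlap:
        raise ValueError(f"chain groups overlap: {sorted(overlap)}")
    present = set(s.chain_ids())
    unknown = (a_set | b_set) - present
    if unknown:
        raise ValueError(f"unknown chain id(s): {sorted(unknown)}")
    ia = [i for i, a in enumerate(s.atoms) if a.chain_id in a_set]
    ib = [i for i, a in enumerate(s.atoms) if a.chain_id in b_set]
    return ia, ib
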