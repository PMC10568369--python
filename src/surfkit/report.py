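"""CSV serialization and PyMOL-script visualization of CF reports.

The quantitative output is a plain CSV matrix (rows × columns of units,
cells to 4 decimal places, net-total row and column appended).  The visual
output is a PML command script — viewer-independent text that PyMOL can
execute — coloring each unit by its net interaction value on a
blue (favorable) / white / red (unfavorable) scale and drawing dashed
distance objects for the strongest pairwise interactions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .cf import CFReport, UnitSpec, residue_totals
from .structure import Structure

__all__ = [
    "ColorScale",
    "write_matrix_csv",
    "color_for_value",
    "pymol_script",
    "default_scale",
    "validate_pml",
]

#: PML commands the emitted scripts may use, with (min, max) argument counts.
_PML_COMMANDS = {
    "load": (1, 2),
    "hide": (1, 2),
    "show": (1, 2),
    "set": (1, 2),
    "set_color": (2, 2),
    "color": (1, 2),
    "distance": (2, 3),
    "bg_color": (1, 1),
}


def validate_pml(text: str) -> None:
    """Syntax-check a PML script; raises ``ValueError`` on the first defect.

    Checks each line against the known command vocabulary, argument counts
    (comma-separated, top-level), balanced parentheses/brackets, and
    non-empty selection expressions.
    """
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 1)
        cmd = parts[0]
        if cmd not in _PML_COMMANDS:
            raise ValueError(f"line {lineno}: unknown PML command {cmd!r}")
        argstr = parts[1] if len(parts) > 1 else ""
        depth = 0
        args: list[str] = []
        cur = ""
        for ch in argstr:
            if ch in "([":
                depth += 1
            elif ch in ")]":
                depth -= 1
                if depth < 0:
                    raise ValueError(f"line {lineno}: unbalanced parentheses")
            if ch == "," and depth == 0:
                args.append(cur.strip())
                cur = ""
            else:
                cur += ch
        if depth != 0:
            raise ValueError(f"line {lineno}: unbalanced parentheses")
        if cur.strip():
            args.append(cur.strip())
        lo, hi = _PML_COMMANDS[cmd]
        if not lo <= len(args) <= hi:
            raise ValueError(
                f"line {lineno}: {cmd} expects {lo}..{hi} args, got {len(args)}")
        if any(not a for a in args):
            raise ValueError(f"line {lineno}: empty argument")

TOTAL_LABEL = "NET_TOTAL"


@dataclass(frozen=True)
class ColorScale:
    """Linear blue→white→red scale over [vmin, 0, vmax]."""

    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError("require vmin < vmax")


def default_scale(rep: CFReport) -> ColorScale:
    """Symmetric scale: vmax = max |net|, so 0 is always white."""
    nets = list(residue_totals(rep).values())
    m = max((abs(v) for v in nets), default=0.0)
    if m == 0.0:
        m = 1.0
    return ColorScale(vmin=-m, vmax=m)


def color_for_value(v: float, scale: ColorScale) -> tuple[float, float, float]:
    """RGB in [0,1]³: blue at vmin (favorable), white at 0, red at vmax."""
    if v <= 0:
        t = min(1.0, v / scale.vmin) if scale.vmin < 0 else 1.0
        return (1.0 - t, 1.0 - t, 1.0)  # white -> blue
    t = min(1.0, v / scale.vmax) if scale.vmax > 0 else 1.0
    return (1.0, 1.0 - t, 1.0 - t)  # white -> red


def write_matrix_csv(rep: CFReport) -> str:
    """Render a CFReport as CSV with labeled net-total margins.

    Header row carries the column-unit labels; the first field of each row
    is the row-unit label; every cell is printed with 4 decimals.  A final
    ``NET_TOTAL`` row and column hold the per-unit sums and grand total.
    """
    lines = []
    col_labels = [u.label for u in rep.cols]
    lines.append(",".join([""] + col_labels + [TOTAL_LABEL]))
    for u, row, tot in zip(rep.rows, rep.cf, rep.row_totals):
        cells = [f"{v:.4f}" for v in row]
        lines.append(",".join([u.label] + cells + [f"{tot:.4f}"]))
    totals = [f"{v:.4f}" for v in rep.col_totals]
    lines.append(",".join([TOTAL_LABEL] + totals + [f"{rep.grand_total:.4f}"]))
    return "\n".join(lines) + "\n"


def _chain_expr(chain_id: str) -> str:
    return chain_id if chain_id else '""'


def _selection(s: Structure, u: UnitSpec) -> str:
    """PyMOL selection expression for a unit's atoms."""
    a0 = s.atoms[u.atom_indices[0]]
    chain = _chain_expr(a0.chain_id)
    if u.kind == "ligand-atom":
        return (f"(chain {chain} and resi {a0.res_seq} "
                f"and name {a0.atom_name})")
    return f"(chain {chain} and resi {a0.res_seq})"


def _closest_pair(s: Structure, u1: UnitSpec, u2: UnitSpec) -> tuple[int, int]:
    best = (u1.atom_indices[0], u2.atom_indices[0])
    best_d = math.inf
    for i in u1.atom_indices:
        ai = s.atoms[i]
        for j in u2.atom_indices:
            aj = s.atoms[j]
            d = ((ai.x - aj.x) ** 2 + (ai.y - aj.y) ** 2 + (ai.z - aj.z) ** 2)
            if d < best_d:
                best_d = d
                best = (i, j)
    return best


def _atom_sel(s: Structure, i: int) -> str:
    a = s.atoms[i]
    return (f"(chain {_chain_expr(a.chain_id)} and resi {a.res_seq} "
            f"and name {a.atom_name})")


def pymol_script(
    s: Structure,
    rep: CFReport,
    scale: ColorScale | None = None,
    top_fraction: float = 0.10,
    structure_path: str = "structure.pdb",
) -> str:
    """Emit a deterministic PML command script visualizing a report.

    Colors every unit by its net CF on the given scale and draws dashed
    distance objects between the closest heavy atoms of the strongest
    ``ceil(top_fraction * nonzero cells)`` pairs, each dash colored by its
    CF value.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if scale is None:
        scale = default_scale(rep)
    lines = [
        f"load {structure_path}, complex",
        "hide everything, complex",
        "show surface, complex",
        "set dash_gap, 0.4",
        "set dash_radius, 0.1",
    ]
    units = {u.label: u for u in rep.rows}
    for u in rep.cols:
        units.setdefault(u.label, u)
    nets = residue_totals(rep)
    for label, u in units.items():
        r, g, b = color_for_value(nets.get(label, 0.0), scale)
        cname = "cf_" + re.sub(r"[^A-Za-z0-9_]", "_", label)
        lines.append(f"set_color {cname}, [{r:.4f}, {g:.4f}, {b:.4f}]")
        lines.append(f"color {cname}, {_selection(s, u)}")

    nonzero = [(abs(rep.cf[r, c]), r, c)
               for r in range(len(rep.rows)) for c in range(len(rep.cols))
               if rep.cf[r, c] != 0.0]
    nonzero.sort(key=lambda t: (-t[0], t[1], t[2]))
    n_dash = math.ceil(top_fraction * len(nonzero)) if nonzero else 0
    for k, (_, r, c) in enumerate(nonzero[:n_dash]):
        i, j = _closest_pair(s, rep.rows[r], rep.cols[c])
        name = f"dash_{k}"
        cr, cg, cb = color_for_value(rep.cf[r, c], scale)
        lines.append(f"distance {name}, {_atom_sel(s, i)}, {_atom_sel(s, j)}")
        lines.append(f"set_color {name}_col, [{cr:.4f}, {cg:.4f}, {cb:.4f}]")
        lines.append(f"color {name}_col, {name}")
        lines.append(f"hide labels, {name}")
    lines.append("bg_color white")
    return "\n".join(lines) + "\n"
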