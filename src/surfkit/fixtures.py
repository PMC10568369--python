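"""Deterministic toy structures for tests, examples and self-checks.

Everything here is generated in memory — no downloads, no data files.  The
two-atom system is the closed-form benchmark for contact areas (two
overlapping spheres → spherical caps); the toy complex is a minimal
two-chain glycine "dimer" with a three-atom ligand sitting in the
interface, small enough that every pipeline runs in well under a second yet
exercising residues, chains, HETATM records and ligand typing.
"""

from __future__ import annotations

import numpy as np

from .atomtypes import TypedAtom, TypeTable, assign_types, default_def, load_def, merge_def
from .geometry import DEFAULT_RADII, RadiiTable
from .structure import Atom, Structure

__all__ = [
    "make_two_atom_fixture",
    "make_toy_complex",
    "make_typed_cloud",
    "toy_def",
    "TOY_LIG_DEF",
]

#: ``.DEF`` fragment typing the toy ligand (two sp3 carbons, one hydroxyl O).
TOY_LIG_DEF = "LIG C1 3\nLIG C2 3\nLIG O1 14\n"


def toy_def() -> TypeTable:
    """Shipped protein table extended with the toy-ligand fragment."""
    return merge_def(default_def(), load_def(TOY_LIG_DEF))


def make_two_atom_fixture(elements: tuple[str, str] = ("C", "C"),
                          d: float = 4.0) -> Structure:
    """Two single-atom residues on chains A and B, centers ``d`` Å apart
    on the x-axis.  Deterministic: same arguments → identical structure."""
    if d <= 0:
        raise ValueError("distance must be positive")
    e1, e2 = (e.upper() for e in elements)
    atoms = [
        Atom(serial=1, atom_name=f"{e1}1", alt_loc="", res_name="TA1",
             chain_id="A", res_seq=1, insertion_code="", x=0.0, y=0.0, z=0.0,
             occupancy=1.0, element=e1, is_hetatm=True),
        Atom(serial=2, atom_name=f"{e2}1", alt_loc="", res_name="TA2",
             chain_id="B", res_seq=1, insertion_code="", x=float(d), y=0.0,
             z=0.0, occupancy=1.0, element=e2, is_hetatm=True),
    ]
    return Structure(atoms=atoms, id=f"two-atom-{e1}{e2}-{d:g}")


# Idealized glycine heavy-atom offsets within a residue (Å).
_GLY_OFFSETS = {
    "N": (0.00, 0.00, 0.00),
    "CA": (1.45, 0.10, 0.00),
    "C": (2.15, 1.30, 0.10),
    "O": (1.60, 2.35, 0.15),
}


def make_toy_complex(seed: int = 1, with_ligand: bool = True) -> Structure:
    """A small two-chain glycine dimer, optionally with a 3-atom ``LIG``.

    Chains A and B run antiparallel 6 Å apart (interface gaps 3-4 Å, well
    inside the solvent-expanded contact range); the ligand sits in the
    interface on its own chain L.  Coordinates carry a small seeded jitter
    (±0.1 Å) so different seeds give distinct but equally valid geometries;
    the same seed always reproduces the identical structure.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    serial = 1

    def jitter() -> np.ndarray:
        return rng.uniform(-0.1, 0.1, size=3)

    for res_i in range(5):
        base = np.array([res_i * 3.8, 0.0, 0.0])
        for name, off in _GLY_OFFSETS.items():
            p = base + np.array(off) + jitter()
            atoms.append(Atom(serial=serial, atom_name=name, alt_loc="",
                              res_name="GLY", chain_id="A", res_seq=res_i + 1,
                              insertion_code="", x=round(p[0], 3),
                              y=round(p[1], 3), z=round(p[2], 3),
                              occupancy=1.0, element=name[0], is_hetatm=False))
            serial += 1
    for res_i in range(5):
        base = np.array([16.0 - res_i * 3.8, 6.1, 0.3])
        for name, off in _GLY_OFFSETS.items():
            p = base + np.array([-off[0], -off[1], off[2]]) + jitter()
            atoms.append(Atom(serial=serial, atom_name=name, alt_loc="",
                              res_name="GLY", chain_id="B", res_seq=res_i + 1,
                              insertion_code="", x=round(p[0], 3),
                              y=round(p[1], 3), z=round(p[2], 3),
                              occupancy=1.0, element=name[0], is_hetatm=False))
            serial += 1
    if with_ligand:
        lig = {"C1": (7.2, 3.6, 1.6), "C2": (8.6, 3.7, 1.7), "O1": (9.5, 4.5, 1.8)}
        for name, pos in lig.items():
            p = np.array(pos) + jitter()
            atoms.append(Atom(serial=serial, atom_name=name, alt_loc="",
                              res_name="LIG", chain_id="L", res_seq=201,
                              insertion_code="", x=round(p[0], 3),
                              y=round(p[1], 3), z=round(p[2], 3),
                              occupancy=1.0, element=name[0], is_hetatm=True))
            serial += 1
    return Structure(atoms=atoms, id=f"toy-complex-{seed}")


def make_typed_cloud(seed: int, n_atoms: int,
                     radii: RadiiTable = DEFAULT_RADII,
                     box: float | None = None,
                     min_sep: float = 1.5) -> list[TypedAtom]:
    """Random typed atom cloud with realistic (≥ ``min_sep`` Å) separations.

    Elements cycle through C, N, O, S; positions are drawn uniformly in a
    cube sized to give a condensed cluster with many overlapping expanded
    spheres, rejecting placements closer than ``min_sep``.
    """
    from .atomtypes import element_fallback_def

    rng = np.random.default_rng(seed)
    if box is None:
        box = max(6.0, 2.2 * n_atoms ** (1 / 3) * 2.0)
    elements = ["C", "N", "O", "S"]
    placed: list[np.ndarray] = []
    while len(placed) < n_atoms:
        p = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(p - q) >= min_sep for q in placed):
            placed.append(p)
    atoms = [
        Atom(serial=i + 1, atom_name=f"{elements[i % 4]}{i + 1}", alt_loc="",
             res_name="CLD", chain_id="A", res_seq=i + 1, insertion_code="",
             x=round(float(p[0]), 3), y=round(float(p[1]), 3),
             z=round(float(p[2]), 3), occupancy=1.0,
             element=elements[i % 4], is_hetatm=True)
        for i, p in enumerate(placed)
    ]
    s = Structure(atoms=atoms, id=f"cloud-{seed}-{n_atoms}")
    table = element_fallback_def(s)
    return assign_types(s, table, radii)
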