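"""Atom–atom contact surface areas by radical-plane partition.

Every heavy atom is modelled as a sphere of *expanded radius*
``r_vdw + r_probe`` (probe = water, 1.4 Å by default).  The expanded sphere
of atom *i* is partitioned among its overlapping neighbors with the power
(Laguerre) distance criterion: a surface point *p* buried inside at least
one neighbor sphere is assigned to the neighbor *j* minimizing
``|p - c_j|^2 - R_j'^2``, the construction whose cell boundaries are the
radical planes of the power diagram.  The area assigned to *j* is the
contact surface ``S_ij``; the unassigned remainder is the solvent-exposed
area.

Areas are evaluated by deterministic spherical quadrature on a near-uniform
Fibonacci lattice (default 5120 points per sphere, accurate to well under
1% for contact patches of a few Å²), with a seeded Monte-Carlo estimator
(:func:`sampling_oracle`) of the identical partition serving as an
independent statistical cross-check.  Because the quadrature grid assigns
each point to exactly one bin, per-atom assigned + exposed areas sum to
``4*pi*R'^2`` exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .atomtypes import TypedAtom

logger = logging.getLogger(__name__)

__all__ = [
    "RadiiTable",
    "DEFAULT_RADII",
    "ContactMap",
    "expanded_radius",
    "find_neighbors",
    "partition_atom_surface",
    "contact_areas",
    "sampling_oracle",
    "sphere_grid",
    "one_sided_areas",
]

MIN_RESOLUTION = 1000

#: Bondi-style van der Waals radii (Å) for common heavy elements.
_BONDI = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "H": 1.20, "D": 1.20,
    "FE": 1.80, "ZN": 1.39, "MG": 1.73, "CA": 2.00, "NA": 2.27,
    "K": 2.75, "MN": 1.80, "CU": 1.40, "NI": 1.63, "CO": 1.80,
    "LI": 1.82, "AL": 1.84, "SI": 2.10, "MO": 1.80,
}


@dataclass(frozen=True)
class RadiiTable:
    """Element → van der Waals radius (Å), with a default for unknowns."""

    radii: dict[str, float] = field(default_factory=lambda: dict(_BONDI))
    default_radius: float = 1.80
    probe_radius: float = 1.40

    def __post_init__(self) -> None:
        if self.default_radius <= 0 or any(r <= 0 for r in self.radii.values()):
            raise ValueError("all radii must be positive")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")

    def vdw_radius(self, element: str) -> float:
        r = self.radii.get(element.upper())
        if r is None:
            logger.warning("unknown element %r: using default radius %.2f Å",
                           element, self.default_radius)
            return self.default_radius
        return r


DEFAULT_RADII = RadiiTable()


def expanded_radius(a: TypedAtom, radii: RadiiTable = DEFAULT_RADII) -> float:
    """Van der Waals radius plus solvent probe radius, in Å."""
    return radii.vdw_radius(a.atom.element) + radii.probe_radius


@dataclass
class ContactMap:
    """Sparse pairwise contact areas plus per-atom solvent-exposed areas.

    Keys of ``areas`` are unordered index pairs ``(i, j)`` with ``i < j``
    into the atom list the map was computed from.
    """

    areas: dict[tuple[int, int], float]
    exposed: dict[int, float]
    resolution: int

    def area(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        return self.areas.get((min(i, j), max(i, j)), 0.0)

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.areas)


def sphere_grid(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere lattice of ``n`` points.

    Fibonacci (golden-angle) spiral: points at constant z-spacing rotated by
    the golden angle, giving close to equal-area cells for any ``n``.
    """
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * (math.pi * (3.0 - math.sqrt(5.0)))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def _centers_and_radii(atoms: list[TypedAtom], radii: RadiiTable):
    centers = np.array([a.atom.coords for a in atoms], dtype=float)
    expanded = np.array([expanded_radius(a, radii) for a in atoms])
    return centers, expanded


def find_neighbors(
    atoms: list[TypedAtom], radii: RadiiTable = DEFAULT_RADII
) -> list[tuple[int, int]]:
    """All unordered index pairs whose expanded spheres overlap.

    Definition: center distance strictly below the sum of expanded radii.
    A k-d tree prunes the search; the result equals the exhaustive
    double-loop definition.  Coincident centers are a hard error (their
    radical plane is undefined).
    """
    if not atoms:
        raise ValueError("need at least one atom")
    centers, expanded = _centers_and_radii(atoms, radii)
    tree = cKDTree(centers)
    rmax = float(expanded.max())
    out: list[tuple[int, int]] = []
    for i, j in sorted(tree.query_pairs(2.0 * rmax)):
        d = float(np.linalg.norm(centers[i] - centers[j]))
        if d == 0.0:
            raise ValueError(
                f"atoms {atoms[i].atom.serial} and {atoms[j].atom.serial} "
                "have coincident centers (degenerate radical plane)")
        if d < expanded[i] + expanded[j]:
            out.append((i, j))
    # query_pairs cannot miss overlaps: d < Ri' + Rj' <= 2 rmax
    return out


def _assign_points(
    points: np.ndarray,
    neighbor_centers: np.ndarray,
    neighbor_radii: np.ndarray,
    neighbor_order: np.ndarray,
) -> np.ndarray:
    """For each surface point, index (into the neighbor arrays) of the owning
    neighbor under the power-distance rule, or -1 if solvent-exposed.

    ``neighbor_order`` ranks neighbors for tie-breaking (lower rank wins).
    """
    n_pts = points.shape[0]
    if neighbor_centers.shape[0] == 0:
        return np.full(n_pts, -1, dtype=int)
    from scipy.spatial.distance import cdist

    r2 = neighbor_radii ** 2
    # (n_pts, n_nb) power distances; non-buried candidates masked out
    power = cdist(points, neighbor_centers, "sqeuclidean")
    power -= r2[None, :]
    power[power >= 0.0] = np.inf  # buried means strictly inside: power < 0
    best = np.argmin(power, axis=1)
    rows = np.arange(n_pts)
    min_power = power[rows, best]
    # tie-break (rare): among equal minimal powers take the lowest rank
    tie_rows = np.flatnonzero(
        np.isfinite(min_power)
        & ((power == min_power[:, None]).sum(axis=1) > 1))
    for r in tie_rows:
        cand = np.flatnonzero(power[r] == min_power[r])
        best[r] = cand[np.argmin(neighbor_order[cand])]
    best[~np.isfinite(min_power)] = -1
    return best


def partition_atom_surface(
    i: int,
    atoms: list[TypedAtom],
    neighbor_idx: list[int],
    radii: RadiiTable = DEFAULT_RADII,
    resolution: int = 5120,
    grid: np.ndarray | None = None,
) -> tuple[dict[int, float], float]:
    """Partition atom ``i``'s expanded sphere among its neighbors.

    Returns ``(per-neighbor area map, exposed area)`` in Å².  The grid is a
    fixed lab-frame lattice of ``resolution`` points scaled to the expanded
    sphere; each buried point goes to the neighbor of minimal power
    distance, ties to the lower atom serial.
    """
    if resolution < MIN_RESOLUTION:
        raise ValueError(f"resolution must be >= {MIN_RESOLUTION}")
    centers, expanded = _centers_and_radii(atoms, radii)
    if grid is None:
        grid = sphere_grid(resolution)
    points = centers[i] + expanded[i] * grid
    nb = np.asarray(neighbor_idx, dtype=int)
    serials = np.array([atoms[j].atom.serial for j in nb], dtype=np.int64)
    owner = _assign_points(points, centers[nb] if nb.size else np.empty((0, 3)),
                           expanded[nb] if nb.size else np.empty(0),
                           serials)
    total = 4.0 * math.pi * expanded[i] ** 2
    w = total / resolution
    area_map: dict[int, float] = {}
    for k, j in enumerate(nb):
        cnt = int(np.count_nonzero(owner == k))
        if cnt:
            area_map[int(j)] = cnt * w
    exposed = int(np.count_nonzero(owner == -1)) * w
    return area_map, exposed


def one_sided_areas(
    atoms: list[TypedAtom],
    radii: RadiiTable = DEFAULT_RADII,
    resolution: int = 5120,
) -> tuple[list[tuple[int, int]], dict[tuple[int, int], float], dict[int, float]]:
    """Ordered one-sided areas: ``(i, j)`` maps to the area of *j*'s cell on
    *i*'s sphere.  Returns (overlapping pairs, area dict, exposed dict).

    Per atom the assigned + exposed areas sum to ``4*pi*Ri'^2`` exactly:
    every grid point falls in exactly one bin.
    """
    pairs = find_neighbors(atoms, radii)
    neighbor_of: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i, j in pairs:
        neighbor_of[i].append(j)
        neighbor_of[j].append(i)
    grid = sphere_grid(resolution)
    area: dict[tuple[int, int], float] = {}
    exposed: dict[int, float] = {}
    for i in range(len(atoms)):
        amap, exp = partition_atom_surface(
            i, atoms, neighbor_of[i], radii, resolution, grid=grid)
        exposed[i] = exp
        for j, a in amap.items():
            area[(i, j)] = a
    return pairs, area, exposed


def contact_areas(
    atoms: list[TypedAtom],
    radii: RadiiTable = DEFAULT_RADII,
    resolution: int = 5120,
    one_sided: bool = False,
) -> ContactMap:
    """Contact surface areas for every atom pair of a typed structure.

    ``S_ij`` is by default the arithmetic mean of the two one-sided areas
    (area of *j*'s cell on *i*'s sphere, and vice versa).  With
    ``one_sided=True`` the raw area of *j*'s cell on *i*'s sphere is stored
    for the pair ``(i, j)``, ``i < j``, without averaging.  Exposed areas
    are recorded per atom either way.
    """
    if resolution < MIN_RESOLUTION:
        raise ValueError(f"resolution must be >= {MIN_RESOLUTION}")
    pairs, one_sided_area, exposed = one_sided_areas(atoms, radii, resolution)
    areas: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        ij = one_sided_area.get((i, j), 0.0)
        ji = one_sided_area.get((j, i), 0.0)
        if one_sided:
            if ij > 0.0:
                areas[(i, j)] = ij  # raw area of j's cell on i's sphere
        else:
            s = 0.5 * (ij + ji)
            if s > 0.0:
                areas[(i, j)] = s
    return ContactMap(areas=areas, exposed=exposed, resolution=resolution)


def sampling_oracle(
    atoms: list[TypedAtom],
    radii: RadiiTable = DEFAULT_RADII,
    n_samples: int = 200_000,
    seed: int = 0,
) -> ContactMap:
    """Monte-Carlo estimator of the same radical-plane partition.

    Draws ``n_samples`` uniform points on each expanded sphere (seeded,
    reproducible) and applies the identical burial/power-distance rule; an
    unbiased estimator of the quadrature areas, used as an independent
    statistical oracle in tests.
    """
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 10000")
    rng = np.random.default_rng(seed)
    pairs = find_neighbors(atoms, radii)
    neighbor_of: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i, j in pairs:
        neighbor_of[i].append(j)
        neighbor_of[j].append(i)
    centers, expanded = _centers_and_radii(atoms, radii)
    one_sided_area: dict[tuple[int, int], float] = {}
    exposed: dict[int, float] = {}
    for i in range(len(atoms)):
        dirs = rng.normal(size=(n_samples, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        points = centers[i] + expanded[i] * dirs
        nb = np.asarray(neighbor_of[i], dtype=int)
        serials = np.array([atoms[j].atom.serial for j in nb], dtype=np.int64)
        owner = _assign_points(points, centers[nb] if nb.size else np.empty((0, 3)),
                               expanded[nb] if nb.size else np.empty(0), serials)
        total = 4.0 * math.pi * expanded[i] ** 2
        w = total / n_samples
        for k, j in enumerate(nb):
            cnt = int(np.count_nonzero(owner == k))
            if cnt:
                one_sided_area[(i, int(j))] = cnt * w
        exposed[i] = int(np.count_nonzero(owner == -1)) * w
    areas: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        s = 0.5 * (one_sided_area.get((i, j), 0.0) + one_sided_area.get((j, i), 0.0))
        if s > 0.0:
            areas[(i, j)] = s
    return ContactMap(areas=areas, exposed=exposed, resolution=n_samples)
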