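# Methods

## Model

`surfkit` scores molecular interactions by pairing a purely geometric
quantity — the surface area in contact between two atoms — with an
empirical atom-type pair potential.

**Contact areas.** Each heavy atom *i* is a sphere of expanded radius
`R'ᵢ = r_vdw(elementᵢ) + r_probe`. Two atoms are *in contact* when their
expanded spheres overlap (`d < R'ᵢ + R'ⱼ`, strict). The surface of each
sphere is partitioned by the power (Laguerre) diagram restricted to the
sphere: a surface point *p* strictly inside at least one neighbor sphere is
assigned to the neighbor *j* minimizing the power distance
`|p − cⱼ|² − R'ⱼ²`; the cell boundaries are the radical planes. The area of
*j*'s cell on *i*'s sphere is the one-sided contact area; the reported
`S_ij` is the arithmetic mean of the two one-sided areas (the two caps are
congruent for equal radii; for unequal radii neither side is privileged,
and the mean keeps `S_ij` a single symmetric pair quantity). Surface not
assigned to any neighbor is the solvent-exposed area.

**Complementarity function.** With atom types `t` from a 40-label SYBYL
vocabulary and a symmetric matrix `ε` (pseudo-energy per Å²),

    CF(unit₁, unit₂) = Σ_{i∈unit₁} Σ_{j∈unit₂} ε(tᵢ, tⱼ) · S_ij.

CF is bilinear in the atom sets, scales linearly with `ε`, and is zero for
non-contacting units. Negative values are favorable. Because contact areas
are computed once on the full structure and shared by every analysis mode,
`S_ij` always reflects occlusion by the complete environment, and the three
modes (chain group vs chain group; residues vs ligand atoms; selected
residues vs all partners) are exactly consistent: per-residue ligand sums
reproduce the chain-group run to machine precision.

In the particular-residues mode, when two selected residues contact each
other the pair appears in both rows (each lists the other among its
columns, with equal CF); the grand total then counts that pair twice —
read per-row nets, not the grand total, in that mode.

## Numerical evaluation

Areas are computed by deterministic quadrature: a Fibonacci (golden-angle)
lattice of `resolution` points (default 5120, floor 1000) is scaled to each
expanded sphere, every point is binned to a neighbor cell or to solvent,
and each point carries equal weight `4πR'²/resolution`. Consequences:

* **Conservation is exact** — per atom, assigned + exposed areas sum to
  `4πR'²` to floating-point precision, at any resolution.
* **Accuracy** — for the closed-form benchmark (equal spheres, R′ = 3.1 Å,
  d = 4 Å; cap area `2πR(R−d/2)` ≈ 21.43 Å²) the default grid is accurate
  to ~0.1%, well within the 1% target.
* **Orientation noise** — the lattice is fixed in the lab frame, so rigid
  motions of the structure change areas within a tolerance, not exactly.
  Measured on random clusters, the noise is ≈0.2 Å² absolute regardless of
  patch size (roughly one row of grid cells along the cap boundary). A 1%
  *relative* bound is therefore meaningful only for patches ≳20 Å²; a
  grazing contact of one or two grid cells (~0.02–0.05 Å²) can change by
  its own magnitude under rotation. Rigid-motion checks accordingly use a
  1%-relative bound on the large benchmark cap and a
  `max(1% relative, 0.1 Å² absolute)` tolerance for arbitrary contacts.
  Aggregate CF values built from near-cancelling sums (e.g. a mixed-sign
  interface total close to zero) inherit the absolute, not the relative,
  error.

An independent seeded Monte-Carlo estimator evaluates the identical
partition with uniform random points on each sphere. Quadrature and
Monte-Carlo are compared within 3σ, where σ combines the binomial standard
errors of both estimators (the lattice treated as a binomial sample of its
own size — conservative, since a low-discrepancy lattice beats random
sampling). The shipped validation runs this comparison at 2×10⁵ samples on
100 random clusters of 5–20 atoms (~1 minute); typical worst-case
deviations are below 1σ.

Tie-breaks and degeneracies: equal power distances go to the lower atom
serial; coincident atom centers are a hard error (undefined radical
plane); an isolated atom is fully exposed; empty reports (no contacts) are
valid outputs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `probe_radius` | 1.40 Å | water-sized solvent probe added to every vdW radius |
| vdW radii | Bondi-style table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, …) | per-element; unknown elements fall back to 1.80 Å with a warning |
| `resolution` | 5120 | quadrature points per sphere; error ∝ 1/√resolution; floor 1000 |
| `top_fraction` | 0.10 | fraction of strongest \|CF\| cells drawn as dashed lines in the PML script |
| color scale | symmetric, `vmax = max\|net\|` | keeps CF = 0 white; blue favorable, red unfavorable |

## Atom typing and the energy matrix

Typing is table-driven: a `.DEF` text table maps `(residue name, atom
name)` → type id 1..40, case-insensitively; later duplicates override
earlier ones with a warning. The shipped protein table covers all heavy
atoms of the 20 standard amino acids plus terminal `OXT`, following
standard SYBYL conventions (backbone N → `N.am`, carbonyl C → `C.2`,
carboxylates → `O.co2`, aromatic rings → `C.ar`/`N.ar`, arginine CZ →
`C.cat`, lysine NZ → `N.4`, …). Ligands and modified residues are covered
by merging extra `.DEF` fragments; a crude element-level generator
(`C → C.3`, `O → O.3`, metals → their ion types, unknown → `Du`) provides
a starting point that should be hand-curated for real ligands.

The shipped pseudo-energy matrix is **synthetic**: a rule-based
construction (hydrophobic–hydrophobic −0.10/Å², donor–acceptor −0.15,
salt bridge ∓0.25 by charge product, metal–acceptor coordination −0.30,
polar/apolar mismatch +0.06, aromatic stacking bonus, `Du` inert). It has
the right structure (symmetric 40×40, favorable-negative) and produces
chemically sensible rankings on the toy systems, but its values are not
fitted to experimental data; for production analyses substitute a
calibrated matrix via `--matrix`. Every algebraic property of the
pipeline (bilinearity, scaling, mode consistency) is matrix-agnostic.

## Synthetic test data

The fixture generator emulates only the geometric and bookkeeping features
the method consumes: correct PDB fixed-column records, chains, residues,
HETATM ligands, realistic interatomic spacings (≥1.5 Å) and interface gaps
within solvent-expanded contact range. It does not emulate real protein
stereochemistry, rotamers, secondary structure, crystallographic artifacts
(altlocs and waters appear only in hand-written parser fixtures), or
chemically meaningful ligand geometry. Passing tests therefore demonstrate
correctness of the geometry, typing, algebra, serialization and CLI — not
predictive accuracy on real complexes, which depends on the energy matrix
used.

Problem sizes used by the shipped validation: two-atom closed-form
benchmarks; 100 random clusters of 5–20 atoms for conservation and oracle
agreement; a 43-atom two-chain complex with a 3-atom ligand for the
pipeline, mode-consistency and CLI checks.

## Design choices

* **Quadrature over analytic polygons.** The exact spherical-polygon
  construction of the power diagram is implementable but hard to verify;
  the equal-weight lattice is simple, exactly conservative, independently
  checkable by Monte-Carlo, and accurate to ≲1% where it matters. The
  contract (burial + power-distance assignment) would admit an analytic
  backend unchanged.
* **Explicit cleaning.** Removing waters/hydrogens/undefined atoms is a
  separate user-invoked step so that hetero-atom handling stays a user
  decision; analysis functions raise on untypeable atoms instead of
  guessing.
* **Hydrogens are stripped by default** (the contact model operates on
  heavy atoms with expanded radii); a flag retains them, in which case
  they occupy surface like any typed atom.
* **Viewer output is a text PML script**, not a binary session file, so
  visualization is testable and diffable without a GUI; loading the script
  in PyMOL reproduces the session.
* **Sequence-adjacent residues are included** in particular-residue mode
  (they are genuine interactions); `--skip-adjacent` excludes i±1
  neighbors on request.

## Limitations

* Contact areas depend on the single input conformation; no ensemble
  averaging.
* The synthetic default matrix is structurally correct but not fitted to
  experimental affinities; quantitative claims require a calibrated
  matrix.
* First PDB model only; mmCIF, assemblies and structure repair are out of
  scope.
* Grazing contacts below ~0.1 Å² are at the resolution limit of the
  default grid (raise `resolution` if they matter).
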