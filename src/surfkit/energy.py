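"""The pairwise atom-type pseudo-energy matrix.

The matrix assigns each unordered pair of SYBYL atom types a pseudo-energy
per unit contact area (Å⁻²).  Sign convention throughout the package:
**negative = favorable, positive = unfavorable**, matching the blue/red
color scale of the visual output.

The shipped default (``energy_matrix_synthetic.csv``) is a constructed,
rule-based matrix — hydrophobic packing, hydrogen-bond donor/acceptor
complementarity, salt bridges, metal coordination — built for this package
and labelled synthetic.  Any 40×40 matrix over the same vocabulary can be
substituted via ``--matrix``/:func:`load_matrix`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .atomtypes import N_TYPES

__all__ = ["EnergyMatrix", "load_matrix", "default_matrix"]

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class EnergyMatrix:
    """Symmetric pairwise pseudo-energy matrix over an atom-type vocabulary."""

    values: np.ndarray
    type_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("energy matrix must be square")
        if v.shape[0] != len(self.type_names):
            raise ValueError("matrix side must match number of type labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("energy matrix contains non-finite entries")
        asym = np.abs(v - v.T)
        if asym.max() > _SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"matrix asymmetric at ({self.type_names[i]}, "
                f"{self.type_names[j]}): {v[i, j]} vs {v[j, i]}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def epsilon(self, t1: int, t2: int) -> float:
        """Pseudo-energy for the interaction of type ids ``t1``, ``t2`` (1-based)."""
        for t in (t1, t2):
            if not 1 <= t <= self.n:
                raise ValueError(f"type id {t} outside 1..{self.n}")
        return float(self.values[t1 - 1, t2 - 1])

    def scaled(self, c: float) -> "EnergyMatrix":
        return EnergyMatrix(values=self.values * c, type_names=self.type_names)


def load_matrix(text: str, strict_size: bool = True) -> EnergyMatrix:
    """Parse a labeled CSV matrix (labels in header row and first column).

    Enforces symmetry to 1e-9.  With ``strict_size`` (the default) the side
    must be exactly 40; disable only to exercise toy alphabets in tests.
    """
    df = pd.read_csv(io.StringIO(text), index_col=0)
    labels_col = tuple(str(c).strip() for c in df.columns)
    labels_row = tuple(str(r).strip() for r in df.index)
    if labels_col != labels_row:
        raise ValueError("row and column labels differ")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("energy matrix contains NaN entries")
    if strict_size and values.shape != (N_TYPES, N_TYPES):
        raise ValueError(
            f"matrix must be {N_TYPES}x{N_TYPES}, got {values.shape[0]}x{values.shape[1]}")
    return EnergyMatrix(values=values, type_names=labels_col)


def default_matrix() -> EnergyMatrix:
    """The matrix shipped with the package (synthetic; see module docstring)."""
    text = resources.files("surfkit.data").joinpath(
        "energy_matrix_synthetic.csv").read_text()
    return load_matrix(text)
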