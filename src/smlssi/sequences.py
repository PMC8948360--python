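"""Excitation sequences: ordered sets of pattern-center positions.

A localization event interrogates the emitter with the beam minimum placed at
K positions r_i spanning a pattern of size ``L`` (the full pattern extent,
which defines the field of view):

* **MINFLUX** — the vertices of an equilateral triangle of circumradius L/2
  plus a fourth exposure at the pattern center (K = 4).
* **RASTMIN** — an m x m raster grid of minima with corners at (+-L/2, +-L/2)
  (K = m^2), as produced by any scanning microscope.

Sequence generation is deterministic.  Orientation conventions (first MINFLUX
vertex on the +y axis; raster rows along y ascending, x ascending within a
row) are arbitrary but fixed so position lists are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = ["ExcitationSequence", "minflux_sequence", "rastmin_sequence"]


@dataclass(frozen=True)
class ExcitationSequence:
    """Ordered list of pattern-center positions for one localization event."""

    method: str
    L: float
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise InvalidParameterError("positions must have shape (K, 2)")
        object.__setattr__(self, "positions", pos)
        half = self.L / 2.0 + 1e-9
        if np.any(np.abs(pos) > half):
            raise InvalidParameterError(
                "all positions must lie within the closed square [-L/2, L/2]^2"
            )

    @property
    def K(self) -> int:
        """Number of exposures."""
        return self.positions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Sequence as a table with columns (index, x_nm, y_nm)."""
        return pd.DataFrame(
            {
                "index": np.arange(self.K),
                "x_nm": self.positions[:, 0],
                "y_nm": self.positions[:, 1],
            }
        )


def minflux_sequence(L: float) -> ExcitationSequence:
    """MINFLUX four-exposure sequence for a pattern of size ``L`` (nm).

    Three exposures at the vertices of an equilateral triangle of circumradius
    L/2 centered at the origin (first vertex on the +y axis), and a fourth,
    final exposure at the pattern center.  The centroid of all four positions
    is the origin.
    """
    if not (L > 0):
        raise InvalidParameterError(f"L must be positive, got {L}")
    r = L / 2.0
    angles = np.array([0.5 * np.pi, 0.5 * np.pi + 2 * np.pi / 3, 0.5 * np.pi + 4 * np.pi / 3])
    vertices = r * np.column_stack([np.cos(angles), np.sin(angles)])
    positions = np.vstack([vertices, [0.0, 0.0]])
    return ExcitationSequence(method="minflux", L=float(L), positions=positions)


def rastmin_sequence(L: float, m: int = 4) -> ExcitationSequence:
    """RASTMIN raster sequence: an m x m grid of minima spanning the FOV.

    Grid corners sit at (+-L/2, +-L/2); nearest-neighbor spacing is L/(m-1).
    Row-major order: rows run over y from -L/2 upward, x ascending within
    each row.
    """
    if not (L > 0):
        raise InvalidParameterError(f"L must be positive, got {L}")
    if int(m) != m or m < 2:
        raise InvalidParameterError(f"grid side m must be an integer >= 2, got {m}")
    m = int(m)
    axis = np.linspace(-L / 2.0, L / 2.0, m)
    xx, yy = np.meshgrid(axis, axis)  # row index -> y, column index -> x
    positions = np.column_stack([xx.ravel(), yy.ravel()])
    return ExcitationSequence(method="rastmin", L=float(L), positions=positions)
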