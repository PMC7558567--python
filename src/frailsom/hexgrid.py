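"""Hexagonal map geometry for the self-organizing map.

Units live on a rows x cols lattice in "odd-r" offset layout (odd rows
shifted half a cell to the right, as in a standard hexagonal packing).
Offset coordinates are converted to cube coordinates, in which the
hexagonal lattice distance has the closed form
``(|dx| + |dy| + |dz|) / 2``; every interior unit then has exactly six
neighbours at distance 1. The map is planar (no wrap-around).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class HexGrid:
    """Planar hexagonal grid with odd-r offset layout.

    Unit ``(r, c)`` has flat index ``r * cols + c``. ``distances`` is the
    full units x units matrix of hexagonal lattice distances.
    """

    rows: int
    cols: int
    layout: str = "odd-r"
    axial_coords: np.ndarray = field(init=False, repr=False, compare=False)
    distances: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.rows < 2 or self.cols < 2:
            raise ValueError(f"grid must be at least 2x2, got {self.rows}x{self.cols}")
        if self.layout != "odd-r":
            raise ValueError(f"unsupported layout {self.layout!r}")
        r = np.repeat(np.arange(self.rows), self.cols)
        c = np.tile(np.arange(self.cols), self.rows)
        # odd-r offset -> axial: q = col - (row - (row & 1)) / 2
        q = c - (r - (r & 1)) // 2
        axial = np.column_stack([q, r])
        # cube coords (x, z, y) with x = q, z = r, y = -x - z
        x, z = axial[:, 0], axial[:, 1]
        y = -x - z
        dx = np.abs(x[:, None] - x[None, :])
        dy = np.abs(y[:, None] - y[None, :])
        dz = np.abs(z[:, None] - z[None, :])
        dist = (dx + dy + dz) / 2.0
        object.__setattr__(self, "axial_coords", axial)
        object.__setattr__(self, "distances", dist)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def unit_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"unit ({row}, {col}) outside {self.rows}x{self.cols} grid")
        return row * self.cols + col

    def neighbors(self, unit: int) -> np.ndarray:
        """Indices of units at hexagonal distance exactly 1."""
        return np.flatnonzero(self.distances[unit] == 1)

    def plot_coords(self) -> np.ndarray:
        """Cartesian centres of the hexagons for rendering.

        Odd rows are shifted half a cell right; row spacing is sqrt(3)/2
        so that unit hexagons pack without gaps.
        """
        r = np.repeat(np.arange(self.rows), self.cols)
        c = np.tile(np.arange(self.cols), self.rows)
        x = c + 0.5 * (r % 2)
        y = r * (np.sqrt(3.0) / 2.0)
        return np.column_stack([x, y])
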