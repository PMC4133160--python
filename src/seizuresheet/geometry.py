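"""Sheet geometry: a rectangular lattice of minicolumns grouped into
macrocolumns, with either toroidal or zero-flux (planar) boundaries.

Units are indexed row-major; macrocolumns are ``macro_edge`` x
``macro_edge`` blocks of minicolumns.  Distances are Euclidean in
micrometres; the torus uses the minimal-image convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np

BOUNDARIES = ("torus", "zero_flux")


@dataclasses.dataclass(frozen=True)
class SheetGeometry:
    n_rows: int
    n_cols: int
    macro_edge: int = 10
    pitch_um: float = 50.0
    boundary: str = "torus"

    def __post_init__(self) -> None:
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        if self.n_rows % self.macro_edge or self.n_cols % self.macro_edge:
            raise ValueError(
                f"sheet dimensions ({self.n_rows}x{self.n_cols}) must be "
                f"divisible by macro_edge ({self.macro_edge})"
            )

    # -- index maps ------------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def macro_rows(self) -> int:
        return self.n_rows // self.macro_edge

    @property
    def macro_cols(self) -> int:
        return self.n_cols // self.macro_edge

    @property
    def n_macros(self) -> int:
        return self.macro_rows * self.macro_cols

    @property
    def rows(self) -> np.ndarray:
        """Row coordinate of every unit (length ``n_units``)."""
        return np.repeat(np.arange(self.n_rows), self.n_cols)

    @property
    def cols(self) -> np.ndarray:
        return np.tile(np.arange(self.n_cols), self.n_rows)

    def unit_index(self, row, col):
        """Row-major unit index; wraps on the torus, rejects out-of-range
        coordinates under zero-flux."""
        row = np.asarray(row)
        col = np.asarray(col)
        if self.boundary == "torus":
            row = row % self.n_rows
            col = col % self.n_cols
        elif np.any((row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)):
            raise IndexError("coordinates outside a zero-flux sheet")
        return row * self.n_cols + col

    def unit_coords(self, index):
        index = np.asarray(index)
        return index // self.n_cols, index % self.n_cols

    @property
    def macro_of_unit(self) -> np.ndarray:
        """Macrocolumn index of every unit."""
        return (self.rows // self.macro_edge) * self.macro_cols + self.cols // self.macro_edge

    def macro_members(self, macro_index: int) -> np.ndarray:
        return np.nonzero(self.macro_of_unit == macro_index)[0]

    def macro_center_unit(self, macro_index: int) -> int:
        mr, mc = divmod(macro_index, self.macro_cols)
        h = self.macro_edge // 2
        return int((mr * self.macro_edge + h) * self.n_cols + mc * self.macro_edge + h)

    # -- metric ----------------------------------------------------------
    def displacement(self, i, j):
        """Signed (drow, dcol) from i to j in lattice units (minimal image
        on the torus)."""
        ri, ci = self.unit_coords(np.asarray(i))
        rj, cj = self.unit_coords(np.asarray(j))
        dr = rj - ri
        dc = cj - ci
        if self.boundary == "torus":
            dr = (dr + self.n_rows // 2) % self.n_rows - self.n_rows // 2
            dc = (dc + self.n_cols // 2) % self.n_cols - self.n_cols // 2
        return dr, dc

    def distance_um(self, i, j):
        dr, dc = self.displacement(i, j)
        return self.pitch_um * np.hypot(dr, dc)

    def distances_from(self, i) -> np.ndarray:
        """Distance in um from unit ``i`` to every unit."""
        return self.distance_um(np.full(self.n_units, i), np.arange(self.n_units))

    # -- neighbourhoods --------------------------------------------------
    def disc(self, center: int, radius_units: float) -> np.ndarray:
        """Units within ``radius_units`` lattice steps of ``center``
        (Euclidean; clipped at zero-flux edges)."""
        r0, c0 = self.unit_coords(center)
        rad = int(np.floor(radius_units))
        out = []
        for dx in range(-rad, rad + 1):
            for dy in range(-rad, rad + 1):
                if np.hypot(dx, dy) > radius_units:
                    continue
                r, c = r0 + dx, c0 + dy
                if self.boundary == "torus":
                    out.append((r % self.n_rows) * self.n_cols + c % self.n_cols)
                elif 0 <= r < self.n_rows and 0 <= c < self.n_cols:
                    out.append(r * self.n_cols + c)
        return np.unique(out)

    def position_um(self, index):
        """(x, y) positions of unit centers in um (col -> x, row -> y)."""
        r, c = self.unit_coords(np.asarray(index))
        return c * self.pitch_um, r * self.pitch_um


def build_geometry(
    n_rows: int,
    n_cols: int,
    macro_edge: int = 10,
    pitch_um: float = 50.0,
    boundary: str = "torus",
) -> SheetGeometry:
    """Construct and validate a :class:`SheetGeometry`."""
    return SheetGeometry(n_rows, n_cols, macro_edge, pitch_um, boundary)
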