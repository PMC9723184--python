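"""Planar analysis grid and raster-stack containers.

All spatial data in this package live on a rectangular lattice of square
cells (1 km by default). Coordinates are planar, cell registration is
cell-center, and cell membership is half-open: a point belongs to cell
(row, col) iff x0 + col*s <= x < x0 + (col+1)*s and likewise for y, so a
boundary point belongs to exactly one cell. Cell ids are row-major
(id = row * n_cols + col) with row 0 at the grid origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np


class GridMismatchError(ValueError):
    """Two layers or maps do not share the same grid geometry."""


@dataclass(frozen=True)
class GridDefinition:
    """Rectangular lattice of square cells.

    Parameters
    ----------
    n_rows, n_cols : int
        Lattice dimensions in cells.
    cell_size : float
        Cell edge length, in km. The analysis resolution is 1 km.
    x0, y0 : float
        Planar coordinates of the grid's lower-left corner.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        """Cell area in km^2."""
        return self.cell_size * self.cell_size

    def cell_index(self, x, y):
        """Row-major cell id(s) for planar point(s); half-open membership."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        if not np.all(ok):
            raise ValueError("point(s) fall outside the grid extent")
        idx = row * self.n_cols + col
        return int(idx) if idx.ndim == 0 else idx

    def cell_center(self, cell_id):
        """(x, y) center coordinates for cell id(s)."""
        cid = np.asarray(cell_id)
        row, col = np.divmod(cid, self.n_cols)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 + (row + 0.5) * self.cell_size
        return x, y

    def same_geometry(self, other: "GridDefinition") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
        )


def _require_same_grid(a: GridDefinition, b: GridDefinition) -> None:
    if not a.same_geometry(b):
        raise GridMismatchError(
            f"grid mismatch: {a.n_rows}x{a.n_cols} cell {a.cell_size} vs "
            f"{b.n_rows}x{b.n_cols} cell {b.cell_size}"
        )


class EnvStack:
    """Named, co-registered environmental predictor layers on one grid.

    Layer names carry a group prefix separated by the first underscore,
    e.g. ``"topographic_slope"`` or ``"bioclimatic_bio12"``.
    """

    def __init__(self, grid: GridDefinition, layers: Mapping[str, np.ndarray]):
        self.grid = grid
        self._layers: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (grid.n_rows, grid.n_cols):
                raise GridMismatchError(
                    f"layer {name!r} shape {arr.shape} does not match grid "
                    f"({grid.n_rows}, {grid.n_cols})"
                )
            self._layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def n_layers(self) -> int:
        return len(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> np.ndarray:
        return self._layers[name]

    def groups(self) -> dict[str, list[str]]:
        """Map group prefix -> layer names, in insertion order."""
        out: dict[str, list[str]] = {}
        for name in self._layers:
            group = name.split("_", 1)[0]
            out.setdefault(group, []).append(name)
        return out

    def values_at(self, cell_ids, names: Iterable[str] | None = None) -> np.ndarray:
        """Feature matrix (n_points, n_layers) at the given cell ids."""
        return self.as_matrix(names)[np.asarray(cell_ids)]

    def as_matrix(self, names: Iterable[str] | None = None) -> np.ndarray:
        """(n_cells, n_layers) row-major matrix of layer values."""
        use = list(names) if names is not None else self.names
        missing = [n for n in use if n not in self._layers]
        if missing:
            raise KeyError(f"unknown layer(s): {missing}")
        return np.column_stack([self._layers[n].ravel() for n in use])

    def subset(self, names: Iterable[str]) -> "EnvStack":
        return EnvStack(self.grid, {n: self._layers[n] for n in names})


@dataclass
class LulcMap:
    """Categorical land-use/land-cover map.

    ``codes`` holds integer class codes indexing into ``classes``. The array
    may be at the analysis resolution (one value per grid cell) or at a
    finer sub-grid resolution: shape ``(n_rows*f, n_cols*f)`` for an integer
    factor ``f`` (e.g. 30-m pixels aggregated onto the 1-km lattice).
    """

    grid: GridDefinition
    classes: tuple[str, ...]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        r, c = self.codes.shape
        if r % self.grid.n_rows or c % self.grid.n_cols:
            raise GridMismatchError(
                f"LULC shape {self.codes.shape} is not an integer multiple of "
                f"the grid ({self.grid.n_rows}, {self.grid.n_cols})"
            )
        if r // self.grid.n_rows != c // self.grid.n_cols:
            raise GridMismatchError("anisotropic sub-grid factors are not supported")
        if self.codes.min() < 0 or self.codes.max() >= len(self.classes):
            raise ValueError("class codes outside the label table")

    @property
    def subgrid_factor(self) -> int:
        return self.codes.shape[0] // self.grid.n_rows

    def class_code(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise KeyError(f"unknown LULC class {label!r}") from None

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.codes.ravel(), minlength=len(self.classes))
        return {lab: int(c) for lab, c in zip(self.classes, counts)}
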