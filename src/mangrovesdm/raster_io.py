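"""ESRI ASCII grid raster I/O.

The pipeline's raster exchange format is the plain-text ESRI ASCII grid
(.asc): a 6-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by rows of values, row 1 at the *top* of the map.
Internally row 0 is at the grid origin (bottom), so rows are flipped on
read and write. Cell registration is cell-center; values round-trip within
float precision and nodata cells survive as NaN.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grids import GridDefinition, GridMismatchError

DEFAULT_NODATA = -9999.0


def write_ascii_grid(
    path, values: np.ndarray, grid: GridDefinition, nodata: float = DEFAULT_NODATA
) -> None:
    """Write a (n_rows, n_cols) array as an ESRI ASCII grid; NaN -> nodata."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_rows, grid.n_cols):
        raise GridMismatchError(
            f"array shape {values.shape} does not match grid ({grid.n_rows}, {grid.n_cols})"
        )
    out = np.where(np.isnan(values), nodata, values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x0}\n"
        f"yllcorner {grid.y0}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridDefinition]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        data = np.loadtxt(fh)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key!r}")
    grid = GridDefinition(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        x0=header.get("xllcorner", 0.0),
        y0=header.get("yllcorner", 0.0),
    )
    data = np.atleast_2d(data)[::-1]
    if data.shape != (grid.n_rows, grid.n_cols):
        raise ValueError(f"{path}: data shape {data.shape} disagrees with header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, grid


def read_stack(paths: dict[str, Path]):
    """Read several .asc layers into an EnvStack, checking alignment."""
    from .grids import EnvStack

    layers = {}
    grid = None
    for name, p in paths.items():
        arr, g = read_ascii_grid(p)
        if grid is None:
            grid = g
        elif not grid.same_geometry(g):
            raise GridMismatchError(
                f"layer {name!r}: extent {g} does not align with {grid}"
            )
        layers[name] = arr
    if grid is None:
        raise ValueError("no layers given")
    return EnvStack(grid, layers)
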