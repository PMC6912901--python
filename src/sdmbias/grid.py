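"""Raster grids and covariate stacks.

Grids live on a regular Cartesian lattice in metres. Row 0 is the *bottom*
row internally (y increases with row index); the ESRI ASCII reader/writer
handles the top-first file convention. Cell centers are at
``origin + (index + 0.5) * cell_size`` and define all point locations used
downstream (simulated signs are cell-resolved). Missing values are NaN and
are excluded from all reductions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Grid",
    "CovariateStack",
    "standardize",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
]

#: Square metres per hectare.
M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class Grid:
    """A single raster layer on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Cell values; NaN marks missing cells. Row 0 is the bottom row.
    cell_size : float
        Cell edge length in metres (default 25, i.e. 0.0625 ha cells).
    origin : (float, float)
        (x, y) of the lower-left corner of the raster, in metres.
    """

    values: np.ndarray
    cell_size: float = 25.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValueError("grid values must be a 2-D array with >= 1 cell")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "values", vals)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_cells(self) -> int:
        """Total cell count S."""
        return self.values.size

    @property
    def cell_area_ha(self) -> float:
        """Cell area a_j in hectares (25 m cells -> 0.0625 ha)."""
        return self.cell_size**2 / M2_PER_HA

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint in metres."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (x, y) of all cell-center coordinates, raveled row-major."""
        x0, y0 = self.origin
        cols = (np.arange(self.n_cols) + 0.5) * self.cell_size + x0
        rows = (np.arange(self.n_rows) + 0.5) * self.cell_size + y0
        xx, yy = np.meshgrid(cols, rows)
        return xx.ravel(), yy.ravel()

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y).

        Points on the upper/right edge are assigned to the last cell so the
        closed extent maps onto valid indices.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y - y0) / self.cell_size).astype(int)
        xmin, ymin, xmax, ymax = self.extent
        inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        if not np.all(inside):
            raise ValueError("points outside the raster extent")
        return np.clip(row, 0, self.n_rows - 1), np.clip(col, 0, self.n_cols - 1)

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.index_of(x, y)
        return self.values[row, col]


@dataclass
class CovariateStack:
    """Named collection of aligned covariate layers (the x_i(s)).

    All layers must share geometry. ``normalization_constants`` maps layer
    name to the (mean, sd) used for standardization so the same transform
    can be replayed on prediction rasters.
    """

    grids: dict[str, Grid]
    standardized: bool = False
    normalization_constants: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("stack needs at least one layer")
        ref = next(iter(self.grids.values()))
        for name, g in self.grids.items():
            if not ref.same_geometry(g):
                raise ValueError(f"layer {name!r} geometry differs from the first layer")

    @property
    def names(self) -> list[str]:
        return list(self.grids)

    @property
    def reference(self) -> Grid:
        return next(iter(self.grids.values()))

    def __getitem__(self, name: str) -> Grid:
        return self.grids[name]

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        """Stack layers into shape (n_rows, n_cols, n_layers)."""
        names = names or self.names
        return np.stack([self.grids[n].values for n in names], axis=-1)

    def values_at(self, x: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Covariate matrix (n_points, n_layers) at point locations."""
        names = names or self.names
        row, col = self.reference.index_of(x, y)
        return np.column_stack([self.grids[n].values[row, col] for n in names])


def standardize(stack: CovariateStack) -> CovariateStack:
    """Center and scale each layer to mean 0, sd 1 over non-missing cells.

    Idempotent; the (mean, sd) constants of the *original* data are kept so
    prediction rasters can be transformed identically. Constant layers are
    rejected (zero sd).
    """
    new_grids: dict[str, Grid] = {}
    constants: dict[str, tuple[float, float]] = {}
    for name, g in stack.grids.items():
        vals = g.values
        mean = float(np.nanmean(vals))
        sd = float(np.nanstd(vals))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"layer {name!r} is constant (zero sd); cannot standardize")
        new_grids[name] = replace(g, values=(vals - mean) / sd)
        prev = stack.normalization_constants.get(name)
        if prev is not None:
            # composing transforms: keep constants mapping raw -> standardized
            mu0, sd0 = prev
            constants[name] = (mu0 + mean * sd0, sd * sd0)
        else:
            constants[name] = (mean, sd)
    return CovariateStack(new_grids, standardized=True, normalization_constants=constants)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_NODATA = -9999.0


def write_ascii_grid(grid: Grid, path) -> None:
    """Write a grid as an ESRI ASCII (.asc) raster (top row first)."""
    vals = np.flipud(grid.values)  # file stores the top row first
    out = np.where(np.isnan(vals), _NODATA, vals)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII (.asc) raster."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for lineno in range(6):
            line = fh.readline()
            m = re.match(r"^\s*([A-Za-z_]+)\s+(-?\d+\.?\d*([eE][+-]?\d+)?)\s*$", line)
            if not m:
                if lineno < 5 and any(k not in header for k in ("ncols", "nrows")):
                    raise ValueError(f"{path}: malformed header at line {lineno + 1}: {line!r}")
                fh.seek(pos)
                break
            header[m.group(1).lower()] = float(m.group(2))
            pos = fh.tell()
        body = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing required header field {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data block is {body.shape}, header declares ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(body == nodata, np.nan, body)
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return Grid(np.flipud(vals), cell_size=header["cellsize"], origin=origin)


def write_stack(stack: CovariateStack, directory) -> None:
    """Write each layer of a stack as ``<name>.asc`` under ``directory``."""
    import os

    os.makedirs(directory, exist_ok=True)
    for name, g in stack.grids.items():
        write_ascii_grid(g, os.path.join(directory, f"{name}.asc"))


def read_stack(paths: dict[str, object] | None = None, directory=None) -> CovariateStack:
    """Assemble a stack from named .asc files or from a directory.

    Layers with mismatching geometry are rejected by the stack constructor.
    """
    import glob
    import os

    if paths is None:
        if directory is None:
            raise ValueError("provide either paths or directory")
        paths = {
            os.path.splitext(os.path.basename(p))[0]: p
            for p in sorted(glob.glob(os.path.join(directory, "*.asc")))
        }
        if not paths:
            raise ValueError(f"no .asc layers found in {directory}")
    grids = {name: read_ascii_grid(p) for name, p in paths.items()}
    return CovariateStack(grids)
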