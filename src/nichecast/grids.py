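"""Gridded rasters and ESRI ASCII grid I/O.

A :class:`RasterGrid` stores one gridded variable on a regular
longitude/latitude lattice (WGS84 decimal degrees).  Values are kept
row-major with the **northernmost row first**, matching the ESRI ASCII
on-disk order.  Cells holding the nodata sentinel are excluded from all
downstream statistics.

An :class:`EnvStack` is an ordered set of layers sharing one geometry —
the in-memory analogue of a directory of ``.asc`` files for one climate
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, GridFormatError, TruncationError

#: Mean Earth radius (IUGG), km — used for all spherical geometry.
EARTH_RADIUS_KM = 6371.0088


@dataclass
class RasterGrid:
    """One gridded variable: geometry plus a 2-D value array (north row first)."""

    x_ll: float
    y_ll: float
    cell_size: float
    nodata_value: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise GridFormatError("values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise GridFormatError("cell_size must be positive")
        if not (-180.0 <= self.x_ll and self.x_east <= 180.0 + 1e-9
                and -90.0 <= self.y_ll and self.y_north <= 90.0 + 1e-9):
            raise GridFormatError("grid footprint must lie within [-180,180]x[-90,90]")

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_east(self) -> float:
        return self.x_ll + self.n_cols * self.cell_size

    @property
    def y_north(self) -> float:
        return self.y_ll + self.n_rows * self.cell_size

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True on valid (non-nodata, finite) cells."""
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.values) & (self.values != self.nodata_value)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def same_geometry(self, other: "RasterGrid", check_mask: bool = True) -> bool:
        geom = (
            self.values.shape == other.values.shape
            and np.isclose(self.x_ll, other.x_ll)
            and np.isclose(self.y_ll, other.y_ll)
            and np.isclose(self.cell_size, other.cell_size)
        )
        if not geom:
            return False
        return (not check_mask) or bool(np.array_equal(self.mask, other.mask))

    def cell_center(self, i: int | np.ndarray, j: int | np.ndarray):
        """Center (lon, lat) of cell (i, j); i = 0 is the northernmost row."""
        lon = self.x_ll + (np.asarray(j) + 0.5) * self.cell_size
        lat = self.y_ll + (self.n_rows - np.asarray(i) - 0.5) * self.cell_size
        return lon, lat

    def point_to_cell(self, lon: float, lat: float):
        """Cell index (i, j) containing a point, or None if outside.

        Cells tile the footprint with half-open intervals
        [west, east) x [south, north); points on the far east/north edge
        of the grid fall outside.
        """
        j = int(np.floor((lon - self.x_ll) / self.cell_size))
        row_from_south = int(np.floor((lat - self.y_ll) / self.cell_size))
        i = self.n_rows - 1 - row_from_south
        if 0 <= i < self.n_rows and 0 <= j < self.n_cols:
            return i, j
        return None

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.x_ll, self.y_ll, self.cell_size,
                          self.nodata_value, self.values.copy())


def read_esri_ascii(path) -> RasterGrid:
    """Read an ESRI ASCII grid (``.asc``).

    Accepts both the ``xllcorner`` and ``xllcenter`` header dialects; the
    center convention is converted to the corner convention by subtracting
    half a cell.  Header keys are case-insensitive.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    tokens = text.split()
    header: dict[str, float] = {}
    pos = 0
    # header = leading alternating key/value pairs until a bare number appears
    while pos + 1 < len(tokens):
        key = tokens[pos].lower()
        if key[0].isdigit() or key[0] in "+-.":
            break
        header[key] = float(tokens[pos + 1])
        pos += 2

    def _get(corner: str, center: str | None = None):
        if corner in header:
            return header[corner], False
        if center is not None and center in header:
            return header[center], True
        raise GridFormatError(f"missing header key: {corner}")

    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridFormatError(f"missing header key: {key}")
    if "nodata_value" not in header:
        raise GridFormatError("missing header key: NODATA_value")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    x_ll, x_is_center = _get("xllcorner", "xllcenter")
    y_ll, y_is_center = _get("yllcorner", "yllcenter")
    if x_is_center:
        x_ll -= cell / 2.0
    if y_is_center:
        y_ll -= cell / 2.0

    data = np.array(tokens[pos:], dtype=float)
    if data.size != n_rows * n_cols:
        raise TruncationError(
            f"expected {n_rows * n_cols} values, found {data.size} in {path}"
        )
    values = data.reshape(n_rows, n_cols)
    return RasterGrid(x_ll, y_ll, cell, header["nodata_value"], values)


def write_esri_ascii(grid: RasterGrid, path, fmt: str = "%.10g") -> None:
    """Write a grid as an ESRI ASCII file (6 header lines, rows north first)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_ll:.10g}\n")
        fh.write(f"yllcorner {grid.y_ll:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata_value:.10g}\n")
        for row in grid.values:
            fh.write(" ".join(fmt % v for v in row))
            fh.write("\n")


@dataclass
class EnvStack:
    """An ordered map of variable name -> RasterGrid sharing one geometry."""

    layers: dict[str, RasterGrid] = field(default_factory=dict)
    scenario_label: str = "current"

    def __post_init__(self):
        names = list(self.layers)
        if names:
            ref = self.layers[names[0]]
            for name in names[1:]:
                if not self.layers[name].same_geometry(ref):
                    raise AlignmentError(
                        f"layer {name!r} does not share geometry with {names[0]!r}"
                    )

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        """Geometry reference: the first layer."""
        return next(iter(self.layers.values()))

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __len__(self) -> int:
        return len(self.layers)

    def check_aligned(self, other: "EnvStack") -> None:
        """Raise AlignmentError if the two stacks differ in geometry or layers."""
        if set(self.variables) != set(other.variables):
            missing = sorted(set(self.variables) ^ set(other.variables))
            raise AlignmentError(
                f"stacks {self.scenario_label!r} and {other.scenario_label!r} "
                f"differ in layers: {missing}"
            )
        if not self.grid.same_geometry(other.grid):
            raise AlignmentError(
                f"stacks {self.scenario_label!r} and {other.scenario_label!r} "
                "differ in grid geometry"
            )

    def values_at_cells(self, cells: np.ndarray) -> dict[str, np.ndarray]:
        """Per-variable values at an (n, 2) array of (row, col) indices."""
        i, j = np.asarray(cells)[:, 0], np.asarray(cells)[:, 1]
        return {name: g.values[i, j] for name, g in self.layers.items()}

    def copy(self, scenario_label: str | None = None) -> "EnvStack":
        new = EnvStack(
            {k: v.copy() for k, v in self.layers.items()},
            scenario_label if scenario_label is not None else self.scenario_label,
        )
        return new
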