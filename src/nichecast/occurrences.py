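"""Presence records: CSV reading, validation against a grid, per-cell thinning.

Occurrence records are (longitude, latitude) pairs in WGS84 decimal
degrees, tied to a raster geometry.  Validation drops records that are
unparseable, outside the lon/lat domain, outside the grid footprint or on
nodata cells.  Thinning keeps at most one record per grid cell — the
first in input order — mirroring the common practice of cell-level
deduplication before fitting a presence/background model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, GridFormatError
from .grids import RasterGrid

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "longitude", "latitude")


@dataclass
class OccurrenceSet:
    """Validated presence coordinates tied to a grid geometry."""

    records: np.ndarray  # (n, 2) array of (lon, lat)
    crs: str = "WGS84"
    thinned: bool = False

    def __post_init__(self):
        self.records = np.asarray(self.records, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records[:, 0]

    @property
    def lat(self) -> np.ndarray:
        return self.records[:, 1]

    def cells(self, grid: RasterGrid) -> np.ndarray:
        """(n, 2) array of (row, col) cell indices on *grid*."""
        out = np.empty((len(self), 2), dtype=int)
        for idx, (lon, lat) in enumerate(self.records):
            cell = grid.point_to_cell(lon, lat)
            if cell is None:
                raise ValueError(f"record ({lon}, {lat}) outside grid footprint")
            out[idx] = cell
        return out


def validate_against_grid(records: np.ndarray, grid: RasterGrid) -> tuple[np.ndarray, int]:
    """Keep records inside the footprint and on valid cells; return (kept, n_dropped)."""
    mask = grid.mask
    kept = []
    dropped = 0
    for lon, lat in np.asarray(records, dtype=float).reshape(-1, 2):
        if not (np.isfinite(lon) and np.isfinite(lat)) or abs(lat) > 90 or abs(lon) > 180:
            dropped += 1
            continue
        cell = grid.point_to_cell(lon, lat)
        if cell is None or not mask[cell]:
            dropped += 1
            continue
        kept.append((lon, lat))
    return np.array(kept, dtype=float).reshape(-1, 2), dropped


def read_occurrences(path, grid: RasterGrid) -> OccurrenceSet:
    """Read a presence CSV (species, longitude, latitude) and validate it.

    Records outside the grid footprint, on nodata cells, or with
    out-of-domain coordinates are dropped (the count is logged).
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise GridFormatError(f"occurrence CSV missing required column: {col}")
    raw = df[["longitude", "latitude"]].apply(pd.to_numeric, errors="coerce").to_numpy()
    kept, dropped = validate_against_grid(raw, grid)
    if dropped:
        logger.info("read_occurrences: dropped %d of %d records", dropped, len(raw))
    if len(kept) == 0:
        raise EmptyInputError(f"no valid occurrence records left from {path}")
    return OccurrenceSet(kept)


def thin_per_cell(occ: OccurrenceSet, grid: RasterGrid) -> OccurrenceSet:
    """Keep at most one record per grid cell (first in input order).

    Idempotent: thinning a thinned set is the identity.
    """
    seen: set[tuple[int, int]] = set()
    kept = []
    for lon, lat in occ.records:
        cell = grid.point_to_cell(lon, lat)
        if cell is None:
            continue
        if cell not in seen:
            seen.add(cell)
            kept.append((lon, lat))
    logger.info("thin_per_cell: %d -> %d records", len(occ), len(kept))
    return OccurrenceSet(np.array(kept).reshape(-1, 2), crs=occ.crs, thinned=True)


def write_occurrences(occ: OccurrenceSet, path, species: str = "synthetic_species") -> None:
    """Write records as a MaxEnt-style samples CSV (species, longitude, latitude)."""
    df = pd.DataFrame(
        {"species": species, "longitude": occ.lon, "latitude": occ.lat}
    )
    df.to_csv(path, index=False, float_format="%.10g")
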