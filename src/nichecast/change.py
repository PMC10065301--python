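"""Temporal comparison of suitability maps.

Given classified maps for two periods, this module computes the
stable/expand/shrink/never overlay, area-weighted change proportions,
the full 4x4 class-transition area matrix, and centroid trajectories of
the most suitable class (area-weighted cell-center means, great-circle
displacement with initial bearing and an 8-sector compass word).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, NichecastError
from .grids import EARTH_RADIUS_KM, RasterGrid
from .suitability import ClassifiedMap, area_grid

# overlay codes
NEVER, STABLE, EXPAND, SHRINK = 0, 1, 2, 3
OVERLAY_NAMES = {NEVER: "never", STABLE: "stable", EXPAND: "expand", SHRINK: "shrink"}

COMPASS_8 = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


def binary_suitable(classified: ClassifiedMap) -> np.ndarray:
    """Boolean mask: suitable = class in {poor, moderate, most}."""
    return classified.classes.mask & (classified.classes.values >= 1)


@dataclass
class ChangeMap:
    """4-way temporal overlay raster (never/stable/expand/shrink)."""

    classes: RasterGrid
    source_pair: tuple[str, str]

    def mask_of(self, code: int) -> np.ndarray:
        return self.classes.mask & (self.classes.values == code)

    def counts(self) -> dict[str, int]:
        return {OVERLAY_NAMES[c]: int(self.mask_of(c).sum()) for c in range(4)}


def _check_geometry(a: RasterGrid, b: RasterGrid) -> None:
    if not a.same_geometry(b):
        raise AlignmentError("maps do not share grid geometry")


def overlay(current: np.ndarray, future: np.ndarray, grid: RasterGrid,
            labels: tuple[str, str] = ("current", "future")) -> ChangeMap:
    """Per-cell truth table of two suitable masks on one geometry.

    Conservation: |stable| + |shrink| = |current|, |stable| + |expand| = |future|.
    """
    if current.shape != future.shape or current.shape != grid.values.shape:
        raise AlignmentError("masks and grid must share shape")
    mask = grid.mask
    vals = np.full(grid.values.shape, grid.nodata_value)
    code = np.where(current & future, STABLE,
                    np.where(current & ~future, SHRINK,
                             np.where(~current & future, EXPAND, NEVER)))
    vals[mask] = code[mask].astype(float)
    out = RasterGrid(grid.x_ll, grid.y_ll, grid.cell_size, grid.nodata_value, vals)
    return ChangeMap(out, labels)


def change_proportions(change: ChangeMap) -> dict[str, float | None]:
    """Area-weighted stable/current, shrink/current and expand/future ratios (%).

    Denominators follow the names: current-suitable area for stable and
    shrink, future-suitable area for expand.  A zero denominator yields
    None (undefined).
    """
    areas = area_grid(change.classes)
    a = {name: float(areas[change.mask_of(code)].sum())
         for code, name in OVERLAY_NAMES.items()}
    current = a["stable"] + a["shrink"]
    future = a["stable"] + a["expand"]
    return {
        "stable_pct_of_current": 100.0 * a["stable"] / current if current > 0 else None,
        "shrink_pct_of_current": 100.0 * a["shrink"] / current if current > 0 else None,
        "expand_pct_of_future": 100.0 * a["expand"] / future if future > 0 else None,
    }


def class_transition(current: ClassifiedMap, future: ClassifiedMap) -> np.ndarray:
    """4x4 matrix M[c_from, c_to] of area (10^4 km^2) moving between classes.

    Row sums equal current per-class areas; column sums future per-class
    areas (valid cells only).
    """
    _check_geometry(current.classes, future.classes)
    if current.breaks != future.breaks:
        raise AlignmentError("classified maps use different class breaks")
    grid = current.classes
    areas = area_grid(grid)
    mask = grid.mask & future.classes.mask
    c_from = current.classes.values[mask].astype(int)
    c_to = future.classes.values[mask].astype(int)
    w = areas[mask]
    M = np.zeros((4, 4))
    np.add.at(M, (c_from, c_to), w)
    return M / 1e4


def centroid(classified: ClassifiedMap, target_class: int = 3) -> tuple[float, float]:
    """Area-weighted mean cell-center (lon, lat) of one class."""
    mask = classified.class_mask(target_class)
    if not mask.any():
        raise NichecastError(f"class {target_class} ({target_class}) is empty")
    grid = classified.classes
    i, j = np.nonzero(mask)
    lon, lat = grid.cell_center(i, j)
    w = area_grid(grid)[mask]
    return float(np.average(lon, weights=w)), float(np.average(lat, weights=w))


# ---------------------------------------------------------------------------
# spherical displacement
# ---------------------------------------------------------------------------

def haversine_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between (lon, lat) points."""
    lon1, lat1, lon2, lat2 = map(np.radians, (p1[0], p1[1], p2[0], p2[1]))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def initial_bearing_deg(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Initial great-circle bearing from north, clockwise, in [0, 360)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (p1[0], p1[1], p2[0], p2[1]))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return float(np.degrees(np.arctan2(x, y)) % 360.0)


def compass_8(bearing_deg: float) -> str:
    """Nearest of 8 compass sectors (45-degree sectors centered on each)."""
    return COMPASS_8[int(np.floor((bearing_deg + 22.5) / 45.0)) % 8]


def displacement(p1: tuple[float, float], p2: tuple[float, float]):
    """(distance km, initial bearing deg, compass word or None if coincident)."""
    d = haversine_km(p1, p2)
    if d == 0.0:
        return 0.0, 0.0, None
    b = initial_bearing_deg(p1, p2)
    return d, b, compass_8(b)


@dataclass
class CentroidTrack:
    """Ordered centroids of the top class across scenarios, with segments."""

    points: list[tuple[str, float, float]]  # (label, lon, lat)
    segments: list[tuple[float, float, str | None]]  # (km, bearing, compass)

    @property
    def overall(self):
        """First-to-last displacement."""
        if len(self.points) < 2:
            return 0.0, 0.0, None
        return displacement(self.points[0][1:], self.points[-1][1:])


def centroid_track(classified_maps: list[tuple[str, ClassifiedMap]],
                   target_class: int = 3) -> CentroidTrack:
    """Centroid trajectory over scenario-ordered classified maps."""
    if not classified_maps:
        raise NichecastError("centroid_track requires at least one map")
    points = []
    for label, cmap in classified_maps:
        try:
            lon, lat = centroid(cmap, target_class)
        except NichecastError as exc:
            raise NichecastError(f"empty target class in scenario {label!r}") from exc
        points.append((label, lon, lat))
    segments = [displacement(points[k][1:], points[k + 1][1:])
                for k in range(len(points) - 1)]
    return CentroidTrack(points, segments)
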