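"""Suitability zoning and area statistics.

The continuous cloglog prediction is binarised at the threshold P that
maximises sensitivity + specificity (background treated as
pseudo-absence), then subdivided into the standard four classes:

    unsuitable  [0, P)        class 0
    poor        [P, 0.33)     class 1
    moderate    [0.33, 0.66)  class 2
    most        [0.66, 1]     class 3

Class areas are computed in spherical geometry (per-row cell area
R^2 * dlon * (sin lat_n - sin lat_s), R = 6371.0088 km) and reported in
10^4 km^2 with shares of the total suitable area and percent changes
against a baseline, rounded half-away-from-zero to two decimals
(printed with one decimal when the second is zero).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import NichecastError
from .grids import EARTH_RADIUS_KM, RasterGrid

logger = logging.getLogger(__name__)

DEFAULT_BREAKS = (0.33, 0.66)

CLASS_NAMES = {0: "unsuitable", 1: "poor", 2: "moderate", 3: "most"}


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def max_sss_threshold(scores_presence, scores_background) -> float:
    """Threshold maximising sensitivity(t) + specificity(t).

    Candidates are all distinct observed scores; sensitivity is the
    presence fraction with score >= t, specificity the background
    fraction with score < t.  Ties among maximisers return the smallest
    threshold.  A fully degenerate input (all scores identical) returns
    that constant with a warning.
    """
    sp = np.sort(np.asarray(scores_presence, dtype=float))
    sb = np.sort(np.asarray(scores_background, dtype=float))
    if sp.size == 0 or sb.size == 0:
        raise NichecastError("max_sss_threshold requires non-empty score lists")
    cand = np.unique(np.concatenate([sp, sb]))
    if cand.size == 1:
        warnings.warn("all scores identical; maxSSS threshold is degenerate")
        return float(cand[0])
    # sens = #presences >= t / n_p ; spec = #background < t / n_b.
    # Integer scoring (common denominator n_p*n_b) keeps ties exact, and
    # argmax then returns the first (smallest t) maximiser.
    n_ge = sp.size - np.searchsorted(sp, cand, side="left")
    n_lt = np.searchsorted(sb, cand, side="left")
    total = n_ge * sb.size + n_lt * sp.size
    return float(cand[np.argmax(total)])


@dataclass
class ClassifiedMap:
    """4-class suitability raster with its threshold and class breaks."""

    classes: RasterGrid  # values in {0,1,2,3}, nodata preserved
    threshold_P: float
    breaks: tuple[float, float] = DEFAULT_BREAKS

    def class_mask(self, cls: int) -> np.ndarray:
        return self.classes.mask & (self.classes.values == cls)

    def counts(self) -> dict[int, int]:
        return {c: int(self.class_mask(c).sum()) for c in range(4)}


def classify(suitability: RasterGrid, P: float,
             breaks: tuple[float, float] = DEFAULT_BREAKS) -> ClassifiedMap:
    """Bin a continuous suitability map into the four classes.

    Cells below P are unsuitable regardless of the fixed breaks; if
    P >= breaks[0] the poor class is structurally empty (logged).
    """
    if not (0.0 < P < 1.0):
        raise NichecastError(f"threshold P must lie in (0,1), got {P}")
    lo, hi = breaks
    if not (0.0 < lo < hi < 1.0):
        raise NichecastError(f"breaks must be strictly increasing in (0,1), got {breaks}")
    if P >= lo:
        logger.info("classify: P=%.4f >= %.2f, the poor class is structurally empty", P, lo)
    mask = suitability.mask
    p = suitability.values
    suitable = mask & (p >= P)
    cls = np.where(suitable, 1.0 + (p >= lo) + (p >= hi), 0.0)
    cls[~mask] = suitability.nodata_value
    grid = RasterGrid(suitability.x_ll, suitability.y_ll, suitability.cell_size,
                      suitability.nodata_value, cls)
    return ClassifiedMap(grid, P, breaks)


# ---------------------------------------------------------------------------
# areas
# ---------------------------------------------------------------------------

def cell_areas(grid: RasterGrid) -> np.ndarray:
    """Per-row cell area in km^2 (north row first); constant within a row."""
    rows = np.arange(grid.n_rows)
    lat_n = grid.y_ll + (grid.n_rows - rows) * grid.cell_size
    lat_s = lat_n - grid.cell_size
    if lat_n.max() > 90.0 + 1e-9 or lat_s.min() < -90.0 - 1e-9:
        raise NichecastError("grid rows extend past a pole")
    dlam = np.radians(grid.cell_size)
    return (EARTH_RADIUS_KM**2 * dlam
            * (np.sin(np.radians(lat_n)) - np.sin(np.radians(lat_s))))


def area_grid(grid: RasterGrid) -> np.ndarray:
    """Cell areas broadcast to the full (rows, cols) shape, km^2."""
    return np.repeat(cell_areas(grid)[:, None], grid.n_cols, axis=1)


def percent_change(new: float, baseline: float) -> float:
    """The report's change rule: (new - baseline) / baseline * 100."""
    if baseline <= 0:
        raise NichecastError("percent change undefined for a non-positive baseline")
    return 100.0 * (new - baseline) / baseline


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the printed-table convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_printed(x: float) -> str:
    """2-decimal half-away rounding, trailing zero trimmed to 1 decimal."""
    r = round_half_away(x, 2)
    s = f"{r:.2f}"
    if s.endswith("0"):
        s = s[:-1]
    return s


# ---------------------------------------------------------------------------
# area report
# ---------------------------------------------------------------------------

@dataclass
class AreaReport:
    """Per-class suitable areas (10^4 km^2), shares and changes vs baseline."""

    class_areas: dict[str, float]  # poor / moderate / most, in 10^4 km^2
    total_suitable: float
    shares: dict[str, float] = field(default_factory=dict)  # % of total suitable
    percent_change: dict[str, float | None] | None = None  # vs baseline, incl. "total"

    @classmethod
    def from_class_areas(cls, most: float, moderate: float, poor: float,
                         baseline: "AreaReport | None" = None) -> "AreaReport":
        """Build a report from per-class areas already in 10^4 km^2 (e.g. a
        published table) using the same share/change arithmetic as the
        raster path."""
        areas = {"poor": poor, "moderate": moderate, "most": most}
        return _finish_report(areas, baseline)

    def printed_shares(self) -> dict[str, str]:
        return {k: format_printed(v) for k, v in self.shares.items()}

    def printed_changes(self) -> dict[str, str]:
        if self.percent_change is None:
            return {}
        return {k: format_printed(v) for k, v in self.percent_change.items()
                if v is not None}


def _finish_report(areas: dict[str, float], baseline: "AreaReport | None") -> AreaReport:
    total = sum(areas.values())
    shares = {k: (100.0 * v / total if total > 0 else float("nan"))
              for k, v in areas.items()}
    change = None
    if baseline is not None:
        change = {}
        base = dict(baseline.class_areas)
        base["total"] = baseline.total_suitable
        cur = dict(areas)
        cur["total"] = total
        for k in cur:
            if base.get(k, 0.0) > 0:
                change[k] = 100.0 * (cur[k] - base[k]) / base[k]
            else:
                change[k] = None  # undefined against a zero baseline
    return AreaReport(areas, total, shares, change)


def area_report(classified: ClassifiedMap, baseline: AreaReport | None = None) -> AreaReport:
    """Spherical-geometry class areas in 10^4 km^2, shares of total suitable,
    and percent change per class (and total) against a baseline report."""
    grid = classified.classes
    areas_km2 = area_grid(grid)
    out = {}
    for c in (1, 2, 3):
        out[CLASS_NAMES[c]] = float(areas_km2[classified.class_mask(c)].sum()) / 1e4
    return _finish_report(out, baseline)
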