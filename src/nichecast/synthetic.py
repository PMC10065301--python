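"""Synthetic landscapes with a known niche truth.

Every downstream stage of the pipeline (feature expansion, maxent fit,
thresholding, zoning, range-shift analytics) is exercised against stacks
generated here, where the data-generating niche is known exactly:

* environmental layers are smooth Gaussian random fields (white noise
  smoothed by an isotropic Gaussian kernel with reflecting boundaries),
  standardised over valid cells, then linearly mixed so that requested
  pairwise Pearson correlations are achieved *exactly* in sample (the
  base fields are empirically orthonormalised before mixing);
* the true suitability is a Gibbs density exp(s(x))/Z with log-density
  s(x) = sum_v w_v * g(v(x)), g the identity (linear style) or the
  negated squared deviation from a per-variable optimum (unimodal);
* presences are multinomial draws from that density, placed at cell
  centers so thinning and value extraction are exactly reproducible;
* "future" stacks shift named layers by additive offsets, emulating
  warming/precipitation scenarios on the current landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import SpecificationError
from .grids import EnvStack, RasterGrid
from .occurrences import OccurrenceSet


@dataclass
class TruthSpec:
    """The data-generating niche: weights, optima, correlation targets, shifts."""

    true_weights: dict[str, float] = field(default_factory=dict)
    optimum_style: str = "linear"  # "linear" | "unimodal"
    optima: dict[str, float] = field(default_factory=dict)
    target_pairwise_r: dict[tuple[str, str], float] = field(default_factory=dict)
    smoothness: float = 3.0  # spatial autocorrelation length, in cells
    warming_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.optimum_style not in ("linear", "unimodal"):
            raise SpecificationError(
                f"optimum_style must be 'linear' or 'unimodal', got {self.optimum_style!r}"
            )
        for pair, r in self.target_pairwise_r.items():
            if not abs(r) < 1.0:
                raise SpecificationError(
                    f"target correlation for {pair} must lie in (-1, 1), got {r}"
                )


def default_geometry(n_rows: int = 100, n_cols: int = 100,
                     cell_size: float = 0.05, x_ll: float = 100.0,
                     y_ll: float = 22.0) -> RasterGrid:
    """A desk-scale subtropical window (defaults: 100x100 cells of 0.05 deg)."""
    return RasterGrid(x_ll, y_ll, cell_size, -9999.0,
                      np.zeros((n_rows, n_cols)))


def layer_names(n_layers: int) -> list[str]:
    return [f"env{k + 1:02d}" for k in range(n_layers)]


def _correlation_matrix(names: list[str], targets: dict[tuple[str, str], float]) -> np.ndarray:
    idx = {n: k for k, n in enumerate(names)}
    C = np.eye(len(names))
    for (a, b), r in targets.items():
        if a not in idx or b not in idx:
            raise SpecificationError(f"correlation target names unknown layer: {(a, b)}")
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    eigmin = np.linalg.eigvalsh(C).min()
    if eigmin < -1e-10:
        raise SpecificationError(
            f"target correlation matrix is not positive semi-definite (min eig {eigmin:.3g})"
        )
    return C


def make_env_stack(n_layers: int, geometry: RasterGrid, spec: TruthSpec,
                   seed: int, scenario_label: str = "current") -> EnvStack:
    """Generate smooth, standardised, exactly-correlated environmental layers.

    Deterministic given ``seed``.  Each layer has mean 0 and variance 1
    over valid cells; pairs named in ``spec.target_pairwise_r`` attain
    their target sample Pearson r exactly.
    """
    if n_layers < 1:
        raise SpecificationError("n_layers must be >= 1")
    names = layer_names(n_layers)
    C = _correlation_matrix(names, spec.target_pairwise_r)
    rng = np.random.default_rng(seed)
    mask = geometry.mask
    n_valid = int(mask.sum())
    if n_valid <= n_layers:
        raise SpecificationError("geometry has too few valid cells for the layer count")

    # smooth base fields on the full rectangle, then restrict to valid cells
    base = np.empty((n_valid, n_layers))
    for k in range(n_layers):
        fld = gaussian_filter(rng.standard_normal(geometry.values.shape),
                              sigma=spec.smoothness, mode="reflect")
        base[:, k] = fld[mask]
    # empirical orthonormalisation -> mixing achieves target correlations exactly
    base -= base.mean(axis=0)
    Q, _ = np.linalg.qr(base)
    Q *= np.sqrt(n_valid)  # unit sample variance per column
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n_layers))
    mixed = Q @ L.T

    layers: dict[str, RasterGrid] = {}
    for k, name in enumerate(names):
        vals = np.full(geometry.values.shape, geometry.nodata_value)
        vals[mask] = mixed[:, k]
        layers[name] = RasterGrid(geometry.x_ll, geometry.y_ll,
                                  geometry.cell_size, geometry.nodata_value, vals)
    return EnvStack(layers, scenario_label)


def true_suitability(stack: EnvStack, spec: TruthSpec) -> RasterGrid:
    """The generating density over valid cells (sums to 1), as a raster.

    Log-density s(x) = sum_v w_v * g(v(x)); density = exp(s)/Z.  With all
    weights zero this is the uniform density 1/N.
    """
    missing = set(spec.true_weights) - set(stack.variables)
    if missing:
        raise SpecificationError(f"truth names unknown layers: {sorted(missing)}")
    grid = stack.grid
    mask = grid.mask
    s = np.zeros(int(mask.sum()))
    for name, w in spec.true_weights.items():
        v = stack[name].values[mask]
        if spec.optimum_style == "unimodal":
            opt = spec.optima.get(name, 0.0)
            s += w * (-((v - opt) ** 2))
        else:
            s += w * v
    s -= s.max()
    dens = np.exp(s)
    dens /= dens.sum()
    vals = np.full(grid.values.shape, grid.nodata_value)
    vals[mask] = dens
    return RasterGrid(grid.x_ll, grid.y_ll, grid.cell_size, grid.nodata_value, vals)


def sample_occurrences(truth: RasterGrid, n: int, seed: int) -> OccurrenceSet:
    """Draw n presence cells ~ density (with replacement), at cell centers."""
    if n < 1:
        raise SpecificationError("n must be >= 1")
    mask = truth.mask
    dens = truth.values[mask]
    total = dens.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise SpecificationError(f"density must sum to 1 (got {total:.6f})")
    rng = np.random.default_rng(seed)
    flat_idx = np.flatnonzero(mask.ravel())
    draws = rng.choice(flat_idx, size=n, replace=True, p=dens / total)
    i, j = np.unravel_index(draws, truth.values.shape)
    lon, lat = truth.cell_center(i, j)
    return OccurrenceSet(np.column_stack([lon, lat]))


def sample_thinned_occurrences(truth: RasterGrid, n: int, seed: int,
                               max_draw_rounds: int = 200) -> OccurrenceSet:
    """Draw presences until exactly n distinct cells are occupied.

    Emulates a cell-thinned compilation of records: multinomial draws
    from the density, deduplicated in draw order, topped up until n
    distinct cells are reached.  Returns a thinned OccurrenceSet.
    """
    mask = truth.mask
    if int(mask.sum()) < n:
        raise SpecificationError("fewer valid cells than requested thinned presences")
    rng = np.random.default_rng(seed)
    dens = truth.values[mask]
    nonzero = int((dens > 0).sum())
    if nonzero < n:
        raise SpecificationError(
            f"density has only {nonzero} cells with positive mass (< n={n})")
    flat_idx = np.flatnonzero(mask.ravel())
    seen: list[int] = []
    seen_set: set[int] = set()
    for _ in range(max_draw_rounds):
        draws = rng.choice(flat_idx, size=n, replace=True, p=dens / dens.sum())
        for d in draws:
            if int(d) not in seen_set:
                seen_set.add(int(d))
                seen.append(int(d))
                if len(seen) == n:
                    break
        if len(seen) == n:
            break
    else:  # pragma: no cover - density too concentrated
        raise SpecificationError("could not occupy n distinct cells; density too peaked")
    i, j = np.unravel_index(np.array(seen), truth.values.shape)
    lon, lat = truth.cell_center(i, j)
    return OccurrenceSet(np.column_stack([lon, lat]), thinned=True)


def gradient_layer(geometry: RasterGrid, direction: str = "east") -> RasterGrid:
    """A deterministic standardised coordinate ramp (mean 0, var 1 on valid
    cells); 'east' increases with longitude, 'north' with latitude.

    Useful to build niches whose response to a uniform shift has a known
    spatial direction (e.g. an eastward habitat displacement).
    """
    if direction not in ("east", "north"):
        raise SpecificationError("direction must be 'east' or 'north'")
    rows, cols = geometry.values.shape
    if direction == "east":
        ramp = np.tile(np.arange(cols, dtype=float), (rows, 1))
    else:
        ramp = np.tile(np.arange(rows, 0, -1, dtype=float)[:, None], (1, cols))
    mask = geometry.mask
    v = ramp[mask]
    ramp = (ramp - v.mean()) / v.std()
    vals = np.full(geometry.values.shape, geometry.nodata_value)
    vals[mask] = ramp[mask]
    return RasterGrid(geometry.x_ll, geometry.y_ll, geometry.cell_size,
                      geometry.nodata_value, vals)


def make_future_stack(stack: EnvStack, spec: TruthSpec, scenario_label: str,
                      noise_sd: float = 0.0, seed: int | None = None) -> EnvStack:
    """Additively shift named layers (warming/precipitation analogue).

    Geometry and nodata mask are unchanged; with ``noise_sd`` > 0 a small
    seeded smooth noise field is added on top of the offsets.
    """
    unknown = set(spec.warming_shift) - set(stack.variables)
    if unknown:
        raise SpecificationError(f"warming_shift names unknown layers: {sorted(unknown)}")
    out = stack.copy(scenario_label)
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    for name, offset in spec.warming_shift.items():
        g = out.layers[name]
        mask = g.mask
        g.values[mask] += offset
        if rng is not None:
            noise = gaussian_filter(rng.standard_normal(g.values.shape),
                                    sigma=spec.smoothness, mode="reflect")
            sd = noise[mask].std()
            if sd > 0:
                g.values[mask] += noise_sd * noise[mask] / sd
    return out


# ---------------------------------------------------------------------------
# default study conditions: a desk-scale analogue of the real analysis
# ---------------------------------------------------------------------------

def default_truth(n_layers: int = 8) -> TruthSpec:
    """The default generating niche used across the analysis scripts.

    Two informative drivers (a thermal and a moisture analogue) plus
    noise layers; two layer pairs are near-duplicates (r = 0.9) to
    exercise the collinearity filter; future scenarios warm the thermal
    driver and dry the moisture driver in proportion to emissions.
    """
    names = layer_names(n_layers)
    weights = {names[0]: 4.0, names[1]: 2.0}
    targets = {}
    if n_layers >= 4:
        targets[(names[0], names[2])] = 0.9
    if n_layers >= 6:
        targets[(names[1], names[3])] = 0.9
    return TruthSpec(
        true_weights=weights,
        optimum_style="unimodal",
        optima={names[0]: 0.8, names[1]: 0.5},
        target_pairwise_r=targets,
        smoothness=6.0,
        warming_shift={names[0]: 0.6, names[1]: -0.3},
    )


def scenario_shifts() -> dict[str, float]:
    """Relative shift magnitude per future scenario (1 = default_truth shift)."""
    return {"2050s-SSP1-2.6": 0.5, "2050s-SSP2-4.5": 1.0, "2050s-SSP5-8.5": 1.8}


def make_scenario_suite(seed: int, n_rows: int = 100, n_cols: int = 100,
                        n_layers: int = 8, n_presences: int = 123,
                        spec: TruthSpec | None = None):
    """Generate the full synthetic study: current + future stacks, presences.

    Returns (stacks: dict label->EnvStack, occurrences, truth_density, spec).
    Presence count defaults to 123 post-thinning-scale records, mirroring
    a cell-thinned herbarium compilation at desk scale.
    """
    spec = spec if spec is not None else default_truth(n_layers)
    geometry = default_geometry(n_rows, n_cols)
    current = make_env_stack(n_layers, geometry, spec, seed)
    stacks = {"current": current}
    for label, scale in scenario_shifts().items():
        scaled = TruthSpec(
            true_weights=spec.true_weights,
            optimum_style=spec.optimum_style,
            optima=spec.optima,
            target_pairwise_r={},
            smoothness=spec.smoothness,
            warming_shift={k: v * scale for k, v in spec.warming_shift.items()},
        )
        stacks[label] = make_future_stack(current, scaled, label)
    truth = true_suitability(current, spec)
    occ = sample_thinned_occurrences(truth, n_presences, seed + 1)
    return stacks, occ, truth, spec


# ---------------------------------------------------------------------------
# toy fixture: a fully enumerated 6x6 worked example
# ---------------------------------------------------------------------------

def make_toy_fixture():
    """A tiny fully enumerated fixture with hand-checkable expected values.

    Returns (stack, occurrences, expected) where ``expected`` holds values
    recomputed here by plain-Python enumeration (independent of the
    vectorised implementations under test): thinned count, maxSSS
    threshold, per-class cell counts, overlay counts against a one-column
    eastward shift, and the area-weighted centroid of the top class.
    """
    n, cell = 6, 0.5
    x_ll, y_ll, nodata = 100.0, 20.0, -9999.0
    temp = np.array([[float(j) for j in range(n)] for _ in range(n)])
    prec = np.array([[float(n - 1 - i) for _ in range(n)] for i in range(n)])
    for i, j in [(0, 0), (5, 5)]:  # two nodata holes
        temp[i, j] = nodata
        prec[i, j] = nodata
    stack = EnvStack(
        {
            "temp": RasterGrid(x_ll, y_ll, cell, nodata, temp.copy()),
            "prec": RasterGrid(x_ll, y_ll, cell, nodata, prec.copy()),
        },
        "toy",
    )
    grid = stack.grid

    # suitability p = mean of the two 0-1 scaled layers, on valid cells
    p = np.full((n, n), nodata)
    for i in range(n):
        for j in range(n):
            if temp[i, j] != nodata:
                p[i, j] = (temp[i, j] / (n - 1) + prec[i, j] / (n - 1)) / 2.0
    suit = RasterGrid(x_ll, y_ll, cell, nodata, p.copy())

    # 8 occurrence points, two sharing cell (1, 4): expect 7 after thinning
    occ_cells = [(1, 4), (1, 4), (0, 4), (2, 3), (2, 4), (3, 3), (1, 3), (4, 1)]
    pts = []
    for i, j in occ_cells:
        lon = x_ll + (j + 0.5) * cell
        lat = y_ll + (n - i - 0.5) * cell
        pts.append((lon, lat))
    occ = OccurrenceSet(np.array(pts))

    # --- expected values by plain enumeration -------------------------------
    expected: dict = {}
    expected["n_raw"] = len(occ_cells)
    expected["n_thinned"] = len(set(occ_cells))

    pres_scores = sorted(p[i, j] for i, j in set(occ_cells))
    bg_scores = [p[i, j] for i in range(n) for j in range(n) if p[i, j] != nodata]
    best_t, best_s = None, -np.inf
    for t in sorted(set(pres_scores) | set(bg_scores)):
        sens = sum(1 for s in pres_scores if s >= t) / len(pres_scores)
        spcf = sum(1 for s in bg_scores if s < t) / len(bg_scores)
        if sens + spcf > best_s + 1e-12:
            best_s, best_t = sens + spcf, t
    expected["maxsss_threshold"] = best_t

    P = best_t
    counts = {0: 0, 1: 0, 2: 0, 3: 0}
    cls = np.full((n, n), -1)
    for i in range(n):
        for j in range(n):
            if p[i, j] == nodata:
                continue
            v = p[i, j]
            c = 0 if v < P else (1 if v < 0.33 else (2 if v < 0.66 else 3))
            counts[c] += 1
            cls[i, j] = c
    expected["class_cell_counts"] = counts

    # overlay vs a one-column-west shift of the suitable mask
    cur = {(i, j) for i in range(n) for j in range(n) if cls[i, j] >= 1}
    fut = {(i, j - 1) for (i, j) in cur if j - 1 >= 0 and p[i, j - 1] != nodata}
    valid = {(i, j) for i in range(n) for j in range(n) if p[i, j] != nodata}
    expected["overlay_counts"] = {
        "stable": len(cur & fut),
        "shrink": len(cur - fut),
        "expand": len(fut - cur),
        "never": len(valid - cur - fut),
    }
    expected["future_mask_cells"] = sorted(fut)

    # area-weighted centroid of the top class (row area by spherical formula)
    import math

    R = 6371.0088
    dlam = math.radians(cell)
    tot = wlon = wlat = 0.0
    for i in range(n):
        for j in range(n):
            if cls[i, j] == 3:
                lat_n = math.radians(y_ll + (n - i) * cell)
                lat_s = math.radians(y_ll + (n - i - 1) * cell)
                a = R * R * dlam * (math.sin(lat_n) - math.sin(lat_s))
                lon_c = x_ll + (j + 0.5) * cell
                lat_c = y_ll + (n - i - 0.5) * cell
                tot += a
                wlon += a * lon_c
                wlat += a * lat_c
    expected["centroid_most"] = (wlon / tot, wlat / tot)

    return stack, occ, suit, expected
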